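"""Bundled reference dataset: published tail fits for ten long novels.

The package ships the per-text power-law fit parameters reported in the
quantitative-linguistics literature for ten long single-author novels in
four languages (words vs lemmas). They serve as the canonical input to the
cross-text comparison battery and as a self-verification surface: every
downstream statistic can be recomputed from these printed values.
"""

from __future__ import annotations

from importlib.resources import files

import numpy as np
import pandas as pd

from .powerlaw import TailFit

__all__ = ["load_reference_fits", "reference_tail_fits"]

_DATA = files("zipflemma") / "data" / "novel_tail_fits.tsv"


def load_reference_fits() -> pd.DataFrame:
    """The reference table as a DataFrame, one row per novel."""
    with _DATA.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def reference_tail_fits() -> tuple[list[TailFit], list[TailFit]]:
    """The reference table as aligned (word, lemma) TailFit lists.

    KS distances and p-values are not part of the published table and are
    reported as NaN; ``n_sims`` and ``seed`` are zeroed for the same reason.
    """
    df = load_reference_fits()
    fits_w, fits_l = [], []
    for _, row in df.iterrows():
        fits_w.append(
            TailFit(a=int(row.a_w), gamma_hat=float(row.gamma_w), sigma=float(row.sigma_w),
                    ks=np.nan, p_value=np.nan, N_a=int(row.N_aw), n_m=int(row.n_mw),
                    n_sims=0, seed=0, label=str(row.label))
        )
        fits_l.append(
            TailFit(a=int(row.a_l), gamma_hat=float(row.gamma_l), sigma=float(row.sigma_l),
                    ks=np.nan, p_value=np.nan, N_a=int(row.N_al), n_m=int(row.n_ml),
                    n_sims=0, seed=0, label=str(row.label))
        )
    return fits_w, fits_l
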