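"""Empirical frequency spectra f(n) and the moment-rescaling collapse.

The spectrum of a frequency table gives, for each observed frequency ``n``,
the fraction ``f(n)`` of types with that frequency. Rescaling both axes by
moment ratios,

    x = n <n> / <n^2>        y = f(n) <n^2>^2 / <n>^3,

is a pure shift in log-log coordinates, so it preserves any power-law shape;
when two distributions share a tail exponent their rescaled tails collapse
onto a single curve. ``collapse_distance`` quantifies that visual collapse
as a mean absolute log10 discrepancy over the overlapping upper decades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus_stats import FrequencyTable

__all__ = ["Spectrum", "empirical_spectrum", "rescale_spectrum", "collapse_distance", "write_spectrum_tsv"]


@dataclass(frozen=True)
class Spectrum:
    """Pairs ``(n, f(n))`` over raw integer frequencies, plus table moments."""

    n: np.ndarray
    f: np.ndarray
    mean_n: float
    mean_n2: float
    x: np.ndarray | None = None
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(self.n) <= 0):
            raise ValueError("n values must be strictly increasing")

    @property
    def rescaled(self) -> bool:
        return self.x is not None


def empirical_spectrum(table: FrequencyTable) -> Spectrum:
    """Spectrum f(n) = (number of types with count n) / V."""
    counts = table.values()
    uniq, mult = np.unique(counts, return_counts=True)
    return Spectrum(
        n=uniq.astype(np.int64),
        f=mult / table.V,
        mean_n=table.mean_n,
        mean_n2=table.mean_n2,
    )


def rescale_spectrum(spec: Spectrum) -> Spectrum:
    """Attach the moment-rescaled coordinates (x, y) to a spectrum."""
    if spec.mean_n <= 0 or spec.mean_n2 <= 0:
        raise ValueError("moments must be positive to rescale")
    x = spec.n * spec.mean_n / spec.mean_n2
    y = spec.f * spec.mean_n2**2 / spec.mean_n**3
    return Spectrum(n=spec.n, f=spec.f, mean_n=spec.mean_n, mean_n2=spec.mean_n2, x=x, y=y)


def _binned_log_y(spec: Spectrum, edges: np.ndarray, min_points: int = 3) -> np.ndarray:
    """log10 of the bin-averaged rescaled spectrum, NaN for unusable bins.

    In the sparse upper tail the raw spectrum is a set of isolated spikes of
    height 1/V, not a density; averaging the bin mass over *all* integer
    frequency sites falling in the bin (occupied or not) restores a density
    estimate that is comparable across vocabulary sizes. Bins carried by
    fewer than ``min_points`` occupied sites — typically the single extreme
    draw — are too noisy to compare and are dropped.
    """
    scale = spec.mean_n2 / spec.mean_n  # x = n / scale
    out = np.full(edges.size - 1, np.nan)
    for k in range(edges.size - 1):
        in_bin = (spec.x >= edges[k]) & (spec.x < edges[k + 1])
        n_sites = math.floor(edges[k + 1] * scale - 1e-9) - math.ceil(edges[k] * scale) + 1
        if int(in_bin.sum()) >= min(min_points, n_sites) and n_sites >= 1:
            mass = float(spec.y[in_bin].sum())
            if mass > 0:
                out[k] = math.log10(mass / n_sites)
    return out


def collapse_distance(s1: Spectrum, s2: Spectrum, decades: float, bins_per_decade: int = 5) -> float:
    """Mean |log10 y1 - log10 y2| over the overlapping top ``decades``.

    Both spectra must be rescaled. The rescaled x-ranges must overlap by at
    least ``decades`` orders of magnitude; within the top ``decades`` of the
    overlap, the spectra are geometrically binned (bins_per_decade per
    decade, bin mass averaged over the integer frequency sites the bin
    covers) and log10 y compared bin by bin over bins populated in both
    spectra. Symmetric in its arguments.
    """
    if not (s1.rescaled and s2.rescaled):
        raise ValueError("both spectra must be rescaled first")
    lo = max(s1.x.min(), s2.x.min())
    hi = min(s1.x.max(), s2.x.max())
    if hi <= 0 or lo <= 0 or math.log10(hi / lo) < decades:
        raise ValueError(f"overlapping x-range spans less than {decades} decades")
    n_bins = int(round(decades * bins_per_decade))
    n_total = int(math.floor(math.log10(hi / lo) * bins_per_decade))
    edges = hi * 10.0 ** (-np.arange(n_total + 1)[::-1] / bins_per_decade)
    y1 = _binned_log_y(s1, edges)
    y2 = _binned_log_y(s2, edges)
    common = ~np.isnan(y1) & ~np.isnan(y2)
    # take the highest window of the requested width whose bins are mostly
    # usable in both spectra; a lone extreme draw can render the very top
    # bins unusable without saying anything about the tail shape
    need = max(2, n_bins // 2)
    for top in range(n_total, n_bins - 1, -1):
        window = slice(top - n_bins, top)
        if int(common[window].sum()) >= need:
            w = common[window]
            return float(np.mean(np.abs(y1[window][w] - y2[window][w])))
    raise ValueError("no commonly populated bins in the comparison range")


def write_spectrum_tsv(spec: Spectrum, path: str | Path) -> None:
    """Plot-data export: columns n, f and (when rescaled) x, y."""
    with open(path, "w", encoding="utf-8") as fh:
        if spec.rescaled:
            fh.write("n\tf\tx\ty\n")
            for n, f, x, y in zip(spec.n, spec.f, spec.x, spec.y):
                fh.write(f"{n}\t{f:.12g}\t{x:.12g}\t{y:.12g}\n")
        else:
            fh.write("n\tf\n")
            for n, f in zip(spec.n, spec.f):
                fh.write(f"{n}\t{f:.12g}\n")
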