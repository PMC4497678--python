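"""Cross-text statistical battery for paired tail parameters.

Given per-text pairs of fitted parameters — the word-form and lemma tail
exponents (gamma_w, gamma_l), or the lower cutoffs (a_w, a_l) — this module
runs the tests used to probe three hypotheses about the word-to-lemma
transformation:

1. *identical distribution within a text*: exact sign-flip ("coin-flip")
   test on |mean(x) - mean(y)| over all 2^N within-text swaps, plus a paired
   t-test whose p-value can be simulated under the null (with the same
   outlier-removal rule applied to data and simulations alike);
2. *E[x|y] = y*: mean independence of the ratio x/y from y, probed by
   Pearson/Spearman correlations with permutation p-values, and by an OLS
   regression of x on y with t-tests of slope against 1 and intercept
   against 0;
3. the symmetric *E[y|x] = x*.

All resampling is reproducible under a stated seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations as _permutations
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedParams",
    "TestResult",
    "RegressionResult",
    "sigma_diff",
    "paired_t",
    "simulated_t_pvalue",
    "coin_flip_test",
    "pearson",
    "spearman",
    "perm_pvalue",
    "mean_independence_regression",
    "compare_texts",
]

EXHAUSTIVE_PERM_LIMIT = 10**6  # N! at or below this -> exact enumeration
DEFAULT_N_PERM = 100_000
COIN_FLIP_MAX_N = 25


@dataclass(frozen=True)
class PairedParams:
    """Aligned per-text parameter vectors for two conditions."""

    labels: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if not (len(self.labels) == self.x.size == self.y.size):
            raise ValueError("labels, x and y must have equal length")
        if self.x.size < 2:
            raise ValueError("need at least 2 paired texts")

    @property
    def N(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    n_resamples: int | str
    seed: int | None = None
    outliers_removed: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit with reference t-tests (slope vs 1, intercept vs 0)."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    df: int

    @property
    def t_slope_vs_1(self) -> float:
        if self.se_slope == 0:  # perfect fit: t is 0 when already at the reference
            return 0.0 if self.slope == 1.0 else math.inf * (self.slope - 1.0)
        return (self.slope - 1.0) / self.se_slope

    @property
    def t_intercept_vs_0(self) -> float:
        if self.se_intercept == 0:
            return 0.0 if self.intercept == 0.0 else math.inf * self.intercept
        return self.intercept / self.se_intercept

    @property
    def p_slope(self) -> float:
        return 2.0 * _sps.t.sf(abs(self.t_slope_vs_1), self.df)

    @property
    def p_intercept(self) -> float:
        return 2.0 * _sps.t.sf(abs(self.t_intercept_vs_0), self.df)


def sigma_diff(sigma1: float, sigma2: float) -> tuple[float, float]:
    """Standard deviation of a difference assuming independence, and its double."""
    if sigma1 < 0 or sigma2 < 0:
        raise ValueError("standard deviations must be non-negative")
    sd = math.hypot(sigma1, sigma2)
    return sd, 2.0 * sd


def _remove_outliers(d: np.ndarray, labels: Sequence[str], n_remove: int) -> tuple[np.ndarray, tuple[str, ...]]:
    if n_remove == 0:
        return d, ()
    order = np.argsort(-np.abs(d), kind="stable")  # ties by original (label) order
    drop = order[:n_remove]
    keep = np.ones(d.size, dtype=bool)
    keep[drop] = False
    return d[keep], tuple(labels[i] for i in drop)


def paired_t(pairs: PairedParams, n_remove: int = 0) -> tuple[float, tuple[str, ...]]:
    """Paired t-statistic on x - y after removing the n_remove largest |d|.

    t = mean(d) * sqrt(M) / sd_unbiased(d) with M the pairs kept.
    """
    d, removed = _remove_outliers(pairs.x - pairs.y, pairs.labels, n_remove)
    if d.size < 2:
        raise ValueError("fewer than 2 pairs remain after outlier removal")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in the paired differences")
    return float(d.mean() * math.sqrt(d.size) / sd), removed


def simulated_t_pvalue(
    t_obs: float, N: int, n_remove: int = 0, n_sims: int = 100_000, seed: int = 0
) -> float:
    """Two-sided p-value of a paired t by simulating the null distribution.

    Each replica draws N independent standard normals (zero-mean differences
    with a common standard deviation), removes the n_remove largest absolute
    values — the same rule applied to the data — and computes t on the rest;
    p is the fraction of replicas with |t| >= |t_obs|.
    """
    if N - n_remove < 2:
        raise ValueError("need at least 2 values after removal")
    if n_sims < 100:
        raise ValueError("n_sims < 100 gives an unstable p-value")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_sims, N))
    if n_remove:
        order = np.argsort(-np.abs(z), axis=1)
        keep = order[:, n_remove:]
        z = np.take_along_axis(z, keep, axis=1)
    M = z.shape[1]
    t_sim = z.mean(axis=1) * math.sqrt(M) / z.std(axis=1, ddof=1)
    return float(np.mean(np.abs(t_sim) >= abs(t_obs)))


def coin_flip_test(pairs: PairedParams) -> tuple[float, float]:
    """Exact sign-flip test on the absolute difference of the means.

    For each of the 2^N configurations of within-text swaps the statistic
    |mean(x') - mean(y')| is recomputed; the p-value is the fraction of
    configurations whose statistic equals or exceeds the observed one (the
    identity configuration always counts, so p >= 2^-N).
    """
    N = pairs.N
    if N > COIN_FLIP_MAX_N:
        raise ValueError(f"exact enumeration limited to N <= {COIN_FLIP_MAX_N}; use a sampled sign-flip test")
    d = pairs.x - pairs.y
    obs = abs(d.mean())
    total = 1 << N
    ge = 0
    chunk = 1 << 16
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total), dtype=np.int64)
        signs = ((idx[:, None] >> np.arange(N)) & 1) * 2 - 1
        stat = np.abs(signs @ d) / N
        ge += int(np.sum(stat >= obs - 1e-12))
    return float(obs), ge / total


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation: covariance over the product of standard deviations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    return float(_sps.pearsonr(x, y).statistic)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman correlation: Pearson on (average) ranks."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    return float(_sps.spearmanr(x, y).statistic)


def perm_pvalue(
    stat: Literal["pearson", "spearman"],
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int | None = None,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for a correlation coefficient.

    Reshuffles y only and counts permutations with |rho| >= |rho_observed|.
    Exhaustive enumeration of all N! orderings is used when feasible
    (N! <= 1e6); otherwise n_perm seeded random permutations (the observed
    ordering included, keeping p > 0).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if stat == "spearman":
        x = _sps.rankdata(x)
        y = _sps.rankdata(y)
    elif stat != "pearson":
        raise ValueError(f"unknown correlation kind {stat!r}")
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    N = x.size
    rho_obs = abs(float(xc @ yc) / N)
    if math.factorial(N) <= EXHAUSTIVE_PERM_LIMIT:
        perms = np.array(list(_permutations(range(N))))
        rhos = np.abs(yc[perms] @ xc) / N
        return float(np.mean(rhos >= rho_obs - 1e-12))
    if n_perm is None:
        n_perm = DEFAULT_N_PERM
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    ge = 1  # the identity permutation
    chunk = 10_000
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        Y = rng.permuted(np.tile(yc, (m, 1)), axis=1)
        rhos = np.abs(Y @ xc) / N
        ge += int(np.sum(rhos >= rho_obs - 1e-12))
        done += m
    return ge / (n_perm + 1)


def mean_independence_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS of the response y on the predictor x with reference t-tests.

    Classical standard errors with N - 2 degrees of freedom; the t
    statistics test the mean-independence reference values slope = 1 and
    intercept = 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if x.std() == 0:
        raise ValueError("zero predictor variance")
    res = _sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        se_slope=float(res.stderr),
        se_intercept=float(res.intercept_stderr),
        df=x.size - 2,
    )


def _correlation_block(x: np.ndarray, y: np.ndarray, n_perm: int | None, seed_seq: np.random.SeedSequence) -> dict:
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(2)]
    out = {}
    for kind, fn, seed in (("pearson", pearson, seeds[0]), ("spearman", spearman, seeds[1])):
        try:
            out[kind] = {"rho": fn(x, y), "p_perm": perm_pvalue(kind, x, y, n_perm, seed)}
        except ValueError as exc:  # constant variable, e.g. x/y with x == y
            out[kind] = {"rho": None, "p_perm": None, "note": str(exc)}
    return out


def _battery_for_kind(
    labels: tuple[str, ...],
    x: np.ndarray,
    y: np.ndarray,
    names: tuple[str, str],
    sigmas: tuple[np.ndarray, np.ndarray] | None,
    n_sims_t: int,
    n_perm: int | None,
    seed_seq: np.random.SeedSequence,
) -> dict:
    nx, ny = names
    pairs = PairedParams(labels=labels, x=x, y=y)
    ss = seed_seq.spawn(6)
    out: dict = {"N": pairs.N, "labels": list(labels), nx: list(map(float, x)), ny: list(map(float, y))}
    if sigmas is not None:
        per_text = []
        for lab, s1, s2, d in zip(labels, sigmas[0], sigmas[1], x - y):
            sd, two_sd = sigma_diff(s1, s2)
            per_text.append({"label": lab, "diff": float(d), "sigma_d": sd, "two_sigma_d": two_sd,
                             "outside_2sigma_d": bool(abs(d) > two_sd)})
        out["sigma_d_table"] = per_text

    for n_remove in (0, 1):
        try:
            t, removed = paired_t(pairs, n_remove=n_remove)
        except ValueError as exc:  # e.g. identical conditions: zero variance
            out[f"paired_t_remove{n_remove}"] = {"t": None, "p_sim": None,
                                                 "outliers_removed": [], "note": str(exc)}
            continue
        p = simulated_t_pvalue(t, pairs.N, n_remove=n_remove, n_sims=n_sims_t,
                               seed=int(ss[n_remove].generate_state(1)[0] % (2**31)))
        out[f"paired_t_remove{n_remove}"] = {"t": t, "p_sim": p, "outliers_removed": list(removed),
                                             "n_sims": n_sims_t}

    stat, p_exact = coin_flip_test(pairs)
    out["coin_flip"] = {"statistic": stat, "p_exact": p_exact, "n_configurations": 2**pairs.N}

    out["direct_correlation"] = _correlation_block(x, y, n_perm, ss[2])
    out["ratio_correlations"] = {
        f"{nx}/{ny}_vs_{ny}": _correlation_block(x / y, y, n_perm, ss[3]),
        f"{ny}/{nx}_vs_{nx}": _correlation_block(y / x, x, n_perm, ss[4]),
    }
    # multiple-testing views over the four ratio-correlation p-values
    cells = [blk[k] for blk in out["ratio_correlations"].values() for k in ("pearson", "spearman")]
    cells = [c for c in cells if c["p_perm"] is not None]
    if cells:
        for method in ("bonferroni", "sidak"):
            adj = multipletests([c["p_perm"] for c in cells], method=method)[1]
            for c, p in zip(cells, adj):
                c[f"p_{method}"] = float(p)

    def reg_dict(pred, resp, name):
        r = mean_independence_regression(pred, resp)
        return {
            "model": name, "slope": r.slope, "se_slope": r.se_slope,
            "intercept": r.intercept, "se_intercept": r.se_intercept, "df": r.df,
            "t_slope_vs_1": r.t_slope_vs_1, "p_slope": r.p_slope,
            "t_intercept_vs_0": r.t_intercept_vs_0, "p_intercept": r.p_intercept,
        }

    out["regressions"] = [
        reg_dict(y, x, f"E[{nx}|{ny}]"),
        reg_dict(x, y, f"E[{ny}|{nx}]"),
    ]
    return out


def compare_texts(
    fits_w: Sequence,
    fits_l: Sequence,
    seed: int = 0,
    n_sims_t: int = 100_000,
    n_perm: int | None = None,
) -> dict:
    """Run the full battery on aligned word-form and lemma tail fits.

    ``fits_w`` and ``fits_l`` are equal-length sequences of TailFit-like
    objects (attributes ``gamma_hat``, ``sigma``, ``a`` and optionally
    ``label``). Emits, for the exponents and for the cutoffs: the per-text
    sigma_d table, paired t-tests with 0 and 1 outliers removed (simulated
    p-values), the exact coin-flip test, direct and ratio correlations with
    permutation p-values (raw and multiplicity-adjusted), and both
    mean-independence regressions — a machine-readable analogue of a
    words-vs-lemmas comparison report.
    """
    if len(fits_w) != len(fits_l):
        raise ValueError("fits_w and fits_l must be aligned and of equal length")
    if len(fits_w) < 2:
        raise ValueError("N >= 2 texts required")
    labels = tuple(
        (getattr(fw, "label", None) or f"text_{i}") for i, fw in enumerate(fits_w)
    )
    gw = np.array([f.gamma_hat for f in fits_w])
    gl = np.array([f.gamma_hat for f in fits_l])
    sw = np.array([f.sigma for f in fits_w])
    sl = np.array([f.sigma for f in fits_l])
    aw = np.array([float(f.a) for f in fits_w])
    al = np.array([float(f.a) for f in fits_l])
    ss = np.random.SeedSequence(seed)
    s_g, s_a = ss.spawn(2)
    return {
        "seed": seed,
        "exponents": _battery_for_kind(labels, gw, gl, ("gamma_w", "gamma_l"), (sw, sl), n_sims_t, n_perm, s_g),
        "cutoffs": _battery_for_kind(labels, aw, al, ("a_w", "a_l"), None, n_sims_t, n_perm, s_a),
    }
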