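"""Discrete power-law model, MLE fitting and Monte-Carlo goodness of fit.

The tail model is the frequency form of Zipf's law: the probability that a
type has frequency ``n`` is ``f(n) = n^-gamma / Z`` for ``n >= a`` (and
optionally ``n <= b`` for a truncated fit), where ``Z`` is the Hurwitz zeta
function ``zeta(gamma, a)`` in the unbounded case. Fitting follows a
two-step procedure: for a candidate lower cutoff ``a`` the exponent is
estimated by numerical maximum likelihood, and the fit quality is measured
by the Kolmogorov-Smirnov distance, whose p-value comes from Monte-Carlo
replicas of the fitted model that are each re-fitted before their own KS
distance is taken (re-using the empirical exponent would inflate p-values).
Candidate cutoffs are scanned on a geometric grid and the smallest accepted
one (p above a threshold, 0.20 by default) is reported, together with the
exponent's standard deviation across the Monte-Carlo re-fits.

Zipf's law is considered valid when the accepted power law spans at least
two decades, ``n_m / a >= 100``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta as _scipy_zeta

__all__ = [
    "DiscretePowerLaw",
    "TailFit",
    "CutoffDiagnostic",
    "ScanResult",
    "GofResult",
    "hurwitz_zeta",
    "mle_exponent",
    "ks_distance",
    "gof_and_sigma",
    "cutoff_grid",
    "scan_lower_cutoff",
    "scan_upper_cutoff",
    "gamma_to_alpha",
    "alpha_to_gamma",
]

GAMMA_MIN = 1.0 + 1e-6
GAMMA_MAX = 10.0
_TABLE_CAP = 1 << 20  # longest inversion table kept in memory
_TAIL_QUANTILE = 1e-9


def hurwitz_zeta(gamma: float, a: int) -> float:
    """Hurwitz zeta ``sum_{k>=a} k^-gamma``; diverges for gamma <= 1."""
    if gamma <= 1:
        raise ValueError(f"Hurwitz zeta diverges for gamma={gamma} <= 1")
    if a < 1:
        raise ValueError("a must be >= 1")
    return float(_scipy_zeta(gamma, a))


def _partial_zeta(gamma: float, a: int, b: int | None) -> float:
    """Normalization ``sum_{k=a}^{b} k^-gamma`` (b=None means infinity)."""
    if b is None:
        return hurwitz_zeta(gamma, a)
    if b < a:
        raise ValueError("b must be >= a")
    if b - a < 100_000:
        k = np.arange(a, b + 1, dtype=float)
        return float(np.sum(k**-gamma))
    # wide truncation: difference of zetas is accurate since gamma > 1 here
    return hurwitz_zeta(gamma, a) - hurwitz_zeta(gamma, b + 1)


@dataclass(frozen=True)
class DiscretePowerLaw:
    """``f(n) = n^-gamma / Z`` on the integer support ``{a, ..., b}``.

    With ``b=None`` the support is unbounded and gamma must exceed 1 so the
    normalization ``Z = zeta(gamma, a)`` is finite.
    """

    gamma: float
    a: int = 1
    b: int | None = None

    def __post_init__(self) -> None:
        if self.a < 1 or self.a != int(self.a):
            raise ValueError("a must be a positive integer")
        if self.b is not None and self.b < self.a:
            raise ValueError("b must be >= a")
        if self.b is None and self.gamma <= 1:
            raise ValueError("unbounded support requires gamma > 1")

    @property
    def Z(self) -> float:
        return _partial_zeta(self.gamma, self.a, self.b)

    def pmf(self, n) -> np.ndarray | float:
        n_arr = np.asarray(n, dtype=float)
        in_support = (n_arr >= self.a) & (n_arr == np.floor(n_arr))
        if self.b is not None:
            in_support &= n_arr <= self.b
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(in_support, np.abs(n_arr) ** -self.gamma / self.Z, 0.0)
        return float(p) if np.isscalar(n) else p

    def sf(self, n) -> np.ndarray | float:
        """Survival ``P(X >= n)`` at integer points, 1 below the support."""
        n_arr = np.atleast_1d(np.asarray(n, dtype=float))
        out = np.empty(n_arr.shape)
        Z = self.Z
        for i, v in enumerate(n_arr):
            vi = max(int(math.ceil(v)), self.a)
            if self.b is not None and vi > self.b:
                out[i] = 0.0
            else:
                out[i] = _partial_zeta(self.gamma, vi, self.b) / Z
        return float(out[0]) if np.isscalar(n) else out

    def cdf(self, n) -> np.ndarray | float:
        """``P(X <= n)`` at integer points."""
        n_arr = np.asarray(n)
        res = 1.0 - self.sf(np.asarray(n_arr, dtype=float) + 1.0)
        return res

    def _inversion_table(self) -> np.ndarray:
        """Cumulative probabilities at ``a, a+1, ...`` up to a far quantile.

        Cached on the instance: repeated sampling from one model (the
        Monte-Carlo goodness-of-fit loop) pays the cumsum once.
        """
        cached = self.__dict__.get("_cum")
        if cached is not None:
            return cached
        if self.b is not None:
            top = self.b
        else:
            # smallest n with P(X > n) <= _TAIL_QUANTILE, via the continuous
            # tail bound  P(X > n) ~ n^(1-gamma) / ((gamma-1) Z)
            est = ((self.gamma - 1) * self.Z * _TAIL_QUANTILE) ** (1.0 / (1.0 - self.gamma))
            top = int(min(max(self.a + 1, est), self.a + _TABLE_CAP))
        top = min(top, self.a + _TABLE_CAP)
        k = np.arange(self.a, top + 1, dtype=float)
        cum = np.cumsum(k**-self.gamma) / self.Z
        object.__setattr__(self, "_cum", cum)
        return cum

    def sample(self, size: int, seed: int | np.random.Generator) -> np.ndarray:
        """Inversion sampling; identical (model, size, seed) gives identical draws."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        cum = self._inversion_table()
        u = rng.random(size)
        idx = np.searchsorted(cum, u, side="right")
        draws = self.a + idx
        overflow = idx >= cum.size
        if np.any(overflow):
            # analytic continuous Pareto tail beyond the table (mass <= 1e-9
            # unless the table was capped): invert the conditional tail law
            n_top = self.a + cum.size - 1
            u2 = rng.random(int(overflow.sum()))
            x = (n_top + 0.5) * u2 ** (-1.0 / (self.gamma - 1.0))
            tail = np.floor(x + 0.5).astype(np.int64)
            tail = np.maximum(tail, n_top + 1)
            if self.b is not None:
                tail = np.minimum(tail, self.b)
            draws[overflow] = tail
        return draws.astype(np.int64)


@dataclass(frozen=True)
class GofResult:
    """Outcome of the Monte-Carlo goodness-of-fit at one fixed cutoff."""

    gamma_hat: float
    sigma: float
    ks: float
    p_value: float
    N_a: int
    n_sims: int


@dataclass(frozen=True)
class TailFit:
    """Accepted power-law tail fit for one frequency distribution."""

    a: int
    gamma_hat: float
    sigma: float
    ks: float
    p_value: float
    N_a: int
    n_m: int
    n_sims: int
    seed: int
    b: int | None = None
    label: str | None = None

    @property
    def zipf_valid(self) -> bool:
        """Two-decade rule: the fitted tail spans at least a factor 100."""
        top = self.n_m if self.b is None else self.b
        return top / self.a >= 100

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "gamma": self.gamma_hat,
            "sigma": self.sigma,
            "ks": self.ks,
            "p_value": self.p_value,
            "N_a": self.N_a,
            "n_m": self.n_m,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "zipf_valid": self.zipf_valid,
        }


@dataclass(frozen=True)
class CutoffDiagnostic:
    a: int
    b: int | None
    gamma_hat: float
    sigma: float
    ks: float
    p_value: float
    N_a: int
    accepted: bool


@dataclass(frozen=True)
class ScanResult:
    """Result of a cutoff scan: the accepted fit (or None) plus diagnostics."""

    fit: TailFit | None
    grid: tuple[CutoffDiagnostic, ...] = field(default_factory=tuple)

    @property
    def found(self) -> bool:
        return self.fit is not None


def _in_range(counts: np.ndarray, a: int, b: int | None) -> np.ndarray:
    counts = np.asarray(counts, dtype=np.int64)
    mask = counts >= a
    if b is not None:
        mask &= counts <= b
    return counts[mask]


def mle_exponent(
    counts: Sequence[int] | np.ndarray,
    a: int,
    b: int | None = None,
    gamma_max: float = GAMMA_MAX,
) -> float:
    """Maximum-likelihood exponent of the tail ``n >= a`` (and ``<= b``).

    Maximizes ``sum_i [-gamma ln n_i] - N ln Z(gamma, a, b)`` over
    ``gamma in (1, gamma_max]`` to a tolerance of 1e-6 in gamma.
    """
    vals = _in_range(np.asarray(counts), a, b)
    if vals.size < 2:
        raise ValueError(f"need at least 2 values with n >= {a}" + (f" and <= {b}" if b else "") + f", got {vals.size}")
    if np.all(vals == vals[0]):
        raise ValueError("all in-range values are equal; exponent is at the boundary")
    sum_log = float(np.sum(np.log(vals)))
    N = vals.size

    def negloglik(gamma: float) -> float:
        return gamma * sum_log + N * math.log(_partial_zeta(gamma, a, b))

    res = minimize_scalar(negloglik, bounds=(GAMMA_MIN, gamma_max), method="bounded", options={"xatol": 1e-7})
    return float(res.x)


def ks_distance(counts: Sequence[int] | np.ndarray, model: DiscretePowerLaw) -> float:
    """Kolmogorov-Smirnov distance on the model's support.

    Supremum over all integers in the support of |empirical CDF - model
    CDF|, both restricted to the fitted range. The empirical CDF is a step
    function, so the supremum is attained either at an observed value or
    just before the next one; both sides are checked.
    """
    vals = _in_range(np.asarray(counts), model.a, model.b)
    if vals.size == 0:
        raise ValueError("no data in the model support")
    uniq, cnt = np.unique(vals, return_counts=True)
    ecdf = np.cumsum(cnt) / vals.size
    Z = model.Z
    g = model.gamma
    tail = 0.0 if model.b is None else float(_scipy_zeta(g, model.b + 1))
    # survival S(v) = P(X >= v) at the observed values and one step past them
    sf_here = (_scipy_zeta(g, uniq.astype(float)) - tail) / Z
    sf_next = (_scipy_zeta(g, uniq.astype(float) + 1.0) - tail) / Z
    if model.b is not None:
        sf_next = np.where(uniq >= model.b, 0.0, sf_next)
    # F(v) = 1 - S(v+1); the empirical CDF is flat between observed values,
    # so the supremum over the whole support is attained at an observed value
    # or at the integer just below the next one — check both sides.
    ecdf_prev = np.concatenate(([0.0], ecdf[:-1]))
    d = max(np.max(np.abs(ecdf - (1.0 - sf_next))), np.max(np.abs(ecdf_prev - (1.0 - sf_here))))
    return float(d)


def gof_and_sigma(
    counts: Sequence[int] | np.ndarray,
    a: int,
    n_sims: int = 1000,
    seed: int | np.random.Generator = 0,
    b: int | None = None,
    gamma_max: float = GAMMA_MAX,
) -> GofResult:
    """Fit the exponent at fixed cutoff and bootstrap its KS p-value.

    Simulates ``n_sims`` datasets of the tail size from the fitted model;
    each replica is re-fitted by MLE at the same cutoffs and its KS distance
    taken against its own re-fit, so the replicas undergo the same procedure
    as the data. ``p`` is the fraction of replica KS distances >= the
    empirical one; ``sigma`` is the standard deviation of the replica
    exponents.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = _in_range(np.asarray(counts), a, b)
    gamma_hat = mle_exponent(vals, a, b, gamma_max)
    model = DiscretePowerLaw(gamma_hat, a, b)
    emp_ks = ks_distance(vals, model)
    N_a = vals.size

    sim_gammas = np.empty(n_sims)
    sim_ks = np.empty(n_sims)
    for i in range(n_sims):
        sim = model.sample(N_a, rng)
        try:
            g = mle_exponent(sim, a, b, gamma_max)
        except ValueError:  # degenerate replica (all values equal)
            g = gamma_max
        sim_gammas[i] = g
        sim_ks[i] = ks_distance(sim, DiscretePowerLaw(g, a, b))
    p = float(np.mean(sim_ks >= emp_ks))
    sigma = float(np.std(sim_gammas, ddof=1)) if n_sims > 1 else 0.0
    return GofResult(gamma_hat=gamma_hat, sigma=sigma, ks=emp_ks, p_value=p, N_a=N_a, n_sims=n_sims)


def cutoff_grid(a_min: int, a_max: int, per_decade: int = 10) -> list[int]:
    """Geometric grid of integer cutoffs, ~per_decade points per decade.

    Built by successively multiplying by ``10^(1/per_decade)`` starting at
    ``a_min`` and rounding each value up to the next integer, then
    deduplicating; the relative spacing is about 26% at the default 10
    points per decade.
    """
    if per_decade < 1:
        raise ValueError("per_decade must be >= 1")
    if not 1 <= a_min <= a_max:
        raise ValueError("need 1 <= a_min <= a_max")
    factor = 10.0 ** (1.0 / per_decade)
    out: list[int] = []
    v = float(a_min)
    while True:
        c = math.ceil(v)
        if c > a_max:
            break
        if not out or c != out[-1]:
            out.append(c)
        v *= factor
    return out


def _counts_array(table) -> np.ndarray:
    """Accept a FrequencyTable, a mapping, or a plain sequence of counts."""
    if hasattr(table, "values") and hasattr(table, "counts"):
        return table.values()
    if hasattr(table, "values") and isinstance(table, dict):
        return np.fromiter(table.values(), dtype=np.int64)
    return np.asarray(table, dtype=np.int64)


def scan_lower_cutoff(
    table,
    per_decade: int = 10,
    p_threshold: float = 0.20,
    n_sims: int = 1000,
    seed: int = 0,
    gamma_max: float = GAMMA_MAX,
    label: str | None = None,
) -> ScanResult:
    """Select the smallest lower cutoff whose power-law fit is accepted.

    Walks the geometric cutoff grid upward from 1; at each candidate ``a``
    the exponent is fitted and the Monte-Carlo KS p-value computed, and the
    first cutoff with ``p > p_threshold`` wins (the smallest accepted cutoff
    gives the widest power-law range). Returns an empty ScanResult (``fit is
    None``) when every candidate is rejected — "no power-law tail found" is
    a result, not an error.
    """
    counts = _counts_array(table)
    n_m = int(counts.max())
    grid = cutoff_grid(1, n_m, per_decade)
    ss = np.random.SeedSequence(seed)
    diagnostics: list[CutoffDiagnostic] = []
    fit: TailFit | None = None
    for a, child in zip(grid, ss.spawn(len(grid))):
        vals = _in_range(counts, a, None)
        if vals.size < 2 or np.all(vals == vals[0]):
            break
        res = gof_and_sigma(vals, a, n_sims=n_sims, seed=np.random.default_rng(child), gamma_max=gamma_max)
        accepted = res.p_value > p_threshold
        diagnostics.append(
            CutoffDiagnostic(a=a, b=None, gamma_hat=res.gamma_hat, sigma=res.sigma, ks=res.ks, p_value=res.p_value, N_a=res.N_a, accepted=accepted)
        )
        if accepted:
            fit = TailFit(
                a=a, gamma_hat=res.gamma_hat, sigma=res.sigma, ks=res.ks, p_value=res.p_value,
                N_a=res.N_a, n_m=n_m, n_sims=n_sims, seed=seed, label=label,
            )
            break
    return ScanResult(fit=fit, grid=tuple(diagnostics))


def scan_upper_cutoff(
    table,
    a: int = 1,
    per_decade: int = 10,
    p_threshold: float = 0.20,
    n_sims: int = 1000,
    seed: int = 0,
    gamma_max: float = GAMMA_MAX,
    label: str | None = None,
) -> ScanResult:
    """Scan truncation points for a second, low-frequency power-law regime.

    Fixes the lower end at ``a`` (1 by default) and tries truncated fits
    ``[a, b]`` with ``b`` descending through the geometric grid from the
    maximum frequency; the largest accepted ``b`` is returned. An empty
    result means the truncated power law is rejected no matter the maximum
    frequency considered.
    """
    counts = _counts_array(table)
    n_m = int(counts.max())
    bs = [b for b in cutoff_grid(max(a + 1, 1), n_m, per_decade)]
    if not bs or bs[-1] != n_m:
        bs.append(n_m)
    bs = sorted(set(b for b in bs if b > a), reverse=True)
    ss = np.random.SeedSequence(seed)
    diagnostics: list[CutoffDiagnostic] = []
    fit: TailFit | None = None
    for b, child in zip(bs, ss.spawn(len(bs))):
        vals = _in_range(counts, a, b)
        if vals.size < 2 or np.all(vals == vals[0]):
            continue
        res = gof_and_sigma(vals, a, n_sims=n_sims, seed=np.random.default_rng(child), b=b, gamma_max=gamma_max)
        accepted = res.p_value > p_threshold
        diagnostics.append(
            CutoffDiagnostic(a=a, b=b, gamma_hat=res.gamma_hat, sigma=res.sigma, ks=res.ks, p_value=res.p_value, N_a=res.N_a, accepted=accepted)
        )
        if accepted:
            fit = TailFit(
                a=a, gamma_hat=res.gamma_hat, sigma=res.sigma, ks=res.ks, p_value=res.p_value,
                N_a=res.N_a, n_m=n_m, n_sims=n_sims, seed=seed, b=b, label=label,
            )
            break
    return ScanResult(fit=fit, grid=tuple(diagnostics))


def gamma_to_alpha(gamma: float) -> float:
    """Frequency-form exponent to rank-form exponent: alpha = 1/(gamma-1)."""
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    return 1.0 / (gamma - 1.0)


def alpha_to_gamma(alpha: float) -> float:
    """Rank-form exponent to frequency-form exponent: gamma = 1 + 1/alpha."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return 1.0 + 1.0 / alpha
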