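"""Most probable number (MPN) estimation for serial dilution culture assays.

The MPN of viable organisms is the value of the Poisson mean that maximizes
the product-binomial likelihood of an observed pattern of growth-positive
tubes across a replicated dilution series.  A tube inoculated with ``v``
sample-equivalents at concentration ``lambda`` is positive with probability
``1 - exp(-lambda * v)`` under Poisson partitioning; the maximum-likelihood
estimate solves the classical score equation

    sum_{positive tubes} v_i / (1 - exp(-lambda * v_i)) = sum_{all tubes} v_i

This module solves that equation directly for arbitrary designs (any
dilution ratio, tier count, or replicate number), replacing published
lookup tables, which are themselves tabulations of the same estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DilutionDesign",
    "ScoreMatrix",
    "MpnResult",
    "MPN_MED",
    "median_table_mpn",
    "round_sig",
    "mpn_estimate",
    "choose_dilution_range",
    "n_viable_from_mpn",
    "relative_viability",
]

#: Median tabulated MPN over calculable tube scores, by replicate count.
#: Used when choosing a dilution range (see :func:`choose_dilution_range`).
MPN_MED = {3: 22.0, 5: 22.0, 10: 21.0}


def median_table_mpn(replicates: int) -> float:
    """Median tabulated MPN for a given replicate count (22 for 3- and
    5-replicate designs, 21 for 10 replicates; 22 otherwise)."""
    return MPN_MED.get(replicates, 22.0)


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class DilutionDesign:
    """Geometry of a serial dilution culture assay.

    Parameters
    ----------
    X : int
        Leading dilution exponent: for a tenfold series, tier ``i`` holds
        sample at relative dilution ``10**(X - i + 1)``.
    DR : float
        Dilution ratio between successive tiers (>= 2).
    q : int
        Number of dilution tiers (>= 2).
    r : int
        Replicate tubes per tier (>= 1).
    V : float
        Incubated volume per tube, mL.
    """

    X: int = -1
    DR: float = 10.0
    q: int = 3
    r: int = 5
    V: float = 5.0

    def __post_init__(self) -> None:
        if self.DR < 2:
            raise ValueError("dilution ratio DR must be >= 2")
        if self.q < 2:
            raise ValueError("need at least 2 tiers")
        if self.r < 1:
            raise ValueError("need at least 1 replicate per tier")
        if self.V <= 0:
            raise ValueError("incubated volume must be positive")

    @property
    def n_tubes(self) -> int:
        return self.q * self.r

    def cf(self, tier: int) -> float:
        """Concentration factor of ``tier`` (1-based): CF(i+1) = CF(i)/DR."""
        if not 1 <= tier <= self.q:
            raise ValueError(f"tier must be in 1..{self.q}")
        return float(self.DR) ** (self.X - tier + 1)

    @property
    def concentration_factors(self) -> tuple[float, ...]:
        return tuple(self.cf(i) for i in range(1, self.q + 1))

    @property
    def tube_volumes(self) -> tuple[float, ...]:
        """Undiluted-sample mL-equivalents per tube, V * CF(i)."""
        return tuple(self.V * c for c in self.concentration_factors)

    @property
    def table_inocula(self) -> tuple[float, ...]:
        """Per-tube inocula in lookup-table reference units.

        The conventional tenfold tables assume inocula 0.1, 0.01, 0.001;
        for a general ratio the analogue is DR**-i for tier i.  The MPN
        estimated against these units is converted to a concentration by
        :func:`n_viable_from_mpn`.
        """
        return tuple(float(self.DR) ** -(i + 1) for i in range(self.q))


@dataclass(frozen=True)
class ScoreMatrix:
    """Per-tier counts of growth-positive tubes."""

    positives: tuple[int, ...]
    r: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "positives", tuple(int(p) for p in self.positives))
        for p in self.positives:
            if not 0 <= p <= self.r:
                raise ValueError(f"positive count {p} outside 0..{self.r}")

    @property
    def q(self) -> int:
        return len(self.positives)

    @property
    def total_positive(self) -> int:
        return sum(self.positives)

    @property
    def all_negative(self) -> bool:
        return self.total_positive == 0

    @property
    def all_positive(self) -> bool:
        return self.total_positive == self.q * self.r

    @property
    def censored(self) -> bool:
        """A score is censored (not calculable) when every tube is positive
        or every tube is negative; the MLE then sits on the boundary."""
        return self.all_negative or self.all_positive


@dataclass
class MpnResult:
    """MPN point estimate with lognormal interval and back-calculation.

    ``mpn`` is in the units implied by the inocula passed to
    :func:`mpn_estimate` (reference-table units when table inocula are
    used); ``n_viable`` is the concentration in cells/mL when set.
    """

    mpn: float
    ci_low: float
    ci_high: float
    n_viable: float | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)
    sigma_ln: float | None = None
    mpn_raw: float | None = None

    @property
    def n_viable_ci(self) -> tuple[float, float] | None:
        """CI bounds rescaled to concentration units (cells/mL)."""
        if self.n_viable is None or not self.mpn_raw:
            return None
        scale = self.n_viable / self.mpn_raw
        return (self.ci_low * scale, self.ci_high * scale)

    @property
    def below_detection(self) -> bool:
        return "below_detection" in self.flags

    @property
    def above_range(self) -> bool:
        return "above_quantitative_range" in self.flags


def _score_equation(lam: float, positives: Sequence[int], reps: Sequence[int],
                    inocula: Sequence[float]) -> float:
    total = sum(r * v for r, v in zip(reps, inocula))
    s = 0.0
    for p, v in zip(positives, inocula):
        if p > 0:
            s += p * v / -math.expm1(-lam * v)
    return s - total


def log_likelihood(lam: float, positives: Sequence[int], reps: Sequence[int],
                   inocula: Sequence[float]) -> float:
    """Product-binomial log-likelihood of a tube score at Poisson mean ``lam``."""
    ll = 0.0
    for p, r, v in zip(positives, reps, inocula):
        neg = r - p
        if p > 0:
            ll += p * math.log(-math.expm1(-lam * v))
        ll += neg * (-lam * v)
    return ll


def _sigma_at(lam: float, inocula: Sequence[float], reps: Sequence[int]) -> float:
    """Hurley–Roscoe standard error of ln(estimate) at the point estimate.

    Unit-free: depends only on the per-tube expected counts ``lam * v``.
    """
    v = np.asarray(inocula, dtype=float)
    r = np.asarray(reps, dtype=float)
    x = lam * v
    with np.errstate(over="ignore"):
        denom = np.expm1(x)
    terms = np.where(np.isfinite(denom) & (denom > 0), v**2 * r / np.where(denom > 0, denom, 1.0), 0.0)
    info = lam**2 * terms.sum()
    return float(info) ** -0.5


def _profile_ci(lam_hat: float, positives, reps, inocula, level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood interval by inverting the likelihood-ratio test."""
    from scipy.stats import chi2

    ll_hat = log_likelihood(lam_hat, positives, reps, inocula)
    drop = chi2.ppf(level, df=1) / 2.0

    def g(lam: float) -> float:
        return log_likelihood(lam, positives, reps, inocula) - (ll_hat - drop)

    lo_bracket = lam_hat
    while g(lo_bracket) > 0 and lo_bracket > 1e-12:
        lo_bracket /= 10.0
    lo = brentq(g, lo_bracket, lam_hat) if g(lo_bracket) <= 0 else 0.0
    hi_bracket = lam_hat
    while g(hi_bracket) > 0 and hi_bracket < 1e12:
        hi_bracket *= 10.0
    hi = brentq(g, lam_hat, hi_bracket) if g(hi_bracket) <= 0 else math.inf
    return lo, hi


def mpn_estimate(
    scores: ScoreMatrix,
    inocula: Sequence[float],
    *,
    sig_figs: int | None = 2,
    ci_method: str = "lognormal",
) -> MpnResult:
    """Maximum-likelihood MPN for a tube score under Poisson partitioning.

    Parameters
    ----------
    scores : ScoreMatrix
        Per-tier positive counts.
    inocula : sequence of float
        Per-tube sample-equivalent inoculum for each tier, strictly
        decreasing.  The estimate is per unit of these inocula: pass
        table reference units (0.1, 0.01, ...) for a table-style MPN, or
        mL-equivalents (``V * CF(i)``) for cells/mL directly.
    sig_figs : int or None
        Significant figures for the reported estimate (None = no rounding).
    ci_method : {"lognormal", "profile"}
        ``lognormal`` returns ``mpn * exp(±2σ)`` with σ the Hurley–Roscoe
        standard error of the log estimate evaluated at the estimate;
        ``profile`` inverts the likelihood-ratio test.

    Censored scores (all tubes negative, or all positive) have no interior
    MLE: all-negative returns 0 with a ``below_detection`` flag; all-positive
    returns the estimate for the largest calculable score (one negative tube
    in the most dilute tier) flagged ``above_quantitative_range`` — a lower
    bound on the true value.
    """
    inocula = [float(v) for v in inocula]
    if len(inocula) != scores.q:
        raise ValueError("one inoculum per tier required")
    if any(b >= a for a, b in zip(inocula, inocula[1:])):
        raise ValueError("inocula must be strictly decreasing across tiers")
    if any(v <= 0 for v in inocula):
        raise ValueError("inocula must be positive")
    reps = [scores.r] * scores.q

    if scores.all_negative:
        return MpnResult(mpn=0.0, ci_low=0.0, ci_high=0.0, flags=("below_detection",))

    flags: tuple[str, ...] = ()
    positives = list(scores.positives)
    if scores.all_positive:
        positives[-1] -= 1  # largest calculable score: a lower bound
        flags = ("above_quantitative_range",)

    lam = brentq(_score_equation, 1e-9, 1e9, args=(positives, reps, inocula), xtol=1e-12, rtol=1e-12)

    if ci_method == "profile":
        lo, hi = _profile_ci(lam, positives, reps, inocula)
        sigma = _sigma_at(lam, inocula, reps)
    elif ci_method == "lognormal":
        sigma = _sigma_at(lam, inocula, reps)
        lo, hi = lam * math.exp(-2 * sigma), lam * math.exp(2 * sigma)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    mpn = round_sig(lam, sig_figs) if sig_figs else lam
    return MpnResult(mpn=mpn, ci_low=lo, ci_high=hi, flags=flags,
                     sigma_ln=sigma, mpn_raw=lam)


def choose_dilution_range(n_estimate: float, V: float, mpn_med: float = 22.0) -> int:
    """Leading dilution exponent X matching an expected concentration.

    Chooses the tenfold series ``10**X, 10**(X-1), ...`` so that the
    expected table MPN falls near the median of calculable outcomes:

        X = round(log10(mpn_med / (n_estimate * V))) - 1

    with ties (.5) rounded away from zero.
    """
    if n_estimate <= 0 or V <= 0 or mpn_med <= 0:
        raise ValueError("n_estimate, V and mpn_med must be positive")
    z = math.log10(mpn_med / (n_estimate * V))
    # nearest integer, ties away from zero
    rounded = math.floor(z + 0.5) if z >= 0 else math.ceil(z - 0.5)
    return int(rounded) - 1


def n_viable_from_mpn(mpn: float, V: float, X: int, dr: float = 10.0) -> float:
    """Concentration of viable cells (cells/mL) from a table-referenced MPN.

    ``n_viable = mpn / V * dr**-(1 + X)``: the table-unit MPN rescaled so
    that the tier-1 tube holds ``V * dr**X`` mL-equivalents of undiluted
    sample (tenfold series by default).
    """
    if mpn < 0:
        raise ValueError("mpn must be non-negative")
    if V <= 0:
        raise ValueError("V must be positive")
    return mpn / V * float(dr) ** -(1 + X)


def relative_viability(n_viable_treated: float, n0: float) -> tuple[float, tuple[str, ...]]:
    """Relative viability RV = N_viable / N_0 with detection-limit flagging.

    Returns the ratio and a flag tuple; an exact zero is annotated as
    bounded by the assay's detection limit rather than a true zero.
    """
    if n0 <= 0:
        raise ValueError("reference concentration n0 must be positive")
    if n_viable_treated < 0:
        raise ValueError("n_viable must be non-negative")
    rv = n_viable_treated / n0
    flags = ("at_detection_limit",) if n_viable_treated == 0 else ()
    return rv, flags
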