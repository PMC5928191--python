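"""Growth-rate computation, balanced-growth QA/QC, and detection-limit calibration.

Cultures are maintained in balanced growth — steady exponential state in
which all cellular constituents grow at the same rate — before any
viability assay.  Growth is tracked by dark-acclimated chlorophyll-a
fluorescence F; semicontinuous dilution (a fraction d of the culture
replaced with fresh medium) is corrected for when computing the specific
growth rate:

    mu_F = ln( F2 / (1 - d) / F1 ) / (t2 - t1)

Balanced growth is accepted when, over at least ten generations, the
coefficients of variation of mu_F and of the photochemical yield Fv/Fm are
both <= 10%; for slowly growing cultures (mu_F < 0.5 / day), where
measurement noise precludes the CV criterion on mu_F, an R^2 >= 0.995 of
ln cumulative (dilution-corrected) fluorescence on time is required
instead.

The fluorometer's lower limit of detection is calibrated by ordinary
least squares of fluorescence on cell concentration over a dilution
series: LLD_cell = 3 * s_yx / m, with s_yx the residual standard error
(n - 2 denominator) and m the slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import t as t_dist

__all__ = [
    "FluorescenceSample",
    "CalibrationFit",
    "BalancedGrowthReport",
    "specific_growth_rate",
    "balanced_growth_check",
    "calibrate_lld",
]


@dataclass(frozen=True)
class FluorescenceSample:
    """One fluorescence reading.

    t is in days; F is dark-acclimated fluorescence (arbitrary units);
    d is the fraction of culture replaced by fresh medium since the
    previous reading (0 <= d < 1); fv_fm the variable-to-maximum
    fluorescence ratio if measured.
    """

    t: float
    F: float
    d: float = 0.0
    f0: float | None = None
    fm: float | None = None
    fv_fm: float | None = None

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("fluorescence must be non-negative")
        if not 0 <= self.d < 1:
            raise ValueError("dilution fraction d must satisfy 0 <= d < 1")
        if self.f0 is not None and self.fm is not None:
            if self.fm < self.f0:
                raise ValueError("Fm must be >= F0")
            if self.fv_fm is None:
                ratio = (self.fm - self.f0) / self.fm if self.fm > 0 else 0.0
                object.__setattr__(self, "fv_fm", ratio)


def specific_growth_rate(s1: FluorescenceSample, s2: FluorescenceSample) -> float:
    """Dilution-corrected specific growth rate (per day) between two readings."""
    if s2.t <= s1.t:
        raise ValueError("second sample must be later than the first")
    if s1.F <= 0 or s2.F <= 0:
        raise ValueError("fluorescence must be positive to compute a rate")
    return math.log(s2.F / (1.0 - s2.d) / s1.F) / (s2.t - s1.t)


def _cv_percent(values: np.ndarray) -> float:
    """Coefficient of variation in percent, sample (n-1) standard deviation."""
    m = values.mean()
    if m == 0:
        return math.inf
    return 100.0 * values.std(ddof=1) / abs(m)


@dataclass
class BalancedGrowthReport:
    """Verdict of the balanced-growth QA/QC check with its statistics."""

    mu_mean: float
    cv_mu: float
    cv_fvfm: float
    r2_cumfl: float
    window_generations: float
    verdict: str           # "pass" | "fail" | "insufficient data"
    criterion: str         # "cv" (fast growers) | "r2" (slow growers) | "none"

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"


def balanced_growth_check(
    history: Sequence[FluorescenceSample],
    *,
    cv_limit: float = 10.0,
    r2_limit: float = 0.995,
    mu_branch: float = 0.5,
    min_generations: float = 10.0,
) -> BalancedGrowthReport:
    """Assess whether a monitored culture is in balanced growth.

    Interval growth rates are computed between consecutive readings; the
    assessment window must span at least ``min_generations`` generations at
    the mean rate.  Fast growers (mean mu >= ``mu_branch``) pass on
    CV[mu] <= ``cv_limit``% and CV[Fv/Fm] <= ``cv_limit``%; slow growers
    pass on R^2 of ln cumulative dilution-corrected fluorescence vs time
    >= ``r2_limit`` together with the Fv/Fm CV criterion.
    """
    if len(history) < 3:
        raise ValueError("need at least 3 samples")
    ts = np.array([s.t for s in history])
    if not np.all(np.diff(ts) > 0):
        raise ValueError("samples must be strictly time-ordered")

    mus = np.array([specific_growth_rate(a, b) for a, b in zip(history, history[1:])])
    mu_mean = float(mus.mean())
    span = float(ts[-1] - ts[0])
    window_gen = span * mu_mean / math.log(2) if mu_mean > 0 else 0.0

    fvfm = np.array([s.fv_fm for s in history if s.fv_fm is not None], dtype=float)
    cv_fvfm = _cv_percent(fvfm) if fvfm.size >= 2 else math.nan
    cv_mu = _cv_percent(mus)

    # cumulative fluorescence: compound the dilution corrections
    # multiplicatively from the first sample
    correction = np.cumprod([1.0] + [1.0 / (1.0 - s.d) for s in history[1:]])
    cum_f = np.array([s.F for s in history]) * correction
    ln_cum = np.log(cum_f)
    slope, intercept = np.polyfit(ts, ln_cum, 1)
    pred = slope * ts + intercept
    ss_res = float(((ln_cum - pred) ** 2).sum())
    ss_tot = float(((ln_cum - ln_cum.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    if window_gen < min_generations:
        return BalancedGrowthReport(mu_mean, cv_mu, cv_fvfm, r2, window_gen,
                                    "insufficient data", "none")

    fvfm_ok = (not math.isnan(cv_fvfm)) and cv_fvfm <= cv_limit
    if mu_mean >= mu_branch:
        ok = cv_mu <= cv_limit and fvfm_ok
        criterion = "cv"
    else:
        ok = r2 >= r2_limit and fvfm_ok
        criterion = "r2"
    return BalancedGrowthReport(mu_mean, cv_mu, cv_fvfm, r2, window_gen,
                                "pass" if ok else "fail", criterion)


@dataclass
class CalibrationFit:
    """Fluorescence-vs-concentration calibration and detection limits.

    lld_cell = 3 * sigma_xy / m is the lowest cell concentration
    distinguishable from blank; lld_f is the fluorescence the regression
    predicts there; delta_f_min is the smallest fluorescence increment
    above lld_f whose lower 95% confidence band still clears lld_f —
    i.e. the minimum demonstrable growth signal.
    """

    m: float
    intercept: float
    sigma_xy: float
    lld_cell: float
    lld_f: float
    delta_f_min: float
    n: int
    flags: tuple[str, ...] = ()

    def fluorescence_at(self, n_cells: float) -> float:
        return self.intercept + self.m * n_cells

    def cells_at(self, fluorescence: float) -> float:
        return (fluorescence - self.intercept) / self.m


def calibrate_lld(
    concentrations: Sequence[float],
    fluorescences: Sequence[float],
    *,
    confidence: float = 0.95,
) -> CalibrationFit:
    """Calibrate detection limits from a dilution series.

    Ordinary least squares of fluorescence on cell concentration; the
    residual standard error uses the n-2 denominator.  The minimal
    demonstrable fluorescence increase ``delta_f_min`` is found by solving
    for the point on the regression line at which the lower confidence
    band of the predicted mean response equals lld_f (t-distribution,
    n-2 df); it is 0 for a perfect fit.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(fluorescences, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired calibration points")
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("concentrations are degenerate (zero variance)")

    n = x.size
    m = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
    b = float(y.mean() - m * x.mean())
    resid = y - (b + m * x)
    sigma_xy = math.sqrt(float((resid**2).sum()) / (n - 2))

    flags: tuple[str, ...] = ()
    if m <= 0:
        flags = ("non_positive_slope",)
        return CalibrationFit(m, b, sigma_xy, math.nan, math.nan, math.nan, n, flags)

    lld_cell = 3.0 * sigma_xy / m
    lld_f = b + m * lld_cell

    if sigma_xy == 0:
        delta_f_min = 0.0
    else:
        tq = float(t_dist.ppf(0.5 + confidence / 2.0, n - 2))
        xbar = float(x.mean())

        def lower_band_minus_lld(xc: float) -> float:
            half = tq * sigma_xy * math.sqrt(1.0 / n + (xc - xbar) ** 2 / sxx)
            return (b + m * xc - half) - lld_f

        hi = lld_cell + 1.0
        while lower_band_minus_lld(hi) < 0 and hi < 1e12:
            hi *= 2.0
        if lower_band_minus_lld(hi) < 0:
            flags = flags + ("confidence_band_never_clears_lld",)
            delta_f_min = math.nan
        else:
            x_star = brentq(lower_band_minus_lld, lld_cell, hi)
            delta_f_min = (b + m * x_star) - lld_f

    return CalibrationFit(m, b, sigma_xy, lld_cell, lld_f, delta_f_min, n, flags)
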