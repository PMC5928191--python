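"""Scoring grow-out tubes and assembling full assay results.

A grow-out tube is scored positive when its fluorescence exceeds a
threshold multiple (8x by default) of the larger of the detection-limit
fluorescence LLD_F and the fluorescence at inoculation, at or before a
principled end point t_end.  The end point is predicted from the growth
observed in the least-dilute tier: regression of ln F on time for points
above LLD_F gives the growth rate mu and an intercept F_Init (the
fluorescence attributable to viable cells at inoculation); more dilute
tiers are expected to follow the same curve scaled down by their relative
dilution, and a safety margin of Y generations (5 by default; 3 as a
faster alternative) is added beyond the predicted time to reach LLD_F:

    t_end = ( Y*ln2 - ln( DR^-tier_offset * F_Init / LLD_F ) ) / mu

A tube with no qualifying observation by t_end is negative; a tube whose
latest reading predates t_end remains pending.  Tier scores feed the MPN
estimator, closing the loop from raw fluorescence time courses to a
viable-cell concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .growth_qc import CalibrationFit, FluorescenceSample
from .mpn import DilutionDesign, MpnResult, ScoreMatrix, mpn_estimate, n_viable_from_mpn

__all__ = [
    "TubeSeries",
    "GrowthFit",
    "ScoringConfig",
    "LagEstimate",
    "AssayIncompleteError",
    "fit_growth_curve",
    "predict_t_end",
    "score_tube",
    "run_assay",
    "estimate_lag",
]


@dataclass(frozen=True)
class TubeSeries:
    """One grow-out tube's fluorescence time course."""

    tier: int
    replicate: int
    samples: tuple[FluorescenceSample, ...]
    f_start: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        ts = [s.t for s in self.samples]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("sample times must be strictly increasing")
        if self.tier < 1:
            raise ValueError("tier is 1-based")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.samples])

    @property
    def fluorescences(self) -> np.ndarray:
        return np.array([s.F for s in self.samples])


@dataclass
class GrowthFit:
    """Exponential-phase fit of a tube: slope mu, day-0 intercept f_init."""

    mu: float
    f_init: float
    r2: float
    n_points: int


@dataclass(frozen=True)
class ScoringConfig:
    """Scoring policy.

    y_margin is the safety margin in generations added beyond the
    predicted time to reach LLD_F (5 covers ~99% of late-growing tubes,
    3 covers ~95%); threshold_factor is the fold increase demanded for a
    positive (8x guards against recovery of treatment-depressed per-cell
    fluorescence being mistaken for growth; 1.5x is a relaxed option when
    per-cell fluorescence is known to be stable).
    """

    y_margin: float = 5.0
    threshold_factor: float = 8.0
    monitor_interval: float = 2.0

    def __post_init__(self) -> None:
        if self.threshold_factor <= 1:
            raise ValueError("threshold_factor must exceed 1")
        if self.y_margin <= 0:
            raise ValueError("y_margin must be positive")


@dataclass
class LagEstimate:
    """Estimated growth lag of a treated tube, in days and generations."""

    lag_days: float
    lag_generations: float
    tier: int | None = None
    replicate: int | None = None


class AssayIncompleteError(RuntimeError):
    """Raised when tubes are still pending at assay assembly time."""

    def __init__(self, pending: list[tuple[int, int, float]]):
        self.pending = pending
        detail = ", ".join(
            f"tier {t} rep {r} (needs {d:.1f} more days)" for t, r, d in pending
        )
        super().__init__(f"assay incomplete; pending tubes: {detail}")


def fit_growth_curve(
    tube: TubeSeries,
    lld_f: float,
    *,
    t_max: float | None = None,
) -> GrowthFit:
    """Regress ln F on time over points above the detection limit.

    Only samples with F > lld_f participate (readings below the limit
    carry no growth information); ``t_max`` optionally restricts the fit
    to the pre-plateau window.  At least 3 qualifying points are required.
    """
    if lld_f <= 0:
        raise ValueError("lld_f must be positive")
    mask = tube.fluorescences > lld_f
    if t_max is not None:
        mask &= tube.times <= t_max
    t = tube.times[mask]
    f = tube.fluorescences[mask]
    if t.size < 3:
        raise ValueError(f"only {t.size} points above LLD_F; need >= 3 for a fit")
    lnf = np.log(f)
    slope, intercept = np.polyfit(t, lnf, 1)
    pred = slope * t + intercept
    ss_tot = float(((lnf - lnf.mean()) ** 2).sum())
    r2 = 1.0 - float(((lnf - pred) ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return GrowthFit(mu=float(slope), f_init=float(np.exp(intercept)), r2=r2, n_points=int(t.size))


def predict_t_end(
    f_init_or_n: float,
    lld: float,
    mu: float,
    tier_offset: int = 0,
    y_margin: float = 5.0,
    *,
    dr: float = 10.0,
) -> float:
    """Predicted assay end point (days) for a tier of a dilution series.

    ``f_init_or_n`` is the tier-1 intercept (fluorescence, against
    ``lld`` = LLD_F) or viable concentration (cells/mL, against LLD_Cell);
    ``tier_offset`` scales it by the relative dilution dr**-tier_offset.
    Round up to whole monitoring days with ``math.ceil`` as needed.
    """
    if mu <= 0:
        raise ValueError("end point undefined for non-positive growth rate")
    if lld <= 0 or f_init_or_n <= 0:
        raise ValueError("lld and f_init_or_n must be positive")
    scaled = dr ** (-tier_offset) * f_init_or_n / lld
    return (y_margin * math.log(2) - math.log(scaled)) / mu


TubeScore = Literal["positive", "negative", "pending"]


def score_tube(
    tube: TubeSeries,
    lld_f: float,
    t_end: float,
    config: ScoringConfig | None = None,
) -> TubeScore:
    """Score a tube positive, negative, or pending.

    Positive: any observation with F >= threshold_factor * max(LLD_F,
    F_start) at t <= t_end — and once positive, always positive, even if
    fluorescence later declines (senescent cultures lose fluorescence).
    Because monitoring is discrete, t_end is rounded up to the tube's
    first reading at or after the raw value: a crossing first seen at
    that reading still counts.  Negative: the threshold is not met by
    that reading.  Pending: the tube has not yet been observed at or
    after t_end.
    """
    cfg = config or ScoringConfig()
    if not tube.samples:
        raise ValueError("tube has no observations")
    threshold = cfg.threshold_factor * max(lld_f, tube.f_start)
    # effective end point: first monitoring day at or after the raw t_end
    later = [s.t for s in tube.samples if s.t >= t_end]
    t_end_eff = min(later) if later else math.inf
    for s in tube.samples:
        if s.t <= t_end_eff and s.F >= threshold:
            return "positive"
    if later:
        return "negative"
    return "pending"


def run_assay(
    tubes: Sequence[TubeSeries],
    design: DilutionDesign,
    calibration: CalibrationFit,
    config: ScoringConfig | None = None,
) -> MpnResult:
    """Score a complete assay and estimate the viable concentration.

    The growth rate and day-0 intercept are fitted on the least-dilute
    tier's growing tubes (tier-wise fallback with dilution rescaling when
    tier 1 has no fittable tube); end points for lower tiers follow from
    the same curve scaled by relative dilution.  All tubes must resolve to
    positive or negative; pending tubes raise :class:`AssayIncompleteError`.
    """
    cfg = config or ScoringConfig()
    lld_f = calibration.lld_f
    by_tier: dict[int, list[TubeSeries]] = {}
    for tube in tubes:
        if not 1 <= tube.tier <= design.q:
            raise ValueError(f"tube tier {tube.tier} outside design (q={design.q})")
        by_tier.setdefault(tube.tier, []).append(tube)

    # reference growth curve: mean mu and tier-1-equivalent F_Init over
    # fittable tubes, preferring the least-dilute tier
    fits: list[tuple[float, float]] = []
    for tier in sorted(by_tier):
        for tube in by_tier[tier]:
            try:
                fit = fit_growth_curve(tube, lld_f)
            except ValueError:
                continue
            if fit.mu > 0:
                # rescale intercept to tier-1 equivalence
                fits.append((fit.mu, fit.f_init * design.DR ** (tier - 1)))
        if fits:
            break

    if not fits:
        # nothing grew anywhere: every tube is negative provided it was
        # monitored at all; MPN is zero with a below-detection flag
        result = mpn_estimate(ScoreMatrix((0,) * design.q, design.r), design.table_inocula)
        result.n_viable = 0.0
        return result

    mu = float(np.mean([m for m, _ in fits]))
    f_init1 = float(np.exp(np.mean([math.log(f) for _, f in fits])))

    positives = []
    pending: list[tuple[int, int, float]] = []
    for tier in range(1, design.q + 1):
        t_end = predict_t_end(f_init1, lld_f, mu, tier_offset=tier - 1,
                              y_margin=cfg.y_margin, dr=design.DR)
        count = 0
        for tube in by_tier.get(tier, []):
            verdict = score_tube(tube, lld_f, t_end, cfg)
            if verdict == "positive":
                count += 1
            elif verdict == "pending":
                pending.append((tier, tube.replicate, t_end - tube.samples[-1].t))
        positives.append(count)
    if pending:
        raise AssayIncompleteError(pending)

    scores = ScoreMatrix(tuple(positives), design.r)
    result = mpn_estimate(scores, design.table_inocula)
    basis = result.mpn_raw if result.mpn_raw is not None else result.mpn
    result.n_viable = n_viable_from_mpn(basis, design.V, design.X, dr=design.DR)
    return result


def estimate_lag(
    fit_treated: GrowthFit,
    f_init_prime_untreated: float,
    n_viable_treated: float,
    *,
    tier: int | None = None,
    replicate: int | None = None,
) -> LagEstimate:
    """Growth lag of a treated sample from viable-cell-normalized intercepts.

    F' = F / N_viable is fluorescence per viable cell; in untreated
    cultures all cells are viable, so its day-0 intercept is the no-lag
    reference.  A treated tube whose normalized intercept falls below the
    untreated mean implies the growth curve is shifted right by

        lag = ln( F'_Init[untreated] / F'_Init[treated] ) / mu[treated]

    Negative lags (treated intercept above the reference) are returned
    as-is; they indicate estimation noise, not time travel.
    """
    if n_viable_treated <= 0:
        raise ValueError("n_viable_treated must be positive")
    if f_init_prime_untreated <= 0 or fit_treated.f_init <= 0:
        raise ValueError("normalized intercepts must be positive")
    if fit_treated.mu <= 0:
        raise ValueError("treated growth rate must be positive")
    f_prime_treated = fit_treated.f_init / n_viable_treated
    lag = math.log(f_init_prime_untreated / f_prime_treated) / fit_treated.mu
    gens = lag * fit_treated.mu / math.log(2)
    return LagEstimate(lag_days=lag, lag_generations=gens, tier=tier, replicate=replicate)
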