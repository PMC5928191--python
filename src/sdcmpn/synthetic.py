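"""Synthetic assay generator with known ground truth.

Emulates the statistical structure assumed by the MPN estimator and by
the precision formula — Poisson partitioning of viable cells into tubes —
together with the phenomenology of fluorescence-monitored grow-outs:
exponential increase at a common rate, an optional lag during which
treatment-depressed per-cell fluorescence recovers, a stationary-phase
plateau with optional post-plateau decline, and multiplicative
(lognormal) measurement noise.  Everything is driven by a single integer
seed, so each fixture is exactly reproducible.

The generator is deliberately simpler than real cultures: there is no
between-cell rate variation, no dose dependence of the growth rate, and
the lag/recovery ramp is an assumption (log-linear), not an observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dose_response import DoseResponseFit, DoseResponsePoint, predict_rv
from .growth_qc import FluorescenceSample
from .mpn import DilutionDesign
from .scoring import TubeSeries, predict_t_end

__all__ = ["SimulationConfig", "simulate_tubes", "simulate_dose_response"]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and phenomenology for one simulated assay.

    per_cell_f is fluorescence per (cells/mL), i.e. the calibration
    slope; blank_f the blank signal level; depression_factor the initial
    per-cell fluorescence multiplier after treatment (0.125 corresponds
    to the strongest depression commonly seen); plateau_f the
    stationary-phase ceiling; decline_rate an optional post-plateau
    exponential decay.  noise_sd is the SD of multiplicative noise on
    ln F.  duration_days defaults to the predicted end point of the most
    dilute tier plus two monitoring intervals.
    """

    n_viable_true: float = 100.0
    design: DilutionDesign = field(default_factory=lambda: DilutionDesign(X=-2))
    mu_true: float = 0.825
    per_cell_f: float = 1.0
    lld_f: float = 117.0
    blank_f: float = 1.0
    lag_days: float = 0.0
    depression_factor: float = 1.0
    plateau_f: float = 1.0e6
    decline_rate: float = 0.0
    noise_sd: float = 0.05
    monitor_interval: float = 2.0
    duration_days: float | None = None

    def __post_init__(self) -> None:
        if self.n_viable_true < 0:
            raise ValueError("n_viable_true must be non-negative")
        if not 0 < self.depression_factor <= 1:
            raise ValueError("depression_factor must be in (0, 1]")
        if self.mu_true <= 0:
            raise ValueError("mu_true must be positive")

    @property
    def schedule(self) -> np.ndarray:
        dur = self.duration_days
        if dur is None:
            # generous default: predicted end point of the most dilute
            # tier for a single cell, plus two extra readings
            f1 = max(self.n_viable_true, 1.0 / self.design.V) \
                * self.design.cf(1) * self.per_cell_f * self.depression_factor
            t_last = predict_t_end(max(f1, 1e-12), self.lld_f, self.mu_true,
                                   tier_offset=self.design.q - 1, y_margin=5.0,
                                   dr=self.design.DR)
            dur = max(t_last, 0.0) + self.lag_days + 2 * self.monitor_interval
        n_steps = int(math.ceil(dur / self.monitor_interval))
        return np.arange(n_steps + 1) * self.monitor_interval


def _depression_recovery(t: np.ndarray, factor: float, lag: float) -> np.ndarray:
    """Per-cell fluorescence multiplier: log-linear ramp from the
    depressed value back to 1 over the lag period (1 thereafter)."""
    if factor >= 1.0 or lag <= 0:
        return np.where(t >= 0, np.where(t < lag, factor, 1.0), factor) if factor < 1 else np.ones_like(t)
    frac = np.clip(t / lag, 0.0, 1.0)
    return np.exp(math.log(factor) * (1.0 - frac))


def simulate_tubes(
    config: SimulationConfig,
    seed: int,
) -> tuple[list[TubeSeries], np.ndarray]:
    """Simulate every tube of an assay; returns (tubes, true cell counts).

    Per tube the viable-cell count is Poisson with mean
    ``n_viable_true * V * CF(tier)``.  The noiseless signal is

        min(plateau_f, count/V * per_cell_f * recovery(t) * exp(mu * max(0, t - lag)))

    with exponential decline after the plateau is reached if
    ``decline_rate`` > 0; blank level is added and lognormal measurement
    noise applied.  Empty tubes emit blank-level noise only.
    """
    rng = np.random.default_rng(seed)
    design = config.design
    t = config.schedule
    tubes: list[TubeSeries] = []
    counts = np.zeros((design.q, design.r), dtype=int)

    for tier in range(1, design.q + 1):
        mean_cells = config.n_viable_true * design.V * design.cf(tier)
        for rep in range(1, design.r + 1):
            count = int(rng.poisson(mean_cells)) if mean_cells > 0 else 0
            counts[tier - 1, rep - 1] = count
            if count > 0:
                conc0 = count / design.V
                growth = np.exp(config.mu_true * np.maximum(t - config.lag_days, 0.0))
                signal = conc0 * config.per_cell_f \
                    * _depression_recovery(t, config.depression_factor, config.lag_days) \
                    * growth
                if config.decline_rate > 0 and np.any(signal >= config.plateau_f):
                    t_peak = t[np.argmax(signal >= config.plateau_f)]
                    signal = np.where(
                        t <= t_peak,
                        np.minimum(signal, config.plateau_f),
                        config.plateau_f * np.exp(-config.decline_rate * (t - t_peak)),
                    )
                else:
                    signal = np.minimum(signal, config.plateau_f)
            else:
                signal = np.zeros_like(t)
            noise = np.exp(rng.normal(0.0, config.noise_sd, size=t.shape))
            f_obs = noise * (config.blank_f + signal)
            samples = tuple(FluorescenceSample(t=float(ti), F=float(fi))
                            for ti, fi in zip(t, f_obs))
            tubes.append(TubeSeries(tier=tier, replicate=rep, samples=samples,
                                    f_start=float(f_obs[0])))
    return tubes, counts


def simulate_dose_response(
    true_fit: DoseResponseFit,
    doses: np.ndarray | list[float],
    reps: int,
    seed: int,
    *,
    noise_sd: float = 0.5,
    n0: float = 1.0,
) -> list[DoseResponsePoint]:
    """Draw noisy relative-viability observations around a true curve.

    Each observation is lognormal around predict_rv(dose) with ln-scale
    SD ``noise_sd``; ``reps`` independent draws per dose.  For end-to-end
    realism (MPN discretization included), instead simulate each dose's
    treated concentration through :func:`simulate_tubes` and the scoring
    pipeline.
    """
    rng = np.random.default_rng(seed)
    points: list[DoseResponsePoint] = []
    for dose in np.asarray(doses, dtype=float):
        rv_true = predict_rv(true_fit, float(dose))
        for _ in range(reps):
            rv = rv_true * math.exp(rng.normal(0.0, noise_sd))
            points.append(DoseResponsePoint(dose=float(dose), rv=rv * n0 / n0))
    return points
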