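"""Precision of MPN estimates as a function of assay design.

The standard error of the log of an MPN estimate under Poisson
partitioning is given by the Hurley–Roscoe expression

    sigma_ln = [ N^2 * sum_i (V*CF(i))^2 * r / (exp(V*CF(i)*N) - 1) ]^(-1/2)

where N is the viable concentration (cells/mL), V the tube volume (mL),
CF(i) the concentration factor of tier i, and r the replicate count.  The
multiplicative 95% interval on the estimate is N/exp(2*sigma) to
N*exp(2*sigma).

A factorial sensitivity analysis over realistic assay configurations
(concentration, volume, tiers, replicates, dilution ratio, with tier count
constrained to a total dilution range of 100–10,000) shows the dilution
ratio DR and replicate number r dominate; a log-log regression over the
grid yields the compact design rule

    sigma_ln ≈ 0.65 * DR^0.266 / sqrt(r)
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PrecisionQuery",
    "GridConfig",
    "PrecisionGridResult",
    "sigma_ln_mpn",
    "sigma_ln_mpn_volumes",
    "cf1_for",
    "run_grid",
    "sigma_approx",
    "ci_factor",
]

# Fitted power-law constants for the design approximation (log-log
# regression over the standard factorial; see run_grid).
APPROX_COEF = 0.65
APPROX_DR_EXP = 0.266


@dataclass(frozen=True)
class PrecisionQuery:
    """Inputs for a single Hurley–Roscoe evaluation."""

    n_viable: float
    V: float
    q: int
    r: int
    DR: float
    cf1: float

    def __post_init__(self) -> None:
        if min(self.n_viable, self.V, self.cf1) <= 0:
            raise ValueError("n_viable, V and cf1 must be positive")
        if self.q < 2:
            raise ValueError("q must be >= 2")
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if self.DR < 2:
            raise ValueError("DR must be >= 2")


def sigma_ln_mpn_volumes(n_viable: float, volumes: Sequence[float], r: int | Sequence[int]) -> float:
    """Hurley–Roscoe sigma from explicit per-tier sample volumes (mL).

    Overflow-safe: tiers with very large expected counts contribute
    nothing (their information term vanishes as exp(x) grows).
    """
    if n_viable <= 0:
        raise ValueError("n_viable must be positive")
    v = np.asarray(volumes, dtype=float)
    rr = np.broadcast_to(np.asarray(r, dtype=float), v.shape)
    x = v * n_viable
    with np.errstate(over="ignore"):
        denom = np.expm1(x)
    terms = np.where(np.isfinite(denom), v**2 * rr / np.where(np.isfinite(denom), denom, 1.0), 0.0)
    info = n_viable**2 * terms.sum()
    return float(info**-0.5)


def sigma_ln_mpn(query: PrecisionQuery) -> float:
    """Standard error of ln(N_viable) for a dilution design.

    Tier concentration factors follow CF(i) = cf1 * DR**-(i-1).
    """
    cf = query.cf1 * query.DR ** -np.arange(query.q, dtype=float)
    return sigma_ln_mpn_volumes(query.n_viable, query.V * cf, query.r)


def cf1_for(n_viable: float, V: float, DR: float) -> float:
    """Tier-1 concentration factor by the standard dilution rule.

    The sample is diluted by DR successively until the expected number of
    organisms per tube, ``V * CF(1) * n_viable``, is at most DR; hence the
    tier-1 tube holds >= 1 expected organism and tier 2 holds <= 1
    (whenever ``V * n_viable >= 1``).
    """
    if min(n_viable, V, DR) <= 0:
        raise ValueError("inputs must be positive")
    cf1 = 1.0
    while V * cf1 * n_viable > DR:
        cf1 /= DR
    return cf1


@dataclass(frozen=True)
class GridConfig:
    """Factorial specification for the design sensitivity analysis.

    Defaults enumerate the standard grid: concentrations 1–20 cells/mL
    (step 1) and 1,000–20,000 (step 1,000); volumes 1–10 mL; replicates
    3–10; dilution ratios 2–10; tier counts 3–8 restricted to a total
    dilution range 100 <= DR**(q-1) <= 10,000.
    """

    n_values: tuple[float, ...] = tuple(range(1, 21)) + tuple(range(1000, 20001, 1000))
    v_values: tuple[float, ...] = tuple(range(1, 11))
    r_values: tuple[int, ...] = tuple(range(3, 11))
    dr_values: tuple[int, ...] = tuple(range(2, 11))
    q_values: tuple[int, ...] = tuple(range(3, 9))
    range_min: float = 100.0
    range_max: float = 10_000.0

    def admissible_q(self, dr: float) -> tuple[int, ...]:
        return tuple(q for q in self.q_values if self.range_min <= dr ** (q - 1) <= self.range_max)


@dataclass
class PrecisionGridResult:
    """Output of the factorial sensitivity analysis."""

    rows: pd.DataFrame
    coef: float            # multiplier exp(intercept) of the power law
    dr_exponent: float
    r_exponent: float
    r_squared: float
    summaries: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_combinations(self) -> int:
        return len(self.rows)


def run_grid(config: GridConfig | None = None) -> PrecisionGridResult:
    """Enumerate the design factorial and regress ln(sigma) on design factors.

    For every surviving combination the tier-1 concentration factor is set
    by :func:`cf1_for` and sigma by the Hurley–Roscoe formula; the power-law
    summary comes from an OLS regression of ln(sigma) on ln(DR) and ln(r)
    with intercept.  Per-(DR, r) medians and 5th/95th percentiles of sigma
    and of the CI factor exp(2*sigma) are tabulated.
    """
    cfg = config or GridConfig()
    recs = []
    for dr in cfg.dr_values:
        qs = cfg.admissible_q(dr)
        for q, n, v in itertools.product(qs, cfg.n_values, cfg.v_values):
            cf1 = cf1_for(n, v, dr)
            cf = cf1 * float(dr) ** -np.arange(q, dtype=float)
            vols = v * cf
            x = vols * n
            with np.errstate(over="ignore"):
                denom = np.expm1(x)
            terms = np.where(np.isfinite(denom), vols**2 / np.where(np.isfinite(denom), denom, 1.0), 0.0)
            base_info = n**2 * terms.sum()  # information per replicate
            for r in cfg.r_values:
                recs.append((dr, q, n, v, r, cf1, (base_info * r) ** -0.5))
    rows = pd.DataFrame(recs, columns=["DR", "q", "n_viable", "V", "r", "cf1", "sigma"])

    y = np.log(rows["sigma"].to_numpy())
    X = np.column_stack([
        np.ones(len(rows)),
        np.log(rows["DR"].to_numpy(dtype=float)),
        np.log(rows["r"].to_numpy(dtype=float)),
    ])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    r2 = 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

    grp = rows.groupby(["DR", "r"])["sigma"]
    summaries = grp.agg(
        median="median",
        p05=lambda s: float(np.percentile(s, 5)),
        p95=lambda s: float(np.percentile(s, 95)),
        count="count",
    ).reset_index()
    # monotone transform: median of exp(2 sigma) == exp(2 * median sigma)
    for col in ("median", "p05", "p95"):
        summaries[f"ci_factor_{col}"] = np.exp(2 * summaries[col])

    return PrecisionGridResult(
        rows=rows,
        coef=float(np.exp(beta[0])),
        dr_exponent=float(beta[1]),
        r_exponent=float(beta[2]),
        r_squared=float(r2),
        summaries=summaries,
    )


def sigma_approx(DR: float, r: int) -> float:
    """Power-law design approximation sigma = 0.65 * DR^0.266 / sqrt(r).

    Fitted over DR in 2..10 and r in 3..10; values outside that domain are
    extrapolations (DR < 2 in particular lies outside the fitted grid).
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    return APPROX_COEF * DR**APPROX_DR_EXP / math.sqrt(r)


def ci_factor(sigma: float) -> float:
    """Multiplicative width exp(2*sigma) of the lognormal 95% interval."""
    return math.exp(2.0 * sigma)
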