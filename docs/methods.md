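# Methods

This note records the statistical models implemented in `sdcmpn`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would want to
know about.

## The MPN model

The estimator assumes viable organisms are Poisson-distributed among
tubes: a tube holding `v` mL-equivalents of sample at concentration `λ`
is sterile with probability `exp(-λ v)`. The likelihood of a score
(per-tier positive counts) is a product of binomials, and the MLE solves
the score equation

    Σ_{positive tubes} v_i / (1 − exp(−λ v_i)) = Σ_{all tubes} v_i

`mpn_estimate` brackets the root in `[1e-9, 1e9]` (table units) and
solves with Brent's method; the tests cross-check every calculable
5-replicate, 3-tier score against a dense-grid likelihood maximizer that
shares no code with the estimator.

*Censoring.* An all-negative score has no interior MLE; it is reported
as 0 with a `below_detection` flag. An all-positive score is likewise
boundary-censored; it is reported as the estimate of the largest
calculable score (one negative tube in the most dilute tier), flagged
`above_quantitative_range`, and should be read as a lower bound.

*Rounding.* Estimates default to 2 significant figures, matching the
convention of the classical lookup tables the estimator replaces. The
range of the standard 5 × 3 tenfold design is then exactly 1.8–1600
organisms, i.e. 0.36–320 cells mL⁻¹ in 5-mL tubes at leading exponent
X = −1.

*Confidence intervals.* The default interval is lognormal,
`mpn · exp(±2σ)`, with σ the Hurley–Roscoe standard error (below)
evaluated at the point estimate — the same σ used in assay design, so
design-time and report-time uncertainty statements agree. A
profile-likelihood interval (likelihood-ratio inversion, χ²₁) is
available via `ci_method="profile"` for small scores where the
lognormal approximation is crude.

*Back-calculation.* The conversion from a table-referenced MPN to a
concentration is `N_viable = MPN · V⁻¹ · 10^−(1+X)`. An alternative
exponent convention, `10^−(1−X)`, appears in some write-ups; it is
inconsistent with the 0.36–320 range above (which requires a factor of
1 at X = −1), so this package uses the `1+X` form throughout.

*Choice of dilution range.* `choose_dilution_range` centres the design
on the median calculable table MPN: `X = round(log10(MPN_med/(N·V))) − 1`
with ties rounded away from zero (ties never arise for realistic
inputs). `MPN_med` is 22 for 3- and 5-replicate designs and 21 for
10-replicate designs; these are conventional constants of the tabulated
estimator, taken as given rather than recomputed.

## Growth QA/QC and detection limits

Specific growth rate is computed from dark-acclimated fluorescence with
the semicontinuous-dilution correction `μ = ln(F₂/(1−d)/F₁)/Δt` (units:
day⁻¹; `d` is the fraction of culture replaced since the previous
reading).

Balanced growth — the steady exponential state in which viability tests
should start — is accepted over a window of at least ten generations
when CV[μ] ≤ 10% and CV[Fv/Fm] ≤ 10% for cultures with mean μ ≥ 0.5
day⁻¹. Below that rate, measurement noise makes the μ-CV criterion
unattainable, so the package instead requires R² ≥ 0.995 for the
regression of ln cumulative (dilution-compounded) fluorescence on time,
together with the Fv/Fm criterion. CVs use the sample (n−1) standard
deviation; the criterion source does not specify a denominator and the
difference is immaterial at the window lengths involved.

The lower limit of detection is calibrated by OLS of fluorescence on
cell concentration over a dilution series: `LLD_cell = 3·s_yx/m` with
`s_yx` the residual standard error (n−2). `delta_f_min`, the smallest
demonstrable fluorescence increase, is the increment above `LLD_F` at
which the lower 95% confidence band of the predicted mean response (t
distribution, n−2 df) equals `LLD_F`; it is found by bracketed
root-finding on the band equation and is 0 for a perfect fit. Its ratio
to `LLD_F` depends strongly on the blank intercept of the calibration;
realistic calibrations with a positive blank put it at a small fraction
(roughly 0.1–0.5) of `LLD_F`, which is why a sub-50% increase above the
detection limit is already demonstrable even though the default scoring
threshold is 8×.

## Scoring and end points

A tube scores positive when fluorescence reaches
`threshold_factor · max(LLD_F, F_start)` at or before `t_end`, and once
positive stays positive — stationary-phase cultures lose fluorescence,
and Monte Carlo as well as bench experience show that single-date
scoring of a declining culture undercounts. The default
`threshold_factor` of 8 guards against treatment-depressed per-cell
fluorescence recovering (without division) being mistaken for growth:
the worst depression commonly observed is about 8-fold. When per-cell
fluorescence is known to be stable, a relaxed 1.5× criterion shortens
assays; positives under 8× are always a subset of positives under 1.5×.

`t_end` extrapolates the least-dilute tier's fitted growth curve
(regression of ln F on time, points above `LLD_F` only) down by each
tier's relative dilution and adds a margin of `Y` generations beyond the
predicted time to reach `LLD_F`:

    t_end = ( Y·ln2 − ln(DR^(−tier_offset) · F_Init / LLD_F) ) / μ

`Y = 5` covers ~99% of late-growing tubes, `Y = 3` ~95%. The tier
correction *lengthens* the wait for more dilute tiers (their curves sit
lower, so they cross the detection limit later); a sign-inverted variant
of this factor circulates in print and is rejected here because it
contradicts the worked benchmark values (12.76 → 13 days at Y = 5 and
11.08 → 11 days at Y = 3 for a species with 0.84-day generation time,
LLD 117 cells mL⁻¹, and 10 cells mL⁻¹ starting concentration, third
tier).

Because monitoring is discrete, the raw `t_end` is rounded up to the
tube's first reading at or after it: a crossing first seen on that
reading still counts, and a tube not yet observed past `t_end` is
`pending`, never negative. `run_assay` refuses to assemble an MPN while
any tube is pending and lists the offenders. If no tube anywhere in the
assay supports a growth fit, the assay is reported below detection; the
caller is responsible for having monitored to the planned duration
before drawing that conclusion.

Growth lag after treatment is estimated from viable-cell-normalized
intercepts, `lag = ln(F′_untreated/F′_treated)/μ_treated`, with the
untreated reference taken as the mean over the untreated top tier.
Negative lags are reported as-is; they are estimation noise, and
truncating them would bias lag distributions upward.

## Dose-response model

Relative viability vs dose is fitted on ln RV (the data span up to six
decades; natural log is used — the base only rescales the residuals).
The model is a shoulder followed by single- or two-component exponential
decline, continuous at the threshold. Fitting profiles `D_Th` over a
candidate grid (observed doses plus a uniform grid) with the remaining
first-order parameters solved in closed form, then polishes; the
biphasic form adds bounded nonlinear least squares (`scipy`'s
trust-region reflective, a Levenberg–Marquardt-class method) from five
deterministic multistarts, with `k₁ ≥ k₂` enforced by the (k₁,k₂,α) ↔
(k₂,k₁,1−α) symmetry. Input points are canonically sorted so fits are
exactly invariant to input order; duplicated points act as weights.

Selection and pruning: the biphasic form is reported only when its
residual standard error (n−p denominator) is strictly lower than the
first-order fit's *and* both sensitivities are positive with k₁ > k₂ —
never with k₂ ≤ 0, which would imply viability increasing at high dose.
When both forms fit essentially perfectly the simpler form wins. If the
95% CI (linearized, from a finite-difference Jacobian at the optimum)
of the intercept covers 1 or that of the threshold covers 0, the term
is removed and the model refitted, mirroring standard
parsimony practice for these curves. With zero-noise data and no doses
below the threshold, (D_Th, RV₀) lie on an exact trade-off ridge; data
at dose 0 (the dark control) anchor both, which is why the package and
its tests always include it.

`dose_for_rv` inverts the fitted curve (closed form for first-order,
bracketed root-finding for biphasic) to 10⁻⁹ relative accuracy;
`normalize_fits` rescales doses and sensitivities by a reference
species' target dose so that cross-species tables are unit-free.
`REFERENCE_RELATIVE_FITS` ships relative-parameter curves for nine
marine phytoplankton taxa as a named fixture; two of those taxa's
printed target doses disagree slightly with the closed form at the
printed parameter precision (noted in the fixture docstring), so they
are not used as numerical benchmarks.

## Design precision

`sigma_ln_mpn` implements the Hurley–Roscoe standard error of
ln(N_viable). It is overflow-safe: tiers with enormous expected counts
contribute no information and are zeroed rather than overflowing.
σ scales exactly as r^(−1/2) (r enters the information sum linearly)
and decreases with V in the dilute regime; once tier counts saturate,
extra volume adds no information, so V-monotonicity is not global.

The factorial sensitivity analysis enumerates N ∈ {1…20} ∪
{1000…20000 step 1000}, V ∈ {1…10}, r ∈ {3…10}, DR ∈ {2…10}, and
q ∈ {3…8} restricted to a total dilution range 100 ≤ DR^(q−1) ≤ 10⁴ —
70,400 surviving combinations. The tier-1 concentration factor follows
the standard bench rule: dilute by DR until `V·CF(1)·N ≤ DR`, so tier 1
holds ≥ 1 expected organism and tier 2 ≤ 1. A log-log OLS of σ on DR
and r (normal equations; three coefficients) explains 96.0% of the
variance and reproduces the power law σ = 0.65·DR^0.266/√r with the r
exponent at −0.5 to machine precision. `sigma_approx` hard-codes the
published constants rather than the refit, so quick-look numbers are
stable across grid changes; at DR = 10, r = 5 the CI factor exp(2σ) is
2.9. Per-(DR, r) summaries report medians and 5th/95th percentiles,
with the median of exp(2σ) computed as exp(2·median σ) (a monotone
transform) and percentiles by linear interpolation.

## Synthetic data

`simulate_tubes` draws per-tube viable counts Poisson(N·V·CF(tier)) —
the same assumption the estimator and σ formula make, which is the
point: it lets coverage claims be tested against their own model. The
fluorescence trajectory is blank + min(plateau, count/V · per-cell
slope · recovery(t) · e^(μ·max(0, t−lag))), times lognormal noise
(default SD 0.05 on ln F, instrument-level). Treatment-depressed
per-cell fluorescence recovers along a log-linear ramp over the lag —
an assumption, as the true recovery shape is not observable from bulk
fluorescence. Post-plateau decline is exponential from the first
reading at the ceiling. The default monitoring interval is 2 days and
the default duration is the predicted most-dilute-tier end point plus
two readings, so unattended simulations are scoreable.

What the generator does *not* emulate: between-cell growth-rate
variation, dose-dependent growth-rate depression, chain-forming or
clumping taxa (which break the Poisson assumption), fluorescence
quenching artefacts, and contamination. Passing coverage tests
therefore show the pipeline is correct *under its own statistical
model*, not that real assays achieve nominal coverage.

`simulate_dose_response` draws RV lognormally around a true curve
(ln-scale SD 0.5 by default, typical of MPN-quantized viability data);
for end-to-end realism each dose can instead be routed through
`simulate_tubes` + `run_assay`.

## Problem sizes and tolerances

The test suite uses 200-replicate simulation studies for both coverage
checks (assay interval coverage ≥ 90%; first-order k CI coverage ≥ 90%)
and a 2,000-tube occupancy check — sizes at which binomial error on a
90% bound is ~2%, sufficient to detect real miscalibration. The
dense-grid MPN oracle uses 2–4 × 10⁵ log-spaced points over λ ∈
[10⁻³, 5·10³], resolving the MLE to ~10⁻⁴ relative, against a 10⁻³
assertion. Root-finding tolerances are 10⁻¹² (score equation) and
10⁻¹⁵ (dose inversion). Parameter-recovery CI calibration is assessed
with the first-order fitter on first-order truth; under full model
selection the biphasic form is occasionally (and legitimately) chosen
on noisy first-order data, which measures selection behaviour rather
than CI calibration.

## Known limitations

- Unequal replicate counts per tier are structurally representable in
  the estimator internals but not exposed or tested.
- The improbability screening that classical tables apply to "unlikely"
  scores is not reimplemented; every non-censored score is estimable.
- The lognormal CI understates uncertainty for scores adjacent to
  censoring (e.g. a single positive tube); use the profile interval
  there.
- `run_assay` assumes a common growth rate across tiers (the model's
  own assumption); strongly dose-dependent growth-rate depression would
  bias `t_end` and is not modelled.
- The relaxed 1.5× scoring threshold is only defensible when per-cell
  fluorescence is demonstrably stable under the treatment studied.
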