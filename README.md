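# sdcmpn

Tools for **serial dilution culture–most probable number (SDC-MPN)
viability assays**: estimating viable-cell concentrations from
growth-positive tube patterns, quality-controlling fluorescence-monitored
cultures, scoring grow-out incubations with principled end points,
fitting shouldered/biphasic UVC dose-response curves, and choosing assay
designs by their statistical precision.

The SDC-MPN method asks a simple question of each tube in a replicated
dilution series — did anything grow? — and converts the pattern of
positive tubes into the most probable number of viable organisms in the
original sample. It measures *viability* (the ability to reproduce)
rather than a proxy of cellular function, which makes it the assay of
record for treatments such as UVC whose primary mode of action is
suppression of reproduction. Its natural users are phycologists and
ballast-water / disinfection researchers who monitor growth by in vivo
chlorophyll-a fluorescence.

## The statistics at the core

**MPN estimation.** Under Poisson partitioning, a tube inoculated with
*v* mL-equivalents of sample at viable concentration *λ* is positive with
probability 1 − e^(−λv). The maximum-likelihood estimate for a score
(positive counts per tier) solves

```
Σ_{positive tubes} v_i / (1 − exp(−λ v_i)) = Σ_{all tubes} v_i
```

which `sdcmpn` solves directly by root-finding for any dilution ratio,
tier count, and replicate number, instead of consulting lookup tables
(themselves tabulations of this estimator).

**Precision.** The standard error of ln(N_viable) for a design with
volume *V*, tiers *i* = 1…q at concentration factors CF(i), and *r*
replicates is

```
σ = [ N² · Σ_i (V·CF(i))²·r / (exp(V·CF(i)·N) − 1) ]^(−1/2)
```

and the lognormal 95% interval on the estimate is N/exp(2σ) — N·exp(2σ).
A factorial sweep over realistic designs collapses to the design rule
σ ≈ 0.65·DR^0.266/√r.

**Scoring end points.** A tube is positive once fluorescence exceeds
8× max(LLD_F, F_start) at or before

```
t_end = ( Y·ln2 − ln(DR^(−tier offset) · F_Init / LLD_F) ) / μ
```

where μ and F_Init come from regression of ln F on time in the
least-dilute tier and Y is a safety margin in generations (5 default, 3
relaxed). Tubes that never meet the threshold by t_end are negative —
never merely "not yet grown".

**Dose-response.** Relative viability vs UVC dose is fitted on the log
scale to a shoulder-plus-biphasic model
RV(D) = RV₀·[(1−α)e^(−k₁(D−D_Th)) + α·e^(−k₂(D−D_Th))] for D > D_Th,
with first-order (k₁ = k₂) and biphasic forms selected by residual error
and sign constraints.

## Worked example

Score (5, 3, 1) on the standard design — five 5-mL replicates per tier
at dilutions 10⁻¹, 10⁻², 10⁻³:

```python
from sdcmpn import ScoreMatrix, mpn_estimate, n_viable_from_mpn

result = mpn_estimate(ScoreMatrix((5, 3, 1), 5), (0.1, 0.01, 0.001))
n_viable = n_viable_from_mpn(result.mpn_raw, V=5.0, X=-1)
print(result.mpn, result.sigma_ln, n_viable)
```

prints

```
110.0 0.5321735193097801 21.728950170971686
```

an MPN of 110 organisms per reference inoculum (2 significant figures,
matching the classical tables), a log-scale standard error of 0.53 —
i.e. a 95% interval of roughly ×/÷ 2.9 — and a viable concentration of
21.7 cells mL⁻¹ for the 5-mL, X = −1 assay.

The same from the shell:

```
sdcmpn mpn scores.csv -V 5 -X -1
sdcmpn design --quick 10 5        # sigma and CI factor for a design
sdcmpn simulate sim.yaml --seed 7 --out tubes.csv
sdcmpn score tubes.csv --lld 117 -X -2
```

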