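# Methods

## Moult scoring

A specimen record holds 0/1 moult scores for the 48 discrete wing and tail
feathers and moulted proportions for the lesser- and median-covert tracts
(too many small feathers to score individually). The moulted plumage area is

    A = Σ_t f_t · a_t        [mm²]

over the ten tracts, with `f_t` the tract's moulted fraction and `a_t` the
species-specific mean tract area. Interpretation choices:

- `a_t` is a **per-tract total**; feathers within a tract share it equally
  (area tables carry only per-tract mm²). A brute-force per-feather sum with
  feather area `a_t / n_t` therefore reproduces `A` exactly, which the tests
  use as an oracle.
- **Missing feathers** (damaged skins) rescale the tract denominator: the
  fraction is moulted-over-*observed*, not moulted-over-total, so damage does
  not bias extent downward. A tract with no observed feather is an error, not
  a zero.
- Feather numbering (P1 = innermost primary, tertials labelled T7–T9,
  descendant covert numbering) is a fixed I/O convention.

**Relative extent** is `A` divided by the species' total wing+tail area, used
for cross-species averaging. The **annual moult index** averages relative
extent per species within a year, averages those species means with equal
weight (so well-sampled species do not dominate), and min–max-normalises the
yearly averages: the lowest yearly mean maps to 0 and the highest to 1. At
least two distinct yearly means are required; a zero range is an error rather
than a silent division by zero. Years with fewer than a configurable minimum
number of species (default 1) are dropped before normalisation; no smoothing
is applied.

## Temperature covariate

Anomalies are °C relative to the 1951–1980 reference mean, annual resolution
only. Two sources are composited over the union of their ranges with
instrumental precedence; a year covered by neither is an error. No
re-baselining, interpolation or monthly downscaling is attempted — a global
annual index cannot support finer inference, so lookups are exact per-year
values.

## Per-species Gamma GLM and AICc selection

Moult extent is positive and right-skewed, so each species is modelled as
`y_i ~ Gamma(ν, µ_i)` with identity link `µ_i = x_iᵀβ`. The identity link is
not variance-stabilising and does not respect the Gamma domain, so the IRLS
update (working response `y`, weights `1/µ²`) is guarded by step-halving
whenever a step would make any fitted mean non-positive; convergence is a
relative deviance change below 1e-10 (or 200 iterations). For a Gamma GLM
the ML mean coefficients do not depend on ν, so ν is profiled afterwards by
solving `log ν − ψ(ν) = mean(y/µ̂ − 1 + log µ̂ − log y)` (bracketed root in
log ν). The reported log-likelihood is the full Gamma likelihood at (β̂, ν̂).

Candidates are hierarchical subsets of {GMTA, sex, GMTA×sex} plus the
intercept-only model — two candidates for monomorphic species, five for
dichromatic ones (the interaction only alongside both main effects). Sex is
coded female = 0, male = 1, so the interaction coefficient is male-relative.
AICc is `−2ℓ + 2k + 2k(k+1)/(n−k−1)` with **k counting the shape parameter**,
since full likelihoods are compared. A candidate is *selected* only when the
runner-up's ΔAICc strictly exceeds the threshold (default 2.00); otherwise
selection is ambiguous ("none"). The runner-up (not the null) defines the
margin; the full ΔAICc vector is reported so either reading can be made.

Practical rules: the response defaults to moulted area in mm² (relative
extent available by config); zero-extent records are outside the Gamma
support and are dropped with a logged count in the pipeline, while the
standalone `fit` CLI subcommand aborts naming the offending specimen (a
user-supplied file with zero rows more likely signals a data problem than a
featherless bird). In dichromatic species, unknown-sex records are dropped
and *all* candidates are refit on the common subset so AICc values are
comparable; species where fewer than 90% of records have known sex are
excluded. The covariate can be swapped from GMTA to calendar year (centred
at its per-species mean for numerical stability; the slope is unchanged by
centring).

## PGLS with Pagel's λ

Cross-species regressions use generalized least squares under
`V(λ) = λ·C + (1−λ)·diag(C)`, where `C` is the Brownian matrix (entry =
shared root-to-tip path length). λ is estimated by maximising the profile
log-likelihood `ℓ(λ) = −½[n log(2πσ̂²) + log|V| + n]`, `σ̂² = rᵀV⁻¹r/n`,
over a 21-point grid refined by bounded scalar optimisation in the
bracketing interval; λ is capped at [0, 1] and ties (within 1e-9) break
toward smaller λ because the profile can be flat or bimodal at small n.
Reported statistics follow the OLS analogues under the GLS inner product:
r² against a GLS intercept-only fit at the same λ, `F = (r²/df1)/((1−r²)/df2)`
with `df1 = predictors`, `df2 = n − predictors − 1`, residual variance on
n − p degrees of freedom, and the ML log-likelihood used for profiling.
p-values are two-tailed at α = 0.05 (for one predictor the F test equals the
two-tailed slope t test). Non-ultrametric trees are accepted with a logged
warning (the Brownian matrix is still well-defined, but λ's interpretation
weakens). λ = 1 PGLS on an ultrametric tree subsumes independent contrasts,
so no separate contrasts method is provided.

Comparative responses: the migration-distance and moult-strategy contrasts
regress the per-species GMTA coefficient — taken from the selected model
when it contains GMTA, else from the lowest-AICc GMTA-containing candidate —
on a binary class indicator. The ornamentation regression uses the GMTA×sex
coefficient from the **full interaction model** for every dichromatic
species, whether or not that model was selected, so the regression covers
the whole dichromatic set rather than only species with decisive interaction
evidence. Both choices are config-exposed.

## Synthetic data generator

The generator emulates the study conditions rather than any particular real
dataset:

| parameter | default | rationale |
|---|---|---|
| species | 19 | study panel size |
| specimens/species | 200 | ≈ observed mean (4012/19 ≈ 211, all > 100) |
| years | 1805–2016, start years 1805–1864 | study period and reported start-year range |
| anomaly series | quadratic trend, ≈ 2.0 °C total rise, noise sd 0.05 °C, centred on 1951–1980 | reported total warming and reference window |
| intercept | 1100 mm² (sd 150 across species) | a partial moult ≈ 20% of a ~6000 mm² wing+tail |
| GMTA slope | 150 mm²/°C (sd 50) | ≈ 15% extent increase per °C, a strong but plausible response |
| sex effect | +100 mm² | males historically moult somewhat more |
| ornamentation slope | −150 mm²/°C per unit | sets the built-in negative interaction–dichromatism relationship |
| interaction noise sd | 25 mm²/°C | species scatter around that relationship |
| Gamma shape ν | 25 | ≈ 20% coefficient of variation, museum-grade noise |
| λ_true | 0.5 | neutral default; experiments set 0 or 1 explicitly |

Species coefficients are multivariate normal with covariance `sd²·Ṽ(λ_true)`
(Ṽ = unit-diagonal Brownian correlation of a simulated Yule tree), so
λ_true controls the phylogenetic signal of the species effects. Specimen
areas are Gamma draws around the identity-link mean, capped at the species
total (cap events are logged; default parameters keep them rare) and
validated to stay positive across each species' observed anomaly range.
Drawn areas are realised into feather scores deterministically: tracts fill
in a fixed priority order (LC, MC, GC, CC, AL, T, R, PC, S, P —
an abstraction of the typical passerine post-juvenile sequence, coverts
before flight feathers), whole feathers in label order, stopping at the
first unaffordable feather; proportion tracts absorb exactly. Scoring a
generated record therefore recovers the drawn area to within one feather's
area, and identical configs yield byte-identical output files.

Effect sizes were fixed by an a-priori power calculation: with ν = 25,
n = 200 and an anomaly sd of ≈ 0.6 °C, the GLM interaction estimate has a
standard error near 50 mm²/°C, giving the 12-species ornamentation
regression (slope −150, predictor sd ≈ 0.4) an expected t ≈ 3.5–4 and
roughly 90% power at α = 0.05 — which the end-to-end recovery experiment
then verifies empirically. The 12-species recovery experiment makes all
species dichromatic because the ornamentation regression is defined only
over dichromatic species.

What the generator does **not** emulate: collection-effort biases over time,
latitude effects, real moult-sequence biology beyond the priority order,
measurement error in tract areas, and overdispersion beyond the Gamma. A
passing recovery suite therefore shows the estimators work under the assumed
model, not that the model fits any particular museum dataset.

## Pipeline

`run_full_analysis` validates paths before any computation, then runs load →
score → index → per-species GLM → PGLS → manifest. Species with fewer than
30 usable specimens (configurable; the study used species with > 100) are
excluded from the comparative stage with a logged list. Outputs are
deterministic given config + inputs; each CSV carries the manifest hash
(sha-256 of the canonical config) in a leading comment line so
mixed-provenance outputs are detectable. Any stage failure removes partial
outputs and surfaces a stage-named error; the CLI maps stages to distinct
exit codes.

## Problem sizes in the test suite

The verification experiments use 50 replicates for slope and end-to-end
recovery, 200 simulated species for null selection calibration, 100
replicates for λ recovery on 50-tip trees, and 100 random records for the
scoring oracle — sizes at which the Monte-Carlo error of each pass/fail
margin is small relative to its threshold. The full suite runs in well under
a minute on one CPU.

## Known limitations

- The identity link admits parameter regions where fitted means approach
  zero; the step-halving guard keeps IRLS inside the domain but data truly
  requiring a negative mean fail with a convergence error rather than a fit.
- λ is bounded at 1 (no extension to the positive-definite limit), and its
  ML estimate is noisy below ~20 species; group contrasts at n ≈ 10 have
  limited power, mirroring the real analysis.
- The min–max moult index is sensitive to extreme years by construction
  (its endpoints are single yearly means).
- Zero-extent specimens cannot enter the Gamma likelihood; if they are
  frequent in a real dataset, the drop-with-count policy changes the
  estimand to "extent conditional on any moult".
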