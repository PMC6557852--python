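# moultclim

Tools for analysing how the extent of the **post-juvenile feather moult** of
passerine birds relates to **global mean temperature anomalies (GMTA)** over
a two-century museum-specimen record.

Juveniles of most passerine species replace only part of their nest-grown
plumage in their first months. How much they replace depends on time and
resources, both of which shift under a warming climate. `moultclim`
implements the full analysis chain for testing that relationship:

1. **Moult scoring** — each specimen carries 0/1 moult scores for 48 wing and
   tail feathers (greater coverts GC1–10, carpal covert CC, alula AL1–3,
   primary coverts PC1–9, primaries P1–10, secondaries S1–6, tertials T7–9,
   rectrices R1–6) plus moulted proportions for the lesser and median
   coverts. The extent statistic is the moulted plumage area
   `A = Σ_t f_t · a_t` (mm²), where `f_t` is tract *t*'s moulted fraction and
   `a_t` its species-specific mean area. A year-averaged, min–max-normalised
   **moult index** summarises all species on a [0, 1] scale.
2. **Climate covariate** — an annual anomaly series (°C relative to the
   1951–1980 reference mean) composited from an instrumental record (1880
   onward) and an earlier glacier-based reconstruction, with instrumental
   precedence on overlap.
3. **Per-species models** — Gamma GLMs with identity link,
   `y ~ Gamma(ν, µ)`, `µ = β₀ + β₁·GMTA (+ β₂·sex + β₃·sex·GMTA)`,
   fitted by positivity-preserving IRLS with profile-ML shape ν, compared by
   AICc (shape counted in *k*); a model is *selected* only when the
   runner-up's ΔAICc exceeds 2.00. Sex terms enter only for sexually
   dichromatic species.
4. **Comparative stage** — cross-species phylogenetic generalized least
   squares (PGLS) with maximum-likelihood Pagel's λ ∈ [0, 1] (λ multiplies
   the off-diagonal entries of the Brownian variance–covariance matrix):
   contrasts of the per-species GMTA response between migration-distance and
   moult-strategy classes, and the regression of the GMTA×sex interaction
   coefficient on the male − female plumage-ornamentation difference.
5. **Synthetic data** — a generator producing complete input bundles
   (ultrametric Yule tree, phylogenetically correlated species coefficients,
   centred anomaly series, tract areas, per-feather specimen records) so
   every stage can be validated by parameter recovery without access to
   museum databases.

## Worked example

```python
import pandas as pd
import moultclim as mc

cfg = mc.SyntheticConfig(n_species=12, n_specimens=200, lambda_true=0.0,
                         dichromatic_fraction=1.0, seed=0)
ds = mc.simulate_dataset(cfg)                      # 2400 specimen records
results = mc.per_species_analysis(ds.records, ds.areas, ds.layout,
                                  ds.gmta, ds.metadata)
interaction = pd.Series({sp: r.fit_for("gmta+sex+gmta:sex").coefficients["gmta:sex"]
                         for sp, r in results.items()})
fit = mc.ornamentation_regression(interaction, ds.metadata["ornament_male"],
                                  ds.metadata["ornament_female"], ds.tree)
```

The per-species AICc table for one species (`mc.selection_table`):

```
        candidate  k   n        aicc  delta_aicc  selected
        intercept  2 200 2793.084733   34.671531     False
             gmta  3 200 2766.460349    8.047147     False
              sex  3 200 2788.854559   30.441357     False
         gmta+sex  4 200 2758.413202    0.000000     False
gmta+sex+gmta:sex  5 200 2759.932182    1.518980     False
```

Here the GMTA+sex model ranks best but its ΔAICc margin over the interaction
model is only 1.52 ≤ 2.00, so the selection is reported as ambiguous
("none") — GMTA clearly matters (ΔAICc 34.7 against the intercept model),
but the sex-interaction evidence is equivocal for this species.

The comparative-stage regression prints

```
ornamentation slope = -161.0 mm2/degC per unit, r2 = 0.62,
F(1,10) = 16.27, p = 0.0024, lambda = 0.00
```

recovering the generator's built-in negative ornamentation effect (−150
mm²/°C per ornamentation-difference unit): species with stronger plumage
dichromatism have lower (more negative) male-relative GMTA×sex interaction
coefficients, i.e. females respond more strongly to warming than males where
males are much more ornamented. λ = 0 matches the generating condition
`lambda_true=0` (no phylogenetic signal in the residuals).

A command-line interface mirrors the library
(`moultclim simulate | score | index | fit | pgls | run-all`):

```bash
moultclim simulate --seed 7 --out data/
moultclim run-all --data-dir data/ --out results/
```

`run-all` writes the per-specimen extent table, the moult-index series, the
per-species selection table, the PGLS reports and a run manifest; reruns
with the same config are byte-identical.

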