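# shockmetab

A tested, reusable implementation of a multi-compartment metabolomics
discrimination pipeline for two-arm animal studies of hemorrhagic shock.
The motivating design compares carbohydrate-prefed (CPF) against fasted
(FS) pigs sampled in four compartments — liver, muscle, serum, urine — at
six timepoints: baseline (B), end of shock (S45), and 2/8/20 h of
resuscitation plus a 48 h recovery point (FR2, FR8, FR20, PR48).  The
question the pipeline answers, per compartment and per timepoint or
consecutive time interval, is: *do the two feeding arms differ in their
metabolite profiles, which metabolites drive the difference, and is the
discrimination statistically defensible?*

Because per-animal concentration tables for such studies are rarely
deposited, the package ships a first-class synthetic-study generator with
known ground truth, so every stage — and the pipeline end to end — is
testable without any external download.

## Pipeline

1. **Preprocessing** (`shockmetab.preprocess`)
   - Urine: concentrations (mM) are multiplied by urine output (cc/hr/kg)
     to give abundances in nmol/h/kg, then transformed as
     `log10(x + 0.1)` so exact zeros (anuric or undetected samples) map to
     −1.  Liver/muscle/serum stay on the concentration scale.
   - Contrasts are a single timepoint or a per-animal difference between
     consecutive timepoints (S45−B, FR2−S45, FR8−FR2, FR20−FR8).
   - Every analysis matrix is autoscaled: per metabolite, mean 0 and unit
     sample standard deviation.
2. **Outlier screening** (`shockmetab.outliers`) — samples outside the 95%
   Hotelling T² ellipse of the first two principal-component scores
   (threshold `2(n−1)/(n−2)·F₀.₉₅(2, n−2)`) are removed once, and the
   remaining rows are re-autoscaled.
3. **PLS-DA** (`shockmetab.plsda`) — two-class partial least squares
   discriminant analysis by single-response NIPALS with deflation; classes
   coded ±1; fit quality reported as R²Y.
4. **Validation** (`shockmetab.validation`) — nested cross-model
   validation (2CV): repeated stratified 75/25 train/test splits; the
   component count is chosen on each training set by leave-10-out inner CV
   minimizing the number of misclassifications (NMC); accuracy ≥ 80% gates
   a model as "potential"; significance by class-label permutation
   (default 1000 iterations) with the add-one p-value
   `p = (1 + #{null ≤ observed}) / (1 + n_perm)`.
5. **Variable ranking** (`shockmetab.plsda.vip_scores`) — Wold's variable
   importance in projection,

   `VIP_j = sqrt( p · Σ_a SSY_a w_ja² / Σ_a SSY_a )`,  `SSY_a = q_a² tₐᵀtₐ`,

   normalized so Σ VIP² = p; metabolites with VIP ≥ 1.0, capped at the 10
   largest, are reported as the primary drivers of the discrimination.
6. **Reporting** (`shockmetab.report`) — model-diagnostics tables
   (R², NMC ± sd, accuracy %, permutation p), VIP tables with per-group
   means, a min-max-scaled heatmap matrix, and a Welch unequal-variance
   t-test for scalar lab values.

## Worked example

Simulate a serum panel of 40 metabolites, 16 animals per arm, with a
standardized effect of d = 2.5 planted on metabolites 1–4 of the S45−B
shock-response interval, then run the full pipeline:

```python
import numpy as np
import shockmetab as sm

cfg = sm.SimulationConfig(
    n_per_group=16, panel_sizes={"serum": 40},
    planted_effects=[sm.PlantedEffect("serum", "S45-B", j, 2.5) for j in range(4)],
    dropout={"CPF": 0.0, "FS": 0.0}, seed=7)
datasets, truth = sm.simulate_study(cfg)

ads = sm.prepare_contrast(datasets, sm.ContrastSpec.from_label("S45-B", "serum"))
scr = sm.screen(ads.values, names=ads.metabolite_names)
y = ads.sample_meta["group"].to_numpy()[scr.kept_rows]
X = ads.values[scr.kept_rows]

diag = sm.outer_cv(X, y, sm.CVConfig(n_outer_repeats=100, seed=7))
perm = sm.permutation_test(X, y, sm.CVConfig(seed=7, perm_repeats=10), n_perm=999)
model = sm.fit_plsda(X, y, diag.a_final, names=ads.metabolite_names, clip=True)
print(sm.select_vip(sm.vip_scores(model)))
```

Output of this exact script:

```
analysis matrix: (32, 40) units: mM
outliers flagged: 2 threshold 6.853
R2Y=0.860  NMC=1.540+-1.105  accuracy=80.75%  gate=True
permutation p = 0.001 (observed NMC 1.60)
selected VIP: ['met003', 'met001', 'met002', 'met007', 'met004', 'met028',
               'met032', 'met026', 'met038', 'met031']
```

Reading it: two of the 32 interval samples fell outside the Hotelling
ellipse and were removed; over 100 outer 75/25 splits the model
misclassified on average 1.54 of 8 test samples (80.75% pooled accuracy,
clearing the 80% gate); none of 999 label permutations matched the
observed cross-validated error, giving the minimum permutation p of
1/(999+1) = 0.001; and all four planted metabolites (met001–met004) are
among the ten reported VIP drivers.

The same pipeline is scriptable from the shell via the `shockmetab`
console command (`simulate`, `preprocess`, `screen`, `fit`, `validate`,
`report` subcommands; run `shockmetab --help`).

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator and its realism limits, all tunable parameters with defaults,
and the numerical conventions (tie-breaks, degenerate cases, seeding).
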