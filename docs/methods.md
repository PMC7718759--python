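# Methods

`chemscreen` implements a four-stage chemical-genetic interaction pipeline
for *Saccharomyces cerevisiae* mutant collections challenged with a toxic
amino-acid analog (the default parameterization follows an AZC-style
proline-analog screen), together with a synthetic-data generator that plays
back the statistical structure each stage assumes.

## Stage 1 — arrayed colony screen (`chemscreen.colony`)

Mutants are pinned in quadruplicate 2×2 blocks in 1536 format (32×48) onto
paired plates with and without drug. Per strain:

1. replicate colonies collapse to their mean (median by config) —
   robust to single missing colonies;
2. strains whose drug-free colony size is strictly below 5% of the plate
   average are excluded as dead/slow (`small_colony`);
3. fitness W = drug size / control size;
4. W is Z-normalized per plate (sample SD, `ddof=1`); the outermost well
   ring is flagged `is_border` and excluded from the mean/SD estimate by
   default (classic edge effect) while still receiving a Z on the same
   scale; a plate with spread at rounding level (SD ≤ 1e−12 relative) is
   flagged `degenerate_plate` rather than silently standardized;
5. alleles of one gene are grouped to a single Z (mean by default, most
   negative by config) and called positive at Z ≥ +3 or negative at
   Z ≤ −1.5 (inclusive thresholds).

Z-scores are computed on fitness ratios, not raw colony sizes: the ratio is
the quantity whose per-plate distribution the thresholds refer to, and it
cancels strain-specific growth differences present in both conditions.

## Stage 2 — liquid growth-curve validation (`chemscreen.liquid`,
`chemscreen.stats`)

OD600 is read every 15 min for 24 h from cultures started at OD 0.1, in
biological triplicate across two independent experiments. Each well's first
reading is subtracted as a per-well blank (floored at 0). Fitness is the
trapezoidal AUC normalized to the wild type in plain medium within the same
experiment, so wild-type plain fitness is 1 by construction. Interactions
are scored against the multiplicative model,

ε = W_ij − W_i · W_j,

pairing replicate k of the observed mutant-in-drug fitness with the
replicate product W_i^(k)·W_j^(k). The per-experiment statistic is the mean
ε; significance comes from a two-sided Welch test of the observed replicates
against the expected products (a one-sample test of the replicate ε against
0 is available by flag). A strain is called only when the mean ε passes the
±0.1 threshold *and* p ≤ 0.05 in **both** experiments — the intersection
rule never calls a strain a single experiment would not. Both signs of
interaction are biologically meaningful (sensitization and suppression), so
all tests in the package are two-sided.

A logistic model N(t) = K / (1 + ((K−N0)/N0)e^(−rt)) can be fitted per well
(`fit_logistic`): nonlinear least squares with deterministic initialization
(K ← max OD, N0 ← first positive OD, r ← slope of log OD over the early
exponential window, fallback 0.5/h), so fits are reproducible without random
restarts. Wells spanning less than 0.05 OD are flagged non-converged; their
empirical AUC remains usable. The default fitness measure is the empirical
trapezoid AUC of the raw curve; the fitted model supplies a closed-form AUC
(`logistic_auc`) for users who prefer the smoothed version. Dose selection
(`select_dose`) picks the dose whose wild-type fitness is nearest the target
drop (default 40%, matching the screen's operating point), breaking ties
toward the lower dose.

## Stage 3 — overexpression suppression (`chemscreen.suppression`)

For each overexpression strain the per-replicate ratio
AUC(drug)/AUC(no drug) is compared with the empty-vector control: fold =
mean ratio / mean control ratio; p from a Welch test of the replicate ratios
against the control's, Benjamini–Hochberg-adjusted across all strains in the
batch (the batch is the analysis family). Suppressor iff fold ≥ 2 and
adjusted p ≤ 0.05. The Welch test runs on ratios, not AUC differences,
because the ratio is the thresholded quantity. A separate `growth_cost`
flag marks strains whose plain-medium AUC falls below 80% of the control's —
a package-defined cutoff for "overexpression itself slows growth".

## Stage 4 — SGA scoring (`chemscreen.sga`)

Validated drug-sensitive alleles are arrayed (randomized positions, three
arrays, quadruplicate colonies) surrounded by a neutral his3Δ control and
crossed to control-tRNA and mistranslating-tRNA queries. Each plate is
normalized by the mean colony size of its embedded control strain, which
removes plate-level nutrient/pinning effects. The score is

score = mean(double-mutant fitness) − Q · mean(control-query fitness),

with Q the query single-mutant fitness (default 0.8: the mistranslating
tRNA alone costs ≈20% growth). Convention adopted here: the control strain
is treated as the invariant normalization standard, so the query's fitness
cost is expressed in the normalized double-mutant fitness rather than
cancelled by within-plate normalization; under this convention a
non-interacting allele scores exactly 0, which is what the multiplicative
expectation requires. This is a deliberate simplification of full SGA
software — no row/column/spatial corrections are applied. Calls: negative
iff score ≤ −0.1 with BH-adjusted Welch p ≤ 0.05 across the array.

## Synthetic data (`chemscreen.simulate`)

A single integer seed fans out to named substreams via
`numpy.random.SeedSequence(seed).spawn`, so every dataset is bit-identical
under regeneration and plates/curves have independent streams.

Colony screen generator — colony size = plate effect × base size × strain
base fitness × (drug multiplier on drug plates) × lognormal colony noise.
Defaults are the screen's study conditions: 4,000 strains, lognormal plate
effect (σ = 0.10), lognormal per-colony noise (CV = 0.10), drug multiplier
0.6 for the wild-type-like response (≈40% fitness drop at the screening
dose), strain-level drug-response heterogeneity (relative SD 0.10 — real
collections show broad, biologically driven spread under drug, which is
what makes a Z of −1.5 a meaningful threshold), 2% planted sensitive
strains shifted −3 null-SD, 0.5% resistant at +4 null-SD, and 0.25% dead
strains at 2% of normal size. "Null SD" is the fitness-ratio SD a
non-interacting strain shows (measurement + heterogeneity). Border blocks
hold a filler strain, mirroring edge-control practice.

Growth-curve generator — for each well a target fitness is drawn
(truth + Gaussian noise, SD 0.05 on the fitness scale) and the logistic K is
solved by root finding so the baseline-subtracted AUC equals target ×
wild-type reference; planted ε values are therefore exact on noiseless data
(verified to <1e−3 through the full pipeline). Gaussian OD noise
(SD 0.005) is added per reading. Growth rate is 0.5/h in plain medium and
0.35/h under drug; fitness differences are realized through K.

SGA generator — allele colony sizes carry the allele fitness
(uniform 0.7–1.0), the query cost Q and any planted deviation on the
mistranslating plates; the control strain is generated at unit fitness on
both queries (it is the normalization standard, see above). Positions are
re-randomized per array.

Suppression generator — works at the AUC-ratio level (the statistics
consume only per-replicate ratios): control ratio 0.183 (the drug reduces
the control's AUC to ≈18% of plain medium), replicate CV 10%, planted
suppressors multiply the ratio by a configurable fold (default 3).

What the generators do *not* model: spatial gradients within plates,
neighbor competition, lag/diauxie deviations from logistic growth, batch
drift between experiments beyond independent noise, and any genuine
biological correlation between stages. Passing recovery tests therefore
demonstrate that the statistics are implemented and calibrated correctly
under their own assumptions, not that real screens reach these accuracies —
a real solid-medium screen's −1.5 Z threshold deliberately trades precision
for sensitivity, and its hit list is expected to contain a majority of
biological-tail false positives that only the liquid validation stage
removes.

## Numerical choices

* Welch t: hand-computed statistic and Welch–Satterthwaite df; p from the
  Student-t CDF. Degenerate convention: both samples constant and equal →
  t = 0, p = 1; constant but different → |t| = ∞, p = 0.
* BH adjustment: step-up with cumulative minimum from the largest rank,
  capped at 1. It never decreases a p-value and preserves ranking order;
  note it is *not* idempotent (re-adjusting adjusted values inflates them),
  a property of the standard procedure itself.
* Z-normalization uses sample SD (ddof = 1, configurable); spread below
  1e−12 (relative) is degenerate.
* Tie-breaks are deterministic everywhere (stable sorts, lower dose on
  dose-selection ties).
* Overlap percentages round half-up to whole percent (2/3 → 67%).

## Problem sizes in tests and the acceptance script

The shipped calibration runs use one 4,000-strain screen (13 plates), 100
noisy logistic fits, 200-strain planted/null liquid experiments (≈2,400
curves each), 20×10-gene suppression batches and one 72-allele SGA array —
sizes chosen to pin the binomial error on every reported rate below the
margin to its threshold while keeping a full run in a few seconds.

## Known limitations

* The supplement replay (`report.reproduce_from_supplements`) expects the
  published supplementary tables to be downloaded separately; it is
  exercised in tests only on synthetic stand-ins shaped like those tables.
* The SGA stage scores a single day-3 colony-size snapshot; no time-series
  or spatial modeling.
* No correction for plate spatial gradients anywhere (a config hook for
  future spatial effects exists in the generator design but defaults off).
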