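# Methods

## Study design the package models

Each enrolled psoriasis patient (with or without psoriatic arthritis) has
experienced at least two biologics. Their PBMCs are cultured under three
condition kinds: unstimulated control, heat-inactivated *S. pyogenes*
group A stimulation ("induced"), and induction plus one biologic at its
steady-state trough serum concentration (adalimumab 4, golimumab 0.5,
certolizumab 20, ustekinumab 0.25, ixekizumab 3.5, secukinumab 16.7 or
34 — the 150 mg and 300 mg monthly regimens — guselkumab 1.2,
risankizumab 2 µg/mL). An 18-analyte multiplex immunoassay measures the
supernatants in pg/mL. Clinically, the absolute PASI score (0–72) is
recorded on day 0 of each biologic course and at an outcome visit: the
visit closest to the PBMC test when the patient had at least 180 days on
that biologic, otherwise day 180 (`select_outcome_pasi`).

The unit of analysis is the **patient-biologic course**, not the patient:
the packaged cohort has 20 patients contributing 44 courses. The control
panel is stored but unused by the change quantities; the induced-only
panel is always the baseline.

## Change quantities and their orientation

For index value *b* at baseline and *t* under the biologic:
rate = (t − b)/b and difference = t − b, and identically for PASI
(after − before, relative to day 0). A negative value always means the
biologic lowered the quantity. The familiar clinical "relative PASI"
(percent improvement) is −100 × rate; the integer view rounds half away
from zero, which reproduces the reported values (18.75 → 19, 96.15 → 96).
Rate is invariant under rescaling of the index; difference is linear in
it; rate = difference / baseline whenever the baseline is nonzero. A
baseline of exactly zero raises rather than silently returning infinity.

## Censoring

Below-detection-range measurements ("OOR<") carry no concentration. Any
censored input censors every index built on it, and censored index
changes are removed **pairwise**, cell by cell, from the correlation
matrices (a course censored for IFN-γ/IL-4 still contributes to the
IFN-γ cell). Additionally, a ratio whose **denominator** is observed but
below a quantification floor (default 0.1 pg/mL) is censored: such
values sit below the reliable region of the assay's standard curve, and
a denominator that small makes the ratio arbitrarily large and
essentially noise — a measured IL-4 of 0.09 pg/mL is still a usable
IL-4 value but not a usable divisor. The floor applies only to
denominators; single-analyte indices are unaffected. An optional
LLOQ/2-style substitution was considered and rejected as the default
because the assay tables this package mirrors leave censored-derived
cells blank rather than imputing them.

## Statistical conventions

* **Spearman's rho** is the Pearson correlation of mid-ranks (average
  ranks for ties); constant vectors are an error (rho undefined).
* **p-values** are two-sided. For n > 9 the t approximation
  `t = rho·√((n−2)/(1−rho²))` on n−2 df is used — the convention of the
  mainstream clinical packages, and the one that reproduces a printed
  p of 0.152 at rho = 0.22, n = 44. For n ≤ 9 the exact permutation
  null over all n! untied rankings is enumerated (cached per n). The
  two branches agree within 0.025 for n = 8–9 over every achievable
  rho, the worst case sitting next to the null where both p ≈ 1.
  |rho| = 1 on the t branch returns the smallest positive float.
* **Mann–Whitney U** reports U of the first group with mid-rank ties.
  The null is enumerated exactly over all group labelings when
  n_a·n_b ≤ 20 or n_a+n_b ≤ 10 (both cheap and the regime where the
  normal approximation is shaky, especially under heavy ties); larger
  samples use the tie-corrected normal approximation without continuity
  correction. A fully tied pooled sample returns p = 1.
* **Matrices** require ≥ 3 pairwise-complete rows per cell; a sparser
  cell is reported undefined rather than raising. Significance stars:
  \* p<0.05, \*\* p<0.01, \*\*\* p<0.001. No multiple-testing correction
  is applied by default, matching the analysis being reproduced;
  `--bh-correct` adds Benjamini–Hochberg q-values for reanalysis.

Whole-cohort and subgroup analyses (per biologic; PsO-only vs PsO+PsA)
produce one matrix per mode, each exportable as long/wide CSV and as an
annotated heatmap. Subgroups with fewer than 4 rows are flagged low-n
but still computed where defined.

## Biologic-selection composite (an extension)

The selection protocol's published form is directional only: prefer the
biologic that suppresses IFN-γ and IL-17A (and the Th1/Th17-over-Th2
ratios) and spares or raises IL-13 and IL-4. The composite score here is
this package's own operationalization of that principle:

    composite(biologic) = mean_i  s_i · r_i / scale_i

over the non-censored indices *i*, where r_i is the reduction rate, s_i
is +1 for IFN-γ-, IL-17A- and ratio-based indices and −1 for IL-13/IL-4,
and scale_i is the standard deviation of index *i*'s rates across that
patient's candidate biologics (within-patient standardization, so
indices with different dynamic ranges weigh comparably; zero spread
falls back to the raw oriented rate). Lower is better; exact ties break
alphabetically. The ranking is deterministic and independent of input
order. It carries no claim of clinical validity.

## Synthetic cohort generator

The generator reproduces the statistical skeleton the analysis assumes,
with defaults frozen to the study conditions:

* **Cohort**: 20 patients; 2 biologics per patient with probability 0.8,
  3 with probability 0.2 (44 expected courses, matching the 16×2 + 4×3
  composition); PsA flag Bernoulli(0.5), yielding roughly the observed
  10/10 split.
* **Concentrations**: per-analyte log-normal unstimulated levels
  (medians IFN-γ 5, IL-13 0.42, IL-4 2.7, IL-17A 5, IL-6 20 pg/mL;
  log-sd 0.9–1.0), multiplied by induction fold changes (IFN-γ ×20,
  IL-13 ×4, IL-4 ×3, IL-17A ×10, IL-6 ×50) so induced medians land in
  the ranges the assay tables report (IFN-γ tens-to-hundreds, IL-13 and
  IL-4 units). Biologic effects are mild class-specific multipliers on
  induced levels (e.g. IL-17 inhibitors ×0.6 on IL-17A, IL-12/23
  inhibitor ×0.8 on IFN-γ, small Th2 elevations), consistent with the
  modest treated/induced shifts the assay shows. Multiplicative
  log-normal noise (σ = 0.15) enters at induction and treatment.
* **Outcome link**: after the panels are realized, each course's actual
  IFN-γ/IL-13 reduction rate is rank-transformed to normal scores *u*;
  a latent `z = r·u + √(1−r²)·ε` with `r = 2·sin(π·ρ_target/6)` (the
  Gaussian-copula Pearson↔Spearman mapping) drives the PASI rate
  through the monotone map `rate = −1 + 1.1·Φ(z)²`, giving mostly
  strong improvements with a small worsening tail (≈5%), as clinical
  response distributions show. Because the coupling uses the realized
  (noisy, censored-before-analysis) suppression, the recovered Spearman
  correlation matches ρ_target without depending on how heterogeneous
  the biologic effects are. Default ρ_target = 0.5, the magnitude of
  the headline rate-mode association.
* **Censoring**: concentrations below per-analyte LLOQs become
  below-range; the IL-4 default (1.0 pg/mL) censors a few percent of
  stimulated IL-4 draws, emulating the single censored course in 44.
  No published LLOQs exist for this assay run, so these are assumptions.
* **Reproducibility**: one `numpy` generator seeded from `seed`; every
  draw flows from it, and equal seeds give identical datasets.

What the generator does **not** emulate: mechanistic immune-network
coupling between analytes (they are independent given the patient),
longitudinal PASI trajectories (one before/after pair per course),
plate/batch effects, and measurement error on PASI itself. Passing
pipeline tests on synthetic data therefore demonstrates correctness of
the statistical machinery under the assumed sampling model, not clinical
validity of the biomarkers.

Calibration is exact for continuous latent pairs; censoring and the
discreteness of small cohorts attenuate it slightly (mean recovered rho
0.48 at a 0.5 target over 20 seeds of ~200 courses — within the ±0.1
Monte-Carlo tolerance the tests assert).

## Numerical and design choices

* Analyte labels are canonical ASCII (``IFN-g``, ``TNF-a``); Greek
  spellings are accepted on input. The panel is a closed 18-member set;
  unknown labels fail at parse time.
* Validation is centralized and reporting-style: `validate_dataset`
  returns one finding per violation instead of raising on construction,
  so invalid rows can be enumerated; the CSV reader raises with file,
  line and field context.
* CSV floats are written with `repr` (shortest exact round-trip).
* Secukinumab courses pair with the dose of the patient's clinical
  regimen where recorded (patient I 150 mg → 16.7 µg/mL; E and G
  300 mg → 34 µg/mL); unrecorded regimens default to the standard
  300 mg trough.
* The packaged cohort stores raw analyte concentrations as printed and
  always recomputes ratio columns from them; a handful of printed
  derived-ratio cells are internally inconsistent with their own raw
  columns (documented in the test suite's spot-check list), and the raw
  values are taken as authoritative.
* Exact-permutation distributions are cached per n; n = 9 (362,880
  permutations) enumerates in about a second once per process.

## Problem sizes

The packaged analyses are desk-scale (44 courses; seconds). Simulation
tests use ~200-course cohorts averaged over 20 seeds for correlation
recovery, and 3–10-patient cohorts for round-trip and censoring
properties.

## Known limitations

* The composite selection score is an unvalidated extension (above).
* The exact Spearman branch uses the untied permutation null even when
  the observed data contain ties (the classical tabled convention).
* Copula calibration degrades as censoring of the target index grows;
  heavy censoring is not corrected for.
* No winsorization or exclusion rule is applied to extreme ratios
  beyond the denominator floor; with very low Th2 denominators,
  ratio-based indices remain heavy-tailed.
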