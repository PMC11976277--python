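# Methods

This note records the statistical model behind `lipidsat`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions a maintainer needs to know.

## Nomenclature and saturation classification

A species record is a lipid-class token plus an ordered tuple of acyl
chains `(carbons, double_bonds)`; chain separators carry meaning (`/` =
sn-resolved, `_` = unresolved) and the canonical serialization is
`CLASS(C:n_C:n)`. Saturation is classified by the **most unsaturated
chain**: 0 double bonds → SFA, 1 → MUFA, ≥2 → PUFA, ≥4 → *highly
unsaturated*. Ether `O-`/`P-` prefixes and ω-position suffixes are parsed
and preserved but never enter saturation arithmetic.

Two conventions were genuinely open and are resolved as follows:

- **Total-composition names** (`PC 38:4`): parsed as a single flagged
  pseudo-chain whose double-bond count is the species total. This is
  conservative — it never understates unsaturation — and keeps such
  species in the double-bond binning. They are *excluded* from the
  unsaturation index by default (their chain-level maximum is unobserved)
  with `include_total_composition=True` available.
- **Phospholipid set**: {PC, PE, PS, PI, PG, LPC, LPE}, with lyso classes
  included; every consumer takes the set as an argument.

## Preprocessing pipeline

The only supported order is **filter → impute → normalize (→ center)**,
enforced by `preprocess()`. Imputation must precede normalization because
missing values skew proportional data; filtering must precede imputation
so that barely-detected species are not given invented group medians.

- **Detection** means non-missing *and strictly positive*: targeted
  platforms export zeros and non-detections interchangeably.
- **Filtering**: retained iff (detected in ≥80% of all non-blank samples
  OR ≥60% of at least one group) AND mean over non-blank samples (missing
  as 0, a conservative choice that makes sparse species clear the bar on
  average) ≥ 2× the blank mean. Blank means are computed per species over
  all blanks. With no blanks the rule passes vacuously with a warning.
  Blanks never count as a group and are dropped after filtering.
- **Imputation**: per-species within-group median of observed values;
  strata with no observation at all stay missing (warned, never invented).
  The operation is idempotent.
- **Normalization**: proportions of the sample total (`total`, for
  class-level composition) or of each class's sample total (`per_class`,
  for species-level comparisons and the index). Observed-but-zero
  denominators are an error naming the sample/class; all-missing strata
  stay missing.
- **Centering**: division by the per-induction control mean of each
  species, applied to normalized proportions (a `center_to_control` call
  on any `NormalizedTable`, so raw-scale centering is possible for
  sensitivity analysis). This removes multiplicative batch effects exactly
  in the noise-free case and pins control per-induction means at 1.

## Differential saturation

Fold-changes are log2(mean case / mean ref) on per-class proportions; the
test is the two-sided pooled-variance Student's t-test on per-sample values
(Welch behind a flag — the pooled form is what "Student's t-test" names).
Raw p-values are the headline (volcano convention); a Benjamini–Hochberg
column is provided but drives nothing. Zero reference means produce a
flagged sentinel, never a silent floor. Note one compositional caveat:
per-class proportions are closed, so depleting a subset of a class
inflates the remaining species' proportions and attenuates the depleted
species' apparent fold-change by log2(1 − (1 − δ)·f) for targeted mass
fraction f. With the default panel (f ≈ 0.1 per class) the attenuation is
≈ 0.08 log2 units at δ = 0.5.

## Unsaturation index and ANOVA

U = (Σ proportions, most-unsaturated chain with 4–6 double bonds) /
(Σ proportions, 0–3), summed jointly across all phospholipid classes (the
literal reading of a "sum of phospholipid species"; per-class averaging is
not the default). Species above six double bonds are excluded from both
sums and counted — the bin definition is taken literally. U is invariant
to per-sample scaling and strictly increasing under mass transfer into the
4–6 bin.

The two-way ANOVA uses type III sums of squares with sum-to-zero coding —
the convention of the GUI packages practitioners compare against — which
matters for the unbalanced cohorts this index is used on (13 controls vs
45 cases per region). Post-hoc disease-vs-control contrasts within each
region use the pooled residual MSE and residual degrees of freedom, with
Šídák adjustment 1 − (1 − p)^m over the m regions. D'Agostino–Pearson
normality statistics are reported per cell and are undefined below n = 8
(the test's own minimum).

## Assay statistics

- **Median survival**: smallest day by which ≥50% of the group has died
  (step-function convention); undefined under >50% censoring. Fractional
  medians arising from averaging replicate vials are accepted as direct
  numeric input to the percent-change calculation, which rounds to the
  nearest integer.
- **Log-rank**: at each distinct event day, observed vs hypergeometric
  expected deaths with the hypergeometric variance (exact under ties);
  χ²(1). Right-censoring is supported in the data model. Validated against
  lifelines to 1e-8 in the test suite.
- **Cold stress**: Pearson χ² of independence without continuity
  correction (the tables are 2×3/3×3, where Yates is not conventional);
  expected counts below 5 are warned about and counted.
- **Feeding**: events / (flies per vial × vials × observations), with
  per-vial totals retained because the vial is the replication unit.

## Synthetic data generator

The generator emulates the *statistical* structure of a targeted
lipidomics run, not its chemistry (no internal standards, MRM spectra or
drift). Defaults describe a human-style neuronal experiment; `fly_brain_config`
and `ftld_cohort_config` package the two other study designs.

- **Panel**: ~300 species across 10 classes, drawn per class without
  replacement from an acyl-chain pool with realistic frequencies (fly mode
  uses a shorter-chain pool, ≤3 double bonds, and lowers the depletion
  threshold to 2). Chains with ≥4 double bonds carry ~6% of the pool
  weight.
- **Abundance**: per-species log-normal baselines (σ ≈ 1.5 across species)
  scaled by (chain-combination weight)^0.5, so species built from common
  chains dominate their class's mass as on real panels. This keeps highly
  unsaturated species at ~10–15% of class mass, which in turn keeps the
  compositional attenuation described above small — a panel-design
  decision, made from the closure algebra, not a fitted value.
- **Noise**: per-cell log-normal with σ = 0.25, a typical replicate CV for
  targeted lipidomics.
- **Effects**: a multiplicative depletion δ on species at or above the
  double-bond threshold in the case group (optionally restricted to
  specific regions); per-induction multiplicative batch shifts;
  region-specific baseline factors on the high-unsaturation species; an
  optional per-sample log-normal "unsaturation tilt" (σ = 0.15 in the
  cohort config) on those species, modelling between-individual
  variability in membrane unsaturation — without it the index's
  between-sample variance would be unrealistically tiny and any test
  trivially powered.
- **Blanks**: flat signal at 5% of the median baseline, so the 2× blank
  rule removes the genuinely low-abundance tail (~5–10% of species)
  rather than being vacuous.
- **Dropout**: logistic in log-abundance (midpoint at the 5th percentile
  of baselines, ceiling 0.25) — any decreasing link would do; this one is
  simple and controllable. Overall missingness lands near 5%.

What passing tests on this generator do **not** show: robustness to
internal-standard miscalibration, instrument drift, lipid
misidentification, or correlated biological covariation between species
beyond the shared-class closure — real data carry all of these.

Survival data are discrete-day (ceiling) exponentials — constant-hazard
deaths match fly lifespan assays well at this resolution — with the
treated hazard scaled by a ratio (Weibull shape available); n = 150 per
arm mirrors the organism assays this accompanies.

## Sizes and numerical conventions

Simulation-based checks use 50 runs (fold-change recovery), 200 cohorts
(index power) and 1000 replicates (type-I calibration), sizes at which
binomial error bounds are tight enough to be meaningful while the full
suite stays in the minutes range on one CPU. Proportion conservation is
asserted to 1e-9; oracle equivalence (lifelines, closed-form t/χ²/F) to
1e-8–1e-10. Ties in imputation medians are irrelevant (standard midpoint
median); filter threshold comparisons are ≥ on exact fractions. All
randomness flows from a single integer seed per generated object.

## Known limitations

- The parser covers the C:n shorthand family used by Lipidyzer-style
  exports, not structure-resolved nomenclature (no sphingoid `d`/`t`
  prefixes, oxidation suffixes or isomer labels).
- No covariate adjustment, mixed-effects or repeated-measures structure
  anywhere; each sample is one independent unit.
- The index ANOVA treats the two regions of one individual as independent
  samples, as the cohort design it mirrors does.
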