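# Methods

This note records the scientific and numerical choices behind `adrpgx`: what
the models assume, what the synthetic-data generator does and does not
emulate, and where the design was genuinely open.

## 1. Locus model and star-allele calling

The bundled CYP2C19 model is deliberately desk-scale: nine ordered 0-based
half-open exons on chromosome 10 with GRCh38-like coordinates, and a
definition table in which each non-reference star allele is tagged by a
single SNV (`src/adrpgx/data/cyp2c19_alleles.tsv`). Real PharmVar definitions
are multi-variant; single-variant definitions keep the exact-set matcher
honest (reference = empty set, unique non-empty sets otherwise) while
remaining fully enumerable in tests. The table is data, not code — users can
swap in fuller definitions, and the loader rejects duplicate labels,
ambiguous (identical) defining sets, and a non-empty reference set.

Two matchers run per sample: a bit-keyed exact lookup (also available
vectorised for simulation-scale cohorts) and an exhaustive scan over the
table. They implement the same mapping by different mechanics, mirroring a
dual-caller consensus design; discordance can only arise through unassigned
haplotypes (variant combinations defining no allele, e.g. injected genotype
noise), and such samples are excluded and counted in the exclusion report.
Missing genotype states are treated as reference for matching but tracked;
samples with more than 20% missing defining positions are excluded.

**\*37 calling.** A sample is a \*37 carrier iff at least one *deletion*
segment (a) intersects the union of exons 1–5 by ≥ 1 bp and (b) has length
within ±50% of 61,800 bp. The published description quantifies the length
only as "~61.8 kbp", so the window is configurable, including "any length".
Duplications and segments confined to exons 6–9 or flanking sequence never
qualify. In the diplotype the deletion replaces the haplotype whose SNV-based
match is the reference label (a deletion carries no SNV alternate states, so
the deleted haplotype reads as reference); if neither haplotype is reference
the later-sorted label is replaced. That rule is not stated in the source
description; it is isolated in one function and configurable via
`call_diplotype`.

## 2. Metaboliser phenotype

The five classes are assigned by counting deficient alleles
({\*2, \*3, \*4, \*8, \*37}) and \*17 copies, not by pair lookup; the
enumerated diplotypes of the published rule serve as the test fixture.
One consequence is documented rather than hidden: a deficient + \*17
compound heterozygote (e.g. \*2/\*17) is *intermediate* under the literal
"carrier of a deficient allele" rule, which coincides with CPIC's class here
but is reached without an activity score. No "likely poor/intermediate"
subcategories are modelled.

## 3. Synthetic cohort generator

The generator is the package's substitute for protected individual-level
data. It draws, per sample:

- **Haplotypes** as whole star-allele labels, i.i.d. under Hardy–Weinberg,
  then expands them to variant-state vectors — every clean haplotype is
  matchable by construction, and injected noise is an explicit, separate act.
  Default frequencies (\*38 0.550, \*1 0.0647, \*17 0.255, \*2 0.120,
  \*3 0.0013, \*4 0.004, \*8 0.005) plus the 1.5% \*37 carrier rate
  reproduce the published five-phenotype split to within a percentage point
  under HWE (poor ≈ 2%, normal ≈ 36–37%, ultrarapid ≈ 6.5%). HWE cannot
  match all five published class frequencies simultaneously; the discrepancy
  is ≈ 1 percentage point in the intermediate class.
- **CNV segments:** carriers get one deletion of length 61.8 kbp ± 3%
  placed to cover exons 1–5 fully; a configurable fraction of non-carriers
  get decoy segments (intronic deletions or a whole-gene duplication) that a
  correct caller must ignore.
- **PGS columns:** multivariate normal with unit marginals and a
  user-supplied positive-semidefinite correlation matrix (identity by
  default — the source reports score correlations only as a figure, so no
  default matrix is asserted).
- **Covariates:** birth year uniform on 1940–2005 (mean age ≈ 50 at the
  2023-style data freeze), sex Bernoulli(0.8 female), ten independent
  standard-normal PCs.
- **Outcomes:** presence of each side effect follows
  `logit p = b₀ + frailty + covariate terms + Σ effect·predictor·in-group`,
  the exact generative inverse of the fitted logistic model. Effects are
  keyed `(predictor, outcome, drug-group)` with log-OR values; an effect on
  outcome `"any"` applies to every simulated code. Covariate effects are
  applied to centred covariates so the baseline logit keeps its marginal
  interpretation.
- **Records:** presence is simulated at the (sample, outcome) level and then
  attributed to one taken drug, preferring drugs inside the effect's group —
  this keeps group-level case/control construction an unbiased readout of
  the generative model. Records are emitted across three layers (ADEQ 30%,
  MHoS 35%, EHR 35%), with a configurable rate of exact duplicates in a
  second layer (default 5%) and of presence/absence conflicts (default 1%).
  The source reports only the total number of removed duplicates, not
  per-layer prevalences or a conflict rate, so these defaults are
  placeholders that force the harmonisation policy to be exercised, not
  estimates.

All draws descend from per-component seed streams of the config seed: each
`simulate_*` stage is independently reproducible, and identical configs give
byte-identical outputs.

**Calibration of the default scenario.** Per-side-effect marginal report
rates use the printed values where available (nausea 15.7%, weight gain
15.3%, sleepiness 15.0%, chills 0.8%, …) and plausible interpolations
otherwise. Independent Bernoulli outcomes at those marginals would pool to
≈ 70% "any side effect", far above the stated 52% — real side effects
co-occur. The default scenario therefore adds a shared per-sample normal
frailty; its SD (≈ 1.31) and the per-outcome baseline logits are solved
deterministically by Gauss–Hermite quadrature so that the marginals hold
*and* the pooled prevalence is 52% (`calibrate_frailty_sd`,
`calibrate_baseline_logits`). Two consequences are worth knowing: (i)
marginal (population-averaged) odds ratios fitted on frailty-bearing
scenarios are attenuated relative to the conditional generating values —
the demo scenario is for structure, not parameter recovery; (ii) the
coverage scenarios used for statistical validation (`cyp2c19_scenario` and
the single-outcome PGS configs) are frailty-free, so fitted CIs are
calibrated against the generating values there.

**What the generator does not emulate:** outcome-specific co-occurrence
structure beyond the single shared frailty, linkage disequilibrium and
imputation uncertainty, dose and timing, free-text EHR content, drug
switching, and any correlation between metaboliser status and PGS. A green
test therefore establishes correctness of the pipeline's logic and the
calibration of its inference under the stated generative model — not
robustness to real-data violations of it.

## 4. Cohort construction

Records merge on the key `(sample, drug, side_effect, present)`; the removed
count is reported. Presence/absence conflicts resolve to *present*
(any-source-positive): the questionnaires exist precisely to capture milder
subjective effects that EHRs miss, so a positive in any layer is treated as
a report. Cases for an (outcome, group) cell are users with ≥ 1 present
record for the outcome on a group drug; controls are group users without
one (side-effect information on *any* drug taken suffices — whether
class-level controls need per-drug information is unstated and implemented
as "any"). `"any"` pools all 23 codes (plus unspecified-`"any"` records);
`"cardiometabolic"` pools heart palpitations, weight gain and blood-pressure
increase. Cells with < 100 cases are dropped (grey-cell semantics). The
depression subgroup keeps samples with ICD-10 F32\*/F33\* prefixes or F41.2
exactly.

Percentages print half-up to one decimal. The published demographics table
is internally inconsistent in its control column and its age row (the
case/control age means imply a pooled mean of 50.9, not the printed 49.9);
only the totals column is treated as ground truth, and the packaged
individual-level fixture reproduces it exactly from the printed marginal
counts.

## 5. Association engine

Fits are maximum-likelihood logistic regressions (statsmodels GLM/IRLS) with
Wald inference — the published symmetric-on-log-scale CIs imply Wald, so
profile likelihood is not used. PGS predictors are standardised to unit SD
within each analysis sample (per-SD ORs); the categorical metaboliser
predictor uses normal as reference. Separation and non-convergence are
flagged (|β| > 15 or se > 50, or IRLS non-convergence) rather than penalised;
flagged fits are excluded from the FDR family with a log entry. The BH
step-up adjustment is implemented directly (with an explicit declared family
size that may exceed the number of emitted tests) and is cross-checked
against an independent reference implementation in the tests. The FDR family
for each scan plan is the set of emitted (non-grey, non-flagged) cells.

Forward stepwise selection starts from the FDR-significant univariate
candidates, adds at each step the candidate with the smallest multivariate
Wald p (ties broken lexicographically, making the procedure independent of
input order and of any seed), stops when no remaining candidate has
p < 0.05, and FDR-corrects the final multivariate model across the retained
predictors only — whether the published correction spanned the full
candidate set is ambiguous; retained-only is the implemented reading.

## 6. Meta-analysis

Fixed-effects IVW on the log-OR scale (combining ORs directly would be
wrong; printed ORs with CIs convert via β = ln OR, se = CI log-width/3.92).
The 9-drug × 3-phenotype family is BH-corrected at size 27. Cells present in
only one cohort pass through as k = 1 results (configurable to drop).
Heterogeneity is not modelled; Cochran's Q is emitted as a diagnostic only.
Second-cohort inputs for simulations are synthesised at the
summary-statistic level (βᵢ ~ N(true, seᵢ)) — the standard design for
validating IVW coverage — with per-cohort SEs ≈ 0.05 matching the precision
implied by the printed CIs.

## 7. Numerical and testing choices

- Coordinates are 0-based half-open internally; VCF positions convert on
  read/write (pysam), BED is native.
- Percentage rounding is decimal half-up, matching printed style, not
  banker's rounding.
- Calibration solves use Brent's method with Gauss–Hermite quadrature
  (41 nodes); tolerances 1e-8–1e-10.
- Replicate-based checks (type-I error in [0.04, 0.06] over 2,000 null
  fits; 95% CI coverage in [0.92, 0.98] over 200 replicates per generating
  effect) use fixed seeds; the bands are ≈ ±2 Monte-Carlo SDs around the
  nominal values, so they are sharp but stable at the chosen seeds.
- The full-pipeline coverage check for the metaboliser effects runs the
  actual variant+CNV caller inside each replicate; PGS coverage uses the
  generative-truth phenotype path, whose equivalence to the caller on clean
  data is separately established by the 10,000-haplotype round-trip test.

## 8. Known limitations

Single-variant allele definitions (no suballeles, no multi-variant
haplotype logic); no CYP2D6/CYP2C9 or other pharmacogenes; no phasing or CNV
segmentation from intensities (segments are consumed, not called); no
random-effects meta-analysis; no NLP — structured records only; the 19-score
PGS roster of the source is represented by 17 named scores covering both
scan plans (the exact roster is not printed). The published adjusted
estimates were fitted on protected data and are not reproducible here;
what the package validates is the machinery and its statistical calibration
on the stated synthetic world.
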