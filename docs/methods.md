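# Methods

## Study design emulated

The cohort is 24 rams — 10 wild-type controls and 14 transgenic animals
carrying a full-length human huntingtin cDNA with 73 CAG repeats, still
presymptomatic at the age modelled — sampled two-hourly over a 25 h window
(15:00 to 15:00 the next day, 13 time points) under dim light and
controlled feeding. Concentrations come from a targeted LC/MS kit panel:
after QC exclusion, 130 metabolites in six classes (20 amino acids, 9
biogenic amines plus taurine, 11 acylcarnitines, 13
lysophosphatidylcholines, 62 phosphatidylcholines, 14 sphingomyelins).
Hourly plasma melatonin (pg/ml) provides each animal's circadian phase
reference.

## QC model

A metabolite is excluded when the fraction of *study* wells flagged out of
range exceeds 0.25. Flags follow the assay's strict inequalities: value <
LOD → `below_lod`; LOD ≤ value < LLOQ → `below_lloq`; value > ULOQ →
`above_uloq`; the three categories are pooled for the 0.25 rule (the
per-category alternative would only be stricter and is not implemented).
Values exactly at LOD count as quantifiable-but-below-LLOQ. "Blank out of
range" is read conventionally as mean blank signal above LOD. The QC2 rule
excludes metabolites whose mid-level QC replicates (4 wells × 5 plates)
have CV > 0.30, pooled across plates. When several rules fire, the reason
recorded is the first in the order out-of-range → blank → QC2.

Between-plate normalization multiplies every value on a plate by
`target / plate QC2 mean`, with the global target the *median* of per-plate
QC2 means — robust to one bad plate, and a fixed point: renormalizing a
normalized table gives factors of exactly 1. QC and blank wells are
normalized along with study wells so the operation is idempotent.

## DLMO estimation and alignment

The dim-light melatonin onset is individual-relative: threshold = 0.25 ×
that animal's maximum observed concentration; DLMO = the first upward
crossing, linearly interpolated between the bracketing hourly samples.
Missing points are skipped (no imputation); a profile that never crosses
from below raises an onset-not-identifiable error rather than guessing.
No curve is fitted — on a piecewise-linear profile the estimator is exact,
and on a sigmoidal onset the residual error is bounded by the curvature
between hourly samples.

Alignment subtracts each sheep's DLMO (unwrapped into its sampling window)
from the sample's unwrapped clock time, so a 25 h window starting at 15:00
with DLMO 21:00 yields offsets in [−6, +18] h. Cross-sheep summaries bin
offsets to the nearest 2 h.

## Screening model

Each metabolite is fitted by ordinary least squares on the ordered design
[genotype, time (categorical, 13 levels), animal, genotype × time] with
sequential (type-I) sums of squares; the animal indicators span the
genotype contrast, so genotype must enter first and one animal column per
genotype is dropped as aliased. F statistics for all terms use the
residual mean square; missing values are dropped row-wise. Genotype,
time and interaction p-values are each adjusted across the panel by the
Benjamini–Hochberg step-up procedure, with significance declared at
FDR < 0.05 (strict).

**Known limitation — anticonservative genotype test.** Treating animal as
a fixed covariate and testing genotype against the *within-animal*
residual ignores that the genotype contrast is estimated across whole
animals: when animals carry shared biological variance, the genotype F
statistic is inflated under the null. On zero-effect synthetic cohorts
with the default (realistic) between-sheep variance, roughly half the
panel reaches FDR < 0.05. A mixed or animal-aggregated model would repair
the calibration but is outside this package's scope (see Non-goals); the
test suite documents the behaviour rather than hiding it. Interpreting
genotype FDRs from this model therefore requires the between-animal
replication to be kept in mind.

Group summaries (mean ± SEM per genotype) pool all non-missing samples
(sheep × time); an option computes SEM over per-sheep 24 h means instead.
Class tabulation compares group means at stored precision: exact ties are
reported as ties, never silently assigned a direction (four acylcarnitines
in the packaged reference table tie at the printed 0.01 µM resolution).

Urea-/NO-cycle ratios — Cit/Arg (nitric-oxide synthase), Cit/Orn
(ornithine carbamoylphosphate transferase), Orn/Arg (arginase) — are
formed per sample (missing if either component is missing; a zero
denominator yields a missing value with a warning) and screened through
the same linear model.

## Panel construction

Pre-selection requires, per marker: genotype FDR < 0.05; a single-marker
(non-cross-validated) AUC above a permutation null at p < 0.05; and a
relative group-mean difference above 5%. The permutation null reassigns
genotype labels to whole animals (preserving the 10/14 split) because
within-animal samples are exchangeable only as a block; the statistic is
orientation-free, max(AUC, 1−AUC), for both the observed value and the
null, and p = (1 + #{null ≥ observed}) / (1 + N) with N = 10,000 by
default. Fewer than 20 distinct label assignments raises an error advising
exact enumeration.

Logistic models use natural-log concentrations; missing values are imputed
as the training-fold raw-scale mean before the transform, and non-positive
values are floored at half the smallest positive observed value. The
fitter is iteratively reweighted least squares (convergence when the
largest coefficient change is < 1e-8, at most 100 iterations); detected
(quasi-)separation triggers a refit with a fixed 1e-6 ridge on the
non-intercept coefficients, flagged on the result. Time of day never
enters the feature set, so a panel can score a single sample drawn at any
time.

Cross-validation is leave-one-sheep-out: each fold trains on all samples
of 23 animals and predicts the held-out animal's 13 samples; imputation
statistics are recomputed per training fold (a deliberately leaky variant
that pools before splitting is available behind a flag for replication
studies). Stepwise selection maximizes the pooled sample-level LOSOCV AUC,
adding the marker with the largest strictly positive gain until no marker
improves it or the size cap (12) is reached; gain ties break by smaller
genotype FDR, then alphabetically, so builds are deterministic. All
intermediate panels are reported with their step AUCs, which are strictly
increasing by construction.

**Known limitation — pessimistic pooled LOSOCV under the null.** Pooling
held-out probabilities across folds mixes fold-specific intercepts: a fold
holding out a control trains at prevalence 14/23, a fold holding out a
case at 13/23, so under the null (marker coefficient ≈ 0) the held-out
controls systematically score *above* the held-out cases and the pooled
AUC falls far below 0.5 (≈ 0.10 on zero-effect cohorts). The bias is
strictly pessimistic — it can hide signal but never manufactures it — and
shrinks as real signal dominates the intercept gap. Sheep-level recovery
of a specific seeded marker set is likewise limited at n = 24 animals:
with realistic between-sheep variance the permutation filter passes only a
subset of the seeded markers and cross-validated AUC gains are noisy, so
greedy selection recovers a median of 3 of 8 seeded markers per run even
while the panel's cross-validated AUC averages above 0.9.

Operating points: sensitivity at a target specificity (default 0.90) scans
all observed thresholds (positive iff probability ≥ threshold), returns
the maximum sensitivity among thresholds meeting the target, breaking ties
toward the lowest qualifying threshold, with no interpolation. Sheep-level
classification thresholds the per-animal median held-out probability at
that same threshold. Per-phase-bin AUCs are computed on the pooled CV
predictions within each 2 h bin; bins missing a class are reported as
undefined, never dropped silently.

## Synthetic cohort generator

Concentrations follow a two-level multiplicative lognormal model (plasma
concentrations are positive and right-skewed, and the analysis itself
log-transforms):

    value = group_mean × sheep_factor × (1 + A·cos(2π(t − DLMO − φ)/24))
            × residual × plate_bias

with mean-preserving lognormal `sheep_factor` (between-animal CV) and
`residual` (within-animal CV), a cosinor rhythm phased to the animal's own
DLMO (default relative amplitude 0.08, peak offsets spread deterministically
by the golden ratio across metabolites), and lognormal plate bias (SD 0.03).
Per-sheep DLMO ~ Normal(21.0, 0.9) h. Cells falling below LOD are
substituted at LOD/2 (kept observable to QC flagging, as an assay would
report trace values, rather than deleted); independent missingness then
blanks cells at rate 0.012. QC2 wells carry each metabolite's nominal value
× plate bias × 3% noise; 20 QC2 wells (4 × 5 plates) are generated.

The `paperlike` preset takes group means from the packaged reference
screen table. Per-metabolite total CV is derived from the printed control
SEM (sd = SEM·√130 pooled samples, printed SEMs floored at 0.005 — half
the printed precision — and the CV clipped to [0.05, 0.6]) and split
equally in variance between the between- and within-animal levels. The
split was checked against the reference table itself: inverting the
printed genotype FDRs to F statistics and comparing the implied
within-animal residual SD with the pooled SD gives a median within/total
SD ratio of ≈ 0.54 across the informative rows, i.e. the real cohort had
at least as much between-animal variance as the equal split assumes.
`zero_effect=True` builds a global-null cohort; `effect_markers=...`
keeps the genotype shift only for a named subset (e.g. the eight-marker
panel set: citrulline, valine, PC aa C40:4, PC aa C36:5, lysoPC a C17:0,
SM (OH) C24:1, threonine, C14:1) and nulls the rest.

Melatonin profiles are hourly over 25 h: a logistic rise whose centre is
solved per animal (bisection) so the noiseless hourly profile's
interpolated 25% crossing sits exactly at the true DLMO, a nocturnal
plateau of 100 pg/ml ending 9 h after onset via a second logistic, additive
noise with SD 10% of the signal, and a 3.9 pg/ml assay floor. At that
noise level the estimator recovers ≥95% of onsets within 0.5 h.

What the generator does *not* emulate: inter-metabolite correlation beyond
shared sheep/plate factors, within-sheep autocorrelation (an AR(1) option
exists but defaults off), assay drift within a plate, and non-lognormal
tails. Tests passing on synthetic cohorts therefore validate the
machinery and its calibration under the stated noise model, not the
biology of any particular real cohort.

The 183-candidate kit fixture appends 53 synthetic violators to the
130-metabolite panel: 27 with 30% of study wells below LOD and 26 whose
QC2 wells alternate at 0.5×/1.5× nominal (CV ≈ 0.51), each failing exactly
one rule by construction, for any generator seed.

## Numerical choices

- Sequential ANOVA uses `numpy.linalg.lstsq` per cumulative design block
  with rank tracking; term df = rank increase. Zero residual df raises.
- BH adjustment is the vectorized step-up (reverse cumulative minimum),
  validated against a brute-force oracle and statsmodels at 1e-12.
- AUC is computed from average ranks (`scipy.stats.rankdata`), identical
  to pair counting with half-credit ties at 1e-10 on adversarial tied data.
- The permutation null is vectorized via per-sheep rank sums, so 10,000
  permutations per marker cost one small matrix product.
- Ward clustering delegates to `scipy.cluster.hierarchy.linkage`
  (Euclidean, deterministic); heat-map profiles are z-scored per
  metabolite before clustering because absolute concentrations span four
  orders of magnitude across classes (raw profiles available via a flag).
- Problem sizes in the test suite: 200 zero-effect cohorts for screening
  calibration, 100 for CV-null calibration, 50 seeded cohorts (1,000
  permutations each) for panel recovery, 1,000 random vectors for each
  oracle-equivalence check, 50 random small designs for the ANOVA oracle.

## Open design decisions taken

- The pooled-sample reading of the published SEMs is the default; the
  per-sheep alternative is exposed as an option.
- The 25% out-of-range rule pools all flag categories.
- Taurine is classed as a biogenic amine (its table position) with a flag
  recording that convention counts it among amino acids; it is
  non-significant, so tabulations are robust to either choice.
- The stepwise search starts from an open first step (no forced seed
  marker).
- The glycerophospholipid total is carried as printed in the reference
  table (62 PC + 13 lysoPC); a conflicting prose count of 76 exists and is
  left unreconciled.
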