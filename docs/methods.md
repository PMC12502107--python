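# Methods

This note documents the models, parameter choices and limitations behind
`galda`. It is written for users who need to judge what a result from this
package does and does not show.

## Study conditions and the synthetic cohort

The default configuration mirrors a three-group glycemic case-control
design: 11 controls (C), 12 prediabetes (PD), 16 type 2 diabetes (T2D) —
39 urine spectra, one per patient — acquired as 32,768 points spanning
−3.313 to 12.706 ppm (≈0.49 milli-ppm per point, the digital resolution of
a 16-ppm window at that point count).

`synthetic.simulate_cohort` draws spectra as sums of absorption-mode
Lorentzian multiplets from a 21-metabolite peak library
(`data/peak_library.yaml`). Each library record carries per-group line
positions (singlet centers, doublet pairs, multiplet envelopes) and a
relative group amplitude. The library encodes the qualitative group
structure of such cohorts: the anomeric glucose doublet at 5.15 ppm and
the 3.20–3.80 ppm glucose envelope only in T2D (urinary glucose appears
only above the renal reabsorption threshold); glycine absent in T2D and
weaker in PD than C; urea (broad singlet, 5.70 ppm) strictly decreasing
C > PD > T2D; acetate and citrate elevated in T2D; pyruvate, glycolate and
hippurate strongest in C; creatinine ~10× the median metabolite amplitude
in every group. Absolute amplitudes are necessarily invented — no
concentration table exists to calibrate them — and are fully configurable;
they are *relative* units in which the additive noise SD is 0.02.

Per-sample nuisance structure, with defaults:

| parameter | default | meaning |
|---|---|---|
| `dilution_sd` | 0.20 | log-normal SD of the global per-sample amplitude (urine concentration/injection volume) |
| `intensity_variation_sd` | 0.25 | log-normal SD of each metabolite's amplitude per sample (biological variability) |
| `noise_sd` | 0.02 | additive i.i.d. Gaussian noise per point |
| `baseline_amplitude` | 0.5 | scale of a random cubic baseline drift |
| `water_band` | 4.73 ppm, FWHM 0.4, amp 2.0 | residual solvent hump left by imperfect suppression |

Lineshapes: Lorentzian, FWHM 0.006 ppm (typical for urine resonances at
300 MHz); broad singlets use 5× that width; doublets split by 0.024 ppm
(~7 Hz) unless the library states a range; multiplets render as 3 evenly
spaced lines (5 when the envelope exceeds 0.2 ppm). `intensity_variation_sd`
exists because without it the within-class variance would collapse to
instrument noise, making cross-validation degenerate; it is the one
nuisance that vector normalization cannot remove.

What the generator does **not** emulate: free-induction decays, phasing or
solvent-suppression artifacts (spectra are phase-perfect by construction);
pH-driven chemical-shift drift between samples (each group's shifts are
fixed); peak-shape distortions; correlated metabolite concentrations
(amplitudes vary independently); and any overlap crowding beyond the 21
library regions (real urine has hundreds of resonances). Consequently,
perfect classification on synthetic cohorts demonstrates that the pipeline
recovers a strong, cleanly encoded group structure — not that real cohorts
of this size would separate as well, and not robustness to shift
misalignment, which real studies must handle upstream.

## Preprocessing

Fixed order: track selection → baseline correction → vector normalization
→ mean centering. Normalizing before baseline correction would leave the
unit-norm postcondition broken by the subsequent subtraction, so the order
is enforced and recorded in the output's provenance list.

*Track selection* keeps the closed [0, 10] ppm window. Window edges are
applied to the axis rounded to 3 decimals (the conventional 0.001-ppm
display precision of shift axes), i.e. with half-a-milli-ppm tolerance at
each edge; on the default grid this retains 20,457 channels. Raw
(unrounded) comparison is available via `decimals=None`.

*Baseline*: asymmetric least squares by default — minimize
Σ wᵢ(yᵢ−zᵢ)² + λ Σ (Δ²z)² with w = 0.01 above the current baseline and
0.99 below, λ = 1e5, 10 reweighting iterations, solved per spectrum as a
symmetric pentadiagonal banded system. ALS needs no peak annotation and is
the de-facto standard for spectroscopy baselines. An iterative-clipping
polynomial fit (degree 3) is the alternative. ALS preserves Lorentzian
peak heights to within ~5% at the default stiffness.

*Normalization*: each row divided by its Euclidean norm (unit-norm checked
at 1e-12); this makes the pipeline exactly invariant to per-sample positive
scaling, the operational definition of dilution removal.

*Centering*: training-partition column means are stored and reused for
test spectra and inside every cross-validation fold — centering with
pooled (train+test) means would leak test information.

## Kennard-Stone splitting

Per class (default), the training count is the nearest integer (half away
from zero) to 0.70 × class size — (8, 8, 11) for (11, 12, 16), i.e. 27
train / 12 test. Selection is max–min on Euclidean distances over the full
preprocessed track, ties broken by lowest index so the split is identical
across platforms. Per-class splitting is the default because pooled KS can
starve a class out of the test set; a pooled mode exists. The degenerate
one-sample selection (k = 1 after rounding) takes the sample farthest from
the class centroid.

## Classifiers

LDA uses the Gaussian pooled-covariance discriminant; covariance
stabilization shrinks toward the diagonal, γ·diag(Σ) + (1−γ)·Σ with
γ = 0.1, automatically once the variable count reaches half the training
sample count (the `auto` rule). QDA estimates per-class covariances and
refuses underdetermined classes unless shrunk or PCA-compressed. PLS-DA is
NIPALS PLS2 on one-hot class indicators (argmax prediction); at full rank
it reproduces least-squares indicator regression. PCA-LDA/PCA-QDA/PLS-DA
component counts are chosen by leave-one-out error on the training
partition over 1..15, smallest count winning ties. The SVM comparison
model delegates to scikit-learn (linear kernel, C = 1) behind the same
fit/predict surface; its internals are out of scope here.

## GA variable selection

*Gene space.* For spectra, chromosomes index means of contiguous 0.01-ppm
bins (~1,000 genes over the track) rather than raw channels. Three reasons:
selected variables come out at the 0.01-ppm granularity at which such
variables are conventionally reported; bin means average ~20 points of
noise; and per-gene mutation at a 1% rate then flips ~10 genes per child —
at 20,457 raw genes it would flip ~200 and the cardinality repair would
destroy inheritance, degenerating the search to random sampling (observed:
occasional selection of isolated noise channels that achieve zero
leave-one-out error yet generalize at only 83–92%). Raw-channel search
remains available (`bin_width=None`).

*Fitness.* `err_LOO + 0.02·risk_LOO + 0.01·|S|/max_vars`. The error term
is the exact LOO misclassification rate of LDA on the masked variables,
computed by rank-one downdates of class means and pooled scatter (no
refitting loop). With 27 samples, many masks tie at zero errors; the 0/1
loss cannot rank them, so the posterior-risk term (mean held-out
1 − P(true class)) orders tied masks by the confidence of their held-out
assignments, and the parsimony term breaks remaining plateaus toward
smaller subsets. Both weights together stay below one misclassification
(1/n), so the error count strictly dominates. A k-fold fitness variant
exists for larger cohorts.

*Search.* Population initialized with cardinalities uniform in
[min_vars, max_vars] = [5, 30]; size-2 tournaments; single-point crossover
p = 0.60; per-gene bit-flip mutation p = 0.01 followed by random add/remove
repair back into the cardinality bounds; elitism of 1 (hence the best-so-far
fitness trace is non-increasing); ties between chromosomes prefer fewer
variables, then the lexicographically lowest index set. The search restarts
3 times from independent seeds and keeps the best chromosome overall. Full
scale is 200 generations × 400 chromosomes; the default *reduced profile*
(20 × 60) finishes in seconds at n = 27 and reaches the same external-test
performance on the synthetic conditions — runs are marked "reduced" vs
"full-scale" in every report. The final classifier is LDA (auto
shrinkage) refit on the selected variables.

On synthetic cohorts the selected sets mix genuinely discriminating
regions (annotatable to the metabolite library) with incidental bins —
roughly half annotate, and every run recovers at least one discriminating
region. That mixture is intrinsic to wrapper selection at n = 27, where
many subsets reach zero cross-validated errors, and mirrors what selected-
variable tables in small-cohort studies typically look like.

## Validation

*Leave-one-patient-out*: one fold per patient; centering means and the
classifier are refit per fold. Variable-selection nesting is explicit:
the default *selection-fixed* mode freezes the GA-selected variables (and
PCA/PLS component counts) chosen on the training partition and refits only
the classifier per fold — this matches common practice but is optimistically
biased, since the held-out sample influenced the selection; the
*fully-nested* mode (`nested_cv`) reruns the GA inside every fold and is
the unbiased (and far slower) estimate. LOOCV is applied to the training
partition by default; whole-dataset use is a caller choice.

*Monte-Carlo CV*: per iteration a stratified 20% of samples (at least one,
at most all-but-one per class, rounded half away from zero) is held out,
the model refit, and held-out predictions accumulated over 1,000 iterations
(100 in the reduced profile) into a counts matrix, reported row-normalized
to percentages with the diagonal mean as "average accuracy". Stratification
avoids empty-class training draws at n = 39; the non-stratified mode errors
on such draws.

*Metrics*: one-vs-rest TP/TN/FP/FN per class; AC/SENS/SPEC as percentages;
SENS/SPEC macro-averaged; overall AC = total correct/total. Zero-denominator
ratios are reported as absent (None) and excluded from macro averages
rather than coerced to zero. Reports round percentages to one decimal;
internal values keep full precision.

## Selected-variable statistics and annotation

Per selected variable: per-group mean/SD of the preprocessed intensity,
classical one-way ANOVA (F = MS_between/MS_within with (k−1, N−k) df),
significance at p < 0.05, and nearest-metabolite annotation. A
summary-statistics ANOVA (`anova_from_summary`) reconstructs F and p
exactly from per-group means/SDs/sizes, enabling verification of published
tables without raw data. Kruskal-Wallis is available behind the same
interface for non-normal variables; the report shows ANOVA by default and
does not automate normality-based test routing. Annotation matches a query
shift against all groups' line centers and multiplet envelopes (containment
counts as distance zero) within a 0.03-ppm tolerance — a typical urine
pH-drift window at 300 MHz; ties break by distance to the component
midpoint, then alphabetically, so annotation is independent of library
record order. Shifts inside the broad 3.20–3.80 glucose envelope annotate
as glucose even when another metabolite's line lies nearby, unless the
query hits that line's center exactly.

## Seeds and determinism

A single pipeline seed feeds named sub-streams (`simulator`, `ga`, `mccv`)
derived via seed sequences, all below 2³¹. Identical configuration + seed
reproduces byte-identical run summaries. Kennard-Stone, LDA/QDA/PLS fits
and annotation are deterministic by construction (explicit tie-break
rules).

## Problem sizes used in the shipped checks

The test suite exercises most components on an eighth-resolution grid
(4,096 points) with the full 39-sample design, and the end-to-end headline
check plus the acceptance script on the full 32,768-point grid with the
reduced GA profile and 100-iteration Monte-Carlo CV — sizes at which the
synthetic conditions already reproduce the target behavior and the whole
suite stays interactive.

## Known limitations

- Wrapper selection at n = 27 overfits by construction; external-test
  perfection on well-separated synthetic cohorts should not be read as an
  expected real-data outcome, and selection-fixed CV numbers are
  optimistic (use `nested_cv` for honest fold-wise selection).
- The generator's independence assumptions (metabolite amplitudes, noise)
  understate the collinearity of real urine spectra.
- No peak alignment/warping, binning-based quantification, or
  probabilistic-quotient normalization is provided; spectra are assumed
  shift-aligned upstream.
- The JCAMP-DX reader is minimal: AFFN `(X++(Y..Y))` tables only, no
  DIF/DUP/SQZ compression.
- LDA's pooled-Gaussian assumptions are not checked; with heavy-tailed
  intensity distributions the QDA/Kruskal-Wallis alternatives may be more
  appropriate.
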