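# Methods

## The experimental design being emulated

The package models a repeated-measures blood time course in a rodent
stroke model: `StudyDesign` defaults to 8 animals sampled at 0, 1, 2, 3,
6 and 24 hours after vessel occlusion with one missing draw (animal 3 at
6 h), giving 47 samples with per-timepoint counts (8, 8, 8, 8, 7, 8).
Times are decimal hours from occlusion; 0 h is the pre-anesthesia
baseline draw. Expression values are log2-scale array summaries.

## Synthetic data generator

Each gene g has a baseline b_g ~ U(4, 12) log2 units, an archetype label
L_g, an amplitude a_g (default 1.5 log2 units for signal genes, 0 for
null genes), and i.i.d. Gaussian noise with SD σ (default 0.25 log2
units). The observed value of gene g in a sample drawn at time t is

    y_g(t) = b_g + a_g · s_L(t) + (batch offset, off by default) + ε,

with s_L the unit-amplitude archetype shape. The canonical shapes on the
grid (0, 1, 2, 3, 6, 24) h are fixed vectors chosen as the minimal
profiles satisfying each archetype's verbal description (A peaks at 2 h,
B at 6 h, C flat at 1 h then peaking at 6 h, D twin peaks at 2 h and 6 h
with a 3 h dip, E trough at 6 h with partial recovery, F monotone decline
through 24 h, G low plateau over 2–6 h, H down at 1 h then up to a 3–6 h
maximum; transient shapes return to within 20 % of their amplitude by
24 h). The default parameter choices reflect a plausible array scale and
the strong effect sizes reported for this system (multiple-log2 changes);
amplitude/noise = 6 gives per-timepoint z-separation of about 6/√8 per
contrast, i.e. near-complete power at the stringent cutoff used below.

What the generator does *not* emulate: probe-level intensity structure,
normalization artifacts, animal-level correlated random effects,
heavy-tailed or variance-heterogeneous noise within a gene, RNA
degradation. Tests passing on this generator therefore demonstrate
correctness of the analysis machinery and its behavior under the study's
nominal noise model — not performance on real arrays.

The published archetype composition (58, 231, 37, 120, 71, 6, 83, 40 for
A–H; 646 genes) is built in; `proportional_archetype_counts(n)` apportions
any other signal-gene total across the archetypes by largest remainder
(1932 → 173/691/111/359/212/18/248/120).

## Per-gene testing: moderated F over neighboring contrasts

Each gene is fit by OLS on a cell-means design (one indicator per time
level), so coefficients are per-time means and the residual variance
s²_g has d_g = n_g − 6 degrees of freedom (41 for a complete gene).
Cell-means rather than reference coding is a presentation choice; the F
statistic is identical either way.

Variance moderation assumes 1/σ²_g ~ χ²(d₀)/(d₀·s₀²). The hyperparameters
are estimated by moment-matching the log sample variances: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2) (ψ the digamma function), the
model implies Var(e) = ψ′(d₀/2) + mean ψ′(d_g/2), so the excess of the
empirical variance of e over the sampling term is inverted through the
trigamma function (monotone geometric bisection on (0, 10⁶], tolerance
1e-10) to give d₀, and s₀² follows from the mean of e. When the empirical
spread does not exceed the sampling term, d₀ = +∞ and s₀² is the
df-weighted pooled variance. Genes with d_g = 0 or s² = 0 are excluded
from the moment fit; d_g = 0 genes receive p = 1 and a flag. This
estimator is cross-checked in the test suite against an independent
R/Bioconductor implementation of the same empirical-Bayes model on a
frozen fixture (agreement ~1e-11 relative on F, p, d₀, s₀²).

The five successive-difference contrasts span the full 5-dimensional
between-time space, so the moderated F over the contrast set equals the
moderated one-way ANOVA F (numerator df 5) — algebraically identical and
numerically stabler; the quadratic form is computed against
C(XᵀX)⁻¹Cᵀ so that per-gene missing cells (unequal group sizes) are
handled without imputation. p-values come from F(5, d₀+d_g)
(χ²₅/5 when d₀ = ∞). Ranking sorts by ascending p with lexical tie-break
on gene ID; significance is the fixed cutoff α = 5×10⁻⁷, mirroring the
source analysis — a Benjamini–Hochberg column is emitted for reference
but plays no role in the defaults.

## Profile clustering and archetype labels

Profiles are per-gene means over the samples available at each timepoint
(7 animals at 6 h under the default design), then mean-centered so that
shape, not magnitude, drives similarity. "Spearman correlation distance
followed by K-means" is ill-posed for a non-Euclidean metric, so it is
realized exactly: profiles are converted to average-rank z-scores
(population SD), in which ‖ũ−ṽ‖² = 2m(1−ρ_Spearman) for tie-free vectors
of length m — squared Euclidean distance *is* the stated distance up to a
constant, and standard K-means (k-means++ seeding, n_init = 50 restarts,
seeded) applies. Constant profiles have undefined rank correlation; they
are excluded from clustering and labeled OTHER. K defaults to 25, the
number of patterns the source study reports.

Centroids (and any centered profile) are labeled by a deterministic rule
cascade on shape features computed from deviations relative to the 0 h
value: peak/trough time, strict interior local maxima, initial direction
(beyond 0.15×range), endpoint return (within 0.2×range), 2–6 h plateau
(spread ≤ 0.15×range), monotone decline. Order matters: the two-peak
shape D is tested before the single-peak shapes, and the monotone decline
F before the recovering declines E and G. These tolerances quantify
verbal shape descriptions and were fixed as part of the design, not
tuned per dataset.

A property worth knowing: archetypes C and G contain exactly tied values
(C at 0/1/24 h, G at 2/3/6 h). Under rank geometry, noise breaks those
ties into discrete orderings, so members of C and G genuinely decompose
into sub-patterns whose mutual Spearman distance exceeds their distance
to neighboring archetypes. Consequently K = 8 recovers the six tie-free
archetypes cleanly (the hyperacute cluster A contains exactly its 58
planted genes across seeds) but splits G and disperses C; at the default
K = 25, majority-label agreement with generator truth exceeds 95 %. This
is a property of the distance, not an implementation artifact, and is
presumably one reason the source analysis clustered at K = 25 before
manually curating eight clinically interesting shapes.

## Candidate-biomarker comparison

Candidate lists are CSV (name, alt_name, source, note); mapping tables
are static TSV (external, internal, kind) — no live ortholog service, for
reproducibility. Name matching is case-insensitive after alias
resolution; candidates resolving to the same current name are merged
(the shipped 74-entry transcription resolves to 73 candidates since BNP
and Nt-proBNP are both NPPB); one-to-many mappings contribute one row
per target with provenance. Entries printed as "NS" (no p-value) count
as p = 1 and are flagged for display rather than dropped. The shipped
transcriptions of the printed tables reproduce the published counts: 29
of 59 literature candidates and 7 of 24 surgery-specific downregulated
genes fall below 5×10⁻⁷. (The upregulated surgery-specific table is
shipped too but its printed prose count disagrees with its printed
p-values — four claimed versus three p-values below the cutoff, Lyve1 at
6.67×10⁻⁷ being just above — so no test asserts a count for it.)

## The stroke clock

`StrokeClock` is a nearest-temporal-profile regressor. Training computes,
per panel gene, the mean and SD over all training samples and the
per-timepoint mean of the standardized values (the centroid curve). A
test sample is standardized with the *training* statistics — a single
sample cannot be standardized against itself, so this is the only
defensible one-sample choice — and scored against the centroid curves
interpolated piecewise-linearly in log(1+t) on a 0.1 h grid over
[0, 24] h that always contains the design timepoints. The estimate t̂
minimizes the mean squared deviation across panel genes; exact score
ties break to the earliest time (clinically conservative: favors
treating). log(1+t) interpolation is used because the sampling grid is
roughly uniform on that axis; linear-in-hours would let the 6–24 h
segment dominate the grid. The window label compares t̂ to τ_w = 4.5 h,
the thrombolysis eligibility horizon.

Panels are chosen as the top-k most significant genes per archetype
(default k = 3 over the 8 archetypes → 24 genes), guaranteeing shape
diversity; the source study's sketch of combining three top genes
pairwise at three timepoints corresponds to a 3-gene panel of those
genes. Standardization makes estimates exactly invariant to per-gene
affine rescaling applied consistently to training and test data.

Evaluation is leave-one-animal-out: all samples of one animal are held
out per fold, the clock is retrained on the remainder, and every
held-out sample is timed. Reported: median absolute error (h) and
within/beyond-4.5 h classification accuracy. On the default design at
the generator's study-level noise (σ = 0.25, amplitude 1.5) the LOAO
median absolute error is ≈ 0.1 h with window accuracy 1.0; error is 0 at
σ = 0 and grows monotonically with σ. A permutation negative control
(shuffled training times) drops window accuracy to the ~2/3 base rate.

## Numerical and degenerate-input conventions

- All randomness flows through `numpy.random.default_rng(seed)`; every
  CLI stage logs its settings, seeds and input SHA-256 digests.
- Matrix TSVs are written at %.17g and parsed with round-trip float
  precision, so write∘read is bit-exact.
- Zero residual variance with a non-zero contrast (noise-free data, no
  prior) yields F = ∞ and the smallest positive p rather than NaN.
- Constant genes: excluded from clustering (degenerate ranks), rejected
  as clock panel members (zero training SD), flat-profile features
  classify as OTHER.
- Problem sizes in the tests and the acceptance script are the study's
  own: 47-sample design, 646 or 19,935 genes, 10 clustering seeds, 50
  K-means restarts, 20–50 replicate draws for hyperparameter-recovery
  checks.

## Known limitations

- The archetype rule tolerances (0.2 return, 0.15 plateau/flat) are
  reasonable formalizations of verbal descriptions; other choices would
  move boundary profiles between neighboring labels (B↔C, E↔G).
- The clock assumes the test sample comes from the trained temporal
  process; it extrapolates nothing beyond 24 h and reports a matching
  score, not a calibrated confidence interval.
- Fixed-effects models only: the repeated-measures correlation within
  animals is ignored in testing (as in the source analysis) and only
  respected by the LOAO evaluation split.
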