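# strokeclock

Time-course analysis of hyperacute blood transcriptomes after experimental
stroke, and a "stroke clock" — an estimator of hours since stroke onset
from a panel of genes with stereotyped temporal expression profiles.

Thrombolysis is only licensed within the first 4.5 h of ischemic stroke
onset, yet onset time is often unknown. In the rodent model this package
targets, whole-blood mRNA was sampled repeatedly in the same animals at
0, 1, 2, 3, 6 and 24 h after middle cerebral artery occlusion (8 animals,
one missed draw, 47 arrays). Many genes change expression within hours and
in reproducible shapes; those overlapping temporal shapes jointly encode
elapsed time. The package re-implements that analysis chain as a tested
pipeline for anyone studying time-resolved blood biomarkers:

1. **Synthetic data** (`strokeclock.simulate`) — a generator that emulates
   the repeated-measures design and plants genes following eight named
   temporal archetypes (A–H: e.g. A = hyperacute transient upregulation
   peaking at 2 h; F = monotone decline through 24 h), with known
   baselines, amplitudes, and Gaussian noise, so every downstream stage is
   testable against ground truth.
2. **Moderated F** (`strokeclock.timecourse`) — per-gene cell-means linear
   models over the time factor, empirical-Bayes variance moderation, and an
   F test over the five neighboring-timepoint contrasts
   (1−0, 2−1, 3−2, 6−3, 24−6): with residual variance s²_g on d_g df and an
   inverse-χ² prior (d₀, s₀²) estimated across genes,

       s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
       F_g = (Cβ̂_g)ᵀ [C(XᵀX)⁻¹Cᵀ]⁻¹ (Cβ̂_g) / (r·s̃²_g),  p from F(r, d₀+d_g),

   ranked with a fixed significance cutoff α = 5×10⁻⁷.
3. **Profile clustering** (`strokeclock.clustering`) — per-timepoint
   averaging, mean centering, K-means under Spearman-correlation distance
   (realized exactly as Euclidean K-means on rank z-scores), and a
   deterministic rule cascade labeling cluster centroids with the A–H
   archetypes.
4. **Biomarker comparison** (`strokeclock.biomarkers`) — locating published
   candidate stroke biomarkers (shipped as transcribed printed tables)
   inside the ranking through a static human→rat mapping, counting
   significant candidates, and Venn condition-specificity partitions.
5. **Stroke clock** (`strokeclock.clock`) — a nearest-temporal-profile
   estimator: panel genes are standardized by training mean/SD, averaged
   per timepoint into centroid curves, interpolated piecewise-linearly in
   log(1+t), and a new sample's hours-since-onset t̂ is the grid point
   minimizing the mean squared deviation, with a within/beyond-4.5 h label.
   Evaluation is leave-one-animal-out (LOAO).

The statistical estimators follow scikit-learn conventions
(`ModeratedFTest`, `SpearmanKMeans`, `StrokeClock` with
`fit`/`predict`/`transform` and fitted `_` attributes) and compose with
sklearn pipelines; the module-level functions are thin wrappers.

## Worked example

```python
import strokeclock as sc
from strokeclock import timecourse, clock

# study-design synthetic data: 646 archetype genes + 2000 null genes
ds = sc.study_dataset(noise_sd=0.25, n_null=2000, seed=1)

ranked = timecourse.rank_genes(ds.expression, ds.samples, alpha=5e-7)
print(f"significant genes: {int(ranked['significant'].sum())} of {len(ranked)}")
print(f"prior df d0 = {ranked.attrs['prior_df']:.1f}, "
      f"prior var s0^2 = {ranked.attrs['prior_var']:.4f}")

# cluster the planted signal genes at low noise and label archetypes
ds_lo = sc.study_dataset(noise_sd=0.1, seed=1)
std = sc.standardize(sc.average_profiles(ds_lo.expression, ds_lo.samples))
assign = sc.assign_archetypes(sc.cluster_profiles(std, k=8, seed=1, n_init=50))
print(assign["archetype"].value_counts().sort_index().to_dict())

# train and evaluate a 24-gene clock panel (3 genes per archetype)
labels = ds.truth.set_index("gene_id")["archetype"]
panel = sc.select_panel(ranked, labels, k_per_archetype=3)
report = clock.evaluate_loao(ds.expression, ds.samples, panel)
print(f"LOAO median |error| = {report.median_abs_error_h:.2f} h, "
      f"4.5 h window accuracy = {report.window_accuracy:.3f}")
```

prints

```
significant genes: 646 of 2646
prior df d0 = 3930.7, prior var s0^2 = 0.0623
{'A': 58, 'B': 248, 'D': 120, 'E': 120, 'F': 6, 'H': 60, 'OTHER': 34}
LOAO median |error| = 0.10 h, 4.5 h window accuracy = 1.000
```

All 646 planted time-responsive genes clear the 5×10⁻⁷ cutoff with no
false positives among the 2000 null genes; the estimated prior variance
(0.0623) matches the generating noise variance (0.25² = 0.0625); the
hyperacute cluster A is recovered with exactly its 58 planted genes (the
two archetypes containing exactly tied values, C and G, split under rank
geometry at K = 8 — see `docs/methods.md`); and the clock places held-out
samples within ~6 minutes of their true draw time at study-level noise.

A CLI mirrors these stages
(`strokeclock simulate|rank|cluster|compare|clock-train|clock-estimate|evaluate`),
writes run logs with settings, seeds and input digests, and accepts a
`--config` YAML of option presets.

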