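# Methods

## The model

Each subject contributes six co-registered scalar volumes — DWI (b = 1000
s/mm² diffusion-weighted intensity), FA, S0 (b = 0 T2 signal), MD, AD, RD —
plus a brain mask and a manually defined tumor ROI, all on one grid
(nominally 1.7 mm isotropic). The analysis is strictly voxel-wise: a voxel
is the 6-vector of its normalized intensities, in the fixed order
(DWI, FA, S0, MD, AD, RD).

**Normalization.** DWI and S0 are in arbitrary scanner units, so every
feature is rescaled per subject to [0, 1] by percentile-clipped min-max
(p1–p99 within the brain mask; values outside the band clip to 0/1). FA is
clipped to [0, 1] and negative diffusivities to 0 beforehand (tensor fits
can produce both; counts are logged). A global z-score mode exists for
comparison. The percentile clip makes the scaling robust to the heavy upper
tails of diffusivity maps; the per-subject record is stored for inversion
and consistency checks. A feature constant within the mask maps to 0.5 with
a warning rather than failing the subject.

**Level 1 — batch SOM.** A rows×cols (default 20×20) self-organizing map is
trained on the pooled in-mask voxels of all subjects. Codebook
initialization samples input rows under the seed; each batch epoch assigns
every voxel to its best-matching unit (BMU) and replaces each codebook
vector by the neighborhood-kernel-weighted mean of the winners' data, with
a Gaussian kernel whose radius decays linearly from max(rows, cols)/2 to 1
over the ordering epochs (default 50). A fine-tuning tail (default
max(5, epochs/5) epochs) then runs with a vanishing neighborhood — plain
Lloyd updates — which sharpens each protocluster onto its own data and
makes the recorded quantization error non-increasing over the tail. Without
the tail, the radius-1 kernel leaves enough smoothing bias that codebook
vectors sit between well-separated tissue clusters and the map quantizes
measurably worse than its own initialization on blob-structured data.
Finally, any node that wins no voxel (a unit stranded between clusters by
the smoothing phase) is snapped to its nearest observed voxel, so every
protocluster represents observed tissue; otherwise such nodes would enter
the second-level partition with meaningless interpolated positions.
Training is deterministic given (seed, input order). Inside training
epochs the BMU search runs in single precision for speed; the public BMU
API and all downstream assignments are double precision with ties broken
to the lowest node index.

**Level 2 — K-means++ on protoclusters.** For each K in the sweep (default
{4, 6, 8, 10, 12, 16, 20}) the 400 codebook vectors are partitioned by
K-means with K-means++ seeding, best of 10 restarts by within-class sum of
squares. Nodes are weighted by their mapped-voxel counts by default, so the
partition reflects the voxel distribution rather than map area; an
unweighted mode exists. Whether the original analysis weighted nodes, or
clustered voxels through nodes, is not determinable from its description;
the weighted-node reading is the package default, not an assertion.
An empty class triggers a reseeded retry (sklearn's relocation makes this
effectively unreachable).

**Canonical class ordering.** Class numbers carry meaning (the warm,
high-numbered end marks high-grade-like tissue), but no explicit rule comes
with the published figures. Labels 1..K are assigned in increasing order of
the centroid score mean(S0, MD, AD, RD) − mean(DWI, FA); ties break by
centroid MD then RD. This reproduces the qualitative published ordering —
the top class is the high-diffusivity / low-anisotropy (necrosis-like)
signature, the bottom classes are S0-dominant — and makes labels
reproducible across runs and seeds.

**DTcI and class-occupancy features.** A DTcI labels each in-scope voxel
with the class of its BMU (0 outside the mask). Per subject, tumor-ROI
class counts c_k (total T) give ratios c_k/T and smoothed log-ratios
ln((c_k + εT/K)/(T + εT)) with ε = 10⁻³. The smoothing is proportional to T
so empty classes stay finite and subjects of different tumor sizes remain
comparable; as ε → 0 the value tends to ln(ratio) for occupied classes.
Natural log throughout (the log base only rescales each feature, and both
the SVM with standardized inputs and the rank-based tests are invariant to
per-feature scale).

**Classification.** Features are the K log-ratios; positive class is
high-grade (or MIB-1 ≥ 5%). Linear-kernel SVM, C = 1, features
standardized with training-fold statistics only — with N = 27 subjects a
linear margin is the conservative choice; an RBF mode is configurable.
Leave-one-out CV pools the 27 held-out decision values for the AUC
(identical to the Mann–Whitney probability) and the 27 hard predictions
for sensitivity/specificity/accuracy — a reading that needs no extra
operating threshold. The LOOCV is repeated 100 times; the pipeline is
otherwise deterministic given the clustering, so repetitions are made
meaningful by re-seeding the K-means++ partition of the fixed SOM per
repetition (documented assumption; with reseeding off all repetitions
coincide and the CIs collapse). Summary CIs are 2.5/97.5 percentiles
across repetitions. Clustering is fit on all subjects before LOOCV — it is
label-free, mirroring the unsupervised-then-supervised pipeline order — and
a leakage-free nested mode (re-partitioning from training-fold node weights
inside every fold) is available behind a flag for methodological
comparison.

## Statistics

* **AUC across the K sweep:** one-way fixed-effects ANOVA on the (K,
  repetition) AUC table; partial η² = SSB/(SSB+SSW); Tukey HSD
  (Tukey–Kramer when unbalanced) via the studentized range. An
  all-constant table (possible when a clean synthetic cohort is separable
  at every K) is flagged degenerate instead of reporting 0/0.
* **Exact WMW:** U counts pairs with ½ for ties. The two-sided p is the
  exact permutation tail P(|U − n₁n₂/2| ≥ observed) over all C(n₁+n₂, n₁)
  group assignments, computed by a dynamic-programming convolution over
  doubled midrank subset sums — identical to literal enumeration, used
  whenever C(n₁+n₂, n₁) ≤ 3×10⁶ (covers the 19 vs 8 and 18 vs 9 cohort
  splits); above the cap, a Monte Carlo permutation estimate with 10⁵
  draws (add-one correction). Among the several exact two-sided
  conventions, the |U − mean| tail was fixed; conventions differ at ties.
  The shift estimate is Hodges–Lehmann (median of pairwise differences)
  with the classical distribution-free CI: order statistics of the
  pairwise differences at ranks read off the exact null U distribution
  (normal-approximation ranks in Monte Carlo mode). Effect size
  r = |Z|/√N with Z from the tie-corrected normal approximation (the
  original report does not define its r; this is the standard choice).
  No multiple-testing correction across classes by default, matching how
  per-class comparisons are reported; Holm is available.
* **Cohort tests:** Pearson χ² without continuity correction — fixed
  because it reproduces the reference cohort's printed sex-ratio p-values
  (.33, .78) — and the pooled-variance two-sample t. The reference
  cohort's grade-by-MIB-group p = .002 is not reproducible from its
  printed 2×2 counts by any standard test (uncorrected ≈ .003, Yates ≈
  .011, Fisher ≈ .006) and is therefore not used as a check.
* **Class intensity profiles (radar data):** per class, the mean
  normalized intensity of each feature over member tumor voxels with a
  percentile-bootstrap 95% CI (default 2000 resamples). "Ratio of
  normalized intensities" is read as the per-class mean in [0, 1]; the
  per-class-mean-over-global-mean alternative is a config flag away in
  spirit but was not needed by any downstream consumer. For classes above
  20,000 voxels the CI (not the mean) is computed on a seeded subsample of
  that size; at that size the CI half-width is already ≲ 0.003, so the
  truncation is negligible. CIs are recentred on the full-class mean and
  clamped to bracket it.

## The synthetic cohort

The generator emulates the study conditions, not the images: 19 low- vs 8
high-grade subjects (18 vs 9 under the MIB-1 5% split), per-subject ROI
sizes from a normal(9564, 4260) truncated to [100, 17463] — matching the
reported per-subject feature counts — and voxels drawn i.i.d. from
tissue-class archetypes.

* **Archetypes.** Default palette of 6: fixed normal-tissue,
  necrosis-like (low DWI/FA, high S0/MD/AD/RD) and dense-cellular (low
  diffusivities) signatures plus seeded random directions, all at
  0.5 + (separation/2)·u for unit vectors u pairwise ≥ 1 apart, so
  pairwise mean distances are ≥ separation/2 (default separation 0.5) and
  means stay in [0, 1]. Per-feature Gaussian noise, default sd 0.05,
  clipped to [0, 1]; independent noise is the simplest model consistent
  with normalized intensities (correlated noise would be a config
  extension). The archetype count is deliberately not tied to any K used
  downstream.
* **Group structure.** Subject mixtures are Dirichlet about their group
  mean (concentration 60 — enough subject-level variability to make the
  classification nontrivial at small ROI sizes without swamping the group
  signal); the high group's mean shifts 0.25 of its weight onto the
  necrosis-like archetype (taken proportionally from the rest), the
  "strong shift" condition. MIB-1 LI is lognormal conditional on grade
  (medians ≈ 2% and 9%, log-sd 0.8/0.9), so the grade and MIB-1 groupings
  correlate but disagree for a few subjects per cohort, as in the
  reference cohort (2 high-grade in the lower-MIB group, 3 low-grade in
  the higher).
* **Geometry.** The ROI is a compact ellipsoid (axis ratio 1.2:1:0.8)
  nested in a brain blob of 1.5× its volume filled with normal-tissue
  voxels; there is no spatial autocorrelation — the pipeline is
  voxel-wise, so spatial texture affects only the cosmetics of rendered
  DTcIs, and no quantitative description of within-tumor texture exists
  to calibrate against.

What passing tests on this phantom do and do not show: they verify that the
implementation recovers planted mixture structure (ARI ≥ 0.8 with the
default separation/noise), that the group signal propagates through
clustering and classification (AUC ≥ 0.95 under the strong shift, chance
under zero shift), and that the statistics are calibrated (per-class exact
WMW type-I error within [0.03, 0.07] at nominal .05 over 200 null
cohorts). They do not show that real meningiomas are Gaussian archetype
mixtures, that clinical AUCs of ~0.96 are reproducible, or that the best K
on real data is 16 — on clean mixtures several K values classify
perfectly, which is why the AUC-vs-K ANOVA can be flagged degenerate on
synthetic runs.

The type-I calibration draws per-subject class-count profiles directly
from the Dirichlet–multinomial null (the same count-generating process the
voxel pipeline induces on occupancy profiles; clustering is label-free and
cannot affect type-I error), rather than re-running 200 voxel-level
pipelines.

## Seeds, determinism, caching

One master seed fans out to every stochastic component (palette, cohort,
per-subject draws, SOM init, per-K and per-repetition K-means++ seeds,
bootstraps, Monte Carlo) via SHA-256 of a documented tag path
(`derive_seed(master, "km", K, "rep", r)`), each child below 2³¹. Identical
configuration and master seed give bit-identical artifacts, verified by
SHA-256 checksums in the run manifest. Pipeline stages cache per artifact:
an unchanged configuration reloads the codebook (round-tripped through
full-precision CSV) and recomputes only missing per-K partitions.

## Problem sizes in the shipped checks

The test suite and acceptance script run the full 27-subject composition
with per-subject ROI sizes drawn from a narrowed range (300–1200 voxels)
for the voxel-level recovery checks, and the full range for the default
acceptance run; group structure, palette, shift, SOM size and all
thresholds are the defaults. The statistics and oracle checks run at the
cohort's native sizes (19 vs 8, C(27,8) enumeration).

## Known limitations

* i.i.d. voxels: no partial-volume gradients, no spatial smoothness, no
  B1/coil inhomogeneity; DTcI renderings of synthetic subjects look
  speckled rather than anatomically smooth.
* The SVM operating point is the classifier's own (hard predictions);
  sensitivity/specificity at other ROC operating points are not reported.
* The nested (leakage-free) CV mode re-partitions only the second
  clustering level per fold; the SOM itself, being trained without labels
  on all subjects, is shared.
* Exact WMW CIs use one fixed two-sided convention; at heavy ties other
  conventions give slightly different p-values.
* Pooled-LOOCV AUC is pessimistic under the null: each held-out subject is
  scored by a model trained on a remainder that over-represents the other
  class, so chance-level estimates land somewhat below 0.5 (typically
  0.38–0.46 on 27-subject null cohorts) rather than at it.
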