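# dtci — diffusion-tensor-based clustered imaging of brain tumors

`dtci` implements a two-level unsupervised clustering analysis of
multiparameter diffusion-tensor imaging (DTI) for grading meningiomas and
estimating their proliferative activity, together with the synthetic cohort
generator, classification and statistics layers needed to study the method
end to end.

Preoperative grading matters: WHO grade II/III meningiomas recur far more
often than grade I tumors, and single MRI parameters (ADC, FA) have proven
unreliable discriminators. The approach here treats each tumor voxel as a
six-dimensional feature vector — diffusion-weighted intensity (DWI),
fractional anisotropy (FA), the b=0 T2 signal (S0), and mean/axial/radial
diffusivity (MD, AD, RD) — and clusters the pooled voxel cloud in two
levels:

1. **SOM.** A 20×20 self-organizing map quantizes the normalized voxel
   vectors into 400 topologically ordered *protoclusters*, filtering voxel
   noise and exposing the intensity structure on per-feature *component
   planes*.
2. **K-means++.** The 400 codebook vectors (weighted by mapped-voxel
   counts) are partitioned into K classes (K ∈ {4, 6, 8, 10, 12, 16, 20}),
   and classes are canonically ordered by a diffusivity score — mean(S0,
   MD, AD, RD) − mean(DWI, FA) — so the top class number is always the
   free-water/necrosis-like end of the spectrum.

Relabeling every voxel with the class of its best-matching unit yields a
**DTcI** (diffusion-tensor-based clustered image). For each subject the
tumor-ROI class occupancies give a K-vector of smoothed log-ratios

&nbsp;&nbsp;&nbsp;&nbsp;f<sub>k</sub> = ln((c<sub>k</sub> + ε·T/K) / (T + ε·T)),&nbsp;&nbsp;
c<sub>k</sub> = class-k voxel count, T = ROI total, ε = 10⁻³,

which a linear SVM classifies (low vs high grade; MIB-1 labeling index < 5%
vs ≥ 5%) under leave-one-out cross-validation repeated 100 times (each
repetition re-seeds the K-means++ partition of the fixed SOM). The
statistics layer compares AUC across the K sweep (one-way ANOVA, partial
η², Tukey HSD), tests per-class log-ratio group differences with the exact
Wilcoxon–Mann–Whitney test (full-enumeration p-values, Hodges–Lehmann shift
with a distribution-free CI, effect size r = |Z|/√N), and reproduces the
cohort-table tests (uncorrected Pearson χ², pooled-variance t).

Because the underlying patient data is not publicly deposited, the package
ships a first-class synthetic cohort generator: 27 subjects (19 low- vs 8
high-grade), tumor ROIs of 100–17,463 voxels, and voxel vectors drawn from
tissue-class archetypes (necrosis-like, dense-cellular, normal tissue, …)
whose mixture proportions differ between groups, with planted per-voxel
ground truth for recovery tests.

## Worked example

```python
import numpy as np
import dtci

# synthetic cohort: 19 low- vs 8 high-grade subjects (reduced ROI sizes)
subjects, cohort, truth = dtci.simulate_cohort(
    n_per_group=(19, 8), seed=42, roi_size_range=(300, 1200))
norm = [(dtci.normalize_features(s.maps), s.roi) for s in subjects]
pool = dtci.pool_voxels(norm, scope="brain")

grid = dtci.train_som(pool, rows=20, cols=20, epochs=50, seed=1)
weights = dtci.node_voxel_counts(grid, pool.X)
part = dtci.cluster_protoclusters(grid, K=16, seed=2, node_weights=weights)

roi_pool = dtci.pool_voxels(norm, scope="roi")
node_counts, sids = dtci.node_count_matrix(grid, roi_pool)
counts = dtci.class_counts_from_nodes(node_counts, part)
profiles = dtci.profiles_from_counts(counts, sids, K=16)
F = np.stack([p.log_ratios for p in profiles])

y = (cohort.grade_group == "high").astype(int).to_numpy()
tests = dtci.per_class_group_comparison(F, y)
print(tests.tail(1)[["class", "p", "r", "hl_shift"]])
```

Running the classification on this cohort prints:

```
pooled 31081 voxels from 27 subjects
SOM quantization error: 0.1548
16-class DTcI grade classification over 100 repeated LOOCVs:
  AUC  0.998  (95% CI 0.987-1.000)
  sens 0.995  spec 0.958  acc 0.969
top-ordered classes, high- vs low-grade log-ratio shift:
  class 16: p = 9.009e-07, r = 0.78, shift = +1.82
```

The top-ordered class (16 — high S0/MD/AD/RD, low DWI/FA, the
necrosis-like signature) is strongly over-occupied in high-grade tumors:
its log-ratio is shifted by +1.8 with effect size r = 0.78 at an exact
two-sided p ≈ 10⁻⁶, and the repeated-LOOCV SVM separates the groups almost
perfectly (mean AUC 0.998). On clean synthetic mixtures the separation is
sharper than on clinical data; the interest is in the recovered structure,
not the absolute numbers.

## Command line

The same pipeline runs from the shell with cached, resumable stages:

```bash
dtci run-all --out run1 --seed 7 --k 4,6,8,10,12,16,20 --n-rep 100
dtci stats   --out run1 --seed 7          # reuses cached artifacts
```

Stages: `simulate`, `extract`, `cluster`, `dtci`, `classify`, `stats`.
Outputs are CSV/JSON tables plus NIfTI volumes, checksummed in
`run1/manifest.json`; identical seeds give bit-identical artifacts.

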