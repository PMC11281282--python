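# shgfiber

Quantification of collagen-1 (Col1) fibers in second-harmonic-generation
(SHG) micrographs, and the downstream statistics that relate fiber content
to cancer recurrence and survival.

Fibrillar collagen is non-centrosymmetric and therefore emits an intrinsic
frequency-doubled signal under two-photon illumination (e.g. 860 nm
excitation detected at 430 nm), so Col1 fibers can be imaged label-free on
ordinary H&E tissue sections. In early-stage non-small cell lung cancer,
denser Col1 networks in the resected tumour are a candidate marker of
recurrence risk. This package implements that analysis chain as a tested,
reusable Python library:

- **Segmentation** — fuzzy c-means (FCM) clustering of voxel intensities,
  implemented from scratch. FCM minimises
  `J(U, V) = Σ_i Σ_k u_ik^m (x_i − v_k)²` subject to `Σ_k u_ik = 1`; the
  cluster with the highest centroid is the fiber class, defuzzified by
  argmax membership.
- **Morphometry** — connected components are measured (skeleton geodesic
  length, ridge width = 2 × mean distance transform on the skeleton) and a
  shape filter keeps only elongated, thin structures; the primary readout is
  **percent fiber volume** = 100 × fiber voxels / total voxels per field of
  view (FOV), averaged over 6–18 FOVs per patient.
- **Stitching** — whole-section quadrant tile scans (~300 µm overlaps) are
  reassembled with correlation-refined integer offsets and max blending.
- **Statistics** — one-tailed unpaired Student t-test on patient means; a
  REML random-intercept model `log(volume) ~ recurrence + (1 | patient)` on
  per-FOV values; Kaplan–Meier curves, the log-rank test, and a hazard ratio
  (primary estimator `(O_high/E_high)/(O_low/E_low)` from the log-rank
  table, Cox as the labelled alternative) after a median split on mean
  fiber volume.
- **Gene panels** — `|log2FC| > 0.5` (~1.4-fold) and `padj ≤ 0.05`
  threshold filtering of differential-expression tables over curated
  ECM / CAF / immune-checkpoint / T-cell panels, with Benjamini–Hochberg
  adjustment for synthetic tables.
- **Synthetic data** — SHG-like fiber images with exact ground truth,
  two-group cohorts with log-scale variance components, exponential
  survival with a specified hazard ratio, and DE tables with planted
  effects, so the whole pipeline is exercisable with no external data.

The library is used from Python; `examples/` holds one short narrative
script per capability.

## Worked example

```sh
python examples/01_segment_synthetic_fov.py
```

```
planted truth fraction : 10.03 %
raw FCM mask fraction  : 10.31 %
percent fiber volume   : 10.05 %
Jaccard vs ground truth: 0.938
```

A synthetic FOV is generated with 10% of its area covered by curvilinear
fibers plus ten bright circular blobs. FCM segmentation alone slightly
over-calls (the blobs are bright too); the length/width shape filter removes
them, leaving an estimate within 0.3 percentage points of the planted truth
and a 0.94 Jaccard overlap with the exact ground-truth mask.

```sh
python examples/02_cohort_recurrence_stats.py
```

```
t-test (recurrent > non-recurrent): t=2.751, df=24, one-sided p=0.0056
mixed model: beta=0.648 (log scale), SE=0.191, one-sided p=0.0003
median split at 3.14 % fiber volume (13 high vs 13 low)
log-rank chi2=8.508, p=0.0035, O/E hazard ratio=3.07 (Cox 3.72)
```

On a simulated 12-vs-14-patient cohort with a true +0.5 log-scale group
effect and a true hazard ratio of 2.7, both tests detect the group
difference (the FOV-level mixed model more sensitively than the
patient-level t-test) and the median-split survival analysis recovers an
elevated hazard in the high-fiber group.

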