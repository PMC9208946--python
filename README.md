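# neurofuzz

Fuzzy C-means MRI tissue segmentation with particle-swarm-optimised
initialisation, adaptive median denoising, and an ALFF/zALFF resting-state
analysis stage with ROI group statistics and ROC discrimination — all
exercisable end-to-end on synthetic, ground-truthed brain phantoms.

## Who this is for

Researchers and students working on brain MR image analysis who want a
small, fully testable implementation of two common pipelines:

1. **Segmentation**: noisy intensity image → adaptive median filter →
   fuzzy C-means (FCM) with PSO-chosen initial centers → hard tissue labels
   (CSF/GM/WM), scored by Jaccard similarity against ground truth.
2. **Resting state**: 4D BOLD series → motion QC and initial-volume
   trimming → band-limited spectral amplitude (ALFF, 0.01–0.08 Hz) →
   whole-brain normalisations mALFF and zALFF → ROI means, two-group tests
   and ROC curves with Youden cut-offs.

Because no public cohort accompanies these methods, the package ships a
seeded phantom generator (concentric multi-tissue images with exact label
maps, impulse/Gaussian corruption, BOLD series with low-frequency
oscillations confined to labelled ROIs) so every stage runs and is verified
without any download.

## The core method

FCM minimises the fuzzified within-cluster objective

    J_m = Σ_i Σ_k u_ik^m ‖x_k − c_i‖²,   m > 1,

alternating `u_ik = 1/Σ_j (d_ik/d_jk)^(2/(m−1))` and
`c_i = Σ_k u_ik^m x_k / Σ_k u_ik^m` until the maximum center displacement
falls below ε or T iterations pass (defaults m = 2, T = 100, ε = 1e-4).
The initial centers are found by a particle swarm whose fitness is the FCM
objective under the memberships a candidate implies — this lands FCM near
the global optimum and cuts iterations-to-convergence roughly threefold on
noisy phantoms. zALFF standardises ALFF as `(ALFF − mean)/SD` over the
brain mask; ROC analysis reports the trapezoidal AUC (equal to the
Mann–Whitney pair-ordering proportion) and the Youden-index cut-off with
its sensitivity and specificity.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

```python
import numpy as np
from neurofuzz import (PhantomSpec, generate_tissue_phantom, corrupt,
                       adaptive_median_filter, FCMConfig, fcm_segment,
                       per_class_jaccard)

spec = PhantomSpec(shape=(64, 64), tissue_means=(20, 120, 220),
                   tissue_sd=5, seed=7)
image, truth = generate_tissue_phantom(spec)
noisy = corrupt(image, "impulse", level=0.1, seed=7)   # 10% salt & pepper
clean = adaptive_median_filter(noisy)

result = fcm_segment(clean, FCMConfig(n_clusters=3), init="pso", seed=7)
print("centers:", np.round(result.model.centers, 2))
print("iterations:", result.model.n_iter, "converged:", result.model.converged)
print("per-class Jaccard:",
      {k: round(v, 4) for k, v in per_class_jaccard(result.label_map, truth).items()})
```

prints

```
centers: [ 20.21 120.04 219.69]
iterations: 3 converged: True
per-class Jaccard: {0: 0.9807, 1: 0.9889, 2: 0.9981}
```

The recovered centers sit on the phantom's class means (20/120/220), the
PSO-seeded run converges in 3 FCM sweeps, and each tissue region overlaps
its ground truth at Jaccard ≈ 0.98–1.0. Skipping the filter and segmenting
the corrupted image directly drops the scores to
`{0: 0.6121, 1: 0.9006, 2: 0.9156}` — the impulse pixels land in the wrong
clusters, which is exactly what the denoising stage removes.

The resting-state branch works the same way:

```python
from neurofuzz import (OscillationSpec, generate_bold_series,
                       compute_alff, compute_zalff)

labels = np.zeros((12, 12), int); labels[4:8, 4:8] = 1
osc = OscillationSpec(roi_label=1, frequency=0.05, amplitude=3.0, noise_sd=0.5)
series, motion = generate_bold_series(labels, [osc], tr=2.0, n_volumes=240,
                                      seed=7, noise_sd=0.5)
z = compute_zalff(compute_alff(series))
print(round(z.values[labels == 1].mean(), 3),   # 2.775  (inside the ROI)
      round(z.values[labels == 0].mean(), 3))   # -0.347 (background)
```

The injected 0.05 Hz oscillation lifts the ROI's standardised low-frequency
amplitude nearly three in-mask SDs above the whole-"brain" mean.

A `neurofuzz` CLI wraps the same functionality
(`neurofuzz phantom|denoise|segment|alff|roc|run`); `neurofuzz run
--config config.json` executes a configured multi-stage pipeline and writes
a manifest with per-artifact SHA-256 hashes, reproducible at fixed seed.

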