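# Methods

This note documents the models and numerical choices behind `neurofuzz`:
a toolkit for fuzzy C-means (FCM) tissue segmentation of noisy MR images
with particle-swarm-optimised initialisation, adaptive median denoising,
and an amplitude-of-low-frequency-fluctuation (ALFF) resting-state stage
with ROI group statistics and ROC discrimination. Everything is exercised
on synthetic phantoms with exact ground truth, so every claim the test
suite makes is checkable against a known answer.

## Fuzzy C-means

Pixels are clustered on intensity alone (a 1D feature), which matches the
gray/white-matter segmentation problem for scalar MR images; spatial or
multi-channel features are out of scope. For data points `x_k`, centers
`c_i` and memberships `u_ik`, FCM minimises the fuzzified within-cluster
sum of squares

    J_m = Σ_i Σ_k u_ik^m ‖x_k − c_i‖²,   m > 1,

by alternating the closed-form updates

    u_ik = 1 / Σ_j (d_ik / d_jk)^(2/(m−1)),
    c_i  = Σ_k u_ik^m x_k / Σ_k u_ik^m.

Defaults: fuzzifier `m = 2`, iteration cap `T = 100`, termination tolerance
`ε = 1e-4`. The monitored quantity for ε is the maximum absolute center
displacement by default; `|ΔJ|` is available via `stop_on="objective"`
(the displacement criterion is the more common convention and is
scale-matched to intensity units). Alternating minimisation guarantees a
non-increasing objective trace, which the suite asserts on random
instances.

**Zero distances.** The membership formula divides by distances, so a point
within `zero_distance_eps` (default 1e-12) of a center receives membership
1 there, split equally over ties. This makes crisp solutions exactly
representable (noiseless phantoms converge to per-class Jaccard 1).

**Label canonicalisation.** After convergence, clusters are renumbered by
ascending center intensity, so label 0 is always the darkest tissue
(CSF < GM < WM under the default phantom means). This makes outputs
invariant to permutations of the initial centers and lets label maps be
compared to ground truth without a matching step. Defuzzification is the
per-pixel membership argmax, ties broken toward the lowest cluster index.

## PSO initialisation

FCM is sensitive to its initial centers: poor initialisation lands in local
minima and takes longer to converge. The initialiser runs a standard global
particle swarm over candidate C-vectors of centers. A particle's fitness is
the FCM objective evaluated under the memberships the candidate implies, so
the swarm optimises exactly the quantity FCM will refine. Velocity update:

    v ← w·v + c1·r1·(pbest − x) + c2·r2·(gbest − x)

with defaults `w = 0.72`, `c1 = c2 = 1.49` (the canonical
constriction-equivalent values), 20 particles and 50 iterations, all
configurable and recorded in output sidecars. Particle positions are
initialised uniformly over the data range with small random initial
velocities (±¼ of the range) to maintain early diversity. Positions are
deliberately *not* clamped to the data range: the objective itself grows
quadratically outside it, and a hard clamp was observed to create an
artificial attractor at the data minimum where the swarm could stagnate.
Degenerate particles (all centers coincident) score +∞. Equal seeds give
identical swarms; the global-best fitness trace is non-increasing by
construction.

The toolkit's PSO-benefit test compares, over 20 seeds on a three-class
phantom with Gaussian noise (sd 15), the median final objective and the
median iterations-to-convergence of PSO-initialised versus
randomly-initialised FCM. On this problem both initialisations usually
reach the same optimum (so the objective medians tie to numerical
precision), but PSO-seeded runs start near the solution and need roughly a
third of the iterations.

## Adaptive median filter

The classical two-stage scheme: for each pixel the window grows from
`s_init` (default 3) through odd sizes to `s_max` (default 7). Stage A asks
whether the window median is strictly between the window minimum and
maximum; if not, the window grows. Once the median is not an extreme,
stage B keeps the original pixel if it is itself not an extreme, otherwise
replaces it with the median. If the window reaches `s_max` with the median
still extreme (e.g. constant neighbourhoods), the pixel takes that median —
this choice makes isolated impulses in flat regions collapse to the
background value, which is the behaviour wanted for salt-and-pepper noise.
Because windows have odd pixel counts, every output value is an observed
input value: the filter invents no intensities. Borders use `reflect`
(default) or `nearest`. 3D volumes are filtered slice-wise by default,
matching 2D acquisition slices; full-3D windows are available by flag.

The filter is paired with the salt-and-pepper corruption model in the
phantom module (an exact fraction of pixels set to 0 or 255 with equal
probability, chosen without replacement), the impulse model this filter is
designed for. The Gaussian corruption model exercises the clustering
robustness tests instead.

## Synthetic phantoms and BOLD series

The default phantom is concentric: equal-width radial bands around the grid
centre, inner to outer, one intensity mean per tissue class
(20 / 120 / 220 on an arbitrary [0, 255] scale for CSF / GM / WM) with
within-class Gaussian spread `tissue_sd = 5`. Geometry is parametric, class
sizes are known, and the generator returns the exact label map, so
segmentation accuracy is measurable without any registration or template.
It emulates none of: anatomical shape, partial-volume mixing, bias fields,
or Rician noise physics — passing tests show algorithmic correctness on
well-posed class structure, not clinical-grade performance on real scans.

BOLD series are simulated per voxel as
`baseline + A·sin(2πft + φ) + N(0, σ)` inside a labelled ROI and
`baseline + N(0, σ)` elsewhere, with repetition time TR stored with the
series (default scenarios use TR = 2 s). Frequencies above Nyquist
(1/(2·TR)) are rejected with an explicit error. Motion traces come in two
scenarios, enough to exercise the QC rule: `clean` (all zeros) and `spike`
(one volume with a 5 mm translation). The test scenarios inject 0.05 Hz
oscillations — inside the standard 0.01–0.08 Hz band — over 240 volumes at
TR = 2 s, against an out-of-band 0.15 Hz control.

## ALFF, mALFF, zALFF

Preprocessing follows the standard resting-state recipe at the level a
pre-aligned phantom needs: the first 15 volumes are dropped (unstable
initial signal); a subject whose motion trace shows any volume translating
more than 3 mm or rotating more than 3° is excluded outright (strict
inequality: a volume at exactly the limit passes). Whole-subject exclusion,
not volume scrubbing, is the implemented policy. Slice timing, realignment
estimation, spatial normalisation and smoothing are out of scope because
phantoms are generated aligned. Nuisance residualisation (mean signal,
motion, CSF/WM regressors) is available as optional OLS residualisation but
defaults to off for phantoms.

Each voxel series is linearly detrended and transformed with a real FFT;
the one-sided amplitude spectrum is `2·|X(f)|/T`. ALFF is the **mean** of
these amplitudes over frequency bins in 0.01–0.08 Hz (inclusive band
edges); a summed-power variant is available. The mean-over-bins convention
makes ALFF scale linearly with signal amplitude and satisfy an exact
sub-band averaging identity, both asserted in tests. Note the independent
DFT oracle used in tests must apply the same linear detrend: a least-squares
line fitted to a finite sinusoid has a small nonzero slope, so detrending
perturbs the spectrum slightly even for integer-cycle signals.

mALFF divides each in-mask voxel by the in-mask mean ALFF (in-mask mean
becomes 1). zALFF is `(ALFF − mean) / SD` with mean and SD taken over the
brain mask, population SD (`ddof=0`) by default and configurable; the map
stores the mean and SD used. By construction the in-mask mean is 0 and SD
is 1 to 1e-9, and zALFF is invariant to global rescaling of the raw series.
SD over the mask (not the full grid) is the implemented reading. A constant
ALFF map has zero SD and is rejected rather than silently producing zeros.

## Group statistics and ROC

ROI means are extracted from a zALFF map and an integer label volume; an
ROI with no in-mask voxels is flagged (NaN, zero count), never imputed.
Group comparison is Welch's t by default (pooled available), with a
summaries-only variant for printed mean ± SD tables; 2×2 count tables get
Pearson's chi-square (df = 1) without continuity correction by default.
p-values are reported uncorrected by default — the implemented inference is
at the level of a handful of named ROIs — with Bonferroni/FDR adjustments
available.

ROC curves are empirical over all distinct thresholds (cases-positive rule
`score ≥ threshold`, or `≤` when the automatic direction chooser flips a
low-scoring case group so AUC ≥ 0.5; the choice is recorded). AUC is
trapezoidal, which for an empirical ROC equals the Mann–Whitney proportion
of correctly ordered case–control pairs with ties counted half — asserted
against exhaustive enumeration. The reported cut-off maximises the Youden
index (sensitivity + specificity − 1), ties broken toward the lowest
threshold. A parameter-recovery test simulates two normal groups separated
by effect size d = 1.2 at n = 50/50 and checks the mean empirical AUC over
200 replicates against the closed form Φ(d/√2) ≈ 0.802.

## Pipeline and formats

Volumes are NIfTI-1, identity RAS+ affine, time axis last, TR in the
time-axis `pixdim`; motion traces are 6-column TSV (mm, degrees); configs,
reports and manifests are JSON. Every pipeline artifact carries a sidecar
with parameters, seed and software version. The pipeline writes
uncompressed `.nii` so that artifact SHA-256 hashes are bit-stable across
reruns (gzip embeds a timestamp); the I/O layer reads and writes `.nii.gz`
fine when asked.

## Problem sizes

The shipped study conditions are 64×64 phantoms (4 096 pixels, three
classes), 20-seed initialisation comparisons, 240-volume BOLD series at
TR = 2 s, and 200-replicate ROC simulations at n = 50/50. These sizes give
law-of-large-numbers headroom on every asserted tolerance (e.g.
class-conditional means within 3 units at sd 5 with ≥ 360 pixels per class)
while keeping the whole suite and the acceptance script each under a
minute of compute, apart from the initialisation comparison which dominates
at roughly fifteen seconds.

## Known limitations

- Intensity-only clustering cannot separate classes with overlapping
  intensity distributions; no spatial regularisation or kernelised variant
  is provided.
- The phantom's geometric simplicity means segmentation scores here are an
  upper bound on what identical settings achieve on real anatomy.
- ALFF is computed by spectral masking of the detrended periodogram, not by
  time-domain bandpass filtering; the two agree for the amplitude summary
  used here but differ if the filtered series itself is wanted.
- The fALFF variant (band amplitude relative to full-spectrum amplitude) is
  not implemented.
- Voxel-wise group inference with cluster correction is out of scope; group
  statistics operate on ROI means.
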