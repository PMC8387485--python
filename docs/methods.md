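# Methods

`ensquant` quantifies the architecture of the enteric nervous system (ENS)
from confocal z-stacks of wholemount gut preparations labelled with a
pan-neuronal fibre marker (TuJ1-like) or a soma marker (HuC/D-like).  This
note documents the models, parameters and numerical choices behind each
stage, and what the synthetic benchmarks do and do not establish.

## The analysis chain

Each field is a calibrated z-stack (default 21 optical sections of
512×512 px, 1 µm z-step, 0.6 µm/px laterally).  The per-field chain is:

1. **Pre-filter** — slice-wise median (radius 2 px) then Gaussian (σ 1 px),
   reflective borders.  A despeckle-plus-smooth chain is the standard
   pragmatic choice for shot-noise-limited confocal data; both steps and
   their sizes are configurable, and `method="none"` bypasses filtering for
   already-clean data.
2. **Maximum-intensity z-projection** to a single frame.  Maximum (rather
   than sum or mean) best preserves thin fibres that wander through z.
3. **Segmentation** — either a WEKA-style trainable pixel classifier
   (random forest, 200 trees, unlimited depth, class-balanced, fixed seed,
   over a multiscale feature bank: Gaussian smoothing,
   Gaussian-derivative gradient magnitude, Laplacian of Gaussian, Hessian
   eigenvalues, difference of Gaussians, structure-tensor eigenvalues at
   σ ∈ {1, 2, 4, 8} px) or a non-learned Otsu auto-threshold.  A classifier
   is trained once per dataset from sparse annotations and applied to all
   fields, never retrained per field.
4. **Density and interganglionic areas** — density is the foreground
   percentage of the mask.  The background (marker-negative space, a proxy
   for interganglionic area) is decomposed into 4-connected components
   (the dual of 8-connected foreground); components touching the border
   are included by default.  Areas are binned with integer-inclusive edges
   0–50 / 51–200 / 201–400 / 401–600 / 601–800 / 801–1000 / >1000 px².
5. **Skeleton census** — the mask is thinned to a 1-px centreline and
   decomposed into a graph: pixels with one 8-neighbour are endpoints,
   two are branch interior ("slab"), three or more are junction
   candidates; touching candidates merge into one junction node so a thick
   crossing is not over-counted.  Branch length is the weighted step
   metric (1, √2, √3 per axis/diagonal/3D-diagonal move).  Three
   configurable graph clean-ups follow:
   * *junction contraction* (default ≤ 3 px): junction pairs linked by a
     stub branch of roughly the fibre width merge into one higher-degree
     junction — thinning splits an X-crossing of thick tubes into two
     nearby Y-junctions, and contraction restores the quadruple point;
   * *spur pruning* (default < 4 px): terminal twigs far shorter than any
     real fibre are thinning artefacts of rough mask boundaries;
   * *small-component filtering* (default < 12 px total length):
     free-standing specks — noise islands, or the dot a lone soma cluster
     thins down to — are not fibre branches.
   Junctions are reported as triple (degree 3), quadruple (degree 4) and
   higher; branches as count, total and mean length.  Degenerate cases are
   well defined: an isolated pixel is a degree-0 node, an isolated cycle
   becomes one anchor node carrying a self-loop branch (self-loops count
   twice in the degree, preserving the handshake lemma).
6. **3D ridge detection** (separate, additionally reported mode) — ridge
   strength is the negated middle Hessian eigenvalue at scale σ
   (default 1.5 px), kept by hysteresis thresholding at 8% / 20% of the
   peak response and thinned to a 1-voxel 3D skeleton.  Because branches
   that cross in different z-planes stay separate in 3D, this census
   includes z-plane branching that the 2D projection census merges.
7. **Orientation and coherency** — the 2×2 structure tensor (gradient σ
   1 px, window σ 4 px) gives per-pixel orientation (axial, (−90°, +90°],
   measured from the image x-axis with y pointing down) and coherency
   (λ₁−λ₂)/(λ₁+λ₂).  The field-level coherency and orientation come from
   the energy-weighted mean tensor — summing tensors lets randomly
   oriented texture cancel (isotropic fields → coherency ≈ 0) while a
   consistently oriented field keeps coherency ≈ 1; the angle of the mean
   tensor is exactly the (λ₁−λ₂)-weighted doubled-angle circular mean.
   The naive arithmetic mean of per-pixel angles is reported alongside
   because it carries a known wrap artefact: fibres pointing "up" and
   "down" register at +90° and −90° and cancel, so the naive mean of a
   vertical field collapses toward 0 and is unstable across noise
   realizations while the axial mean stays pinned to the ±90° axis.  Both
   coherency scales (0–1 and ×100 "%") are emitted.
8. **Soma counting** — Otsu threshold, 8-connected components, per-particle
   area (µm², via pixel_size²) and circularity 4πA/P² with the Crofton
   perimeter estimate, clamped to [0, 1]; the default filter accepts
   10 µm²–∞ and circularity 0.00–1.00.  Touching somata are not split by
   default (a distance-transform watershed is available but off).  Counts
   are averaged per subject; group statistics run over subject means.
9. **Cohort statistics** — Welch's unequal-variance t-test
   (Welch–Satterthwaite df, two-sided) per metric, significance stars at
   0.05/0.01/0.001/0.0001, no multiple-testing correction by default
   (Holm available).  The statistical unit defaults to the subject
   (fields are averaged per animal first); a per-field mode exists.
   Relative expression uses ΔΔCT: per-sample ΔCT = CT_target − CT_reference,
   baselined to the control-group mean ΔCT; fold = 2^(−ΔΔCT); the group
   point estimate 2^(−mean ΔΔCT) is exactly 1 for the control group by
   construction; not-detected targets report fold 0.00 with a flag; group
   significance is tested on ΔCT values, not folds.

## The synthetic-scene generator

The generator produces confocal-like stacks with exact ground truth so
every stage above can be validated end to end.

**Geometry.**  Ganglia sit on a jittered rows×cols lattice; each pair of
lattice neighbours is connected with probability `connective_prob`
(optionally biased toward a preferred axis by `anisotropy`), and each
connective sprouts a Poisson(`extra_branch_rate`) number of secondary
fibres.  A sprout splits its parent connective at a degree-3 way-point and
ends free; candidate sprouts that would pass within two fibre-widths of
other structure are rejected (bounded retries), so the drawn geometry is
the true topology — no accidental crossings.  Fibres render as tubes
(distance-to-polyline ≤ width/2, via a Euclidean distance transform with
the z-step/pixel-size anisotropy), ganglia as discs; the union of supports
is the ground-truth mask.  Rendering applies Gaussian PSF blur (lateral
σ 1 px, axial σ 0.75 slices), Poisson shot noise scaled by `photon_scale`
(default 200 photons at peak), additive Gaussian read noise (σ 2) and a
constant background (10).  `photon_scale=inf` with zero σs gives the exact
noiseless limit.

**Ground truth.**  Junction/branch counts are *skeleton-equivalent*:
degree-2 way-points of the geometric graph are smoothed out (a centreline
census cannot see them) and a component reduced to a pure cycle counts as
one self-loop branch.  Density truth is the foreground fraction of the
projected support, recomputable by direct counting.

**Defaults as study conditions.**  The full-scale control spec (5×5
lattice, ganglion radius 16 px, fibre width 11 px, connective probability
0.85, sprout rate 2.5) yields ~28.5% projected density at 512×512; the
knockout-like variant (`NetworkSpec.dense_variant()`: fully connected,
sprout rate 4.5, width 15 px) yields ~37% — the same band and contrast
as wholemount colon fields.  The scaled 128×128 benchmark pair
(`control_small` / `variant_small`) reproduces that density ratio (~1.35)
while also contrasting junction and branch-length truth, which is what a
phenotype with denser, more branched fibres looks like at that scale.
The lateral calibration default of 0.6 µm/px makes a 512-px field
~307 µm wide, so ~150 non-overlapping 6-µm-radius somata fit per field —
consistent with myenteric HuC/D counts at this magnification.  Soma
scenes place discs with a minimum centre distance of 2.5× the radius;
optional "debris" blobs are constrained below the 10 µm² particle filter.

**Randomness.**  All randomness flows from one integer seed through named
substreams (scene, subject, field indices), so any single scene is
reproducible in isolation and cohorts are bit-reproducible.

**What the generator does not emulate** — and hence what green tests do
not show about real tissue: vendor PSF models, vignetting and stitching
artefacts, autofluorescence gradients, fibre curvature and calibre
variation along a bundle, somata overlapping in z, and intensity
heterogeneity between neurons.  Passing benchmarks demonstrate that the
measurement chain is correct and well calibrated on images whose
structure is known; they do not certify segmentation accuracy on any
particular real dataset.

## Subject-level variation and benchmark sizes

Cohorts draw a log-normal multiplier (σ = 0.05) per subject on
`connective_prob`, so fields within an animal are correlated and the
animal is the honest statistical unit.  The benchmark battery uses: 10
noiseless 200×200 scenes (exact recovery), 10 default-SNR 256×256 scenes
(tolerance recovery), 100 replicate 6-vs-6 cohorts of 5 fields at 128×128
(detection power), and 400 null cohorts of identical specs at 64×64 with
2 fields per subject (type-I calibration) — sizes chosen so the whole
battery runs on a laptop-class machine while keeping the binomial noise
on the estimated rates well inside the asserted bands.

## Known limitations

* The 2D census runs on z-projections, so branches crossing in different
  z-planes merge into spurious junctions there; the 3D ridge mode exists
  precisely for that case but is slower and noisier at low SNR.
* Junction contraction and spur pruning thresholds are expressed in
  pixels and should scale with fibre width if the imaging scale changes.
* The classifier is intensity-sensitive (no feature normalization, as in
  the standard WEKA workflow): a model trained at one exposure degrades
  on images an order of magnitude dimmer.
* Circularity uses the Crofton perimeter; other perimeter estimators
  shift the circularity of small particles noticeably.
* Orientation is a single axial summary per field; full orientation
  distributions (e.g. von Mises mixtures) are out of scope.
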