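# Methods

This note documents the models and procedures implemented in `handvein`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open. Sizes and defaults
quoted here are the package's own choices; every empirical statement is
computed by the test suite or `scripts/acceptance.py`.

## Acquisition geometry (optics)

The camera is modeled as a thin lens with focal length `f`, f-number
`N` and circle of confusion `c`. Hyperfocal distance and the
depth-of-field limits at focus distance `s` follow the standard
relations

    H  = f²/(Nc) + f
    Dn = s(H−f)/(H+s−2f)
    Df = s(H−f)/(H−s)   (infinite for s ≥ H, reported with a flag)

Angles of view are `2·atan(d/2f)` per sensor extent; the field of view
at a working distance uses first-order pinhole scaling. The sensor is
mounted in portrait orientation, so the *short* physical side maps to
the horizontal image axis. The diagonal uses the active-area diagonal
`√(w²+h²)` (≈ 6.14 mm for the 4.9×3.7 mm reference sensor), not the
nominal type designation, because that is what the projection geometry
actually sees. Computations are double precision; rounding happens only
at the presentation layer.

## Frame synchronization (claps)

Sensors that free-run on a trigger line can miss a small number of
start-of-capture pulses. The schedule therefore brackets the payload
with a 10-frame binary clap pattern on the illumination, preceded by 10
blank frames: `blanks ⊕ code ⊕ payload ⊕ code`. Recovery: the per-frame
brightness (mean over the central 50% crop, robust to vignetting) is
binarized at the midpoint of a two-cluster 1-D k-means split — which
makes detection exactly invariant to affine brightness changes — and
both code positions are located by exact ±1 correlation. The inter-clap
distance certifies that no payload frame was lost; only head-frame
drops are tolerated. The default code `1010110011` is non-constant and
has no period-1 self-similarity; both claps use the same code.

## Stereo depth

Calibration consumes a per-camera 3×3 projection matrix, a
5-coefficient radial/tangential distortion vector, and the right
camera's rotation/translation relative to the left camera (the
reference frame). Rectification constructs a shared orientation whose
x-axis lies along the baseline (the rotation is applied analytically;
each output pixel is mapped back through the inverse rectifying
rotation, distorted, and sampled bilinearly), after which a 3-D point
projects to the same row in both views and `d = x − x′ = Bf/z ≥ 0`.

Disparity search is ZNCC block matching (default 9×9 support, search
range 0–64 px) with winner-take-all selection, parabola sub-pixel
refinement around the cost peak, and three validity gates: minimum peak
correlation (0.5), minimum local texture, and a left-right consistency
check (≤ 1 px), which empirically removes the gross outliers that
otherwise accumulate along the half-occluded left border. Semi-global
cost aggregation is deliberately not reimplemented; the matcher is
specified and tested at the contract level (median |d−d_true| ≤ 1 px on
synthetic dot scenes, slanted-plane slope within 5%). View alignment
back-projects each reference pixel through its depth, transforms into
the source camera and samples bilinearly; missing depth produces
counted NaN holes, never silent zeros.

## Photometric stereo

Four frames lit from the corners of the LED frame are modeled as
Lambertian under distant isotropic sources: `I = L·N` per pixel, solved
by `G = pinv(L)·I`, `albedo = ‖G‖`, `N = G/‖G‖`. Flat-field division by
a constant-albedo reference plane (one per source) cancels the
inverse-square falloff; the assumption is that the hand is nearly
planar and close to the reference plane. Shadowed pixels (intensity
below 2% of a frame's 99th percentile) and near-zero-albedo pixels are
masked rather than solved. Depth from normals (Fourier integration with
the mean gradient restored as an explicit ramp) is provided as a
utility only.

## Finger segmentation

Foreground: Otsu threshold plus morphological opening with a disk
(radius 5), which removes specks smaller than the element. Fingers are
peeled off tallest-first: the topmost foreground row marks a tip, the
run containing it is traced downward row by row (8-connected, the span
allowed to grow one pixel per side), and tracing stops when the run
width exceeds `width_stop_factor = 1.8` times the running median width
— the palm junction — with a 12-row warm-up before the stop can fire.
The traced region is erased (plus sub-200-px crumbs, which otherwise
masquerade as fingertips) and the procedure repeats until four fingers
are found. Anatomical labels come from the centroid x-order; with the
palm toward the camera the right hand reads index→little left-to-right
and the left hand the reverse (configurable, since palm orientation is
a property of the presentation protocol). Fewer than four fingers is
not an error but marks the sample incomplete — three fingers cannot be
labeled unambiguously — and incomplete samples are excluded from
recognition experiments.

Rotation normalization fits a least-squares line through the per-row
mask midpoints (rows below 80% of the median width are excluded — the
tip/base corner rows otherwise bias the fit by ~0.7° at 10° tilt) and
rotates image and mask about the mask centroid by the negative of the
axis angle. The normalized finger is then re-cropped around its
straightened axis using the median midline and median row width; this
step matters for matching, because raw trace boxes occasionally include
palm-flare rows that shift the crop laterally by 10–20 px, which is
outside the matcher's default translation search.

## Vein enhancement and maximum-curvature templates

The enhancement interface is pluggable (learned enhancers can be
registered); the default classical enhancer (1) divides out a global
illumination field fitted as a low-order 2-D polynomial over the mask —
division, not subtraction, because the field is multiplicative, and a
polynomial because a finite smoothing kernel cannot track a ramp near
the crop boundary — then (2) subtracts a Gaussian background (σ = 20 px)
and normalizes by the local standard deviation at the same scale.

Maximum-curvature extraction scans intensity profiles, smooths them
(Gaussian, σ = 2 px), and computes `κ = P″/(1+P′²)^{3/2}` with central
differences. Veins are intensity valleys, i.e. maximal runs of positive
profile curvature; each run deposits `κ_max × run width` at its
curvature maximum — wide deep valleys score highest, and the maximum
sits on the vein centerline. A connectivity filter adds
`min(max of 2 neighbours ahead, max of 2 behind)` along the scan
direction, reinforcing aligned responses. Scores are accumulated over
the configured directions and binarized at the median of the strictly
positive scores (with a 1e-9 relative tolerance so floating-point ties
land together). The image is standardized inside the mask first, making
the template exactly invariant to gain/offset; invalid pixels are
filled with the nearest valid value along each scan line, making
background padding exactly equivalent to the array edge (translation
covariance).

**Scan directions.** The default is transverse-only: veins run roughly
along the finger, so transverse profiles present their sharpest valley
cross-sections. The classical four-direction variant of this feature
family is available via `MCParams.directions`, but measured against the
generator's ground truth the longitudinal scan — which runs *along* the
veins — marks mostly noise (mean active-pixel distance to the true
centerline 5.9 px with four directions vs 0.7 px transverse-only), so
it is not the default. The mask is eroded by 8 px before scoring;
silhouette-edge and tip-cap shading otherwise produce spurious
curvature responses.

## Matching

Binary templates are compared by cross-correlation computed in the
frequency domain, rounded to exact integer overlap counts (verified
against an exhaustive spatial-domain search, bundled as
`match_templates_bruteforce`). The search window is ±20% of the mean
template extent per axis; the score is peak overlap divided by the
smaller active count, which bounds it to [0, 1] and sends
identical templates to 1. Ties are broken toward the smallest
translation. Rotation is not searched — normalization is assumed to
have removed it.

## Protocols, evaluation and fusion

One sample per identity (the lowest sample index — a deterministic
stand-in for an arbitrary choice) is enrolled; every remaining sample
is a probe compared once against its own identity and against three
zero-effort impostors drawn without replacement with a recorded seed.
`FMR` is the percentage of impostor comparisons with score ≥ threshold,
`FNMR` the percentage of genuine comparisons below it, and
`HTER = (FMR+FNMR)/2` (an exact invariant of every result object).
The operating threshold is the smallest value on the sorted
dev-impostor grid whose dev FMR does not exceed the target (default
0.1%), transferred unchanged to the eval split.

Fusion represents each hand probe by its (index, middle, ring) score
vector and fits an RBF-kernel SVM (scikit-learn defaults,
class-balanced) on the dev genuine/impostor vectors; its signed
decision values are the classification scores. One refinement to the
threshold rule: when the dev decision values are separable, every
threshold between the highest impostor and the lowest genuine value
realizes the same dev FMR/FNMR, and the SVM's values saturate at the
margin edges (±1), so the smallest admissible threshold sits exactly on
the impostor-side margin and transfers poorly. The fusion threshold is
therefore placed at the midpoint of that equivalent interval (the
maximum-margin choice); dev rates are unchanged by construction, and
measured eval FMR drops from several percent to zero on the default
benchmark. Raw single-finger thresholds keep the plain grid rule.

## Synthetic data: what it emulates, and what it does not

An identity fixes four finger silhouettes (rounded, mildly tapered
strips with elliptical tip caps joined by a palm) and one vein tree per
finger: a trunk random-walks from base to tip with 2–7 side branches,
widths 2–4.6 px tapering distally, all confined to the silhouette.
A sample render applies per-sample jitter — whole-hand rotation
(±3°), translation (±8 px), intensity gain (±10%), a linear
illumination gradient (±15%) — then draws veins as Gaussian-profile
valleys at 25% contrast and adds Gaussian noise (σ = 1% of full scale,
a realistic shot/read-noise level for 10-bit capture at short
integration times), quantized to the 10-bit range. Ground truth
(silhouette, per-finger masks and labels, analytic vein centerlines,
applied pose) accompanies every render; generators are pure functions
of their seeds. The default benchmark is 20 subjects × 2 hands ×
5 samples (sample seeds 0–4), sized to run in about a minute on one
core.

The stereo generator projects a random dot texture through a known
depth map (disparity solved as a fixed point so the warp is consistent
with `d = Bf/z`); the photometric generator renders `albedo·max(0,L·N)`
with an optional point-source falloff baked into frames and flat-field
references alike.

What the generator does **not** model: skin texture and speckle,
wavelength-dependent penetration (850 vs 950 nm are labels, not
physics), camera-specific differences, specularities, shadows between
fingers, thumbs, and population-scale diversity of hand geometry.
Consequently the synthetic benchmark is a *correctness and sensitivity*
harness: passing it shows the pipeline recovers what it is designed to
recover under controlled degradation, not that any particular error
rate would be achieved on real captures — absolute error rates on real
data are expected to be substantially worse and protocol-dependent.
Identity information in the renders lives almost entirely in the vein
topology, which is exactly what the features are built to capture, so
separations are optimistic by construction.

## Numerical choices and degenerate inputs

- Disparity ≤ 0 maps to an undefined-depth flag (NaN), never an
  exception mid-map; untextured scenes yield mostly-invalid maps with a
  warning.
- Rank-deficient light rigs raise a solvability error naming the
  unobservable direction; ≥1% dead flat-field pixels warn and mask.
- Constant images are rejected by Otsu masking (empty-mask error) but
  `extract_fingers` converts that to an empty, incomplete result.
- A flat profile everywhere raises an empty-template error (templates
  must have ≥1 and ≤30% active pixels).
- All rates are computed at full precision and rounded to two decimals
  only for presentation.

## Known limitations

- The block matcher is O(D·H·W) dense ZNCC; it is sized for the
  synthetic scenes and VGA-class frames, not real-time use.
- Midline-based rotation normalization assumes a roughly straight
  finger; strongly flexed fingers would need a curved-axis model.
- The enhancement baseline is classical; a learned enhancer can be
  registered under the same interface but none ships with the package.
- Fusion uses raw finger scores (a normalization switch exists); score
  calibration to likelihood ratios is out of scope.
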