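# Methods

## Problem and model

`tubershape` grades a single produce item (the motivating crop is the potato
tuber) photographed on a dark board as **regular** or **irregular** in shape.
The underlying model is geometric: a regular tuber is approximately
elliptical, so the distance between its silhouette and the best-fitting
ellipse is a direct measure of irregularity. The pipeline is:

1. **Preprocess** the RGB capture to a clean binary silhouette at the fixed
   working extents 614×410 (width × height): area-interpolation resize,
   weighted-average graying (0.299/0.587/0.114), Otsu binarisation,
   morphological open/close with a disc, majority (median) edge smoothing,
   largest-component selection, centroid centring.
2. **Extract the contour** Q by Moore-neighbour border following on the mask.
3. **Fit an ellipse** to the contour points by direct constrained least
   squares and sample its boundary into the point set P.
4. **Score** the contour against the ellipse with four features:
   perimeter ratio `C = C_p / C_e`, area ratio `A = A_p / A_e`,
   bidirectional Hausdorff distance
   `H(P,Q) = max(h(P,Q), h(Q,P))`, `h(P,Q) = max_p min_q ||p − q||_2`,
   and the IoU of the filled contour (truth region) and the filled ellipse
   (prediction region).
5. **Threshold**: `H ≤ 21 px → regular`, `H > 21 → irregular`; or
   `IoU > 0.925 → regular`, `IoU ≤ 0.925 → irregular`. The ratios C and A
   are computed and reported but do not carry a decision rule: on real
   produce their regular/irregular distributions overlap, so no single
   cut separates the classes.

For multi-view captures of one object, per-view features are combined with
the worst-case rule — maximum H, minimum IoU — before thresholding, so an
irregularity visible from any single pose decides the grade.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| working extents | 614×410 | px | all pixel-valued thresholds are defined here; the pipeline forces this size |
| HD threshold | 21 | px | separates regular from irregular silhouettes at working extents; scales linearly with resolution (see below) |
| IoU threshold | 0.925 | — | dimensionless, resolution-independent |
| morphological disc radius | 2 | px | removes segmentation specks/holes below ~5 px without eating lobes |
| median window | 5 | px | smooths staircase edges; changes blob area < 5% for blobs ≥ 25 px across |
| ellipse sample spacing | ≤ 1 | px | makes the discretisation error of H at most ~1 px, far below the 21 px threshold |

Boundary semantics are exact: H equal to the threshold grades regular, IoU
equal to the threshold grades irregular.

The HD threshold is a length in pixels. Scaling the canvas and the object by
a factor *s* scales H by *s* (verified to ±2 px raster error in the tests),
so the value 21 is valid **only** at 614×410; the preprocessing stage
enforces those extents rather than trusting the caller. Thresholds also
depend on the crop variety; they are config values, not constants of nature.

## Numerical choices

* **Ellipse fit.** Fitzgibbon's direct least-squares conic fit with the
  ellipse constraint `4AC − B² = 1`, in the Halir–Flusser block formulation,
  on mean-centred coordinates. The constraint guarantees an ellipse for any
  input in general position; exact-ellipse inputs are recovered to ~1e−9.
  Hough-transform and edge-tracing fitters are out of scope (slower, and the
  noise the algebraic fit is sensitive to is already removed upstream by the
  morphological and median filters). No RANSAC.
* **Conic → geometric conversion** goes through the eigendecomposition of
  the quadratic-form matrix (semi-axes `sqrt(−Q(centre)/λ_i)`), which is
  robust for all rotations including the circular limit, where the angle is
  arbitrary and reported modulo the eigenvector convention.
* **Hausdorff distance** is computed from exact pairwise L2 distances in
  blocks (no spatial index); it is bit-identical to the brute-force double
  loop, which the tests assert.
* **Perimeters.** `polygon_perimeter` is the plain edge-length sum of the
  polygon. Inside `compute_features` the contour perimeter is measured on
  the chain resampled every 4 px because the raw 8-connected pixel chain
  overestimates a smooth boundary's length by ~5% (digitisation staircase
  bias); with resampling the perimeter ratio of an exact ellipse blob is
  1.00–1.01. The ellipse perimeter uses Ramanujan's second approximation
  (relative error < 1e−4 up to aspect ratio 5).
* **Rasterisation.** Contour regions are filled with an even-odd scanline
  fill plus the drawn boundary (a 10×10 axis-aligned square covers exactly
  11×11 lattice pixels); ellipse regions are pixels whose centres satisfy
  the implicit inequality. Inside `compute_features` the fitted ellipse is
  rasterised without a fits-in-canvas check: a fit may legitimately overhang
  the canvas for objects near the border, and off-canvas area contributes no
  pixels to either region.
* **Degenerate inputs** raise typed exceptions (no contrast, empty mask,
  object too large to centre, collinear fit input, non-ellipse conic). The
  CLI maps any failure to the label `undetermined` and exit code 2; exit 0
  is regular, 1 irregular, for sorter-line integration.
* **Contour ordering** is canonical — counter-clockwise in (x right, y down)
  coordinates, starting at the topmost-then-leftmost boundary pixel — so
  contour-valued results are byte-reproducible.
* A Canny-based contour mode (thresholds 50/150 on the 0–255 scale) is kept
  behind a flag for fidelity to edge-detector-based implementations; on a
  clean binary mask it yields the same boundary to within ~1 px, and the
  default border following needs no tuning parameters.

## Synthetic data: what it emulates, what it does not

No public capture set with irregular-shape labels exists, so the generator
is the test bed. Shapes are star-convex radial perturbations of an ellipse:

    r(φ) = r_e(φ) · (1 + α·cos(kφ + ψ)) + jitter(φ)

with `r_e` the polar radius of the base ellipse, `k` the lobe count, `α` the
lobe amplitude (fraction of the local radius) and `jitter` a smooth random
harmonic perturbation (orders 8–15, RMS given in pixels) standing in for
natural surface roughness. Photometry emulates the capture rig: object
pixels at luma ≈ 192 (yellow-brown), background ≈ 30, Gaussian noise σ = 8 —
strongly bimodal so Otsu behaves as designed. Everything is deterministic
given the seed.

Dataset sampling ranges: semi-major axis a ∈ [80, 140] px, aspect
b/a ∈ [0.55, 0.95], pose uniform, centre within ±12 px of the canvas centre.
Regular class: α = 0, jitter 0.5 px. Irregular class: k ∈ {3,…,6},
α ∈ [0.25, 0.45] (capped so the shape fits the canvas), jitter 1 px. The
amplitude range was calibrated once against the fixed thresholds and frozen:
it produces Hausdorff distances of roughly 18–65 px and IoU of 0.55–0.76 for
the irregular class, against H ≈ 1–3 px and IoU ≥ 0.98 for the regular
class — the same comfortable separation the method exhibits on real graded
produce. A small fraction of low-amplitude, small, thin shapes fall just
under the 21 px Hausdorff threshold; they are genuine borderline cases and
are left in.

What the generator does **not** emulate: real tuber texture, eyes and
blemishes, soft shadows, specular highlights, perspective foreshortening,
multi-object scenes, and the real-world severity distribution of
irregularity. Passing the synthetic suite therefore demonstrates the
correctness of the geometry and the decision logic under the intended
imaging conditions, not field performance on any particular variety.

## Problem sizes used by the checks

The end-to-end suites grade 50–200 rendered samples per run and the
reproduction script uses the 148-sample split (98 regular + 50 irregular)
that matches the published validation set; Monte-Carlo fit-recovery checks
use 100 seeds at 200 points. These sizes give stable statistics while a full
run of suite plus script stays in the minutes range on one CPU.

## Known limitations

* Thresholds are variety-specific and resolution-specific by construction;
  no learning or per-variety calibration is provided (out of scope).
* One object per frame; the largest connected component wins, everything
  else is discarded.
* Star-convex shapes only in the generator; real silhouettes with deep
  re-entrant folds are representable by the contour machinery but not
  generated.
* The bottom of the object is invisible to a single top-down view; the
  multi-view aggregation rule mitigates but cannot eliminate
  pose-dependent misses.
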