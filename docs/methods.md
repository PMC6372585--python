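# Methods

## The measurement problem

The mesangium is the matrix/cell compartment inside the glomerular capillary
tuft; its volume and its fraction of the tuft, Vv(mes/glom), grade the
severity of diabetic kidney disease. All three measurement routes in this
package start from the same primitive — closed planar contours traced on
parallel sections of known thickness *t* — and differ only in how they turn
areas into volumes. That shared currency (the `Contour`, a simple
counter-clockwise polygon in µm, tagged with compartment and section index)
is what makes the methods directly comparable inside one toolkit.

## Serial-section 3D reconstruction

Sections are assumed to be parallel, uniformly *t* apart, and related only
by in-plane rigid motion (one block, one magnification: no scaling, no
reflection). The contour measured on section *i* represents the slab
`[i·t, (i+1)·t)` and is extruded into a right prism of height *t*; no
surface is interpolated between planes, so a sparse stack looks like stacked
cylinders and converges to the true shape as sections are added. Two
consequences are deliberate:

- **Volume is exact by construction**: the mesh volume equals
  `Σ area × t`, the same quantity the Cavalieri estimator targets, so the
  3D and point-counting estimates are commensurable and the identity is
  testable at 10⁻⁹ relative (it holds to ~10⁻¹⁵ in practice).
- **Surface area is a modeling choice**: the reported value is the
  *external* surface of the prism union — lateral faces (`perimeter × t`)
  plus the exposed parts of the slab-interface caps. Because prisms are
  axis-aligned slabs, the interface overlap is computed exactly with 2D
  polygon booleans; no 3D boolean engine is involved.

Prism caps are triangulated without Steiner points (convex fan, otherwise
ear clipping), so each prism is watertight by construction; disjoint
contours stay separate bodies of one mesh and volumes add.

## Rigid registration

Manual alignment of successive sections on recognizable fixed structures is
replaced by least-squares orthogonal Procrustes on ≥ 2 matched fiducial
points (four is typical): closed-form SVD fit, sign-corrected so the
rotation never reflects. Pairwise fits are composed into a chain with the
**middle section as reference** (shortest worst-case composition path; the
choice is recorded in the alignment JSON). Correspondence is by list order —
automatic fiducial matching is out of scope.

The reported residual is the per-coordinate RMS `sqrt(SS/(2N))`. With
isotropic Gaussian noise σ on one point set, its expectation is
`σ·sqrt(1 − 3/(2N))` — 2N coordinates minus the 3 fitted rigid parameters —
which the validation battery checks by simulation (the sample-mean of the
RMS sits ~5% below the square-root-of-mean closed form by Jensen's
inequality, well inside the 10% check band).

## Segmentation

PAS chemistry stains mesangial matrix magenta over a hematoxylin
counterstain. Camera RGB is converted to optical density per channel
(`OD = −log10((I+1)/256)`), unmixed by least squares against unit stain
vectors (default PAS vector (0.175, 0.972, 0.154) with a standard
hematoxylin vector and an orthogonal residual; both overridable — real-image
users must calibrate their own vectors), and the PAS channel is thresholded.
The threshold defaults to Otsu's criterion computed on tissue pixels over
256 bins (deterministic; manual override available, since historically the
operator thresholded by eye). Cleanup: morphological opening+closing at
0.5 µm radius, hole filling, and a 5 µm² minimum region area — all below
biological scale, all exposed in the stain model. The tuft ("total
glomerular area") is defined operationally as the filled outer boundary of
the 2 µm-closed union of tissue-positive pixels; this definition is written
into output metadata because no standard operational definition exists.
Contours are traced at the 0.5 iso-level with sub-pixel marching squares and
simplified at 0.25 pixel tolerance.

Raising the OD threshold can never increase mesangial area: thresholding,
opening, closing, hole filling and small-region removal are all monotone
operators, so the pipeline is monotone end to end.

## Stereology

`V̂ = t · a_p · ΣP` with `a_p = spacing²` and a systematic uniform random
(SUR) offset drawn from `[0, spacing)²` per replicate — unbiased for the
sectioned object by construction. Points are classified against contours
(boundary hits within 10⁻⁹ µm count ½ by default — the Gundersen
convention; strict and inclusive rules are available) or against binary
masks (a point scores the pixel it falls in). One grid serves all sections
of a stack; its extent is the padded bounding box of the reference
compartment. PSI divides mesangial by tuft hits over either all serial
sections or only the middle one (both modes exist because protocols differ;
the mode is written into outputs). Line-intercept length sampling is not
implemented — the point-counting reading of the protocol is the one
realized. Planimetry converts the mean profile area to volume by extrusion
(default, `t_equiv` = section thickness) or Weibel–Gomez
(`V = (1.38/1.1)·Ā^{3/2}`); the model is always recorded.

## Phantom generator

The phantom emulates the acquisition this toolkit targets: an ellipsoidal
tuft, a mesangial compartment built as the level set of a sum of isotropic
Gaussian blobs at Poisson-disc-sampled centers (lobulated, connected regions
with a single threshold scalar), the threshold bisected (≤ 60 steps) until
the realized voxel Vv is within 0.01 of target. Sections of thickness *t*
are taken about the tuft mid-plane; each slab's mid-plane label mask is
rendered to RGB through the same Beer–Lambert model the segmentation module
inverts (mesangium PAS 0.90 / hematoxylin 0.25; remaining tuft 0.10 / 0.45;
background white), degraded with Gaussian sensor noise, rigidly perturbed
(the perturbation is recorded), and stamped with four 0.5 µm fiducial dots
on a ring outside the tuft. All randomness flows from the spec seed;
identical specs are bit-identical. Cohorts draw per-phantom target Vv from
truncated normals at the preset group levels (normo 0.47 ± 0.15, micro
0.53 ± 0.09, macro 0.76 ± 0.08) with child seeds `seed + index`.

Defaults: 6 sections × 1 µm at 0.25 µm pixels with ~2 µm misalignment — the
sectioning geometry of the emulated protocol — on a 40×36×32 µm semi-axis
tuft at 0.25 µm voxels (4× finer than the section thickness, so the oracle's
voxelization error is far below estimator error). A full-size glomerulus
(~100 µm radius) at that voxel pitch would be ~10⁹ voxels; the scaled-down
tuft preserves every geometric relationship the estimators are sensitive to.
Validation experiments state their own (smaller, full-depth) phantom sizes
in `glomorph/validation.py`.

What the phantom does **not** emulate: capillary lumina and nuclei inside
the tuft, podocytes, staining heterogeneity, section compression/tears, or
TEM-resolution texture. Passing tests therefore demonstrate estimator
correctness under idealized optics and chemistry — not robustness to real
histology artifacts, where stain calibration and fiducial choice remain the
user's responsibility.

## Method comparison statistics

One-way within-subject (repeated-measures) ANOVA by the standard
decomposition `SS_total = SS_method + SS_subject + SS_error`, with
`F(k−1, (k−1)(n−1))` and **no sphericity correction by default** (matching
how such comparisons are conventionally reported; the correction can be
requested). Zero error variance is flagged as infinite F rather than hidden.
Post-hoc: paired t-tests per method pair with percent differences
(`100·(mean_B − mean_A)/mean_A`), raw and Bonferroni-adjusted p-values (the
adjustment is reported alongside because the convention varies). Units with
any missing method are dropped listwise with a logged count. Pearson
correlations require ≥ 3 complete units and refuse zero-variance columns.
Group comparisons use Welch's t for two groups, one-way ANOVA for more.
Glomeruli are treated as independent units; mixed-effects nesting of
glomeruli within patients is out of scope.

## Numerical choices and degenerate inputs

- Contours with < 3 vertices, zero area, or self-intersections are rejected
  at construction — never silently repaired (segmentation applies its own
  minimum-area filter first).
- Boundary classification tolerance: 10⁻⁹ µm, far below pixel scale.
- Empty images segment to an empty list (not an error); > 50% PAS-positive
  area logs a miscalibration warning but still returns.
- Degenerate stain matrices, empty grids, zero reference counts, zero tuft
  areas, and gaps in the fiducial chain raise specific named errors.
- Percent-difference antisymmetry holds exactly:
  `(1 + pct(A,B)/100)(1 + pct(B,A)/100) = 1`.

## Validation battery and problem sizes

`scripts/acceptance.py` (and `tests/test_acceptance.py`) measure, from
scratch at each run: Cavalieri bias on an r = 20 µm voxel sphere (t = 2 µm,
spacing 2 µm, 500 SUR offsets; |bias| < 1% observed ~0.04%) and the CV
ladder over spacings 1/2/4/8 µm; the extrusion volume identity and
watertightness on 100 random stacks; sphere reconstruction convergence over
5→80 sections; rigid recovery on recorded phantom perturbations (≤ 10⁻⁵ rad,
≤ 10⁻³ µm) and the noisy-residual law (1000 fits, σ = 0.5 µm); pooled
mesangial Dice and end-to-end Vv error on a 20-section rendered phantom;
ANOVA agreement with a brute-force oracle on 100 random tables (≤ 10⁻¹⁰);
the eroded-mask PSI study on 20 phantoms (PSI significantly below 3D, 3D
within 5% of truth); and group ordering over 100 preset cohorts. The whole
battery runs in roughly half a minute on one CPU.

## Known limitations

- The extrusion model cannot capture between-section shape change; with few
  thick sections both the 3D and Cavalieri volumes describe the sectioned
  slab, not the whole glomerulus.
- Surface area depends on the union-of-prisms convention and will
  overestimate smooth biological surfaces (staircase effect).
- Segmentation assumes two dominant stains and a calibrated color model; it
  does not separate mesangial cells from matrix.
- Fiducial-based registration is only as good as the fiducials; no
  intensity-based fallback exists.
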