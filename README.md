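# glomorph

Glomerular morphometry from serial histology sections.

Mesangial expansion — growth of the supporting matrix compartment inside the
glomerular capillary tuft — is a structural hallmark of diabetic kidney
disease, and its quantification (mesangial volume, mesangial/total area
ratio, fractional volume Vv(mes/glom)) is the bread and butter of renal
biopsy morphometry. `glomorph` implements the three measurement routes used
in that field as one tested toolkit:

- **Serial-section 3D reconstruction**: PAS-stained serial sections are
  segmented by color deconvolution, rigidly aligned from matched fiducial
  landmarks, and each traced contour is extruded into a prism of the section
  thickness *t*, so the mesh volume is exactly the Cavalieri sum
  `V = Σᵢⱼ Aᵢⱼ · t` over sections *i* and contours *j*.
- **Cavalieri / PSI point counting**: a systematic uniform random grid of
  pitch *s* scores hits per compartment; the absolute volume estimate is
  `V̂ = t · s² · ΣP` and the mesangial fractional volume is
  `Vv(mes/glom) = ΣP_mes / ΣP_tuft` (boundary hits count ½, the Gundersen
  convention).
- **Planimetry**: direct profile-area measurement of traced outlines, with
  an explicit area→volume model (extrusion by an equivalent thickness, or
  the Weibel–Gomez quasi-sphere rule `V = (β/k)·Ā^{3/2}`, β = 1.38, k = 1.1).

Because real biopsy measurements have no accessible ground truth, the
package ships a **synthetic glomerulus phantom generator**: a voxelized
ellipsoidal tuft containing lobulated mesangial blobs tuned by bisection to
a target Vv, sectioned into slabs, rendered as PAS-like RGB images with
noise, per-section rigid misalignment and embedded fiducial dots. Voxel
counts give exact compartment volumes, so every estimator's bias and
precision can be measured end to end. A repeated-measures comparison module
(within-subject ANOVA, post-hoc paired contrasts with percent differences,
pairwise Pearson correlations, group tests) mirrors how such methods are
compared on patient cohorts.

## Worked example

Generate a phantom, segment and align its rendered sections, and reconstruct:

```bash
glomorph phantom --seed 7 --vv 0.5 --radii 14,12,10 --blobs 8 \
    --voxel-size 0.5 --pixel-size 0.5 --thickness 2.0 --n-sections 8 --out run/p
# -> phantom written to run/p (realized Vv = 0.491)

glomorph segment run/p/section_*.tiff --pixel-size 0.5 --thickness 2.0 \
    --out run/contours.json
python -c "import json,pathlib; d=json.loads(pathlib.Path('run/contours.json').read_text()); \
t=json.loads(pathlib.Path('run/p/truth.json').read_text()); d['fiducials']=t['fiducials']; \
pathlib.Path('run/contours.json').write_text(json.dumps(d))"   # attach fiducials
glomorph align --contours run/contours.json --out run/aligned.json
glomorph reconstruct --contours run/aligned.json --out run/rec
# -> mesangial volume 3458.3 µm³, mes/total ratio 0.520 -> run/rec

glomorph psi --contours run/aligned.json --spacing 2.0 --seed 1 --out run/psi.csv
# -> Vv(mes/glom) = 0.510
```

The reconstructed mes/total ratio (0.520) and the PSI fraction (0.510) both
track the phantom's target Vv of 0.5; `run/p/truth.json` holds the exact
voxel-count volumes they are judged against. The same operations are
available as library functions (`generate_phantom`, `segment_compartments`,
`build_alignment_chain`, `reconstruct_mesh`, `cavalieri_volume`,
`psi_fractional_volume`, `planimetry`, `repeated_measures_anova`).

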