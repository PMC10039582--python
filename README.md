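# femrec

Statistical shape and appearance modelling (SSAM) of the femur with 2D–3D
reconstruction from simulated planar radiographs, including simulated distal
bone defects and clinically used anatomical-angle scoring.

The toolkit covers the full loop:

1. **`femrec.phantom`** — seeded populations of parametric femur-like
   phantoms (fixed-topology surface meshes, Hounsfield-unit voxel volumes
   with a cortical shell and medullary canal, analytic landmarks and angles).
2. **`femrec.ssam`** — model building: rigid ICP alignment, multi-level
   B-spline free-form-deformation correspondence, tetrahedral interiors
   morphed by a harmonic (Laplace) boundary-value solve, nearest-voxel HU
   mapping, and PCA over the joint shape(+appearance) vectors.
3. **`femrec.drr`** — digitally reconstructed radiographs with the linear
   opacity transfer `op = 0.25·HU/1700` and absorption-only compositing;
   perspective (1500 mm source distance) and parallel ray models; sub-pixel
   silhouette contours; distal defect cropping at any fraction of the
   projected bone length.
4. **`femrec.reconstruct`** — recovery of PCA mode weights from one (AP) or
   two (AP+ML) radiographs by bound-constrained L-BFGS-B, run incrementally
   one mode at a time, minimising either the mean contour distance or
   `1 − Pearson r` of the grey values after 2D contour-based alignment.
5. **`femrec.anatomy`** — surface RMSE/Hausdorff after ICP alignment, head
   sphere fit, and six anatomical measures (bow, FAA–FMA, neck,
   diaphyseal–condylar and both version angles) that are rigidly invariant
   and validated against the phantom generator's analytic ground truth.
6. **`femrec.pipeline`** — the leave-one-out defect-level sweep
   (0/10/20/50 %) producing a tidy per-case results table.

## CLI

All commands live under a single entry point:

```bash
femrec phantom --n 40 --seed 42 --spacing 1.0 --out phantoms/
femrec build-model --pop-seed 42 --n 15 --out model.h5
femrec project --model model.h5 --weights w.json --views ap,ml --defect 0.2 --out drrs/
femrec reconstruct --model model.h5 --targets drrs/ --metric contour --views ap_ml --modes 14 --out result.json
femrec evaluate --recon result.stl --truth phantoms/phantom_000.stl --out report.json
femrec run-experiment --config exp.yaml --out sweep/
```

Meshes are written as ASCII STL/PLY, volumes as NIfTI/MetaImage, radiographs
as 16-bit TIFF with a JSON geometry/mask sidecar, models as one HDF5 file,
and experiment output as per-case JSON plus `results.csv`.

## Conventions

Anatomical frame: right-handed, x medial→lateral, y posterior→anterior,
z distal→proximal, millimetres everywhere. AP projections look along −y,
ML along +x; detector rows run proximal→distal. Mode weights are expressed
in standard deviations (`instance = mean + Σ bᵢ√λᵢ eᵢ`).
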