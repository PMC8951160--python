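# ctcloud

Reconstruct labeled 3D point-cloud models from stacks of 2D micro-CT slice
images, export them as Wavefront OBJ vertex files, and analyse their
morphometry and deformation over time. A fully synthetic phantom generator
with exact ground truth makes every pipeline stage testable without scanner
data.

## What it does

* **stack_io** — natural-sort discovery and loading of TIFF/PNG/BMP/JPEG
  slice stacks; physical voxel spacing (`dx`, `dy`, `dz` in µm) is always
  supplied by the operator, never silently inferred; fixed-ratio 16→8 bit
  normalization.
* **segmentation** — inclusive grey-window masks and per-slice edge
  detection. Roberts cross (2×2 diagonal differences) is the primary
  operator, implemented directly; Prewitt, Sobel, LoG, zero-cross, Canny
  and an approximate Canny are available for comparison.
* **reconstruct** — two routes to a point cloud with
  `x = j·dx, y = i·dy, z = k·dz` (slice index `k` is 1-based):
  * *direct*: every voxel passing an optional foreground window;
  * *segmented*: per-slice solid-object boundary (`outer_surface`), edges
    of dark internal features such as pores and cracks
    (`internal_feature`), and solid-boundary pixels adjacent to features
    (`wood_boundary`). The segmented cloud is always far smaller than the
    direct one.
* **obj_io** — vertex-only OBJ write/read with a fixed label→colour scheme
  (blue outer surface, light-blue internal features, green wood boundary,
  grey interior); byte-idempotent round trips.
* **morphometrics** — percent-change / index-100 tables between scan-year
  models, principal-axis bounding dimensions (with a minimal-box fallback
  for degenerate clouds), voxel-count volumes, exact nearest-neighbour
  distance fields, and point-to-point ICP rigid registration.
* **phantom** — synthetic tapered-ellipsoid "wood" solids with planted
  crack slabs and spherical pores, optional bending and shrinkage,
  additive Gaussian noise, and closed-form ground-truth volumes.

## CLI

```sh
# generate a synthetic stack (TIFFs + spec echo + ground truth)
ctcloud phantom --out scratch/stack

# segmented reconstruction with the 110:130 feature window
ctcloud reconstruct --input scratch/stack --mode segmented --window 110:130 \
    --dx 50 --dy 50 --dz 50 --out scratch/model.obj

# edge-detector comparison on one slice (PNG masks + CSV counts)
ctcloud edges --input scratch/stack --slice 30 --out scratch/edges

# dimensions / volume of a model, and deformation between two models
ctcloud morph report scratch/model.obj
ctcloud morph compare new.obj ref.obj --csv distances.csv --icp
```

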