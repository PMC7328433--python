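# tesvox

Volumetric finite-element simulation of transcranial electrical stimulation
(TES), operating directly on labeled voxel grids.

Transcranial electrical stimulation drives a weak current (typically 1–2 mA)
through scalp electrodes; the electric field it produces inside the brain
depends strongly on the conductive anatomy between the electrodes — the
resistive skull, the highly conductive cerebrospinal fluid (CSF) and the
shunting scalp. `tesvox` predicts that field by solving the quasi-static
volume-conduction equation ∇·(σ∇V) = 0 with Neumann current boundary
conditions on a segmented head volume. Instead of building a tetrahedral
surface mesh, every labeled voxel becomes one trilinear hexahedral finite
element, which makes the pipeline fully automatic: any integer-labeled NIfTI
volume (or 4-D tissue-probability volume) goes in, voltage and field volumes
come out.

The pipeline stages, each usable on its own:

* **`tesvox.volumes`** — labeled / probability / field volumes, NIfTI I/O, the
  canonical tissue vocabulary (WM, GM, CSF, skull, scalp, air cavity, gel,
  electrode).
* **`tesvox.touchup`** — post-segmentation repair: mask smoothing, removal of
  disconnected islands, and heuristic sealing of gaps in the GM/CSF/skull
  layers, with an exception mask that protects genuine skull openings (optic
  canal, foramen magnum).
* **`tesvox.electrodes`** — 10-20 / 10-10 / 10-05 positions generated on a
  unit sphere and projected onto the subject's scalp via four fiducials;
  disc, pad and ring electrodes voxelized with a conductive gel layer.
* **`tesvox.fem`** — the voxel-native hexahedral FEM: assembly, current
  boundary conditions, a Jacobi-preconditioned conjugate-gradient solve, and
  element-centered E and J fields. Optionally the mesh is geometry-adapted:
  nodes on tissue interfaces are projected onto caller-supplied smooth
  surfaces, which removes the staircase error at high-contrast boundaries.
* **`tesvox.phantoms` / `tesvox.oracle` / `tesvox.validation`** — synthetic
  phantoms with exactly known geometry, the analytic Legendre-series solution
  for a multilayer sphere, and the end-to-end comparison between the two.
* **`tesvox.metrics`** — field-difference maps, segmentation differences, and
  the prediction-validation statistics (Pearson r, regression slope s).

## Worked example

Simulate a classic C3–anode / C4–cathode montage (1 mA) on a four-layer
sphere phantom:

```bash
tesvox phantom --kind sphere --radii 80,83,87,92 \
    --tissues gm,csf,skull,scalp --voxel 2.0 --out head.nii.gz
tesvox run --input head.nii.gz --recipe "C3:1.0,C4:-1.0" \
    --out sim --skip-touchup
```

The run takes under a minute and writes `voltage.nii.gz`, `efield.nii.gz`,
`emag.nii.gz`, the electrode-augmented label volume, a per-tissue summary and
a provenance record. The summary for this example:

```
label,tissue,voxels,mean_E_V_per_m,median_E_V_per_m,max_E_V_per_m,mean_J_A_per_m2
2,gm,267761,0.0990,0.0750,0.5937,0.0273
3,csf,32058,0.0920,0.0617,0.5993,0.1518
4,skull,45424,1.2701,0.1939,47.798,0.0127
5,scalp,62354,0.3795,0.0883,17.488,0.1765
7,gel,76,25.862,25.600,35.945,7.7585
8,electrode,52,0.1107,0.1067,0.1544,11.072
```

Mean brain field ≈ 0.1 V/m per mA — the expected order of magnitude for TES —
with the largest fields under the electrodes and inside the resistive skull.

The same pipeline is available from Python:

```python
from tesvox.pipeline import RunConfig, run_pipeline

run_pipeline(RunConfig(input_path="head.nii.gz",
                       recipe="C3:1.0,C4:-1.0",
                       output_dir="sim",
                       conductivity={"skull": 0.015}))
```

Montage recipes are `NAME:CURRENT_mA[:SHAPE[:DIMS][:o=ox,oy,oz]]`, comma
separated — e.g. a 50×30 mm pad pair:
`"C3:2:pad:50x30x3:o=0,1,0,Fp2:-2:pad:50x30x3:o=1,0,0"`. Voxel coordinates
can replace names: `"@(34,120,88):1.0,Oz:-1.0"`.

## Validation against the analytic sphere

The solver is validated end to end against the exact Legendre-series solution
for a four-layer sphere (brain 80 mm, CSF 83 mm, skull 87 mm, scalp 92 mm;
conductivities 0.276 / 1.65 / 0.01 / 0.465 S/m) with a near-antipodal 1 mA
electrode pair:

```bash
tesvox validate-sphere --voxel 2.0 --report report.json
```

With the geometry-adapted mesh the relative L2 voltage error (outside 10 mm
caps around the electrodes) is

| voxel size | rel. L2 voltage error |
|-----------:|----------------------:|
| 4 mm       | 0.356                 |
| 2 mm       | 0.0284                |
| 1 mm       | 0.0110                |

(at 4 mm the CSF and skull shells are thinner than the voxel, so the geometry
cannot be represented; the error falls monotonically with resolution). The
2 mm validation runs in ~2 minutes on one CPU core; 1 mm takes ~12 minutes
and ~4 GB of memory.

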