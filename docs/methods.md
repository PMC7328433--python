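# Methods

This document records the physical model, the numerical methods, the default
parameters (with rationale), and the known limitations of `tesvox`.

## Physical model

Transcranial electrical stimulation operates far below the frequencies where
capacitive or inductive effects matter in tissue, so the electric potential
obeys the quasi-static volume-conduction equation

    ∇·(σ ∇V) = 0   in the head,
    σ ∂V/∂n = j    on electrode contact surfaces (injected current density),
    σ ∂V/∂n = 0    elsewhere on the boundary (air is insulating),

with σ the piecewise-constant tissue conductivity. The electric field is
E = −∇V and the current density J = σE. The potential is determined up to an
additive constant; `tesvox` reports it in the zero-mean gauge over the domain
nodes.

## Tissue vocabulary and conductivities

Labels are fixed package-wide: 0 background, 1 white matter, 2 gray matter,
3 CSF, 4 skull, 5 scalp, 6 internal air cavity, 7 electrode gel, 8 electrode
conductor. Default conductivities (S/m), all overridable per run:

| tissue     | σ (S/m) | rationale                                            |
|------------|--------:|------------------------------------------------------|
| white matter | 0.126 | standard literature value (isotropic)                |
| gray matter  | 0.276 | standard literature value                            |
| CSF          | 1.65  | standard literature value                            |
| skull        | 0.01  | standard literature value (compact-bone dominated)   |
| scalp        | 0.465 | standard literature value                            |
| gel          | 0.3   | typical conductive-gel value                         |
| electrode    | 100   | see below                                            |

The electrode conductor is deliberately *not* given a metallic 10⁷ S/m:
100 S/m is already more than four orders of magnitude above every tissue, so
the electrode behaves as an equipotential body, while a truly metallic value
would wreck the conditioning of the stiffness matrix for no change in the
field (the solution depends only on the contrast).

Internal air cavities (label 6) are **excluded from the computational
domain** rather than given a near-zero conductivity: in the Neumann
formulation an exterior boundary is exactly an insulating boundary, which is
the physically correct behavior of air, and excluding the voxels avoids the
catastrophic ill-conditioning that a 10⁻⁷-ish conductivity would cause.

## Segmentation touch-up

Automated segmentations leave specks, islands and — most damaging — gaps in
the thin GM/CSF/skull layers through which a brain voxel can touch skull or
scalp directly, short-circuiting the conductive CSF. The repair runs three
stages:

1. **Mask smoothing** — morphological open-then-close of every tissue mask
   with a ball of radius `smoothing_radius_mm` (default 1 mm, a no-op at
   resolutions coarser than 2 mm). Voxels claimed by several smoothed masks
   go to the highest-precedence tissue (WM > GM > CSF > skull > scalp > air);
   the head may not grow beyond the original extent dilated by one voxel.
2. **Island removal** — per tissue, 6-connected components smaller than
   `min_component_fraction` (default 5%) of the largest component are
   relabeled to the modal label of their boundary neighbors.
3. **Gap sealing**, iterated to a fixed point: (a) any CSF/skull/scalp/
   background voxel face-adjacent to WM becomes GM; (b) any skull/scalp/
   background/air voxel face-adjacent to brain becomes CSF; (c) any
   scalp/background voxel face-adjacent to CSF becomes skull. Rules (b) and
   (c) respect the **exception mask**, which marks genuine skull openings
   (optic canal, foramen magnum) that must remain conduits of current. The
   interpretation adopted here: the GM rule is unconditional (exposed white
   matter is always a segmentation error), while the CSF and skull jackets
   honor the exceptions.

All connectivity is 6-connectivity (shared faces): it is the strictest notion
of "touching" and prevents diagonal current leakage. On completion no
WM/GM voxel is face-adjacent to skull/scalp/background outside the exception
mask, and the repair is idempotent; both properties are tested.

The smoothing radius and component fraction are exposed rather than
hard-coded because published tools describe such parameters only as "chosen
conservatively"; the defaults here are deliberately conservative.

## Electrode placement

**Positions.** The 10-20 / 10-10 / 10-05 systems are generated on a unit
sphere by their proportional construction: the sagittal nasion–inion arc in
5% steps, the 10%-elevation ring in 2.5% circumference steps (with the
temporal compound names FT7, FTT7, TTP7, …), fifteen transverse rows between
ring anchors through the midline subdivided in sixteenths ('h' names at the
5% intermediates), and an equatorial lower ring (9/10 names), plus the legacy
T3/T4/T5/T6 aliases. This yields 283 named positions. Published counts for
the "10-05 system" vary with which optional rings are included; `tesvox`
documents and tests its own generated vocabulary (every generated name must
resolve to a scalp-surface point) rather than assert any particular count.
The template is rotated into the subject frame built from four fiducials
(nasion, inion, left/right preauricular) and projected radially from the head
center onto the outermost scalp voxel.

**Voxelization.** The outward surface normal is a least-squares plane fit
over the scalp surface within 5 mm. The gel slab spans the gel thickness
above the anchoring surface point and reaches one voxel *into* surface
crevices so that face contact with the scalp is guaranteed on staircase
surfaces; the conductor body (disc, pad or ring) sits on top. Only
background voxels are ever converted, so placement cannot modify tissue; a
collision with a previously placed electrode is an error.

At grids coarser than the electrode geometry, a 2 mm layer could contain no
voxel centers at all. Rule adopted: the gel band extends to
max(gel_thickness, 1.5 × voxel) above the anchoring scalp voxel center and
the conductor is at least one voxel layer thick. At 1 mm resolution this
reduces exactly to the nominal geometry (a 6 mm × 2 mm disc voxelizes to
≈ 226 voxels, its true volume); at 4 mm it guarantees representability for
the convergence ladder.

## Finite-element discretization

Every non-background, non-air voxel is one trilinear hexahedral element with
its tissue's conductivity. For a rectangular voxel the 8×8 element stiffness
is integrated exactly by 2×2×2 Gauss quadrature. Currents are Neumann loads:
each electrode's total current is spread over its exposed outer faces (faces
adjacent to background) in proportion to face area and converted to nodal
loads (a quarter per face node). The load vector sums to zero to machine
precision, and the anode's load equals the requested current exactly.

The assembled operator is symmetric positive semidefinite with one constant
nullspace mode per connected component; the zero-sum load lies in its range,
so a Jacobi-preconditioned conjugate-gradient solve converges without
pinning a reference node. Convergence is declared at a relative residual
`tol` (default 10⁻⁸) and verified a posteriori; the gauge is fixed by
subtracting the mean. The solve is deterministic.

The element field is the negative gradient of the trilinear interpolant at
the element center. No smoothing is applied across tissue boundaries: |E| at
a conductivity interface is genuinely discontinuous (only tangential E and
normal σE are continuous), so each voxel reports its own tissue's one-sided
field. A 6-tetrahedra (Kuhn split) discretization of the same voxel grid is
provided as an internal cross-check.

### Geometry-adapted meshing

A staircase voxel surface systematically misrepresents a smooth high-contrast
interface; on the four-layer sphere at 2 mm this *geometry* error is ~8% in
voltage and does not vanish when the same voxelized labels are solved on a
refined mesh — no solver on center-sampled labels can remove it. When the
caller can describe the true interfaces as smooth surfaces (projector
callables `points_mm -> (projected_points_mm, distance_mm)`),
`fem.assemble(..., adapt_surfaces=[...])` therefore shifts mesh nodes that
lie on conductivity interfaces or the outer surface onto the nearest surface
(clamped to 0.7 × voxel), and the elements become general isoparametric
hexahedra with per-element Jacobians. A safeguard loop relaxes any node whose
shift would produce a non-positive Jacobian, so the operator remains SPD for
arbitrary surfaces. This is the standard remedy for staircase error in
voxel-based head modeling. The sphere validation uses shell-radius
projectors; ordinary user volumes, for which no surface model exists, run on
the plain voxel mesh.

## Analytic sphere oracle

For concentric piecewise-homogeneous shells with a surface point source and
sink, the potential is a Legendre series with per-shell coefficients fixed by
continuity of V and σ∂V/∂r, regularity at the center, and the surface Neumann
condition. Numerics: coefficients are propagated shell-to-shell as a 2×2
solve per harmonic in a radius-normalized basis; in the outer shell the
slowly converging part is summed in closed form (the homogeneous-sphere
point-source potential) and only the geometrically decaying difference series
is truncated; fields come from term-wise differentiation with the apparent
1/sin γ singularity cancelled analytically. Evaluation is chunked (200k
points) so memory stays O(points + terms). The series is validated against
the closed form, finite-difference gradients, interface continuity and
source/sink antisymmetry.

The FEM comparison excludes 10 mm caps around the electrodes, where the
finite disc and the analytic point source legitimately disagree, and
compares at the actual (possibly adapted) element centers in a common
zero-mean gauge. Headline numbers (tol 10⁻⁶, 400 terms): relative L2 voltage
error 0.356 at 4 mm, 0.0284 at 2 mm, 0.0110 at 1 mm.

## Comparison metrics

Field comparisons use the voxelwise Euclidean norm d = ‖E_A − E_B‖,
restricted to voxels where both segmentations agree, so field differences are
not conflated with tissue-assignment differences. Segmentation differences
are absolute symmetric-difference volumes per tissue (cm³) rather than Dice
scores, which saturate for large structures and hide exactly the thin-layer
discrepancies that matter; Dice is available as a secondary output.
Prediction validation regresses measurement on prediction (prediction as the
independent variable, intercept included): Pearson r captures the spatial
pattern, the slope s the magnitude, and the intercept absorbs any additive
gauge offset.

## Known limitations

* Conductivities are isotropic; white-matter anisotropy (from diffusion
  imaging) is not modeled.
* The electrode–skin interface has no impedance model; the gel/conductor
  stack is purely ohmic.
* Geometry adaptation requires caller-supplied smooth surfaces; arbitrary
  segmented volumes run on the plain voxel mesh and inherit its staircase
  error at high-contrast interfaces (a few percent in voltage at 2 mm for
  head-like geometry, concentrated near the skull).
* One element per voxel means memory and time grow with the full labeled
  grid; a 1 mm whole-head volume (~4 × 10⁶ elements) solves in minutes and a
  few GB, but much finer grids would need a multigrid preconditioner.
* Voxel axes must be orthogonal (the affine may translate and permute/flip
  axes, but not shear).
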