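"""Synthetic labeled volumes with exactly known geometry.

Layered concentric spheres stand in for a head (thin CSF and skull shells are
the regime that matters for current flow), axis-aligned slabs provide 1-D
closed forms for the solver, and controllable defects (single-voxel shell
punctures, cylindrical skull channels mimicking an optic canal) exercise the
segmentation touch-up.  Shell membership is evaluated at voxel centers with no
partial-volume averaging, which keeps analytic voxel-count oracles exact.

Generation is deterministic: defect locations are explicit in the spec; the
convenience randomizer :func:`punch_shell_holes` takes an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .volumes import (
    AIR,
    BG,
    CSF,
    GM,
    NAME_TO_LABEL,
    SCALP,
    SKULL,
    WM,
    LabeledVolume,
)

#: Default 4-layer head: brain (GM) 80 mm, CSF to 83 mm, skull to 87 mm,
#: scalp to 92 mm — thin CSF/skull shells like a real head.
DEFAULT_RADII = (80.0, 83.0, 87.0, 92.0)
DEFAULT_TISSUES = ("gm", "csf", "skull", "scalp")


@dataclass
class Defect:
    """One deliberate flaw in a phantom.

    kind="puncture": the single voxel at ``voxel`` is relabeled to ``label``.
    kind="channel": voxels of tissue ``through`` within ``radius_mm`` of the
    ray from the volume center along ``axis`` are relabeled to ``label``
    (a synthetic skull opening).  ``exception`` marks the defect as a genuine
    anatomical feature that gap-sealing must preserve.
    """

    kind: str
    label: int
    voxel: tuple[int, int, int] | None = None
    axis: tuple[float, float, float] | None = None
    radius_mm: float = 3.0
    through: int = SKULL
    exception: bool = False


@dataclass
class PhantomSpec:
    kind: str = "layered_sphere"  # or "slab"
    radii_mm: tuple[float, ...] = DEFAULT_RADII
    tissues: tuple[str, ...] = DEFAULT_TISSUES  # innermost -> outermost
    voxel_mm: float | tuple[float, float, float] = 2.0
    margin_voxels: int = 2
    # slab-only geometry: lateral extent and per-layer thickness along z
    slab_size_mm: tuple[float, float] = (50.0, 50.0)
    thicknesses_mm: tuple[float, ...] = (50.0,)
    defects: list[Defect] = field(default_factory=list)

    def __post_init__(self) -> None:
        vox = np.atleast_1d(np.asarray(self.voxel_mm, dtype=float))
        if np.any(vox <= 0):
            raise GeometryError("voxel size must be positive")
        radii = np.asarray(self.radii_mm, dtype=float)
        if self.kind == "layered_sphere":
            if np.any(np.diff(radii) <= 0) or radii[0] <= 0:
                raise GeometryError("radii must be positive and strictly increasing")
            if len(radii) != len(self.tissues):
                raise GeometryError("one tissue per shell required")

    @property
    def voxel(self) -> np.ndarray:
        v = np.asarray(self.voxel_mm, dtype=float)
        return np.full(3, float(v)) if v.ndim == 0 else v

    def labels(self) -> list[int]:
        return [NAME_TO_LABEL[t] for t in self.tissues]


def _grid_and_affine(half_extent_mm: np.ndarray, voxel: np.ndarray, margin: int):
    """Symmetric grid holding ±half_extent with a margin; origin at center voxel."""
    half_n = np.ceil(half_extent_mm / voxel).astype(int) + margin
    shape = 2 * half_n + 1
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = voxel
    affine[:3, 3] = -half_n * voxel
    return shape, affine, half_n


def make_layered_sphere(spec: PhantomSpec) -> LabeledVolume:
    """Concentric-shell sphere phantom; world origin at the sphere center.

    A voxel takes the tissue of the innermost shell whose radius is >= the
    distance from its center to the origin; defects are applied last.
    """
    if spec.kind != "layered_sphere":
        raise GeometryError(f"spec kind is {spec.kind!r}, expected 'layered_sphere'")
    voxel = spec.voxel
    radii = np.asarray(spec.radii_mm, dtype=float)
    shape, affine, _ = _grid_and_affine(np.full(3, radii[-1]), voxel, spec.margin_voxels)
    coords = [
        (np.arange(shape[d]) * voxel[d] + affine[d, 3]) for d in range(3)
    ]
    r2 = (
        coords[0][:, None, None] ** 2
        + coords[1][None, :, None] ** 2
        + coords[2][None, None, :] ** 2
    )
    labels = np.zeros(tuple(shape), dtype=np.int16)
    shell_codes = spec.labels()
    # paint outermost first so inner shells overwrite
    for radius, code in zip(radii[::-1], shell_codes[::-1]):
        labels[r2 <= radius * radius] = code
    vol = LabeledVolume(labels, affine)
    _apply_defects(vol, spec.defects)
    return vol


def make_slab(spec: PhantomSpec) -> LabeledVolume:
    """Axis-aligned (possibly layered along z) block with background margin.

    The block's ±z faces are exposed so plate electrodes can be stacked on
    them; world origin is at the block center.
    """
    if spec.kind != "slab":
        raise GeometryError(f"spec kind is {spec.kind!r}, expected 'slab'")
    voxel = spec.voxel
    lx, ly = spec.slab_size_mm
    tz = float(np.sum(spec.thicknesses_mm))
    if len(spec.thicknesses_mm) != len(spec.tissues):
        raise GeometryError("one tissue per slab layer required")
    m = spec.margin_voxels
    extent = np.array([lx, ly, tz])
    # block aligned to voxel boundaries: a 50 mm edge at 1 mm is exactly 50 voxels
    n_in = np.ceil(extent / voxel - 0.5).astype(int)
    shape = n_in + 2 * m
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = voxel
    affine[:3, 3] = (0.5 - m) * voxel  # voxel m has its center at 0.5*h
    coords = [(np.arange(shape[d]) + 0.5 - m) * voxel[d] for d in range(3)]
    inx = (coords[0] > 0) & (coords[0] < lx)
    iny = (coords[1] > 0) & (coords[1] < ly)
    labels = np.zeros(tuple(shape), dtype=np.int16)
    z0 = 0.0
    for thickness, tissue in zip(spec.thicknesses_mm, spec.tissues):
        inz = (coords[2] > z0) & (coords[2] < z0 + thickness)
        block = inx[:, None, None] & iny[None, :, None] & inz[None, None, :]
        labels[block] = NAME_TO_LABEL[tissue]
        z0 += thickness
    vol = LabeledVolume(labels, affine)
    _apply_defects(vol, spec.defects)
    return vol


def add_plate_electrodes(
    vol: LabeledVolume, thickness_voxels: int = 1
) -> tuple[LabeledVolume, dict[str, np.ndarray]]:
    """Stack full-cross-section plate electrodes on a slab's ±z faces.

    Returns the augmented volume and the voxel-index arrays of the two plates
    ("top" = +z, "bottom" = -z), for use as FEM current-boundary electrodes.
    The plates cover exactly the block's cross-section, so the injected
    current density is laterally uniform — the 1-D closed-form regime.
    """
    from .volumes import ELECTRODE

    out = vol.copy()
    nz = out.data.shape[2]
    occupied = out.data > 0
    kz = np.nonzero(occupied.any(axis=(0, 1)))[0]
    klo, khi = int(kz.min()), int(kz.max())
    if klo < thickness_voxels or khi + thickness_voxels >= nz:
        raise GeometryError("not enough z margin for plate electrodes")
    cross = occupied[:, :, khi]
    plates: dict[str, np.ndarray] = {}
    for name, ks in (
        ("top", range(khi + 1, khi + 1 + thickness_voxels)),
        ("bottom", range(klo - thickness_voxels, klo)),
    ):
        idx = []
        for k in ks:
            ij = np.argwhere(cross)
            out.data[ij[:, 0], ij[:, 1], k] = ELECTRODE
            idx.append(np.column_stack([ij, np.full(len(ij), k)]))
        plates[name] = np.concatenate(idx, axis=0)
    return out, plates


def _channel_mask(vol: LabeledVolume, d: Defect) -> np.ndarray:
    axis = np.asarray(d.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    shape = vol.data.shape
    ijk = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    xyz = vol.world_coords(ijk)
    t = xyz @ axis
    perp = xyz - t[:, None] * axis[None, :]
    within = (np.linalg.norm(perp, axis=1) <= d.radius_mm) & (t > 0)
    return within.reshape(shape)


def _apply_defects(vol: LabeledVolume, defects: list[Defect]) -> None:
    for d in defects:
        if d.kind == "puncture":
            i, j, k = d.voxel
            if not all(0 <= x < n for x, n in zip((i, j, k), vol.data.shape)):
                raise GeometryError(f"puncture voxel {d.voxel} outside the grid")
            vol.data[i, j, k] = d.label
        elif d.kind == "channel":
            mask = _channel_mask(vol, d) & (vol.data == d.through)
            vol.data[mask] = d.label
        else:
            raise GeometryError(f"unknown defect kind {d.kind!r}")


def exception_mask(spec: PhantomSpec, vol: LabeledVolume) -> np.ndarray:
    """Binary mask of all defect voxels flagged ``exception`` in the spec."""
    mask = np.zeros(vol.data.shape, dtype=bool)
    for d in spec.defects:
        if not d.exception:
            continue
        if d.kind == "puncture":
            mask[d.voxel] = True
        else:
            mask |= _channel_mask(vol, d)
    return mask


def punch_shell_holes(
    spec: PhantomSpec,
    n: int,
    seed: int,
    shell: int = CSF,
    inner: int = GM,
    new_label: int = SKULL,
) -> PhantomSpec:
    """Return a copy of ``spec`` with ``n`` single-voxel punctures added.

    Punctures are placed on shell voxels that are 6-adjacent to the inner
    tissue, so each one creates a genuine inner-tissue/outer-tissue contact
    for the gap-sealing heuristics to repair.  Deterministic given ``seed``.
    """
    base = make_layered_sphere(
        PhantomSpec(
            kind=spec.kind,
            radii_mm=spec.radii_mm,
            tissues=spec.tissues,
            voxel_mm=spec.voxel_mm,
            margin_voxels=spec.margin_voxels,
        )
    )
    candidates = np.argwhere((base.data == shell) & _adjacent_to(base.data, inner))
    if len(candidates) < n:
        raise GeometryError(
            f"only {len(candidates)} candidate voxels for {n} punctures"
        )
    rng = np.random.default_rng(seed)
    picks = candidates[rng.choice(len(candidates), size=n, replace=False)]
    defects = list(spec.defects) + [
        Defect(kind="puncture", voxel=tuple(int(x) for x in p), label=new_label)
        for p in picks
    ]
    return PhantomSpec(
        kind=spec.kind,
        radii_mm=spec.radii_mm,
        tissues=spec.tissues,
        voxel_mm=spec.voxel_mm,
        margin_voxels=spec.margin_voxels,
        slab_size_mm=spec.slab_size_mm,
        thicknesses_mm=spec.thicknesses_mm,
        defects=defects,
    )


def _adjacent_to(labels: np.ndarray, target: int) -> np.ndarray:
    """Voxels with at least one 6-neighbor carrying ``target``."""
    hit = labels == target
    out = np.zeros_like(hit)
    out[1:, :, :] |= hit[:-1, :, :]
    out[:-1, :, :] |= hit[1:, :, :]
    out[:, 1:, :] |= hit[:, :-1, :]
    out[:, :-1, :] |= hit[:, 1:, :]
    out[:, :, 1:] |= hit[:, :, :-1]
    out[:, :, :-1] |= hit[:, :, 1:]
    return out
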