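"""Standard EEG-system scalp coordinates and virtual electrode voxelization.

The 10-20 / 10-10 / 10-05 systems place electrodes by proportional subdivision
of arcs spanned between four fiducials (nasion, inion, left/right preauricular
points).  Positions are generated here on an idealized unit sphere by that
proportional construction — the sagittal nasion-inion arc, the 10%-elevation
circumferential ring, transverse row arcs between ring anchors through the
midline, and an equatorial lower ring — then mapped into the subject frame
built from the fiducials and projected radially from the head center onto the
outermost scalp voxel.  This is deterministic and mesh-free; the generated
vocabulary (282 named positions plus legacy T3/T4/T5/T6 aliases) follows the
standard naming grammar: 'z' midline, odd numbers left / even right growing
outward, 'h' for the intermediate 5% positions, temporal letter switches
(FT7, FTT7, TTP7, ...) on the ring, and 9/10 for the ring 10% below.

Electrodes are voxelized directly onto the labeled volume: a gel layer is
stacked on the scalp along the locally estimated outward surface normal,
then the conductor body (disc, pad or ring).  Only background voxels are ever
converted, so placement cannot modify tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import CollisionError, ConfigurationError, PlacementError
from .volumes import BG, ELECTRODE, GEL, SCALP, LabeledVolume

# --------------------------------------------------------------------------
# unit-sphere template of the 10-05 superset
# --------------------------------------------------------------------------

_MIDLINE = [
    "Nz", "NFpz", "Fpz", "AFpz", "AFz", "AFFz", "Fz", "FFCz", "FCz", "FCCz",
    "Cz", "CCPz", "CPz", "CPPz", "Pz", "PPOz", "POz", "POOz", "Oz", "OIz", "Iz",
]

# ring names front -> back on the LEFT side, at 2.5% circumference steps
_RING_LEFT = [
    "Fpz", "Fp1h", "Fp1", "AFp7", "AF7", "AFF7", "F7", "FFT7", "FT7", "FTT7",
    "T7", "TTP7", "TP7", "TPP7", "P7", "PPO7", "PO7", "POO7", "O1", "OI1", "Oz",
]

# transverse rows: (row prefix, midline fraction, left ring anchor)
_ROWS = [
    ("AFp", 0.15, "AFp7"),
    ("AF", 0.20, "AF7"),
    ("AFF", 0.25, "AFF7"),
    ("F", 0.30, "F7"),
    ("FFC", 0.35, "FFT7"),
    ("FC", 0.40, "FT7"),
    ("FCC", 0.45, "FTT7"),
    ("C", 0.50, "T7"),
    ("CCP", 0.55, "TTP7"),
    ("CP", 0.60, "TP7"),
    ("CPP", 0.65, "TPP7"),
    ("P", 0.70, "P7"),
    ("PPO", 0.75, "PPO7"),
    ("PO", 0.80, "PO7"),
    ("POO", 0.85, "POO7"),
]

# equatorial lower ring: (name stem, circumference fraction of the left point)
_LOWER = [
    ("F9", 0.15), ("FT9", 0.20), ("T9", 0.25), ("TP9", 0.30),
    ("P9", 0.35), ("PO9", 0.40), ("I1", 0.45),
]

#: legacy 10-20 temporal names
ALIASES = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

SYSTEM_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
]


def _mirror_name(name: str) -> str:
    """Left-side name -> right-side name (odd number -> odd+1)."""
    digits = "".join(ch for ch in name if ch.isdigit())
    n = int(digits)
    return name.replace(digits, str(n + 1), 1)


def _circle_through(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray):
    """Center, radius and in-plane basis of the circle through three points
    on the unit sphere (the intersection of their common plane with it)."""
    normal = np.cross(p2 - p1, p3 - p1)
    nn = np.linalg.norm(normal)
    if nn < 1e-12:
        raise ConfigurationError("arc endpoints are collinear")
    normal /= nn
    center = normal * (p1 @ normal)  # plane offset from sphere center
    u = p1 - center
    rho = np.linalg.norm(u)
    u /= rho
    w = np.cross(normal, u)
    return center, rho, u, w


def _arc_points(left: np.ndarray, mid: np.ndarray, right: np.ndarray, fracs):
    """Points at the given fractions along the circle arc left->mid->right."""
    center, rho, u, w = _circle_through(left, mid, right)

    def angle(p):
        d = p - center
        return np.arctan2(d @ w, d @ u)

    th_m = angle(mid) % (2 * np.pi)
    th_r = angle(right) % (2 * np.pi)
    if th_m > th_r:  # orient so left(0) -> mid -> right increases
        th_m, th_r = 2 * np.pi - th_m, 2 * np.pi - th_r
        w = -w
    out = []
    for f in fracs:
        th = f * th_r
        out.append(center + rho * (np.cos(th) * u + np.sin(th) * w))
    return out


def unit_sphere_positions() -> dict[str, np.ndarray]:
    """All 10-05 template positions on the unit sphere.

    Idealized frame: +x right, +y anterior (nasion), +z superior (vertex);
    nasion, inion and the preauricular points lie on the equator.
    """
    pos: dict[str, np.ndarray] = {}
    # sagittal midline, 5% steps of the nasion-inion arc over the vertex
    for i, name in enumerate(_MIDLINE):
        th = np.pi * i * 0.05
        pos[name] = np.array([0.0, np.cos(th), np.sin(th)])
    # 10% ring: small circle at 18 deg elevation, 2.5% circumference steps
    lam = np.pi * 0.1
    for i, name in enumerate(_RING_LEFT):
        g = i * 0.025
        p = np.array(
            [-np.cos(lam) * np.sin(2 * np.pi * g),
             np.cos(lam) * np.cos(2 * np.pi * g),
             np.sin(lam)]
        )
        pos.setdefault(name, p)
        if 0 < i < len(_RING_LEFT) - 1:
            pos[_mirror_name(name)] = p * np.array([-1.0, 1.0, 1.0])
    # transverse rows between ring anchors through the midline point
    row_fracs = [i / 16 for i in range(1, 16)]  # interior only
    for prefix, f_mid, left_anchor in _ROWS:
        left = pos[left_anchor]
        right = pos[_mirror_name(left_anchor)]
        mid = pos[f"{prefix}z"]
        pts = _arc_points(left, mid, right, row_fracs)
        # inward from the left anchor (which is the row's lateral-7 site on
        # the ring), through the midline, out to the right anchor; 'h' sites
        # lie just inward of their numbered neighbor
        names = (
            [f"{prefix}7h", f"{prefix}5", f"{prefix}5h", f"{prefix}3",
             f"{prefix}3h", f"{prefix}1", f"{prefix}1h", f"{prefix}z",
             f"{prefix}2h", f"{prefix}2", f"{prefix}4h", f"{prefix}4",
             f"{prefix}6h", f"{prefix}6", f"{prefix}8h"]
        )
        for name, p in zip(names, pts):
            pos.setdefault(name, p)
    # lower (equatorial) ring
    for stem, g in _LOWER:
        p = np.array([-np.sin(2 * np.pi * g), np.cos(2 * np.pi * g), 0.0])
        pos[stem] = p
        pos[_mirror_name(stem)] = p * np.array([-1.0, 1.0, 1.0])
    return pos


def system_names(system: str = "10-05") -> list[str]:
    """Electrode names of a system ('10-20', '10-10' or the full '10-05')."""
    all_names = list(unit_sphere_positions())
    if system in ("10-05", "10-5"):
        return all_names
    if system in ("10-10",):
        simple = {
            "Fp", "AF", "F", "FC", "FT", "C", "T", "CP", "TP", "P", "PO", "O",
            "I", "N",
        }
        out = []
        for name in all_names:
            if name.endswith("h"):
                continue
            stem = name.rstrip("z0123456789")
            if stem in simple:
                out.append(name)
        return out
    if system in ("10-20",):
        return list(SYSTEM_1020)
    raise ConfigurationError(f"unknown EEG system {system!r}")


# --------------------------------------------------------------------------
# montage data model
# --------------------------------------------------------------------------

DEFAULT_DISC = (6.0, 2.0)  # radius, height (mm): the standard small TES disc
DEFAULT_GEL_MM = 2.0


@dataclass
class ElectrodeSpec:
    """One electrode: a name or voxel coordinate, a shape, and a current."""

    id: str | tuple[int, int, int]
    current_mA: float
    shape: str = "disc"
    dims: tuple[float, ...] = DEFAULT_DISC
    orientation: tuple[float, float, float] | None = None  # pads only
    gel_thickness_mm: float = DEFAULT_GEL_MM

    def __post_init__(self) -> None:
        if self.shape not in ("disc", "pad", "ring"):
            raise ConfigurationError(f"unknown electrode shape {self.shape!r}")
        dims = tuple(float(d) for d in self.dims)
        need = {"disc": 2, "pad": 3, "ring": 3}[self.shape]
        if len(dims) != need:
            raise ConfigurationError(
                f"{self.shape} needs {need} dimensions, got {len(dims)}"
            )
        if any(d <= 0 for d in dims):
            raise ConfigurationError("electrode dimensions must be positive")
        if self.shape == "ring" and dims[0] >= dims[1]:
            raise ConfigurationError("ring inner radius must be < outer radius")
        if self.shape == "pad":
            if self.orientation is None:
                raise ConfigurationError("pad electrodes need an orientation vector")
            if np.linalg.norm(self.orientation) == 0:
                raise ConfigurationError("pad orientation vector must be nonzero")
        if self.gel_thickness_mm <= 0:
            raise ConfigurationError("gel thickness must be positive")
        self.dims = dims

    @property
    def key(self) -> str:
        return self.id if isinstance(self.id, str) else "@" + ",".join(map(str, self.id))


@dataclass
class Montage:
    """Electrode set plus the fiducials anchoring the EEG coordinate system."""

    electrodes: list[ElectrodeSpec]
    fiducials: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        currents = [e.current_mA for e in self.electrodes]
        if abs(sum(currents)) > 1e-9:
            raise ConfigurationError(
                f"electrode currents must sum to zero, got {sum(currents):g} mA"
            )
        if not (any(c > 0 for c in currents) and any(c < 0 for c in currents)):
            raise ConfigurationError(
                "montage needs at least one anode and one cathode"
            )


# --------------------------------------------------------------------------
# scalp-surface geometry
# --------------------------------------------------------------------------

def _scalp_surface(v: LabeledVolume):
    """(surface voxel indices, their world centers, head center) for scalp
    voxels that are 6-adjacent to background or to the grid boundary."""
    labels = v.data
    scalp = labels == SCALP
    if not scalp.any():
        raise PlacementError("volume has no scalp voxels")
    bg = labels == BG
    adj = np.zeros_like(scalp)
    padded = np.pad(bg, 1, constant_values=True)
    adj |= padded[:-2, 1:-1, 1:-1] | padded[2:, 1:-1, 1:-1]
    adj |= padded[1:-1, :-2, 1:-1] | padded[1:-1, 2:, 1:-1]
    adj |= padded[1:-1, 1:-1, :-2] | padded[1:-1, 1:-1, 2:]
    surf = np.argwhere(scalp & adj)
    centers = v.world_coords(surf)
    head_center = v.world_coords(np.argwhere(scalp)).mean(axis=0)
    return surf, centers, head_center


def standard_positions(
    scalp: LabeledVolume,
    fiducials: dict[str, tuple[float, float, float]],
    system: str = "10-05",
) -> dict[str, np.ndarray]:
    """World coordinates (mm) of the EEG-system positions on the scalp.

    Template positions on the unit sphere are rotated into the frame defined
    by the fiducials and projected radially from the head center onto the
    outermost scalp voxel; every returned point is a scalp-surface voxel
    center.
    """
    required = ("nasion", "inion", "lpa", "rpa")
    missing = [k for k in required if k not in fiducials]
    if missing:
        raise PlacementError(f"missing fiducials: {missing}")
    surf, centers, head_center = _scalp_surface(scalp)
    tree = cKDTree(centers)
    for name in required:
        d, _ = tree.query(np.asarray(fiducials[name], float))
        if d > 20.0:
            raise PlacementError(
                f"fiducial {name!r} is {d:.1f} mm from the scalp surface (> 20 mm)"
            )
    # subject frame from the fiducials
    nas = np.asarray(fiducials["nasion"], float) - head_center
    ini = np.asarray(fiducials["inion"], float) - head_center
    lpa = np.asarray(fiducials["lpa"], float) - head_center
    rpa = np.asarray(fiducials["rpa"], float) - head_center
    x = rpa - lpa
    x = x / np.linalg.norm(x)
    y = nas - ini
    y = y - (y @ x) * x
    y = y / np.linalg.norm(y)
    z = np.cross(x, y)
    frame = np.column_stack([x, y, z])  # template -> world rotation

    out: dict[str, np.ndarray] = {}
    wanted = set(system_names(system))
    template = unit_sphere_positions()
    for name, p in template.items():
        if name not in wanted:
            continue
        direction = frame @ p
        out[name] = _project_to_surface(scalp, tree, centers, surf, head_center, direction)
    return out


def _project_to_surface(v, tree, centers, surf, head_center, direction):
    """Outermost scalp voxel center along a ray from the head center."""
    labels = v.data
    step = 0.3 * float(v.voxel_sizes.min())
    rmax = float(np.max(np.linalg.norm(centers - head_center, axis=1))) + 3 * step
    radii = np.arange(0.0, rmax, step)
    pts = head_center[None, :] + radii[:, None] * direction[None, :]
    ijk = v.voxel_index(pts)
    ok = np.all((ijk >= 0) & (ijk < np.array(labels.shape)), axis=1)
    hits = np.zeros(len(ijk), dtype=bool)
    hits[ok] = labels[ijk[ok, 0], ijk[ok, 1], ijk[ok, 2]] == SCALP
    if not hits.any():
        raise PlacementError("projection ray misses the scalp")
    far = pts[np.nonzero(hits)[0][-1]]
    _, idx = tree.query(far)
    return centers[idx]


# --------------------------------------------------------------------------
# voxelization
# --------------------------------------------------------------------------

def _surface_normal(position, tree, centers, head_center, radius_mm=5.0):
    """Outward normal from a least-squares plane over the local surface."""
    idx = tree.query_ball_point(position, radius_mm)
    radial = position - head_center
    radial = radial / np.linalg.norm(radial)
    if len(idx) < 4:
        return radial
    pts = centers[idx] - centers[idx].mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    normal = vt[-1]
    if normal @ radial < 0:
        normal = -normal
    return normal


def place_electrode(
    v: LabeledVolume,
    e: ElectrodeSpec,
    position: np.ndarray,
) -> tuple[LabeledVolume, np.ndarray]:
    """Voxelize one electrode (gel then conductor) at a scalp position.

    The outward surface normal is a least-squares plane fit over the scalp
    surface within 5 mm; the gel slab spans the gel thickness above the
    surface (reaching one voxel into surface crevices so that face contact
    with the scalp is guaranteed on staircase surfaces), and the conductor
    body sits on top of the gel.  Only background voxels are converted.

    Returns the augmented volume and the (N, 3) body voxel indices.
    """
    position = np.asarray(position, dtype=float)
    surf, centers, head_center = _scalp_surface(v)
    tree = cKDTree(centers)
    d, _ = tree.query(position)
    if d > 20.0:
        raise PlacementError(
            f"electrode position {position} is {d:.1f} mm off the scalp surface"
        )
    n = _surface_normal(position, tree, centers, head_center)
    # tangent frame
    if e.shape == "pad":
        o = np.asarray(e.orientation, float)
        u = o - (o @ n) * n
        if np.linalg.norm(u) < 1e-9:
            raise PlacementError("pad orientation is parallel to the surface normal")
        u = u / np.linalg.norm(u)
    else:
        seed = np.array([1.0, 0.0, 0.0])
        if abs(seed @ n) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        u = seed - (seed @ n) * n
        u = u / np.linalg.norm(u)
    w = np.cross(n, u)

    if e.shape == "disc":
        radius, height = e.dims
        lateral_extent = radius
    elif e.shape == "ring":
        inner, outer, height = e.dims
        lateral_extent = outer
    else:
        length, width, height = e.dims
        lateral_extent = float(np.hypot(length, width)) / 2

    gel = e.gel_thickness_mm
    burrow = float(v.voxel_sizes.max())  # reach into surface staircase
    reach = lateral_extent + gel + height + burrow + 2 * float(v.voxel_sizes.max())
    lo = v.voxel_index(position - reach)
    hi = v.voxel_index(position + reach)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(v.data.shape) - 1)
    ranges = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    ijk = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    xyz = v.world_coords(ijk)
    rel = xyz - position
    t = rel @ n
    lat = rel - t[:, None] * n[None, :]

    if e.shape == "disc":
        in_lateral = np.linalg.norm(lat, axis=1) <= radius
    elif e.shape == "ring":
        rho = np.linalg.norm(lat, axis=1)
        in_lateral = (rho >= inner) & (rho <= outer)
    else:
        in_lateral = (np.abs(lat @ u) <= length / 2) & (np.abs(lat @ w) <= width / 2)

    # a layer thinner than one voxel cannot be represented at this grid:
    # the first background voxel-center shell lies up to one voxel pitch above
    # the anchoring scalp voxel center, so the gel band must extend past it,
    # and both gel and conductor must be at least one voxel layer thick
    hn = float(v.voxel_sizes.max())
    gel_top = max(gel, 1.5 * hn)
    body_top = gel_top + max(height, hn)
    # band edges sit exactly on voxel-center planes for axis-aligned normals;
    # nudge them down so rounding in t never drops the first body layer
    eps = 1e-6 * hn
    gel_zone = in_lateral & (t >= -burrow - eps) & (t < gel_top - eps)
    body_zone = in_lateral & (t >= gel_top - eps) & (t < body_top - eps)
    region = gel_zone | body_zone
    cur = v.data[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
    if np.any(region & ((cur == GEL) | (cur == ELECTRODE))):
        raise CollisionError(
            f"electrode {e.key!r} overlaps a previously placed electrode or gel"
        )
    out = v.copy()
    gel_vox = ijk[gel_zone & (cur == BG)]
    body_vox = ijk[body_zone & (cur == BG)]
    if len(body_vox) == 0:
        raise PlacementError(f"electrode {e.key!r} voxelized to an empty body")
    out.data[gel_vox[:, 0], gel_vox[:, 1], gel_vox[:, 2]] = GEL
    out.data[body_vox[:, 0], body_vox[:, 1], body_vox[:, 2]] = ELECTRODE
    # gel must actually touch scalp through at least one face
    from .phantoms import _adjacent_to

    touching = _adjacent_to(out.data, SCALP)
    gel_mask = np.zeros(out.data.shape, dtype=bool)
    gel_mask[gel_vox[:, 0], gel_vox[:, 1], gel_vox[:, 2]] = True
    if not (gel_mask & touching).any():
        raise PlacementError(f"gel of electrode {e.key!r} does not contact the scalp")
    return out, body_vox


def apply_montage(
    v: LabeledVolume, m: Montage
) -> tuple[LabeledVolume, dict[str, np.ndarray]]:
    """Place every electrode of the montage; returns the augmented volume and
    a map electrode-id -> body voxel indices for boundary conditions.

    Placement is in list order and deterministic; any single failure aborts
    with the failing electrode named.
    """
    named = [e for e in m.electrodes if isinstance(e.id, str)]
    positions: dict[str, np.ndarray] = {}
    if named:
        positions = standard_positions(v, m.fiducials)
        for alias, target in ALIASES.items():
            positions.setdefault(alias, positions[target])
    out = v
    voxel_map: dict[str, np.ndarray] = {}
    for e in m.electrodes:
        if isinstance(e.id, str):
            if e.id not in positions:
                raise PlacementError(f"unknown electrode name {e.id!r}")
            pos = positions[e.id]
        else:
            surf, centers, _ = _scalp_surface(out)
            tree = cKDTree(centers)
            world = out.world_coords(np.asarray(e.id, float))
            _, idx = tree.query(world)
            pos = centers[idx]
        try:
            out, body = place_electrode(out, e, pos)
        except (PlacementError, CollisionError) as exc:
            raise type(exc)(f"placing electrode {e.key!r} failed: {exc}") from exc
        if e.key in voxel_map:
            raise CollisionError(f"duplicate electrode id {e.key!r}")
        voxel_map[e.key] = body
    return out, voxel_map
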