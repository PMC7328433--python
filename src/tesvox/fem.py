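"""Voxel-native finite-element solver for the quasi-static volume-conduction
problem ∇·(σ∇V) = 0.

Instead of building a tetrahedral surface-conforming mesh, every non-background
voxel of the labeled volume becomes one trilinear hexahedral element with the
uniform conductivity of its tissue.  Current injection is a pure Neumann
boundary condition: each electrode's total current is spread over its exposed
outer surface (element faces adjacent to background) in proportion to face
area, and converted to equivalent nodal loads.  The voltage is defined up to a
constant and reported in the zero-mean gauge over domain nodes.

The element electric field is the (constant-per-element here: evaluated at the
element center) negative gradient of the trilinear interpolant.  No smoothing
is applied across tissue boundaries: the field at a conductivity interface is
genuinely discontinuous (only the tangential E and the normal current density
σE are continuous), so each voxel reports the field of its own tissue side.

Internal air cavities are excluded from the computational domain rather than
given a near-zero conductivity: an exterior boundary is a natural zero-flux
(insulating) boundary in the Neumann formulation, which is physically
equivalent for air and avoids catastrophic ill-conditioning.

Units: geometry is converted from mm to meters internally; conductivities are
S/m, currents are specified in mA and applied in A, voltages come out in V and
fields in V/m.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import (
    AlignmentError,
    BoundaryConditionError,
    ConfigurationError,
    SolverError,
)
from .volumes import (
    AIR,
    BG,
    CANONICAL_LABELS,
    CSF,
    ELECTRODE,
    GEL,
    GM,
    SCALP,
    SKULL,
    WM,
    FieldVolume,
    LabeledVolume,
)

#: Literature-based tissue conductivities (S/m).  CSF, gray matter and skull
#: are the values the comparison studies in this field use; white matter and
#: scalp likewise come from the standard literature set.  The electrode
#: conductor is deliberately NOT given a metallic 10^7 S/m — 100 S/m is more
#: than four orders of magnitude above every tissue, which already makes the
#: electrode an equipotential body without wrecking the conditioning of the
#: stiffness matrix.
DEFAULT_CONDUCTIVITIES: dict[int, float] = {
    WM: 0.126,
    GM: 0.276,
    CSF: 1.65,
    SKULL: 0.01,
    SCALP: 0.465,
    GEL: 0.3,
    ELECTRODE: 100.0,
}

#: Element corner c sits at voxel offset CORNERS[c] (i fastest).
CORNERS = np.array([[(c >> 0) & 1, (c >> 1) & 1, (c >> 2) & 1] for c in range(8)])


@dataclass
class ConductivityTable:
    """Map tissue label -> conductivity (S/m)."""

    values: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDUCTIVITIES)
    )

    @classmethod
    def default(cls, **overrides_by_name: float) -> "ConductivityTable":
        """Defaults with keyword overrides by tissue name, e.g. ``skull=0.015``."""
        from .volumes import NAME_TO_LABEL

        values = dict(DEFAULT_CONDUCTIVITIES)
        for name, sigma in overrides_by_name.items():
            if name not in NAME_TO_LABEL:
                raise ConfigurationError(f"unknown tissue name {name!r}")
            values[NAME_TO_LABEL[name]] = float(sigma)
        return cls(values)

    def __getitem__(self, label: int) -> float:
        return self.values[label]

    def __post_init__(self) -> None:
        for label, sigma in self.values.items():
            if sigma <= 0:
                raise ConfigurationError(
                    f"conductivity for label {label} must be positive, got {sigma}"
                )

    def scaled(self, factor: float) -> "ConductivityTable":
        return ConductivityTable({k: v * factor for k, v in self.values.items()})


def hex_stiffness(h_m: np.ndarray, n_gauss: int = 2) -> np.ndarray:
    """8x8 stiffness of a rectangular trilinear brick with unit conductivity.

    ``h_m`` are the edge lengths in meters; 2x2x2 Gauss quadrature integrates
    the trilinear gradients exactly.
    """
    h = np.asarray(h_m, dtype=float)
    pts, wts = np.polynomial.legendre.leggauss(n_gauss)
    signs = 2 * CORNERS - 1  # (8,3) in ±1
    K = np.zeros((8, 8))
    detj = np.prod(h / 2)
    for xi, wx in zip(pts, wts):
        for eta, wy in zip(pts, wts):
            for zeta, wz in zip(pts, wts):
                q = np.array([xi, eta, zeta])
                # dN_c/dxi_d = (s_d/2) * prod_{e != d} (1 + s_e q_e)/2
                grad = np.empty((8, 3))
                for d in range(3):
                    other = [e for e in range(3) if e != d]
                    grad[:, d] = (signs[:, d] / 2) * np.prod(
                        (1 + signs[:, other] * q[other]) / 2, axis=1
                    )
                grad_phys = grad * (2.0 / h)  # chain rule x = h/2 (xi+1)
                K += wx * wy * wz * detj * (grad_phys @ grad_phys.T)
    return K


def _gauss_grad_table(n_gauss: int = 2) -> list[tuple[np.ndarray, float]]:
    """[(dN/dxi at the Gauss point (8,3), weight)] on the reference cube."""
    pts, wts = np.polynomial.legendre.leggauss(n_gauss)
    signs = 2 * CORNERS - 1
    table = []
    for xi, wx in zip(pts, wts):
        for eta, wy in zip(pts, wts):
            for zeta, wz in zip(pts, wts):
                q = np.array([xi, eta, zeta])
                g = np.empty((8, 3))
                for d in range(3):
                    other = [e for e in range(3) if e != d]
                    g[:, d] = (signs[:, d] / 2) * np.prod(
                        (1 + signs[:, other] * q[other]) / 2, axis=1
                    )
                table.append((g, float(wx * wy * wz)))
    return table


_GAUSS_TABLE = _gauss_grad_table()


def tet_equivalent_stiffness(h_m: np.ndarray) -> np.ndarray:
    """8x8 stiffness of a voxel split into 6 linear tetrahedra (Kuhn).

    Provided as an internal cross-check of the hexahedral discretization: both
    operate on the same voxel grid and node set, so their solutions can be
    compared directly.
    """
    h = np.asarray(h_m, dtype=float)
    corner_index = {tuple(c): i for i, c in enumerate(CORNERS)}
    K = np.zeros((8, 8))
    basis = np.eye(3, dtype=int)
    for perm in itertools.permutations(range(3)):
        verts = [np.zeros(3, dtype=int)]
        for axis in perm:
            verts.append(verts[-1] + basis[axis])
        X = np.array(verts, dtype=float) * h  # (4,3) physical coords
        # gradients of barycentric coordinates: rows of inv([[1,x]]) below
        A = np.hstack([np.ones((4, 1)), X])
        G = np.linalg.inv(A)[1:, :].T  # (4,3) grad of each P1 basis fn
        vol = abs(np.linalg.det(X[1:] - X[0])) / 6.0
        Kt = vol * (G @ G.T)
        ids = [corner_index[tuple(v)] for v in verts]
        for a in range(4):
            for b in range(4):
                K[ids[a], ids[b]] += Kt[a, b]
    return K


@dataclass
class FEMSystem:
    """Assembled sparse system on the compacted node set of the domain."""

    matrix: sp.csr_matrix
    load: np.ndarray  # A, per compact node
    node_flat_ids: np.ndarray  # compact node -> flat id on the (n+1)^3 node grid
    elem_nodes: np.ndarray  # (Ne, 8) compact node ids
    elem_ijk: np.ndarray  # (Ne, 3) voxel indices
    sigma_e: np.ndarray  # (Ne,) S/m
    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    voxel_mm: np.ndarray
    labels: np.ndarray  # reference to the label grid used for assembly
    #: set when the mesh was geometry-adapted: actual node coordinates (mm)
    node_positions_mm: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_flat_ids)

    @property
    def node_grid_shape(self) -> tuple[int, int, int]:
        nx, ny, nz = self.grid_shape
        return (nx + 1, ny + 1, nz + 1)

    def node_ijk(self) -> np.ndarray:
        """(n_nodes, 3) grid coordinates of the compact nodes."""
        _, ny1, nz1 = self.node_grid_shape
        f = self.node_flat_ids
        k = f % nz1
        j = (f // nz1) % ny1
        i = f // (nz1 * ny1)
        return np.column_stack([i, j, k])

    def node_world_mm(self) -> np.ndarray:
        """World coordinates (mm) of the compact nodes (voxel corners, or the
        shifted positions when the mesh was geometry-adapted)."""
        if self.node_positions_mm is not None:
            return self.node_positions_mm
        ijk = self.node_ijk().astype(float) - 0.5  # corner (i,j,k) = center - h/2
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def element_centers_mm(self) -> np.ndarray:
        """(Ne, 3) element centers (mm): mean of the 8 actual corner positions."""
        return self.node_world_mm()[self.elem_nodes].mean(axis=1)

    def with_load(self, load: np.ndarray) -> "FEMSystem":
        return replace(self, load=load)


def _orthogonality_check(affine: np.ndarray) -> None:
    R = affine[:3, :3]
    G = R.T @ R
    off = G - np.diag(np.diag(G))
    if np.max(np.abs(off)) > 1e-6 * np.max(np.diag(G)):
        raise ConfigurationError(
            "voxel axes must be orthogonal for the hexahedral discretization"
        )


def _min_det_jacobian(
    Xm: np.ndarray, elem_nodes: np.ndarray, chunk: int
) -> np.ndarray:
    """Per-element minimum Jacobian determinant over the Gauss points."""
    out = np.full(len(elem_nodes), np.inf)
    for start in range(0, len(elem_nodes), chunk):
        sl = slice(start, min(start + chunk, len(elem_nodes)))
        X = Xm[elem_nodes[sl]]
        for g, _w in _GAUSS_TABLE:
            J = np.einsum("eca,cb->eab", X, g)
            out[sl] = np.minimum(out[sl], np.linalg.det(J))
    return out


def _interface_nodes(
    elem_nodes: np.ndarray, sigma_e: np.ndarray, n_nodes: int
) -> np.ndarray:
    """Nodes incident to elements of differing conductivity, or lying on the
    outer domain surface (fewer than 8 incident elements)."""
    first = np.full(n_nodes, np.nan)
    multi = np.zeros(n_nodes, dtype=bool)
    count = np.zeros(n_nodes, dtype=np.int32)
    for c in range(8):
        nd = elem_nodes[:, c]  # distinct within a column by construction
        seen = first[nd]
        multi[nd] |= ~np.isnan(seen) & (seen != sigma_e)
        first[nd] = np.where(np.isnan(seen), sigma_e, seen)
        count[nd] += 1
    return multi | (count < 8)


def _adapted_positions(
    pos0_mm: np.ndarray,
    elem_nodes: np.ndarray,
    sigma_e: np.ndarray,
    h_mm: np.ndarray,
    surfaces,
    max_shift_factor: float,
    chunk: int,
) -> np.ndarray:
    """Project interface/surface nodes onto the nearest smooth surface.

    Each surface is a callable ``points_mm -> (projected_points_mm,
    distance_mm)``.  Shifts are clamped to ``max_shift_factor`` voxels; any
    element tangled by the shifts (non-positive Jacobian) has its nodes
    relaxed back toward the regular grid until the mesh is valid, so the
    assembled operator is always SPD regardless of the surfaces supplied.
    """
    n = len(pos0_mm)
    movable = _interface_nodes(elem_nodes, sigma_e, n)
    best = pos0_mm.copy()
    bestd = np.full(n, np.inf)
    for proj in surfaces:
        t, d = proj(pos0_mm)
        better = np.asarray(d) < bestd
        best[better] = np.asarray(t)[better]
        bestd[better] = np.asarray(d)[better]
    clamp = max_shift_factor * float(h_mm.max())
    move = movable & (bestd <= clamp)
    shift = np.zeros_like(pos0_mm)
    shift[move] = best[move] - pos0_mm[move]

    det_ref = float(np.prod(h_mm / 1000.0 / 2.0))
    threshold = 0.05 * det_ref
    for _ in range(10):
        bad = _min_det_jacobian((pos0_mm + shift) / 1000.0, elem_nodes, chunk)
        bad = bad <= threshold
        if not bad.any():
            break
        bad_nodes = np.unique(elem_nodes[bad])
        # halve, then fully revert shifts that refuse to untangle
        small = np.linalg.norm(shift[bad_nodes], axis=1) < 0.05 * clamp
        shift[bad_nodes] *= 0.5
        shift[bad_nodes[small]] = 0.0
    else:
        raise ConfigurationError(
            "geometry adaptation failed to produce a valid mesh"
        )
    return pos0_mm + shift


def assemble(
    v: LabeledVolume,
    sigma: ConductivityTable,
    discretization: str = "hex",
    chunk: int = 400_000,
    sigma_voxels: np.ndarray | None = None,
    adapt_surfaces=None,
    max_shift_factor: float = 0.7,
) -> FEMSystem:
    """Assemble the stiffness operator on the labeled volume.

    One element per non-background, non-air-cavity voxel.  The operator is
    symmetric positive semidefinite; its nullspace is one constant mode per
    connected component of the domain.

    sigma_voxels, if given, is a float array on the voxel grid holding a
    per-voxel conductivity (S/m) that overrides the label lookup wherever it
    is positive — the anti-aliasing hook for callers that know sub-voxel
    tissue fractions (e.g. analytically generated phantoms).  Domain
    membership is still decided by the labels.

    adapt_surfaces, if given, is a sequence of smooth-surface projectors
    (callables ``points_mm -> (projected_points_mm, distance_mm)``).  Nodes on
    conductivity interfaces or the outer staircase surface that lie within
    ``max_shift_factor`` voxels of a surface are moved onto it and the
    elements become general (isoparametric) hexahedra — the geometry-adapted
    meshing that removes the staircase error at high-contrast boundaries
    (essential for quantitative agreement with smooth-geometry analytic
    solutions).  Only available for the hex discretization.
    """
    labels = np.ascontiguousarray(v.data)
    _orthogonality_check(v.affine)
    domain = (labels != BG) & (labels != AIR)
    if not domain.any():
        raise ConfigurationError("volume contains no conductive voxels")
    present = sorted(int(x) for x in np.unique(labels[domain]))
    missing = [p for p in present if p not in sigma.values]
    if missing:
        names = [CANONICAL_LABELS.get(m, str(m)) for m in missing]
        raise ConfigurationError(
            f"no conductivity for labels {missing} ({names})"
        )
    h_m = v.voxel_sizes / 1000.0
    if discretization == "hex":
        Ke = hex_stiffness(h_m)
    elif discretization == "tet":
        Ke = tet_equivalent_stiffness(h_m)
    else:
        raise ConfigurationError(f"unknown discretization {discretization!r}")

    nx, ny, nz = labels.shape
    nz1, ny1 = nz + 1, ny + 1
    ii, jj, kk = np.nonzero(domain)
    elem_ijk = np.column_stack([ii, jj, kk]).astype(np.int32)
    base = (ii.astype(np.int64) * ny1 + jj) * nz1 + kk
    offsets = (CORNERS[:, 0].astype(np.int64) * ny1 + CORNERS[:, 1]) * nz1 + CORNERS[:, 2]
    elem_flat = base[:, None] + offsets[None, :]  # (Ne, 8) flat node ids

    node_flat_ids, elem_nodes = np.unique(elem_flat, return_inverse=True)
    elem_nodes = elem_nodes.reshape(elem_flat.shape).astype(np.int32)
    n = len(node_flat_ids)

    sig_of_label = np.zeros(labels.max() + 1)
    for lab, s in sigma.values.items():
        if lab <= labels.max():
            sig_of_label[lab] = s
    sigma_e = sig_of_label[labels[ii, jj, kk]]
    if sigma_voxels is not None:
        sv = np.asarray(sigma_voxels, dtype=float)
        if sv.shape != labels.shape:
            raise ConfigurationError(
                "sigma_voxels shape does not match the volume grid"
            )
        override = sv[ii, jj, kk]
        sigma_e = np.where(override > 0, override, sigma_e)

    node_positions_mm = None
    if adapt_surfaces is not None:
        if discretization != "hex":
            raise ConfigurationError(
                "geometry adaptation requires the hex discretization"
            )
        k_ = node_flat_ids % nz1
        j_ = (node_flat_ids // nz1) % ny1
        i_ = node_flat_ids // (nz1 * ny1)
        nijk = np.column_stack([i_, j_, k_]).astype(float) - 0.5
        pos0 = nijk @ v.affine[:3, :3].T + v.affine[:3, 3]
        node_positions_mm = _adapted_positions(
            pos0, elem_nodes, sigma_e, v.voxel_sizes, adapt_surfaces,
            max_shift_factor, chunk,
        )

    K = sp.csr_matrix((n, n))
    rows_l = np.repeat(np.arange(8), 8)
    cols_l = np.tile(np.arange(8), 8)
    if node_positions_mm is None:
        ke_flat = Ke[rows_l, cols_l]
        for start in range(0, len(sigma_e), chunk):
            sl = slice(start, min(start + chunk, len(sigma_e)))
            en = elem_nodes[sl]
            data = sigma_e[sl, None] * ke_flat[None, :]
            rows = en[:, rows_l].ravel()
            cols = en[:, cols_l].ravel()
            K = K + sp.coo_matrix(
                (data.ravel(), (rows, cols)), shape=(n, n)
            ).tocsr()
    else:
        Xm_all = node_positions_mm / 1000.0
        for start in range(0, len(sigma_e), chunk):
            sl = slice(start, min(start + chunk, len(sigma_e)))
            en = elem_nodes[sl]
            X = Xm_all[en]  # (ne, 8, 3)
            Ke_iso = np.zeros((len(X), 8, 8))
            for g, w in _GAUSS_TABLE:
                J = np.einsum("eca,cb->eab", X, g)
                detJ = np.linalg.det(J)
                invJ = np.linalg.inv(J)
                G = np.einsum("cb,eba->eca", g, invJ)  # dN/dx
                Ke_iso += (w * detJ)[:, None, None] * np.einsum(
                    "eca,eda->ecd", G, G
                )
            data = sigma_e[sl, None, None] * Ke_iso
            rows = en[:, rows_l].ravel()
            cols = en[:, cols_l].ravel()
            K = K + sp.coo_matrix(
                (data.reshape(len(X), 64).ravel(), (rows, cols)), shape=(n, n)
            ).tocsr()
    return FEMSystem(
        matrix=K,
        load=np.zeros(n),
        node_flat_ids=node_flat_ids,
        elem_nodes=elem_nodes,
        elem_ijk=elem_ijk,
        sigma_e=sigma_e,
        grid_shape=labels.shape,
        affine=v.affine.copy(),
        voxel_mm=v.voxel_sizes.copy(),
        labels=labels,
        node_positions_mm=node_positions_mm,
    )


# face -> (axis, side, corner ids on that face)
_FACES = []
for axis in range(3):
    for side in (0, 1):
        ids = [c for c in range(8) if CORNERS[c, axis] == side]
        _FACES.append((axis, side, np.array(ids)))


def apply_current_bc(
    sys: FEMSystem,
    electrode_voxels: dict[str, np.ndarray],
    currents_mA: dict[str, float],
) -> FEMSystem:
    """Distribute each electrode's current over its exposed outer surface.

    Exposed faces are element faces adjacent to background (or to the grid
    boundary).  The electrode's total current is split across faces in
    proportion to exact face area and converted to nodal loads, a quarter of a
    face's current to each of its four nodes.  The resulting load vector sums
    to zero by current conservation.
    """
    if set(electrode_voxels) != set(currents_mA):
        raise ConfigurationError("electrode_voxels and currents keys differ")
    total = sum(currents_mA.values())
    if abs(total) > 1e-9:
        raise ConfigurationError(
            f"currents must sum to zero (net {total:g} mA)"
        )
    labels = sys.labels
    nx, ny, nz = sys.grid_shape
    nz1, ny1 = nz + 1, ny + 1
    h_m = sys.voxel_mm / 1000.0
    face_area = [h_m[1] * h_m[2], h_m[0] * h_m[2], h_m[0] * h_m[1]]

    # map flat node id -> compact id
    load = np.zeros(sys.n_nodes)
    for name, vox in electrode_voxels.items():
        vox = np.asarray(list(vox)) if not isinstance(vox, np.ndarray) else vox
        vox = vox.reshape(-1, 3).astype(np.int64)
        face_nodes = []  # list of (n_faces, 4) flat node ids per orientation
        face_areas = []
        for axis, side, ids in _FACES:
            nb = vox.copy()
            nb[:, axis] += 1 if side == 1 else -1
            outside = (nb[:, axis] < 0) | (nb[:, axis] >= labels.shape[axis])
            inside = ~outside
            exposed = outside.copy()
            if inside.any():
                lab = labels[nb[inside, 0], nb[inside, 1], nb[inside, 2]]
                exposed[inside] = lab == BG
            if not exposed.any():
                continue
            base = (vox[exposed, 0] * ny1 + vox[exposed, 1]) * nz1 + vox[exposed, 2]
            offs = (
                CORNERS[ids, 0].astype(np.int64) * ny1 + CORNERS[ids, 1]
            ) * nz1 + CORNERS[ids, 2]
            face_nodes.append(base[:, None] + offs[None, :])
            face_areas.append(np.full(exposed.sum(), face_area[axis]))
        if not face_nodes:
            raise BoundaryConditionError(
                f"electrode {name!r} has no exposed face adjacent to background"
            )
        nodes = np.concatenate(face_nodes, axis=0)
        areas = np.concatenate(face_areas)
        I_A = currents_mA[name] * 1e-3
        face_I = I_A * areas / areas.sum()
        compact = np.searchsorted(sys.node_flat_ids, nodes)
        if not np.array_equal(sys.node_flat_ids[compact], nodes):
            raise BoundaryConditionError(
                f"electrode {name!r} references nodes outside the domain"
            )
        np.add.at(load, compact.ravel(), np.repeat(face_I / 4.0, 4))
    return sys.with_load(load)


@dataclass
class FEMSolution:
    """Node voltages plus element-centered E and J on the voxel grid."""

    voltages: np.ndarray  # V, per compact node, zero-mean gauge
    E: FieldVolume  # V/m, element (= voxel) centered
    J: FieldVolume  # A/m^2
    system: FEMSystem
    residual: float
    iterations: int

    def voltage_volume(self) -> np.ndarray:
        """Voxel-centered voltage (mean of the 8 corner nodes); 0 outside."""
        out = np.zeros(self.system.grid_shape)
        vc = self.voltages[self.system.elem_nodes].mean(axis=1)
        e = self.system.elem_ijk
        out[e[:, 0], e[:, 1], e[:, 2]] = vc
        return out

    def domain_mask(self) -> np.ndarray:
        mask = np.zeros(self.system.grid_shape, dtype=bool)
        e = self.system.elem_ijk
        mask[e[:, 0], e[:, 1], e[:, 2]] = True
        return mask


def _element_fields(sys: FEMSystem, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Element-centered E = -∇V of the trilinear interpolant, and J = σE."""
    Vc = x[sys.elem_nodes]  # (Ne, 8)
    if sys.node_positions_mm is None:
        h_m = sys.voxel_mm / 1000.0
        E = np.empty((len(Vc), 3))
        for d in range(3):
            w = np.where(CORNERS[:, d] == 1, 0.25, -0.25)
            E[:, d] = -(Vc @ w) / h_m[d]
    else:
        # isoparametric gradient at the element center (xi = 0)
        g0 = (2 * CORNERS - 1) / 8.0  # dN/dxi at center
        Xm = sys.node_positions_mm / 1000.0
        E = np.empty((len(Vc), 3))
        chunk = 400_000
        for start in range(0, len(Vc), chunk):
            sl = slice(start, min(start + chunk, len(Vc)))
            X = Xm[sys.elem_nodes[sl]]
            J = np.einsum("eca,cb->eab", X, g0)
            invJ = np.linalg.inv(J)
            grad_xi = Vc[sl] @ g0  # (ne, 3)
            E[sl] = -np.einsum("eb,eba->ea", grad_xi, invJ)
    J = sys.sigma_e[:, None] * E
    return E, J


def solve(
    sys: FEMSystem,
    tol: float = 1e-8,
    maxiter: int = 10_000,
    x0: np.ndarray | None = None,
) -> FEMSolution:
    """Jacobi-preconditioned conjugate-gradient solve of K V = b.

    The operator is singular (constants in the nullspace) but the zero-sum
    load lies in its range, so CG converges; the gauge is fixed afterwards by
    subtracting the mean over domain nodes.  Deterministic: CG from a fixed
    start is seed-free.
    """
    A = sys.matrix
    b = sys.load
    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        x = np.zeros(sys.n_nodes)
        res, iters = 0.0, 0
    else:
        d = A.diagonal()
        Minv = sp.diags(1.0 / d)
        count = {"n": 0}

        def cb(_xk):
            count["n"] += 1

        x, info = spla.cg(
            A, b, x0=x0, rtol=tol, atol=0.0, maxiter=maxiter, M=Minv, callback=cb
        )
        res = float(np.linalg.norm(b - A @ x) / bnorm)
        iters = count["n"]
        if info != 0 or res > tol * 10:
            raise SolverError(
                f"CG did not converge in {maxiter} iterations "
                f"(relative residual {res:.3e})",
                residual=res,
            )
        x = x - x.mean()
    E, J = _element_fields(sys, x)
    Egrid = np.zeros(sys.grid_shape + (3,))
    Jgrid = np.zeros(sys.grid_shape + (3,))
    e = sys.elem_ijk
    Egrid[e[:, 0], e[:, 1], e[:, 2]] = E
    Jgrid[e[:, 0], e[:, 1], e[:, 2]] = J
    return FEMSolution(
        voltages=x,
        E=FieldVolume(Egrid, sys.affine.copy()),
        J=FieldVolume(Jgrid, sys.affine.copy()),
        system=sys,
        residual=res,
        iterations=iters,
    )


def field_to_grid(sol: FEMSolution, v: LabeledVolume) -> FieldVolume:
    """Return the element-centered E field on the volume's voxel grid.

    The voxel-native discretization makes this exact — each element *is* a
    voxel — so no resampling or smoothing across tissue boundaries occurs.
    The field value at a conductivity interface is the one-sided field of the
    voxel's own tissue; the interface value itself is analytically undefined.
    """
    if v.data.shape != sol.system.grid_shape or not np.allclose(
        v.affine, sol.system.affine
    ):
        raise AlignmentError("solution and volume are not on the same grid")
    return FieldVolume(sol.E.data.copy(), sol.E.affine.copy())


def current_through_plane(sol: FEMSolution, axis: int, index: int) -> float:
    """Net current (A) crossing the voxel layer ``index`` along ``axis``.

    Sums element J·(face area) over the layer — a discrete-conservation
    diagnostic for phantoms where a plane separates anode from cathode.
    """
    h_m = sol.system.voxel_mm / 1000.0
    area = np.prod(np.delete(h_m, axis))
    e = sol.system.elem_ijk
    sel = e[:, axis] == index
    Jax = sol.J.data[e[sel, 0], e[sel, 1], e[sel, 2], axis]
    return float(Jax.sum() * area)


def tissue_summary(sol: FEMSolution, v: LabeledVolume):
    """Per-tissue mean/median/max |E| and J table (pandas DataFrame)."""
    import pandas as pd

    mag = sol.E.magnitude()
    jmag = sol.J.magnitude()
    rows = []
    mask = sol.domain_mask()
    for lab in sorted(np.unique(v.data[mask]).tolist()):
        sel = (v.data == lab) & mask
        rows.append(
            {
                "label": int(lab),
                "tissue": v.label_table.get(int(lab), str(lab)),
                "voxels": int(sel.sum()),
                "mean_E_V_per_m": float(mag[sel].mean()),
                "median_E_V_per_m": float(np.median(mag[sel])),
                "max_E_V_per_m": float(mag[sel].max()),
                "mean_J_A_per_m2": float(jmag[sel].mean()),
            }
        )
    return pd.DataFrame(rows)
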