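"""End-to-end validation of the voxel FEM against the analytic sphere oracle.

Builds a layered-sphere phantom, places a near-antipodal disc-electrode pair,
solves the volume-conduction problem, and compares the voltage distribution
with the exact Legendre-series solution for the same shell geometry with
point electrodes.  A cap around each electrode is excluded from the error
norm: there the finite disc and the analytic point source legitimately
disagree, and the comparison would measure the electrode model rather than
the solver.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from . import fem
from .electrodes import DEFAULT_DISC, DEFAULT_GEL_MM, ElectrodeSpec, place_electrode
from .oracle import SphereModel
from .phantoms import PhantomSpec, make_layered_sphere
from .volumes import ELECTRODE, GEL, LabeledVolume

#: near-antipodal electrode directions (unit vectors): vertex and a point
#: 170 degrees away — exactly antipodal placement would make the problem
#: symmetric enough to hide sign/orientation bugs.
SOURCE_DIR = (0.0, 0.0, 1.0)
SINK_DIR = (np.sin(np.deg2rad(170.0)), 0.0, np.cos(np.deg2rad(170.0)))

DEFAULT_SPHERE_SIGMAS = {"gm": 0.276, "csf": 1.65, "skull": 0.01, "scalp": 0.465}


def _surface_point(vol: LabeledVolume, direction: np.ndarray) -> np.ndarray:
    """Scalp-surface voxel center nearest the outer-radius point along
    ``direction`` (the phantom's world origin is the sphere center)."""
    from .electrodes import _scalp_surface

    _, centers, _ = _scalp_surface(vol)
    radius = np.linalg.norm(centers, axis=1).max()
    tree = cKDTree(centers)
    _, idx = tree.query(radius * np.asarray(direction, float))
    return centers[idx]


def shell_projectors(radii_mm, center_mm=(0.0, 0.0, 0.0)):
    """Smooth-surface projectors for concentric spheres, one per radius —
    the ``adapt_surfaces`` input for geometry-adapted FEM assembly."""
    c = np.asarray(center_mm, dtype=float)

    def make(R):
        def proj(points_mm):
            rel = np.asarray(points_mm, dtype=float) - c
            r = np.linalg.norm(rel, axis=1)
            r_safe = np.maximum(r, 1e-9)
            return c + rel * (R / r_safe)[:, None], np.abs(r - R)

        return proj

    return [make(float(R)) for R in radii_mm]


def sphere_fem_solution(
    radii_mm=(80.0, 83.0, 87.0, 92.0),
    sigmas: dict[str, float] | None = None,
    voxel_mm: float = 2.0,
    current_mA: float = 1.0,
    tol: float = 1e-8,
    x0: np.ndarray | None = None,
    adapted: bool = True,
):
    """Phantom + electrodes + FEM solve; returns (volume-with-electrodes,
    solution, electrode surface points).

    With ``adapted`` (the default) the mesh nodes on shell interfaces are
    projected onto the exact sphere surfaces before assembly; without it the
    plain staircase voxel mesh is used (mainly for convergence studies of the
    unadapted discretization).
    """
    sigmas = dict(DEFAULT_SPHERE_SIGMAS if sigmas is None else sigmas)
    # margin must leave headroom for the gel + conductor stack above the scalp
    stack_mm = max(DEFAULT_GEL_MM, 1.5 * voxel_mm) + max(DEFAULT_DISC[1], voxel_mm)
    margin = int(np.ceil(stack_mm / voxel_mm)) + 2
    spec = PhantomSpec(
        kind="layered_sphere", radii_mm=tuple(radii_mm), voxel_mm=voxel_mm,
        margin_voxels=margin,
    )
    vol = make_layered_sphere(spec)
    points = {}
    voxel_map = {}
    for name, direction, current in (
        ("anode", SOURCE_DIR, current_mA),
        ("cathode", SINK_DIR, -current_mA),
    ):
        pos = _surface_point(vol, np.asarray(direction))
        e = ElectrodeSpec(id=name, current_mA=current, shape="disc", dims=DEFAULT_DISC,
                          gel_thickness_mm=DEFAULT_GEL_MM)
        vol, body = place_electrode(vol, e, pos)
        points[name] = pos
        voxel_map[name] = body
    table = fem.ConductivityTable.default(**sigmas)
    surfaces = shell_projectors(radii_mm) if adapted else None
    system = fem.assemble(vol, table, adapt_surfaces=surfaces)
    system = fem.apply_current_bc(
        system, voxel_map, {"anode": current_mA, "cathode": -current_mA}
    )
    sol = fem.solve(system, tol=tol, x0=x0)
    return vol, sol, points


def sphere_voltage_error(
    radii_mm=(80.0, 83.0, 87.0, 92.0),
    sigmas: dict[str, float] | None = None,
    voxel_mm: float = 2.0,
    current_mA: float = 1.0,
    exclusion_mm: float = 10.0,
    n_terms: int = 400,
    tol: float = 1e-8,
    adapted: bool = True,
) -> dict:
    """Relative L2 voltage error of the FEM against the analytic series.

    Compared at the element centers of head-tissue elements (the actual,
    possibly geometry-adapted, corner positions), excluding caps of
    ``exclusion_mm`` around the analytic electrode points; both solutions are
    put in the zero-mean gauge over the compared set.
    """
    sig = dict(DEFAULT_SPHERE_SIGMAS if sigmas is None else sigmas)
    vol, sol, _ = sphere_fem_solution(
        radii_mm, sig, voxel_mm, current_mA, tol, adapted=adapted
    )
    sysm = sol.system
    e = sysm.elem_ijk
    lab_e = vol.data[e[:, 0], e[:, 1], e[:, 2]]
    centers = sysm.element_centers_mm()
    R = float(radii_mm[-1])
    src = R * np.asarray(SOURCE_DIR)
    snk = R * np.asarray(SINK_DIR)
    keep = (
        ~np.isin(lab_e, (GEL, ELECTRODE))
        & (np.linalg.norm(centers - src, axis=1) > exclusion_mm)
        & (np.linalg.norm(centers - snk, axis=1) > exclusion_mm)
    )
    xyz = centers[keep]
    r = np.linalg.norm(xyz, axis=1)
    outside = r > R  # staircase scalp centers can poke past the outer radius
    xyz[outside] *= ((R * (1 - 1e-9)) / r[outside])[:, None]
    model = SphereModel(
        radii_mm=tuple(radii_mm),
        sigmas_S_per_m=tuple(sig[t] for t in ("gm", "csf", "skull", "scalp")),
        source=SOURCE_DIR,
        sink=tuple(SINK_DIR),
        current_mA=current_mA,
        n_terms=n_terms,
    )
    v_ref = model.voltage(xyz, demean=True)
    v_fem = sol.voltages[sysm.elem_nodes[keep]].mean(axis=1)
    v_fem = v_fem - v_fem.mean()
    err = float(np.linalg.norm(v_fem - v_ref) / np.linalg.norm(v_ref))
    return {
        "voxel_mm": float(voxel_mm),
        "rel_l2_voltage_error": err,
        "n_points": int(len(xyz)),
        "solver_residual": sol.residual,
        "solver_iterations": sol.iterations,
    }


def convergence_ladder(
    voxel_sizes=(4.0, 2.0, 1.0), tol: float = 1e-6, n_terms: int = 400, **kwargs
) -> list[dict]:
    """Voltage error at successively finer voxel sizes (coarse to fine)."""
    return [
        sphere_voltage_error(voxel_mm=h, tol=tol, n_terms=n_terms, **kwargs)
        for h in voxel_sizes
    ]
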