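"""One-call simulation pipeline: labels in, fields and reports out.

Mirrors the one-line usage of volumetric TES simulators: the user names an
input volume, a montage recipe and (optionally) conductivities; the pipeline
runs touch-up, electrode placement, the FEM solve, and writes all volumes,
summary tables and a provenance record sufficient to re-run the identical
simulation.  Everything is deterministic — there is no randomness anywhere in
the chain.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, fem
from .electrodes import (
    DEFAULT_DISC,
    DEFAULT_GEL_MM,
    ElectrodeSpec,
    Montage,
    _scalp_surface,
    apply_montage,
)
from .errors import RecipeError
from .touchup import TouchupConfig, run_touchup
from .volumes import (
    LabeledVolume,
    ProbabilityVolume,
    labels_from_probabilities,
    read_volume,
    write_scalar_volume,
    write_volume,
)

log = logging.getLogger("tesvox")


@dataclass
class RunConfig:
    input_path: str
    recipe: str
    output_dir: str
    fiducials: dict[str, tuple[float, float, float]] | None = None  # None: derive
    conductivity: dict[str, float] = field(default_factory=dict)  # name -> S/m
    smoothing_radius_mm: float = 1.0
    min_component_fraction: float = 0.05
    exception_mask_path: str | None = None
    skip_touchup: bool = False
    tol: float = 1e-8
    log_level: str = "INFO"


# ---- recipe parsing -------------------------------------------------------

_DIMS_RE = re.compile(r"^\d+(\.\d+)?(x\d+(\.\d+)?)*$")


def _split_entries(text: str) -> list[str]:
    """Split on top-level commas, then merge continuation chunks (an entry
    always contains a ':'; bare numbers belong to the previous entry's
    orientation vector)."""
    chunks, depth, cur = [], 0, ""
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            chunks.append(cur)
            cur = ""
        else:
            cur += ch
    chunks.append(cur)
    entries: list[str] = []
    for chunk in chunks:
        if ":" in chunk or not entries:
            entries.append(chunk)
        else:
            entries[-1] += "," + chunk
    return [e.strip() for e in entries if e.strip()]


def parse_recipe(text: str, gel_thickness_mm: float = DEFAULT_GEL_MM) -> Montage:
    """Parse a montage recipe string into a :class:`Montage`.

    Grammar per entry, entries comma-separated::

        NAME[@(i,j,k)]:CURRENT_mA[:SHAPE[:DIMS][:o=ox,oy,oz]]

    SHAPE is disc (dims RADIUSxHEIGHT), pad (LENGTHxWIDTHxHEIGHT, orientation
    required) or ring (INNERxOUTERxHEIGHT).  Omitted shape/dims default to the
    standard 6 mm x 2 mm disc with 2 mm gel.  Example::

        C3:1.0:disc:6x2,Fp2:-0.5,Oz:-0.5
    """
    if not text or not text.strip():
        raise RecipeError("empty montage recipe")
    electrodes = []
    for pos, entry in enumerate(_split_entries(text)):
        parts = entry.split(":")
        if len(parts) < 2:
            raise RecipeError(f"entry {pos} ({entry!r}): missing ':CURRENT'")
        head = parts[0].strip()
        m = re.match(r"^(?P<name>[^@]*)@\((?P<coord>[-\d\s,\.]+)\)$", head)
        if m:
            coord = tuple(int(float(x)) for x in m.group("coord").split(","))
            if len(coord) != 3:
                raise RecipeError(f"entry {pos}: coordinate must have 3 components")
            eid: str | tuple = coord
        elif head:
            eid = head
        else:
            raise RecipeError(f"entry {pos}: empty electrode name")
        try:
            current = float(parts[1])
        except ValueError:
            raise RecipeError(
                f"entry {pos} ({entry!r}): bad current {parts[1]!r}"
            ) from None
        shape, dims, orientation = "disc", DEFAULT_DISC, None
        for extra in parts[2:]:
            extra = extra.strip()
            if extra in ("disc", "pad", "ring"):
                shape = extra
            elif extra.startswith("o="):
                try:
                    orientation = tuple(float(x) for x in extra[2:].split(","))
                except ValueError:
                    raise RecipeError(
                        f"entry {pos}: bad orientation {extra!r}"
                    ) from None
            elif _DIMS_RE.match(extra):
                dims = tuple(float(x) for x in extra.split("x"))
            else:
                raise RecipeError(f"entry {pos}: unrecognized token {extra!r}")
        if shape == "disc" and len(dims) != 2:
            dims = DEFAULT_DISC
        electrodes.append(
            ElectrodeSpec(
                id=eid,
                current_mA=current,
                shape=shape,
                dims=dims,
                orientation=orientation,
                gel_thickness_mm=gel_thickness_mm,
            )
        )
    return Montage(electrodes=electrodes)


# ---- fiducial convenience -------------------------------------------------

def derive_fiducials(v: LabeledVolume) -> dict[str, tuple[float, float, float]]:
    """Fiducials at the scalp-surface extremes of the world axes.

    Suitable for phantoms and roughly ACPC-aligned heads: nasion/inion at the
    ±y extremes, preauricular points at the ±x extremes of the scalp surface,
    all taken near the axial plane through the scalp centroid.
    """
    _, centers, head_center = _scalp_surface(v)
    rel = centers - head_center
    near_plane = np.abs(rel[:, 2]) < max(3.0 * v.voxel_sizes.max(), 5.0)
    cand = centers[near_plane] if near_plane.any() else centers
    relc = cand - head_center
    return {
        "nasion": tuple(cand[np.argmax(relc[:, 1])]),
        "inion": tuple(cand[np.argmin(relc[:, 1])]),
        "rpa": tuple(cand[np.argmax(relc[:, 0])]),
        "lpa": tuple(cand[np.argmin(relc[:, 0])]),
    }


# ---- pipeline -------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> Path:
    """Execute touch-up -> electrodes -> FEM -> outputs; returns the output dir.

    Writes: ``labels_touched.nii.gz``, ``labels_electrodes.nii.gz``,
    ``voltage.nii.gz`` (V), ``efield.nii.gz`` (V/m, 3 components),
    ``emag.nii.gz``, ``tissue_summary.csv`` and ``provenance.json``.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage: read input %s", cfg.input_path)
    vol = read_volume(cfg.input_path)
    if isinstance(vol, ProbabilityVolume):
        vol = labels_from_probabilities(vol)

    exception = None
    if cfg.exception_mask_path:
        ex = read_volume(cfg.exception_mask_path)
        exception = np.asarray(ex.data) > 0
    if cfg.skip_touchup:
        touched = vol
    else:
        log.info("stage: touch-up")
        touched = run_touchup(
            vol,
            TouchupConfig(
                smoothing_radius_mm=cfg.smoothing_radius_mm,
                min_component_fraction=cfg.min_component_fraction,
                exception_mask=exception,
            ),
        )
    write_volume(touched, out / "labels_touched.nii.gz")

    log.info("stage: electrode placement")
    montage = parse_recipe(cfg.recipe)
    montage.fiducials = cfg.fiducials or derive_fiducials(touched)
    with_elec, voxel_map = apply_montage(touched, montage)
    write_volume(with_elec, out / "labels_electrodes.nii.gz")

    log.info("stage: FEM solve")
    sigma = fem.ConductivityTable.default(**cfg.conductivity)
    for name, default_sigma in (("electrode", 100.0), ("gel", 0.3)):
        if name not in cfg.conductivity:
            log.info(
                "using default %s conductivity %.3g S/m (configurable)",
                name,
                default_sigma,
            )
    system = fem.assemble(with_elec, sigma)
    currents = {e.key: e.current_mA for e in montage.electrodes}
    system = fem.apply_current_bc(system, voxel_map, currents)
    sol = fem.solve(system, tol=cfg.tol)

    log.info("stage: outputs (residual %.2e, %d iterations)", sol.residual, sol.iterations)
    write_scalar_volume(sol.voltage_volume(), with_elec.affine, out / "voltage.nii.gz")
    write_volume(sol.E, out / "efield.nii.gz")
    write_scalar_volume(sol.E.magnitude(), with_elec.affine, out / "emag.nii.gz")
    fem.tissue_summary(sol, with_elec).to_csv(out / "tissue_summary.csv", index=False)

    provenance = {
        "tesvox_version": __version__,
        "config": {
            "input_path": cfg.input_path,
            "recipe": cfg.recipe,
            "fiducials": {k: list(map(float, p)) for k, p in montage.fiducials.items()},
            "conductivity_overrides": cfg.conductivity,
            "conductivity_S_per_m": {str(k): v for k, v in sigma.values.items()},
            "smoothing_radius_mm": cfg.smoothing_radius_mm,
            "min_component_fraction": cfg.min_component_fraction,
            "exception_mask_path": cfg.exception_mask_path,
            "skip_touchup": cfg.skip_touchup,
            "tol": cfg.tol,
        },
        "solver": {"residual": sol.residual, "iterations": sol.iterations},
        "currents_mA": currents,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out
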