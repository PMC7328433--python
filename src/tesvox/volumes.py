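"""Labeled, probabilistic and vector-field volumes on a common voxel grid.

Every stage of the pipeline exchanges data through the types defined here.
Coordinates follow the NIfTI convention: voxel indices are 0-based and the
world position (mm) of the *center* of voxel (i, j, k) is ``affine @ (i, j, k, 1)``.
Anisotropic voxel sizes are supported throughout; all geometric quantities are
expressed in millimetres, never in voxel counts.

The canonical tissue-label vocabulary is fixed so that every stage's contract
is testable against the same integer codes:

====  ===========
code  tissue
====  ===========
0     background (exterior air)
1     white matter
2     gray matter
3     CSF
4     skull
5     scalp
6     air cavity (intracranial/sinus air)
7     electrode gel
8     electrode conductor
====  ===========

Labels 7 and 8 are created only by electrode placement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ConfigurationError, VolumeFormatError

# Canonical label codes.
BG = 0
WM = 1
GM = 2
CSF = 3
SKULL = 4
SCALP = 5
AIR = 6
GEL = 7
ELECTRODE = 8

CANONICAL_LABELS: dict[int, str] = {
    BG: "background",
    WM: "wm",
    GM: "gm",
    CSF: "csf",
    SKULL: "skull",
    SCALP: "scalp",
    AIR: "air",
    GEL: "gel",
    ELECTRODE: "electrode",
}

NAME_TO_LABEL: dict[str, int] = {v: k for k, v in CANONICAL_LABELS.items()}

#: Tie-break / contest precedence for tissues, highest priority first.
TISSUE_PRECEDENCE: tuple[int, ...] = (WM, GM, CSF, SKULL, SCALP, AIR)


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise VolumeFormatError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise VolumeFormatError("affine is singular")
    sizes = np.linalg.norm(affine[:3, :3], axis=0)
    if np.any(sizes <= 0):
        raise VolumeFormatError("voxel sizes must be strictly positive")
    return affine


@dataclass
class LabeledVolume:
    """3-D integer tissue-label grid with a voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray
    label_table: dict[int, str] = field(default_factory=lambda: dict(CANONICAL_LABELS))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"label data must be 3-D, got {self.data.ndim}-D"
            )
        if not np.issubdtype(self.data.dtype, np.integer):
            raise VolumeFormatError("label data must have an integer dtype")
        self.affine = _check_affine(self.affine)
        present = set(np.unique(self.data).tolist())
        missing = present - set(self.label_table)
        if missing:
            raise VolumeFormatError(
                f"labels {sorted(missing)} present in data but absent from label_table"
            )

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Edge lengths (mm) of a voxel along each grid axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        """World (mm) coordinates of voxel centers, ijk of shape (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxel_index(self, world: np.ndarray) -> np.ndarray:
        """Nearest voxel index for world-mm points of shape (..., 3)."""
        world = np.asarray(world, dtype=float)
        inv = np.linalg.inv(self.affine)
        ijk = world @ inv[:3, :3].T + inv[:3, 3]
        return np.rint(ijk).astype(int)

    def copy(self) -> "LabeledVolume":
        return LabeledVolume(self.data.copy(), self.affine.copy(), dict(self.label_table))


@dataclass
class ProbabilityVolume:
    """4-D (x, y, z, tissue) posterior-probability volume in [0, 1]."""

    data: np.ndarray
    affine: np.ndarray
    tissue_order: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise VolumeFormatError(
                f"probability data must be 4-D, got {self.data.ndim}-D"
            )
        if self.data.shape[3] != len(self.tissue_order):
            raise VolumeFormatError("channel count does not match tissue_order")
        self.affine = _check_affine(self.affine)
        if self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9:
            raise VolumeFormatError("probabilities must lie in [0, 1]")
        if self.data.sum(axis=3).max() > 1 + 1e-6:
            raise VolumeFormatError("per-voxel probabilities sum to more than 1")


@dataclass
class FieldVolume:
    """4-D (x, y, z, 3) electric-field volume in V/m; zero outside the head."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[3] != 3:
            raise VolumeFormatError("field data must have shape (nx, ny, nz, 3)")
        self.affine = _check_affine(self.affine)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.data, axis=3)


def _best_affine(img: nib.Nifti1Image) -> np.ndarray:
    """sform if set, else qform, else scaled identity from the zooms."""
    hdr = img.header
    sform, scode = hdr.get_sform(coded=True)
    if scode:
        return np.asarray(sform, dtype=float)
    qform, qcode = hdr.get_qform(coded=True)
    if qcode:
        return np.asarray(qform, dtype=float)
    zooms = hdr.get_zooms()[:3]
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = zooms
    return aff


def read_volume(path: str | Path) -> LabeledVolume | ProbabilityVolume:
    """Read a NIfTI file as a labeled or probability volume.

    Integer-typed 3-D data becomes a :class:`LabeledVolume` (label names from a
    ``<stem>.labels.json`` sidecar when present, else the canonical vocabulary);
    4-D float data becomes a :class:`ProbabilityVolume` whose tissue order is
    taken from the sidecar or defaults to the canonical tissue precedence.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise VolumeFormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    affine = _best_affine(img)
    data = np.asanyarray(img.dataobj)
    sidecar = _sidecar_path(path)
    if data.ndim == 3:
        if not np.issubdtype(data.dtype, np.integer):
            raise VolumeFormatError(
                f"{path}: 3-D volume has float dtype; expected integer labels"
            )
        table = dict(CANONICAL_LABELS)
        if sidecar.exists():
            raw = json.loads(sidecar.read_text())
            table = {int(k): str(v) for k, v in raw.items()}
        for v in np.unique(data):
            table.setdefault(int(v), f"label{int(v)}")
        return LabeledVolume(data.astype(np.int16), affine, table)
    if data.ndim == 4:
        order = [CANONICAL_LABELS[t] for t in TISSUE_PRECEDENCE]
        if sidecar.exists():
            raw = json.loads(sidecar.read_text())
            order = list(raw.get("tissue_order", order))
        if data.shape[3] != len(order):
            order = [f"tissue{i}" for i in range(data.shape[3])]
        return ProbabilityVolume(np.asarray(data, dtype=float), affine, order)
    raise VolumeFormatError(
        f"{path}: expected a 3-D label or 4-D probability volume, got {data.ndim}-D"
    )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".labels.json")
    return path.with_suffix(".labels.json")


def write_volume(v: LabeledVolume | ProbabilityVolume | FieldVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; labeled volumes get a JSON label sidecar."""
    path = Path(path)
    if isinstance(v, LabeledVolume):
        img = nib.Nifti1Image(v.data.astype(np.int16), v.affine)
        img.header.set_sform(v.affine, code=1)
        img.header.set_qform(v.affine, code=1)
        nib.save(img, str(path))
        _sidecar_path(path).write_text(
            json.dumps({str(k): v.label_table[k] for k in sorted(v.label_table)}, indent=1)
        )
        return
    if isinstance(v, ProbabilityVolume):
        img = nib.Nifti1Image(v.data.astype(np.float32), v.affine)
        img.header.set_sform(v.affine, code=1)
        nib.save(img, str(path))
        _sidecar_path(path).write_text(json.dumps({"tissue_order": v.tissue_order}))
        return
    img = nib.Nifti1Image(v.data.astype(np.float32), v.affine)
    img.header.set_sform(v.affine, code=1)
    nib.save(img, str(path))


def write_scalar_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a plain 3-D scalar map (voltage, |E|) as NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine, float))
    img.header.set_sform(np.asarray(affine, float), code=1)
    nib.save(img, str(path))


def labels_from_probabilities(p: ProbabilityVolume) -> LabeledVolume:
    """Collapse tissue posteriors to a label volume.

    A voxel receives the tissue of maximal probability when that maximum
    carries at least half of the voxel's total probability mass; otherwise the
    residual mass wins and the voxel is background.  Ties are broken by the
    fixed anatomical precedence WM > GM > CSF > skull > scalp > air cavity.
    """
    try:
        codes = np.array([NAME_TO_LABEL[name] for name in p.tissue_order])
    except KeyError as exc:
        raise ConfigurationError(
            f"unknown tissue name {exc.args[0]!r}; known: "
            f"{sorted(NAME_TO_LABEL)}"
        ) from exc
    # Reorder channels by precedence so argmax's first-hit rule implements the
    # tie-break.
    order = np.argsort([TISSUE_PRECEDENCE.index(c) for c in codes])
    stacked = p.data[..., order]
    codes = codes[order]
    best = np.argmax(stacked, axis=3)
    best_p = np.max(stacked, axis=3)
    total = stacked.sum(axis=3)
    labels = codes[best].astype(np.int16)
    labels[(best_p < 0.5 * total) | (best_p <= 0)] = BG
    return LabeledVolume(labels, p.affine)


def check_canonical(v: LabeledVolume, allowed: set[int] | None = None) -> None:
    """Raise :class:`VocabularyError` if ``v`` uses non-canonical labels."""
    from .errors import VocabularyError

    allowed = allowed if allowed is not None else set(CANONICAL_LABELS)
    present = set(np.unique(v.data).tolist())
    bad = present - allowed
    if bad:
        raise VocabularyError(f"non-canonical labels present: {sorted(bad)}")
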