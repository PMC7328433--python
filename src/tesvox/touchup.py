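"""Post-segmentation repair: smoothing, disconnected-voxel removal, and
heuristic gap sealing with foramen exceptions.

Automated tissue segmentations of the head leave single-voxel specks, small
disconnected islands, and — most damaging for current-flow modeling — gaps in
the thin gray-matter, CSF and skull layers.  A brain voxel that touches skull
or scalp through such a gap short-circuits the highly conductive CSF layer and
distorts the simulated field.  The repair here seals those gaps from the
inside out (GM around exposed WM, CSF around exposed brain, skull around
exposed CSF) while honoring an exception mask that protects genuine skull
openings (optic canal, foramen magnum), which are real conduits of current
into the head and must not be walled off.

Connectivity is 6-connectivity (shared faces) throughout: it is the strictest
notion of "touching" and prevents diagonal leakage of current paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import AlignmentError
from .volumes import (
    AIR,
    BG,
    CSF,
    ELECTRODE,
    GEL,
    GM,
    SCALP,
    SKULL,
    TISSUE_PRECEDENCE,
    WM,
    LabeledVolume,
    check_canonical,
)

#: 6-connectivity structuring element (faces only).
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class TouchupConfig:
    """Morphology parameters for the repair.

    The released tools in this field describe these parameters only as
    "selected conservatively", so they are exposed with conservative defaults:
    a 1 mm smoothing ball (a no-op at resolutions coarser than 2 mm) and a 5%
    minimum component fraction.
    """

    smoothing_radius_mm: float = 1.0
    min_component_fraction: float = 0.05
    exception_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.smoothing_radius_mm < 0:
            raise ValueError("smoothing_radius_mm must be non-negative")
        if not (0 <= self.min_component_fraction < 1):
            raise ValueError("min_component_fraction must be in [0, 1)")

    def mask_for(self, v: LabeledVolume) -> np.ndarray:
        if self.exception_mask is None:
            return np.zeros(v.data.shape, dtype=bool)
        m = np.asarray(self.exception_mask)
        if m.shape != v.data.shape:
            raise AlignmentError(
                f"exception mask shape {m.shape} does not match volume {v.data.shape}"
            )
        return m.astype(bool)


def _ball(radius_mm: float, voxel_mm: np.ndarray) -> np.ndarray | None:
    """Ellipsoidal footprint of a radius_mm ball at the grid's resolution;
    None when the ball is smaller than one voxel (identity)."""
    semi = radius_mm / voxel_mm
    if np.all(semi < 1.0):
        return None
    half = np.floor(semi).astype(int)
    grids = np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij")
    d2 = sum((g / s) ** 2 for g, s in zip(grids, semi))
    return d2 <= 1.0 + 1e-9


def smooth_masks(v: LabeledVolume, cfg: TouchupConfig) -> LabeledVolume:
    """Morphological open-then-close of every tissue mask.

    Tissues are processed in the fixed order WM, GM, CSF, skull, scalp, air
    cavity; voxels claimed by several smoothed masks go to the
    highest-precedence tissue, voxels claimed by none become background.  The
    head may not grow beyond the original scalp dilated by one voxel.
    """
    check_canonical(v)
    out = v.copy()
    footprint = _ball(cfg.smoothing_radius_mm, v.voxel_sizes)
    if footprint is None:
        return out
    labels = v.data
    new = np.zeros_like(labels)
    claimed = np.zeros(labels.shape, dtype=bool)
    for tissue in TISSUE_PRECEDENCE:  # high precedence claims first
        mask = labels == tissue
        if not mask.any():
            continue
        sm = ndimage.binary_opening(mask, structure=footprint)
        sm = ndimage.binary_closing(sm, structure=footprint)
        take = sm & ~claimed
        new[take] = tissue
        claimed |= take
    # electrodes/gel, if present, pass through untouched
    for tissue in (GEL, ELECTRODE):
        keep = labels == tissue
        new[keep] = tissue
        claimed |= keep
    # clip to the original head extent dilated by one voxel
    head = labels != BG
    allowed = ndimage.binary_dilation(head, structure=STRUCT_6)
    new[~allowed] = BG
    out.data = new
    return out


def remove_disconnected(v: LabeledVolume, cfg: TouchupConfig) -> LabeledVolume:
    """Relabel small disconnected islands of each tissue.

    For every tissue, 6-connected components strictly smaller than
    ``min_component_fraction`` x (largest component) are relabeled to the
    modal label of their boundary neighbors; the largest component is always
    retained.  Absent tissues are a no-op.
    """
    check_canonical(v)
    out = v.copy()
    labels = out.data
    for tissue in TISSUE_PRECEDENCE:
        mask = labels == tissue
        if not mask.any():
            continue
        comp, ncomp = ndimage.label(mask, structure=STRUCT_6)
        if ncomp <= 1:
            continue
        sizes = np.bincount(comp.ravel())[1:]  # component ids are 1-based
        threshold = cfg.min_component_fraction * sizes.max()
        for cid in np.nonzero(sizes < threshold)[0] + 1:
            blob = comp == cid
            ring = ndimage.binary_dilation(blob, structure=STRUCT_6) & ~blob
            neighbor_labels = labels[ring]
            neighbor_labels = neighbor_labels[neighbor_labels != tissue]
            if len(neighbor_labels) == 0:
                continue
            # lowest label wins ties (bincount argmax), i.e. precedence order
            modal = int(np.bincount(neighbor_labels).argmax())
            labels[blob] = modal
    return out


def _adjacent_to_any(labels: np.ndarray, targets: tuple[int, ...]) -> np.ndarray:
    hit = np.isin(labels, targets)
    out = np.zeros_like(hit)
    out[1:, :, :] |= hit[:-1, :, :]
    out[:-1, :, :] |= hit[1:, :, :]
    out[:, 1:, :] |= hit[:, :-1, :]
    out[:, :-1, :] |= hit[:, 1:, :]
    out[:, :, 1:] |= hit[:, :, :-1]
    out[:, :, :-1] |= hit[:, :, 1:]
    return out


def seal_gaps(v: LabeledVolume, cfg: TouchupConfig) -> LabeledVolume:
    """Seal gaps in the GM/CSF/skull layers by converting offending neighbors.

    Three rules, iterated to a fixed point:

    b) GM rule (first): any CSF/skull/scalp/background voxel face-adjacent to
       a WM voxel becomes GM.
    a) CSF rule: any skull/scalp/background/air-cavity voxel face-adjacent to
       a brain (WM or GM) voxel becomes CSF — except inside the exception
       mask.
    c) skull rule: any scalp/background voxel face-adjacent to a CSF voxel
       becomes skull — except inside the exception mask.

    WM, GM, gel and electrode voxels are never relabeled.  Termination is
    guaranteed: every conversion moves a voxel toward interior tissue and no
    rule undoes another's conversions.
    """
    check_canonical(v)
    out = v.copy()
    labels = out.data
    exception = cfg.mask_for(v)
    while True:
        changed = False
        # (b) GM around exposed WM
        target = np.isin(labels, (CSF, SKULL, SCALP, BG))
        conv = target & _adjacent_to_any(labels, (WM,))
        if conv.any():
            labels[conv] = GM
            changed = True
        # (a) CSF around exposed brain
        target = np.isin(labels, (SKULL, SCALP, BG, AIR)) & ~exception
        conv = target & _adjacent_to_any(labels, (WM, GM))
        if conv.any():
            labels[conv] = CSF
            changed = True
        # (c) skull around exposed CSF
        target = np.isin(labels, (SCALP, BG)) & ~exception
        conv = target & _adjacent_to_any(labels, (CSF,))
        if conv.any():
            labels[conv] = SKULL
            changed = True
        if not changed:
            return out


def run_touchup(v: LabeledVolume, cfg: TouchupConfig | None = None) -> LabeledVolume:
    """Full repair: smooth, remove islands, then seal gaps.

    On completion no WM/GM voxel is face-adjacent to skull, scalp or
    background outside the exception mask, and reapplying the repair to its
    own output changes nothing.
    """
    cfg = cfg or TouchupConfig()
    out = smooth_masks(v, cfg)
    out = remove_disconnected(out, cfg)
    out = seal_gaps(out, cfg)
    return out


def brain_exposure(v: LabeledVolume, exception_mask: np.ndarray | None = None) -> int:
    """Number of WM/GM voxels face-adjacent to skull/scalp/background through
    non-excepted voxels — the quantity run_touchup drives to zero."""
    labels = v.data
    offending = np.isin(labels, (SKULL, SCALP, BG))
    if exception_mask is not None:
        offending &= ~exception_mask.astype(bool)
    exposed = np.isin(labels, (WM, GM)) & _adjacent_to_any(
        np.where(offending, labels, -1), (SKULL, SCALP, BG)
    )
    return int(exposed.sum())
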