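"""Quantitative comparison of field and segmentation volumes, and the
prediction-validation statistics.

Field comparisons use the voxelwise Euclidean norm of the vector difference,
d = ||E_A - E_B||, restricted (when two label volumes are supplied) to voxels
where both segmentations agree — differences in the field should not be
conflated with differences in tissue assignment.  Segmentation differences
are reported as absolute symmetric-difference volumes in cm^3 per tissue
rather than overlap scores: for large structures a Dice coefficient saturates
near 1 and hides exactly the thin-layer discrepancies that matter for current
flow, so Dice is available only as a secondary output.

Prediction validation regresses measurement on prediction: the Pearson
correlation r captures whether the spatial pattern is right, and the slope s
of the ordinary-least-squares fit (prediction as the independent variable,
intercept included) captures whether the magnitude is right — s = 1 means
correct magnitude.  The intercept absorbs the arbitrary additive constant of
any voltage-based readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import AlignmentError, UndefinedStatisticError
from .volumes import GM, WM, FieldVolume, LabeledVolume


@dataclass
class ComparisonResult:
    """Voxelwise field-difference volume with per-tissue summaries."""

    d: np.ndarray  # scalar |E_A - E_B| (V/m); NaN where not compared
    mask: np.ndarray  # where the comparison was evaluated
    per_tissue: "object"  # pandas DataFrame: label, tissue, mean, median
    hist_bins: np.ndarray  # brain-voxel histogram bin edges
    hist_counts: np.ndarray


@dataclass
class ValidationStats:
    r: float  # Pearson correlation
    s: float  # OLS slope, measurement ~ prediction
    intercept: float
    n: int


def field_difference(
    EA: FieldVolume,
    EB: FieldVolume,
    labels: tuple[LabeledVolume, LabeledVolume] | None = None,
    n_bins: int = 50,
) -> ComparisonResult:
    """Voxelwise d = ||E_A - E_B|| with per-tissue means and a brain histogram.

    With a pair of label volumes the comparison is restricted to voxels whose
    labels agree; the histogram is over the brain (WM + GM) voxels of the
    comparison mask.
    """
    import pandas as pd

    if EA.data.shape != EB.data.shape or not np.allclose(EA.affine, EB.affine):
        raise AlignmentError("field volumes are not on the same grid")
    d = np.linalg.norm(EA.data - EB.data, axis=3)
    shape = d.shape
    if labels is not None:
        a, b = labels
        if a.data.shape != shape or b.data.shape != shape:
            raise AlignmentError("label volumes do not match the field grid")
        mask = (a.data == b.data) & (a.data > 0)
        ref = a
    else:
        mask = np.ones(shape, dtype=bool)
        ref = None
    dm = np.where(mask, d, np.nan)
    rows = []
    if ref is not None:
        for lab in sorted(np.unique(ref.data[mask]).tolist()):
            sel = mask & (ref.data == lab)
            rows.append(
                {
                    "label": int(lab),
                    "tissue": ref.label_table.get(int(lab), str(lab)),
                    "voxels": int(sel.sum()),
                    "mean_d_V_per_m": float(d[sel].mean()),
                    "median_d_V_per_m": float(np.median(d[sel])),
                }
            )
        brain = mask & np.isin(ref.data, (WM, GM))
    else:
        brain = mask
    vals = d[brain]
    if vals.size:
        counts, bins = np.histogram(vals, bins=n_bins)
    else:
        counts, bins = np.zeros(n_bins, dtype=int), np.linspace(0, 1, n_bins + 1)
    return ComparisonResult(
        d=dm, mask=mask, per_tissue=pd.DataFrame(rows), hist_bins=bins, hist_counts=counts
    )


def segmentation_difference(
    a: LabeledVolume,
    b: LabeledVolume,
    fov_mask: np.ndarray | None = None,
):
    """Absolute per-tissue symmetric-difference volumes in cm^3.

    For each tissue, the volume of voxels that exactly one of the two
    segmentations assigns to it, scaled by the voxel volume; optionally
    restricted to a field-of-view mask.
    """
    import pandas as pd

    if a.data.shape != b.data.shape or not np.allclose(a.affine, b.affine):
        raise AlignmentError("label volumes are not on the same grid")
    scope = (
        np.ones(a.data.shape, dtype=bool) if fov_mask is None else fov_mask.astype(bool)
    )
    vox_cm3 = a.voxel_volume_mm3 / 1000.0
    tissues = sorted(
        set(np.unique(a.data[scope]).tolist()) | set(np.unique(b.data[scope]).tolist())
    )
    rows = []
    for t in tissues:
        if t == 0:
            continue
        sym = ((a.data == t) ^ (b.data == t)) & scope
        rows.append(
            {
                "label": int(t),
                "tissue": a.label_table.get(int(t), str(t)),
                "difference_cm3": float(sym.sum() * vox_cm3),
            }
        )
    return pd.DataFrame(rows)


def dice_coefficient(a: LabeledVolume, b: LabeledVolume, tissue: int) -> float:
    """Secondary overlap score 2|A∩B|/(|A|+|B|) for one tissue."""
    ma, mb = a.data == tissue, b.data == tissue
    denom = ma.sum() + mb.sum()
    if denom == 0:
        raise UndefinedStatisticError(f"tissue {tissue} absent from both volumes")
    return float(2.0 * (ma & mb).sum() / denom)


def validate_predictions(predicted: np.ndarray, measured: np.ndarray) -> ValidationStats:
    """Pearson r and best-linear-fit slope of measurement against prediction.

    The prediction is the independent variable; the intercept is fitted (it
    absorbs any additive gauge offset) but is reported only as metadata.
    """
    predicted = np.asarray(predicted, dtype=float).ravel()
    measured = np.asarray(measured, dtype=float).ravel()
    if predicted.shape != measured.shape or len(predicted) < 3:
        raise UndefinedStatisticError(
            "need equal-length prediction/measurement vectors with n >= 3"
        )
    if not (np.all(np.isfinite(predicted)) and np.all(np.isfinite(measured))):
        raise UndefinedStatisticError("non-finite values in inputs")
    if np.ptp(predicted) == 0 or np.ptp(measured) == 0:
        raise UndefinedStatisticError("zero variance makes r and s undefined")
    fit = stats.linregress(predicted, measured)
    return ValidationStats(
        r=float(fit.rvalue),
        s=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(predicted),
    )


def project_field(E: FieldVolume, direction: np.ndarray) -> np.ndarray:
    """Scalar projection of the field onto a unit vector.

    In-vivo recordings between adjacent electrodes measure the field's
    projection onto their separation direction, not its magnitude; apply this
    before validating against such measurements.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return E.data @ d
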