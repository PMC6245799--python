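"""Parametric response mapping (PRM) of paired lung CT and Pi10.

Voxels of co-registered inspiratory/expiratory CT volumes are jointly
thresholded within a lung mask:

* emphysema:    inspiratory HU < -950
* fSAD:         inspiratory HU > -950 and expiratory HU < -856
  (functional small-airways disease, i.e. non-emphysematous gas trapping)
* normal:       inspiratory HU > -950 and expiratory HU >= -856
* unclassified: inspiratory HU exactly -950 (the class inequalities are
  strict on both sides; with integer HU this is a real case).  A switch
  folds these voxels into the normal class instead.

Registration of expiration to inspiration is assumed done upstream; the
classification accepts an optional alignment hook that defaults to the
identity.  Percentages are reported over masked voxels (whole-lung
denominator, the PRM-literature convention).

Pi10 standardizes airway wall thickness: the square root of wall area is
regressed on internal perimeter across measured airways and the fitted
value at a perimeter of 10 mm is reported.
"""

from __future__ import annotations

import warnings
from collections.abc import Callable
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "OUTSIDE_MASK",
    "EMPHYSEMA",
    "FSAD",
    "NORMAL",
    "UNCLASSIFIED",
    "PRMSummary",
    "classify_prm_voxels",
    "summarize_prm",
    "compute_pi10",
    "ellipsoid_mask",
    "load_volume",
    "save_volume",
]

# label codes of the PRM label volume
OUTSIDE_MASK = 0
EMPHYSEMA = 1
FSAD = 2
NORMAL = 3
UNCLASSIFIED = 4

INSP_THRESHOLD_HU = -950.0
EXP_THRESHOLD_HU = -856.0

HU_RANGE = (-1024.0, 3071.0)


@dataclass(frozen=True)
class PRMSummary:
    """Per-subject PRM percentages over masked voxels."""

    pct_emphysema: float
    pct_fsad: float
    pct_normal: float
    pct_unclassified: float
    n_masked: int

    def as_dict(self) -> dict:
        return asdict(self)


def classify_prm_voxels(
    insp: np.ndarray,
    exp: np.ndarray,
    mask: np.ndarray,
    *,
    insp_threshold: float = INSP_THRESHOLD_HU,
    exp_threshold: float = EXP_THRESHOLD_HU,
    fold_unclassified_to_normal: bool = False,
    align: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Label every voxel of a co-registered inspiratory/expiratory pair.

    ``align`` is an optional hook mapping the expiratory volume into the
    inspiratory frame (identity by default; deformable registration is
    out of scope).  Returns a uint8 volume with the module's label codes,
    ``OUTSIDE_MASK`` exactly where the mask is false.
    """
    insp = np.asarray(insp, dtype=float)
    exp = np.asarray(exp, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if align is not None:
        exp = np.asarray(align(exp), dtype=float)
    if insp.shape != exp.shape or insp.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: insp {insp.shape}, exp {exp.shape}, mask {mask.shape}"
        )
    if not (np.isfinite(insp[mask]).all() and np.isfinite(exp[mask]).all()):
        raise ValueError("non-finite HU values inside the lung mask")
    for name, vol in (("inspiratory", insp), ("expiratory", exp)):
        vals = vol[mask]
        if vals.size and (vals.min() < HU_RANGE[0] or vals.max() > HU_RANGE[1]):
            warnings.warn(
                f"{name} HU outside the plausible CT range {HU_RANGE}",
                stacklevel=2,
            )

    labels = np.zeros(insp.shape, dtype=np.uint8)
    emph = mask & (insp < insp_threshold)
    fsad = mask & (insp > insp_threshold) & (exp < exp_threshold)
    normal = mask & (insp > insp_threshold) & (exp >= exp_threshold)
    uncls = mask & (insp == insp_threshold)
    labels[emph] = EMPHYSEMA
    labels[fsad] = FSAD
    labels[normal] = NORMAL
    labels[uncls] = NORMAL if fold_unclassified_to_normal else UNCLASSIFIED
    return labels


def summarize_prm(labels: np.ndarray) -> PRMSummary:
    """Percentages of each PRM class over masked voxels."""
    labels = np.asarray(labels)
    n_masked = int((labels != OUTSIDE_MASK).sum())
    if n_masked == 0:
        raise ValueError("empty lung mask: no voxels to summarize")
    pct = lambda code: 100.0 * float((labels == code).sum()) / n_masked
    return PRMSummary(
        pct_emphysema=pct(EMPHYSEMA),
        pct_fsad=pct(FSAD),
        pct_normal=pct(NORMAL),
        pct_unclassified=pct(UNCLASSIFIED),
        n_masked=n_masked,
    )


def compute_pi10(
    internal_perimeter_mm: np.ndarray,
    wall_area_mm2: np.ndarray,
) -> float:
    """Square root of wall area at a standardized 10 mm internal perimeter.

    Fits sqrt(wall area) on internal perimeter by ordinary least squares
    across the measured airways and evaluates the line at 10 mm.  A
    single airway is accepted only if it was measured exactly at a 10 mm
    perimeter.
    """
    per = np.asarray(internal_perimeter_mm, dtype=float)
    wa = np.asarray(wall_area_mm2, dtype=float)
    if per.shape != wa.shape or per.ndim != 1 or per.size == 0:
        raise ValueError("perimeters and wall areas must be matching 1-D arrays")
    if np.any(per <= 0) or np.any(wa <= 0):
        raise ValueError("perimeters and wall areas must be positive")
    if per.size == 1:
        if np.isclose(per[0], 10.0):
            return float(np.sqrt(wa[0]))
        raise ValueError("a single airway must be measured at a 10 mm perimeter")
    if np.unique(per).size < 2:
        raise ValueError("at least two distinct internal perimeters are required")
    slope, intercept = np.polyfit(per, np.sqrt(wa), 1)
    return float(intercept + slope * 10.0)


def ellipsoid_mask(
    shape: tuple[int, int, int],
    semiaxes: tuple[float, float, float] | None = None,
    center: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Solid ellipsoid lung-mask stand-in used by the synthetic volumes."""
    shape = tuple(int(s) for s in shape)
    if center is None:
        center = tuple((s - 1) / 2.0 for s in shape)
    if semiaxes is None:
        semiaxes = tuple(max(s * 0.45, 1.0) for s in shape)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    mask = r2 <= 1.0
    if not mask.any():
        raise ValueError("ellipsoid mask is empty for the requested geometry")
    return mask


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns the data array and voxel spacing (mm)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def save_volume(path, data: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write an array as NIfTI with a diagonal affine from the spacing."""
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
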