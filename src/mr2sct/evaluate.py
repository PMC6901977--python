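"""HU error metrics and tissue-stratified cohort reports.

Synthetic-CT accuracy is quantified per subject by the mean absolute error
(MAE) and mean error (ME) between true and synthetic CT over the body
outline::

    MAE = (1/n) Σ |CT(i) − sCT(i)|        ME = (1/n) Σ (CT(i) − sCT(i))

so a *positive* ME means the synthetic CT underestimates HU.  The body mask
comes from Otsu's threshold on the true CT followed by morphological
operations (closing, hole filling, largest connected component), and a
300-HU threshold on the *true* CT splits the body into bone and soft
tissue.  Cohort reports follow the usual six-column layout
(MAE/ME × soft/bone/overall) with a mean ± SD summary row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .grids import ImageGrid

#: HU threshold separating bone from soft tissue on the true CT
BONE_HU_THRESHOLD = 300.0

REPORT_COLUMNS = ["mae_soft", "mae_bone", "mae_overall",
                  "me_soft", "me_bone", "me_overall"]


def _arr(img) -> np.ndarray:
    return img.data if isinstance(img, ImageGrid) else np.asarray(img, float)


# --------------------------------------------------------------------------
# masks
# --------------------------------------------------------------------------


def otsu_foreground(image, min_separation: float = 0.0) -> np.ndarray:
    """Foreground mask from Otsu's threshold on the intensity histogram.

    Raises if the histogram is degenerate (constant image) or, when
    ``min_separation`` is set, if the two Otsu classes are closer than that
    — the signature of an image with no real foreground.
    """
    a = _arr(image)
    if np.ptp(a) == 0:
        raise ValueError("cannot threshold a constant image")
    thr = threshold_otsu(a)
    fg = a > thr
    if not fg.any() or fg.all():
        raise ValueError("Otsu threshold produced an empty class")
    if min_separation > 0:
        if a[fg].mean() - a[~fg].mean() < min_separation:
            raise ValueError(
                "Otsu classes are not separated enough: no foreground found")
    return fg


def body_mask(ct, closing_radius: int = 3,
              min_separation: float = 300.0) -> np.ndarray:
    """Body outline of a CT slice.

    Otsu's threshold separates background air from the body; binary closing
    (disk of ``closing_radius`` px), hole filling and largest-connected-
    component selection clean the mask.  ``min_separation`` (HU) guards
    against images with no body: on an all-air slice the two Otsu classes
    are only noise apart and an error is raised.
    """
    fg = otsu_foreground(ct, min_separation=min_separation)
    fg = morphology.closing(fg, morphology.disk(closing_radius))
    fg = ndimage.binary_fill_holes(fg)
    lab = measure.label(fg)
    if lab.max() == 0:
        raise ValueError("no body component found")
    sizes = np.bincount(lab.ravel())[1:]
    return lab == (int(np.argmax(sizes)) + 1)


@dataclass
class RegionMasks:
    """Body partition: bone = body ∧ (true CT > threshold); soft = rest."""

    body: np.ndarray
    bone: np.ndarray
    soft: np.ndarray

    def __post_init__(self) -> None:
        if (self.bone & self.soft).any():
            raise ValueError("bone and soft masks must be disjoint")
        if not ((self.bone | self.soft) == self.body).all():
            raise ValueError("bone and soft masks must partition the body")


def split_tissues(ct_true, body: np.ndarray,
                  threshold: float = BONE_HU_THRESHOLD) -> RegionMasks:
    """Split the body into bone and soft tissue on the *true* CT only."""
    body = np.asarray(body, bool)
    if not body.any():
        raise ValueError("empty body mask")
    bone = body & (_arr(ct_true) > threshold)
    return RegionMasks(body=body, bone=bone, soft=body & ~bone)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


def _check(ct, sct, mask) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a, b = _arr(ct), _arr(sct)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    m = np.asarray(mask, bool)
    if m.shape != a.shape:
        raise ValueError("mask shape mismatch")
    if not m.any():
        raise ValueError("empty mask")
    return a, b, m


def mae(ct, sct, mask) -> float:
    """Mean absolute HU error over the mask."""
    a, b, m = _check(ct, sct, mask)
    return float(np.mean(np.abs(a[m] - b[m])))


def me(ct, sct, mask) -> float:
    """Mean signed HU error (CT − sCT); positive = sCT underestimates."""
    a, b, m = _check(ct, sct, mask)
    return float(np.mean(a[m] - b[m]))


def difference_map(ct, sct) -> ImageGrid:
    """Per-pixel |CT − sCT| map (gray-scale renderable)."""
    a, b = _arr(ct), _arr(sct)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    spacing = ct.spacing if isinstance(ct, ImageGrid) else (1.0, 1.0)
    return ImageGrid(np.abs(a - b), spacing=spacing, modality="CT", units="HU",
                     meta={"kind": "absolute difference map"})


def evaluate_pair(ct, sct, body: np.ndarray | None = None,
                  threshold: float = BONE_HU_THRESHOLD) -> dict:
    """Six Table-style metrics for one subject (pooled over its pixels)."""
    if body is None:
        body = body_mask(ct)
    regions = split_tissues(ct, body, threshold)
    out = {}
    for name, m in (("soft", regions.soft), ("bone", regions.bone),
                    ("overall", regions.body)):
        out[f"mae_{name}"] = mae(ct, sct, m)
        out[f"me_{name}"] = me(ct, sct, m)
    return out


# --------------------------------------------------------------------------
# cohort report
# --------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-subject metrics plus cohort mean ± SD (population SD)."""

    per_subject: pd.DataFrame  # one row per subject, REPORT_COLUMNS
    mean: pd.Series
    sd: pd.Series

    def to_csv(self, path) -> None:
        table = self.per_subject.copy()
        table.loc["mean"] = self.mean
        table.loc["sd"] = self.sd
        table.to_csv(path)

    def __str__(self) -> str:
        lines = [self.per_subject.round(1).to_string()]
        lines.append("mean ± sd: " + "  ".join(
            f"{c}={self.mean[c]:.0f}±{self.sd[c]:.0f}" for c in REPORT_COLUMNS))
        return "\n".join(lines)


def cohort_report(subjects: list, threshold: float = BONE_HU_THRESHOLD) -> EvalReport:
    """Evaluate a list of (true CT, synthetic CT) subject pairs.

    Metrics are pooled over each subject's pixels (per-subject, not
    per-slice); the summary row is the cohort mean with population SD.
    """
    if not subjects:
        raise ValueError("cohort_report requires at least one subject")
    rows = [evaluate_pair(ct, sct, threshold=threshold) for ct, sct in subjects]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS,
                      index=[f"subject_{i + 1}" for i in range(len(rows))])
    return EvalReport(per_subject=df, mean=df.mean(), sd=df.std(ddof=0))
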