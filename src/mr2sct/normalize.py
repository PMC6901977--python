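"""MR intensity standardization by decile-landmark histogram matching.

T2-weighted MR intensities are arbitrary and drift between scans, which
degrades both multimodal registration and intensity-based learning.  The
standardization used here is the classical two-stage landmark scheme:

1. *fit* — for each training image, record its intensity landmarks (a low
   percentile cap, the interior decile percentiles 10th…90th, and a high
   cap) over the Otsu foreground; the cohort **standard scale** is the
   per-landmark mean across training images;
2. *apply* — map each image onto the standard scale by the piecewise-linear
   transform sending its own landmarks onto the standard landmarks.

The transform is monotone, maps each landmark exactly onto its standard
counterpart, and is clamped to the standard caps outside the cap range.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .evaluate import otsu_foreground
from .grids import ImageGrid

#: interior percentiles of the default decile-landmark convention
DECILES = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)

#: default percentile caps suppressing outlier tails
DEFAULT_CAPS = (1.0, 99.0)


@dataclass(frozen=True)
class LandmarkScale:
    """Ordered intensity landmarks (low cap, interior deciles, high cap)."""

    landmarks: np.ndarray

    def __post_init__(self) -> None:
        lm = np.asarray(self.landmarks, float)
        object.__setattr__(self, "landmarks", lm)
        if lm.ndim != 1 or lm.size < 3:
            raise ValueError("need at least 3 landmarks (caps plus interior)")
        if np.any(np.diff(lm) < 0):
            raise ValueError("landmarks must be non-decreasing")

    def __len__(self) -> int:
        return self.landmarks.size

    @property
    def interior(self) -> np.ndarray:
        return self.landmarks[1:-1]

    def fingerprint(self) -> str:
        return hashlib.sha256(
            np.round(self.landmarks, 6).tobytes()).hexdigest()[:16]


class StandardScale(LandmarkScale):
    """Cohort standard scale: per-position mean of training LandmarkScales."""


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def compute_landmarks(image, foreground_mask: np.ndarray | None = None,
                      caps: tuple[float, float] = DEFAULT_CAPS,
                      interior_percentiles: tuple[float, ...] = DECILES,
                      ) -> LandmarkScale:
    """Decile landmarks of an image's foreground intensity histogram.

    Percentiles use linear interpolation between order statistics (the
    numpy default).  If no mask is given, the Otsu foreground of the image
    is used.  ``interior_percentiles`` is configurable for other landmark
    conventions; the default is the nine decile boundaries 10th…90th (the
    median is the 50th).  Constant images raise; a near-constant histogram
    yields flat (non-strict) landmark runs, which `apply_standardization`
    rejects when used as the *own* scale.
    """
    low, high = caps
    if not (0 <= low < high <= 100):
        raise ValueError("caps must satisfy 0 <= low < high <= 100")
    a = image.data if isinstance(image, ImageGrid) else np.asarray(image, float)
    if foreground_mask is None:
        foreground_mask = otsu_foreground(a)
    m = np.asarray(foreground_mask, bool)
    if not m.any():
        raise ValueError("empty foreground mask")
    vals = a[m]
    if np.ptp(vals) == 0:
        raise ValueError("constant image: degenerate histogram")
    pct = np.percentile(vals, [low, *interior_percentiles, high])
    return LandmarkScale(pct)


def _pool_adjacent_violators(v: np.ndarray) -> np.ndarray:
    """Isotonic (non-decreasing) projection by pool-adjacent-violators."""
    values = list(map(float, v))
    weights = [1.0] * len(values)
    out_v: list[float] = []
    out_w: list[float] = []
    for val, w in zip(values, weights):
        out_v.append(val)
        out_w.append(w)
        while len(out_v) > 1 and out_v[-2] > out_v[-1]:
            v2, w2 = out_v.pop(), out_w.pop()
            v1, w1 = out_v.pop(), out_w.pop()
            out_v.append((v1 * w1 + v2 * w2) / (w1 + w2))
            out_w.append(w1 + w2)
    result = []
    for val, w in zip(out_v, out_w):
        result.extend([val] * int(round(w)))
    return np.array(result)


def fit_standard_scale(scales: list[LandmarkScale]) -> StandardScale:
    """Element-wise mean of cohort landmark scales.

    Means of monotone vectors are monotone, so the isotonic repair (pool
    adjacent violators) only ever triggers on numerical ties.
    """
    if not scales:
        raise ValueError("need at least one LandmarkScale")
    lengths = {len(s) for s in scales}
    if len(lengths) != 1:
        raise ValueError(f"mixed landmark lengths: {sorted(lengths)}")
    mean = np.mean([s.landmarks for s in scales], axis=0)
    if np.any(np.diff(mean) < 0):
        mean = _pool_adjacent_violators(mean)
    return StandardScale(mean)


def apply_standardization(image, own: LandmarkScale,
                          std: StandardScale) -> ImageGrid:
    """Map an MR image onto the standard scale.

    Piecewise-linear between landmarks (each own landmark maps exactly onto
    the corresponding standard landmark); beyond the caps the boundary
    segments are extended linearly, so background air keeps its contrast
    with the foreground instead of being pinned to the cap value.  The own
    scale must be strictly increasing, otherwise the map is ill-defined.
    """
    if len(own) != len(std):
        raise ValueError("own and standard scales must have the same length")
    x = own.landmarks
    y = std.landmarks
    if np.any(np.diff(x) <= 0):
        raise ValueError("own landmark scale is not strictly increasing")
    a = image.data if isinstance(image, ImageGrid) else np.asarray(image, float)
    out = np.interp(a, x, y)
    lo = a < x[0]
    hi = a > x[-1]
    out[lo] = y[0] + (a[lo] - x[0]) * (y[1] - y[0]) / (x[1] - x[0])
    out[hi] = y[-1] + (a[hi] - x[-1]) * (y[-1] - y[-2]) / (x[-1] - x[-2])
    if isinstance(image, ImageGrid):
        res = image.with_data(out, units="standardized")
        res.meta["standard_scale"] = std.fingerprint()
        return res
    return ImageGrid(out, modality="MR", units="standardized",
                     meta={"standard_scale": std.fingerprint()})


def standardize_cohort(train_images: list, all_images: list | None = None,
                       caps: tuple[float, float] = DEFAULT_CAPS,
                       ) -> tuple[StandardScale, list[ImageGrid]]:
    """Fit the standard scale on training images and standardize a set.

    The scale is fitted on ``train_images`` only (no leakage); each image in
    ``all_images`` (default: the training images) is then mapped through its
    *own* landmarks onto the standard scale.
    """
    scales = [compute_landmarks(img, caps=caps) for img in train_images]
    std = fit_standard_scale(scales)
    targets = all_images if all_images is not None else train_images
    out = [apply_standardization(img, compute_landmarks(img, caps=caps), std)
           for img in targets]
    return std, out


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------


def save_scale(scale: LandmarkScale, path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {"landmarks": scale.landmarks.tolist(),
         "standard": isinstance(scale, StandardScale)}, indent=2))


def load_scale(path: str | Path) -> LandmarkScale:
    d = json.loads(Path(path).read_text())
    cls = StandardScale if d.get("standard") else LandmarkScale
    return cls(np.asarray(d["landmarks"], float))
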