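"""Intensity-based 2-D CT/MR registration.

Implements the registration design used for CT↔MR alignment in
MRI-only-planning pipelines: a multi-resolution rigid stage driven by
Mattes-style mutual information (Parzen-smoothed joint histogram), followed
by an optional coarse B-spline deformable refinement whose objective is
MI minus a bending-energy smoothness penalty.

Everything is deliberately 2-D and self-contained: the similarity metric,
the pyramid, the optimizers and the transform algebra are all implemented
here so that each stated algorithmic choice is individually testable.

Coordinate convention
---------------------
Transforms are *pull-back* maps: ``warp(img, T)`` produces
``out(p) = img(T(p))`` for every output pixel ``p``; rigid transforms rotate
about the image centre.  Composition ``a.compose(b)`` is the map
``p -> a(b(p))``, i.e. the transform equivalent to warping with ``b`` first
and then ``a``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize
from scipy.interpolate import RectBivariateSpline

from .grids import AIR_HU, ImageGrid

# --------------------------------------------------------------------------
# transforms
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation (degrees, about the image centre) plus translation (pixels).

    ``translation`` is ``(tx, ty)`` in (column, row) pixel units.
    """

    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls(0.0, (0.0, 0.0))

    @property
    def is_identity(self) -> bool:
        return self.rotation == 0.0 and self.translation == (0.0, 0.0)

    def matrix(self) -> np.ndarray:
        """2×2 rotation matrix acting on (x, y) offsets from the centre."""
        th = math.radians(self.rotation)
        c, s = math.cos(th), math.sin(th)
        return np.array([[c, -s], [s, c]])

    def apply(self, x: np.ndarray, y: np.ndarray,
              shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Map output-grid coordinates to input coordinates."""
        cy = (shape[0] - 1) / 2.0
        cx = (shape[1] - 1) / 2.0
        dx, dy = x - cx, y - cy
        m = self.matrix()
        tx, ty = self.translation
        xin = m[0, 0] * dx + m[0, 1] * dy + cx + tx
        yin = m[1, 0] * dx + m[1, 1] * dy + cy + ty
        return xin, yin

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Transform equivalent to ``p -> self(other(p))`` (same centre)."""
        m = self.matrix()
        t = m @ np.asarray(other.translation) + np.asarray(self.translation)
        return RigidTransform2D(self.rotation + other.rotation,
                                (float(t[0]), float(t[1])))

    def inverse(self) -> "RigidTransform2D":
        m = self.matrix().T  # R^{-1}
        t = -m @ np.asarray(self.translation)
        return RigidTransform2D(-self.rotation, (float(t[0]), float(t[1])))


@dataclass
class BSplineField:
    """Coarse free-form deformation: a control-point displacement grid.

    Control point ``(i, j)`` sits at pixel ``(i*spacing, j*spacing)`` (row,
    col); ``displacements`` has shape (ny, nx, 2) storing (dx, dy) pixels.
    The dense field is the interpolating bicubic spline through the control
    displacements, which reproduces affine fields exactly.
    """

    spacing: float
    displacements: np.ndarray

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 3 or self.displacements.shape[2] != 2:
            raise ValueError("displacements must have shape (ny, nx, 2)")
        if self.displacements.shape[0] < 4 or self.displacements.shape[1] < 4:
            raise ValueError("need at least a 4×4 control grid for cubic interpolation")

    @classmethod
    def zeros(cls, shape: tuple[int, int], spacing: float) -> "BSplineField":
        """Zero field whose control grid covers an image of ``shape``."""
        ny = max(4, int(math.ceil((shape[0] - 1) / spacing)) + 1)
        nx = max(4, int(math.ceil((shape[1] - 1) / spacing)) + 1)
        return cls(spacing, np.zeros((ny, nx, 2)))

    def _splines(self) -> tuple[RectBivariateSpline, RectBivariateSpline]:
        ny, nx = self.displacements.shape[:2]
        rows = np.arange(ny) * self.spacing
        cols = np.arange(nx) * self.spacing
        sx = RectBivariateSpline(rows, cols, self.displacements[:, :, 0], kx=3, ky=3, s=0)
        sy = RectBivariateSpline(rows, cols, self.displacements[:, :, 1], kx=3, ky=3, s=0)
        return sx, sy

    def dense(self, shape: tuple[int, int]) -> np.ndarray:
        """Dense (H, W, 2) displacement field (dx, dy) on the pixel grid."""
        sx, sy = self._splines()
        rows = np.arange(shape[0])
        cols = np.arange(shape[1])
        return np.stack([sx(rows, cols), sy(rows, cols)], axis=-1)


@dataclass(frozen=True)
class CompositeTransform:
    """Rigid initialization followed by a deformable refinement.

    Pull-back rule: ``p -> rigid(p + u(p))`` where ``u`` is the dense field
    (the field refines residual misalignment after the rigid stage).
    """

    rigid: RigidTransform2D
    field: BSplineField


@dataclass
class RegistrationResult:
    transform: RigidTransform2D | CompositeTransform
    metric: float
    trace: list = dc_field(default_factory=list)
    low_confidence: bool = False


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------


def _default_fill(image: ImageGrid | np.ndarray) -> float:
    if isinstance(image, ImageGrid) and image.modality == "CT":
        return AIR_HU
    return 0.0


def warp(image: ImageGrid | np.ndarray,
         transform: RigidTransform2D | BSplineField | CompositeTransform,
         fill: float | None = None):
    """Resample an image through a transform with linear interpolation.

    Out-of-field pixels take ``fill`` (air HU for CT, 0 for MR by default).
    The identity rigid transform returns a bit-identical copy.
    """
    arr = image.data if isinstance(image, ImageGrid) else np.asarray(image, float)
    if fill is None:
        fill = _default_fill(image)
    if isinstance(transform, RigidTransform2D) and transform.is_identity:
        out = arr.copy()
    else:
        yy, xx = np.mgrid[0:arr.shape[0], 0:arr.shape[1]].astype(float)
        if isinstance(transform, RigidTransform2D):
            xin, yin = transform.apply(xx, yy, arr.shape)
        elif isinstance(transform, BSplineField):
            u = transform.dense(arr.shape)
            xin, yin = xx + u[:, :, 0], yy + u[:, :, 1]
        elif isinstance(transform, CompositeTransform):
            u = transform.field.dense(arr.shape)
            xin, yin = transform.rigid.apply(xx + u[:, :, 0], yy + u[:, :, 1], arr.shape)
        else:
            raise TypeError(f"unsupported transform type {type(transform)!r}")
        out = ndimage.map_coordinates(arr, [yin, xin], order=1, mode="constant",
                                      cval=fill)
    if isinstance(image, ImageGrid):
        return image.with_data(out)
    return out


# --------------------------------------------------------------------------
# Mattes mutual information
# --------------------------------------------------------------------------


def _bspline3(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline kernel, support |t| < 2, integral 1."""
    at = np.abs(t)
    out = np.zeros_like(at)
    m1 = at < 1
    m2 = (at >= 1) & (at < 2)
    out[m1] = (4 - 6 * at[m1] ** 2 + 3 * at[m1] ** 3) / 6.0
    out[m2] = (2 - at[m2]) ** 3 / 6.0
    return out


def _bin_weights(values: np.ndarray, bins: int, kernel: str):
    """Map samples to fractional bin coordinates and kernel weights.

    Returns (indices, weights) lists: for 'nearest' a single (idx, 1) pair,
    for 'bspline' the four nearest bins with cubic-B-spline weights.
    """
    vmin, vmax = float(values.min()), float(values.max())
    if vmax <= vmin:
        raise ValueError("cannot bin a constant image (degenerate intensity range)")
    if kernel == "nearest":
        u = (values - vmin) / (vmax - vmin) * (bins - 1e-9)
        idx = np.floor(u).astype(np.intp)
        return [(idx, np.ones_like(values, dtype=float))]
    if kernel != "bspline":
        raise ValueError(f"unknown Parzen kernel {kernel!r}")
    # keep the 4-bin support of the cubic kernel inside [0, bins)
    u = 1.5 + (values - vmin) / (vmax - vmin) * (bins - 4.0)
    base = np.floor(u).astype(np.intp)
    pairs = []
    for k in range(-1, 3):
        idx = base + k
        pairs.append((idx, _bspline3(u - idx)))
    return pairs


def joint_histogram(fixed: np.ndarray, moving: np.ndarray, bins: int = 32,
                    kernel: str = "bspline") -> np.ndarray:
    """Parzen-windowed joint intensity histogram, normalized to sum 1."""
    fw = _bin_weights(fixed.ravel(), bins, kernel)
    mw = _bin_weights(moving.ravel(), bins, kernel)
    h = np.zeros((bins, bins))
    for fi, wf in fw:
        for mi, wm in mw:
            np.add.at(h, (fi, mi), wf * wm)
    s = h.sum()
    if s <= 0:
        raise ValueError("empty joint histogram")
    return h / s


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def histogram_entropy(image: np.ndarray, bins: int = 32,
                      kernel: str = "bspline") -> float:
    """Marginal (Shannon) entropy in nats under the same binning as the MI."""
    h = np.zeros(bins)
    for idx, w in _bin_weights(np.asarray(image, float).ravel(), bins, kernel):
        np.add.at(h, idx, w)
    return _entropy(h / h.sum())


def mattes_mi(fixed: ImageGrid | np.ndarray, moving: ImageGrid | np.ndarray,
              bins: int = 32, mask: np.ndarray | None = None,
              kernel: str = "bspline") -> float:
    """Mutual information (nats) of the Parzen-smoothed joint histogram.

    Higher values mean better alignment.  ``kernel='bspline'`` (default)
    spreads each sample over the four nearest bins with cubic-B-spline
    weights; ``'nearest'`` gives the classical hard-binned histogram.
    """
    f = fixed.data if isinstance(fixed, ImageGrid) else np.asarray(fixed, float)
    m = moving.data if isinstance(moving, ImageGrid) else np.asarray(moving, float)
    if f.shape != m.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {m.shape}")
    if bins < 8:
        raise ValueError("need at least 8 histogram bins")
    if mask is not None:
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError("empty mask")
        f, m = f[mask], m[mask]
    h = joint_histogram(f, m, bins=bins, kernel=kernel)
    pf = h.sum(axis=1)
    pm = h.sum(axis=0)
    return _entropy(pf) + _entropy(pm) - _entropy(h)


# --------------------------------------------------------------------------
# rigid registration
# --------------------------------------------------------------------------


def _pyramid(arr: np.ndarray, levels: int) -> list[np.ndarray]:
    """Coarse-to-fine Gaussian pyramid; element i has factor 2**(levels-1-i)."""
    out = []
    for i in range(levels):
        factor = 2 ** (levels - 1 - i)
        if factor == 1:
            out.append(arr)
        else:
            sm = ndimage.gaussian_filter(arr, sigma=0.5 * factor)
            out.append(sm[::factor, ::factor])
    return out


def register_rigid(fixed: ImageGrid | np.ndarray, moving: ImageGrid | np.ndarray,
                   levels: int = 3, bins: int = 32, method: str = "powell",
                   kernel: str = "nearest", coarse_search: bool = True,
                   rot_range: float = 12.0, trans_range: float = 16.0,
                   mi_floor: float = 0.15, seed: int = 0,
                   max_iter: int = 200) -> RegistrationResult:
    """Multi-resolution rigid alignment maximizing mutual information.

    A coarse-to-fine pyramid (downsampled by 2 per level) is traversed; at
    each level the MI between the fixed image and the warped moving image is
    maximized over (rotation, tx, ty).  The metric is evaluated over the
    overlap domain only (out-of-field pixels are excluded, not filled), and
    uses hard binning by default: the Parzen kernel's smoothing makes the
    self-similarity optimum sit a fraction of a degree off identity on noisy
    images, while ``kernel='nearest'`` recovers identity exactly
    (``kernel='bspline'`` selects the smoothed metric).  ``method='powell'``
    uses a derivative-free direction-set search; ``method='asgd'`` uses an
    adaptive-gain stochastic finite-difference gradient ascent on a random
    pixel subset per iteration.  The coarsest level optionally starts from an
    exhaustive grid sweep so captures up to ``rot_range`` degrees and
    ``trans_range`` pixels are reliable.

    Returns the transform that pulls ``moving`` onto ``fixed``
    (``warp(moving, result.transform) ≈ fixed``).  If the final MI falls
    below ``mi_floor`` the result is flagged low-confidence.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    f = fixed.data if isinstance(fixed, ImageGrid) else np.asarray(fixed, float)
    m = moving.data if isinstance(moving, ImageGrid) else np.asarray(moving, float)
    if f.shape != m.shape:
        raise ValueError("fixed and moving must share dimensions")
    fill = _default_fill(moving)
    fpyr, mpyr = _pyramid(f, levels), _pyramid(m, levels)
    rng = np.random.default_rng(seed)

    def objective(params: np.ndarray, flev: np.ndarray, mlev: np.ndarray,
                  factor: int, subset: np.ndarray | None = None) -> float:
        t = RigidTransform2D(params[0], (params[1] / factor, params[2] / factor))
        # metric over the overlap domain only: out-of-field pixels are
        # excluded rather than filled, so the fill value cannot bias the
        # joint histogram
        w = warp(mlev, t, fill=np.nan)
        valid = ~np.isnan(w)
        if valid.sum() < 0.25 * w.size:
            return 0.0  # (near-)empty overlap: worst possible score
        fv, wv = flev[valid], w[valid]
        if subset is not None:
            sel = subset[subset < fv.size]
            fv, wv = fv[sel], wv[sel]
        try:
            return -mattes_mi(fv, wv, bins=bins, kernel=kernel)
        except ValueError:  # constant overlap etc.
            return 0.0

    params = np.zeros(3)
    w0 = warp(m, RigidTransform2D(params[0], (params[1], params[2])),
              fill=np.nan)
    if (~np.isnan(w0)).sum() < 0.25 * w0.size:
        raise ValueError(
            "fixed and moving images do not overlap at initialization; "
            "provide a better starting transform")
    trace: list[float] = []
    for i, (flev, mlev) in enumerate(zip(fpyr, mpyr)):
        factor = 2 ** (levels - 1 - i)
        if i == 0 and coarse_search:
            best = (objective(params, flev, mlev, factor), params.copy())
            rots = np.arange(-rot_range, rot_range + 1e-9, 4.0)
            ts = np.arange(-trans_range, trans_range + 1e-9, max(4.0, factor * 2.0))
            for r in rots:
                for tx in ts:
                    for ty in ts:
                        p = np.array([r, tx, ty])
                        v = objective(p, flev, mlev, factor)
                        if v < best[0]:
                            best = (v, p)
            params = best[1]
        if method == "powell":
            res = optimize.minimize(
                objective, params, args=(flev, mlev, factor),
                method="Powell",
                options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": max_iter})
            params = res.x
            trace.append(-float(res.fun))
        elif method == "asgd":
            n = flev.size
            sub = min(n, 4096)
            gain_a, gain_big_a, alpha = 8.0, 20.0, 0.602
            scale = np.array([0.5, 1.0, 1.0])  # deg vs px step scaling
            for k in range(max_iter):
                subset = rng.choice(n, size=sub, replace=False)
                grad = np.zeros(3)
                eps = np.array([0.2, 0.5, 0.5])
                for j in range(3):
                    dp = np.zeros(3)
                    dp[j] = eps[j]
                    grad[j] = (objective(params + dp, flev, mlev, factor, subset)
                               - objective(params - dp, flev, mlev, factor, subset)) / (2 * eps[j])
                step = gain_a / (gain_big_a + k + 1) ** alpha
                params = params - step * scale * grad
            trace.append(-objective(params, flev, mlev, factor))
        else:
            raise ValueError(f"unknown optimizer method {method!r}")

    transform = RigidTransform2D(float(params[0]), (float(params[1]), float(params[2])))
    final = -objective(params, fpyr[-1], mpyr[-1], 1)
    return RegistrationResult(transform=transform, metric=final, trace=trace,
                              low_confidence=final < mi_floor)


# --------------------------------------------------------------------------
# bending energy and deformable refinement
# --------------------------------------------------------------------------


def bending_energy(field: BSplineField, shape: tuple[int, int] | None = None) -> float:
    """Thin-plate bending energy of the dense displacement field.

    Integral (unit pixel area) over the image domain of
    ``uxx² + 2·uxy² + uyy²`` summed over both displacement components, with
    the second derivatives evaluated analytically from the interpolating
    spline.  Zero for any globally affine field.
    """
    ny, nx = field.displacements.shape[:2]
    if shape is None:
        shape = (int((ny - 1) * field.spacing) + 1, int((nx - 1) * field.spacing) + 1)
    rows = np.arange(shape[0], dtype=float)
    cols = np.arange(shape[1], dtype=float)
    total = 0.0
    for spl in field._splines():
        dyy = spl(rows, cols, dx=2, dy=0)
        dxy = spl(rows, cols, dx=1, dy=1)
        dxx = spl(rows, cols, dx=0, dy=2)
        total += float(np.sum(dxx ** 2 + 2 * dxy ** 2 + dyy ** 2))
    return total


def register_bspline(fixed: ImageGrid | np.ndarray, moving: ImageGrid | np.ndarray,
                     init: RigidTransform2D, grid_spacing: float,
                     penalty_weight: float = 1e-4, bins: int = 32,
                     max_iter: int = 60) -> RegistrationResult:
    """Deformable refinement after a rigid initialization.

    Maximizes ``MI − penalty_weight · bending_energy`` over the control-point
    displacements of a coarse B-spline field (L-BFGS-B with finite-difference
    gradients).  The rigid init is applied to the moving image first, so the
    field models only residual deformation.
    """
    if init is None:
        raise ValueError("register_bspline requires a rigid init (rigid stage first)")
    if grid_spacing < 4:
        raise ValueError("grid_spacing below 4 px is ill-posed at this scale")
    f = fixed.data if isinstance(fixed, ImageGrid) else np.asarray(fixed, float)
    fill = _default_fill(moving)
    m0 = warp(moving, init, fill=fill)
    m0 = m0.data if isinstance(m0, ImageGrid) else m0
    field0 = BSplineField.zeros(f.shape, grid_spacing)
    shape_cp = field0.displacements.shape
    trace: list[float] = []

    def objective(flat: np.ndarray) -> float:
        fld = BSplineField(grid_spacing, flat.reshape(shape_cp))
        w = warp(m0, fld, fill=fill)
        try:
            mi = mattes_mi(f, w, bins=bins)
        except ValueError:
            mi = 0.0
        val = -mi + penalty_weight * bending_energy(fld, f.shape)
        trace.append(-val)
        return val

    res = optimize.minimize(objective, field0.displacements.ravel(),
                            method="L-BFGS-B", jac=None,
                            options={"maxiter": max_iter, "eps": 0.25})
    fld = BSplineField(grid_spacing, res.x.reshape(shape_cp))
    final_mi = mattes_mi(f, warp(m0, fld, fill=fill), bins=bins)
    return RegistrationResult(transform=CompositeTransform(init, fld),
                              metric=float(final_mi), trace=trace)
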