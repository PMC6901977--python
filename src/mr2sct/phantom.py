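"""Co-registered synthetic CT/MR head-phantom pairs.

The pipeline operates on paired CT and T2-weighted MR axial slices.  This
module generates digital phantoms with the structure those pairs must have:

* CT in Hounsfield units — air near −1000 HU, soft tissue near 0–100 HU,
  bone well above the 300-HU bone/soft-tissue split, plus additive Gaussian
  detector noise (CT is quantitatively calibrated, so no bias field);
* T2-weighted MR in arbitrary units with a deliberately *non-monotone*
  tissue-to-intensity mapping (cortical bone and air are both dark, CSF is
  bright), a smooth multiplicative bias field, Rician magnitude noise and a
  per-subject global intensity gain — the inter-scan variability that
  intensity standardization exists to remove;
* an optional known rigid misalignment applied to the MR image only, so
  registration recovery can be scored against ground truth.

Anatomy is schematic: nested ellipses and annuli (scalp soft tissue, a
subcutaneous fat layer, a skull annulus, an air sinus cavity, two bright CSF
ventricles).  Overlaps are resolved in painter's order — later tissues in
``PhantomSpec.tissue_set`` overwrite earlier ones — with the documented
stacking body → fat → bone → cavities → CSF.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import ImageGrid
from .register import RigidTransform2D, warp

log = logging.getLogger(__name__)

#: integer codes written into the label mask
LABEL_CODES = {"air": 0, "soft_tissue": 1, "fat": 2, "bone": 3, "csf": 4}


# --------------------------------------------------------------------------
# parametric geometry (pixel coordinates)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned-after-rotation ellipse: centre (cx, cy), radii (rx, ry)."""

    cx: float
    cy: float
    rx: float
    ry: float
    angle: float = 0.0  # degrees

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
        th = np.radians(self.angle)
        dx, dy = xx - self.cx, yy - self.cy
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        return (u / self.rx) ** 2 + (v / self.ry) ** 2 <= 1.0

    def to_dict(self) -> dict:
        return {"kind": "ellipse", **asdict(self)}


@dataclass(frozen=True)
class Annulus:
    """Elliptical ring: outer ellipse minus a concentric inner one."""

    cx: float
    cy: float
    rx: float
    ry: float
    thickness: float
    angle: float = 0.0

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        outer = Ellipse(self.cx, self.cy, self.rx, self.ry, self.angle)
        inner = Ellipse(self.cx, self.cy, max(self.rx - self.thickness, 0.0),
                        max(self.ry - self.thickness, 0.0), self.angle)
        return outer.mask(shape) & ~inner.mask(shape)

    def to_dict(self) -> dict:
        return {"kind": "annulus", **asdict(self)}


@dataclass(frozen=True)
class FullField:
    """The whole image; used for the air background."""

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        return np.ones(shape, dtype=bool)

    def to_dict(self) -> dict:
        return {"kind": "full_field"}


Shape = Ellipse | Annulus | FullField


# --------------------------------------------------------------------------
# specification types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueDef:
    """One tissue class: its CT/MR intensity statistics and its region.

    HU ranges are validated so the 300-HU bone/soft-tissue split is
    meaningful on every phantom: bone means above 300 HU, air at or below
    −900 HU, the remaining soft classes inside [−200, 300) HU.
    """

    label: str
    ct_hu_mean: float
    ct_hu_sd: float
    mr_mean: float
    mr_sd: float
    geometry: Shape

    def __post_init__(self) -> None:
        if self.label not in LABEL_CODES:
            raise ValueError(f"unknown tissue label {self.label!r}")
        if self.label == "bone" and not self.ct_hu_mean > 300:
            raise ValueError("bone ct_hu_mean must exceed 300 HU")
        if self.label == "air" and not self.ct_hu_mean <= -900:
            raise ValueError("air ct_hu_mean must be <= -900 HU")
        if self.label in ("soft_tissue", "fat", "csf") and not (
                -200 <= self.ct_hu_mean < 300):
            raise ValueError(f"{self.label} ct_hu_mean must lie in [-200, 300) HU")
        if self.ct_hu_sd < 0 or self.mr_sd < 0:
            raise ValueError("intensity SDs must be non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic subject."""

    image_size: int
    tissue_set: tuple[TissueDef, ...]
    bias_field_amplitude: float = 0.0
    mr_noise_sigma: float = 0.0
    ct_noise_sigma: float = 0.0
    psf_fwhm_px: float = 0.0
    misalignment: RigidTransform2D | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.bias_field_amplitude < 0 or self.mr_noise_sigma < 0 \
                or self.ct_noise_sigma < 0 or self.psf_fwhm_px < 0:
            raise ValueError("amplitudes, sigmas and PSF width must be >= 0")
        object.__setattr__(self, "tissue_set", tuple(self.tissue_set))

    def to_dict(self) -> dict:
        d = {
            "image_size": self.image_size,
            "bias_field_amplitude": self.bias_field_amplitude,
            "mr_noise_sigma": self.mr_noise_sigma,
            "ct_noise_sigma": self.ct_noise_sigma,
            "psf_fwhm_px": self.psf_fwhm_px,
            "seed": self.seed,
            "misalignment": None if self.misalignment is None else {
                "rotation": self.misalignment.rotation,
                "translation": list(self.misalignment.translation)},
            "tissue_set": [
                {"label": t.label, "ct_hu_mean": t.ct_hu_mean,
                 "ct_hu_sd": t.ct_hu_sd, "mr_mean": t.mr_mean,
                 "mr_sd": t.mr_sd, "geometry": t.geometry.to_dict()}
                for t in self.tissue_set],
        }
        return d


@dataclass
class PhantomPair:
    """One subject: CT, MR, the painted label mask and the ground truth."""

    ct: ImageGrid
    mr: ImageGrid
    labels: np.ndarray
    true_misalignment: RigidTransform2D
    spec: PhantomSpec | None = None
    empty_tissues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.ct.shape == self.mr.shape == self.labels.shape):
            raise ValueError("ct, mr and labels must share dimensions")


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def _paint_labels(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                              np.ndarray, np.ndarray, list[str]]:
    """Rasterize tissues in painter's order; later TissueDefs win."""
    shape = (spec.image_size, spec.image_size)
    labels = np.zeros(shape, dtype=np.int16)
    ct_mean = np.full(shape, -1000.0)
    ct_sd = np.zeros(shape)
    mr_mean = np.zeros(shape)
    mr_sd = np.zeros(shape)
    empty: list[str] = []
    for t in spec.tissue_set:
        m = t.geometry.mask(shape)
        if not m.any():
            empty.append(t.label)
            log.warning("tissue %r rasterized to an empty region", t.label)
            continue
        labels[m] = LABEL_CODES[t.label]
        ct_mean[m] = t.ct_hu_mean
        ct_sd[m] = t.ct_hu_sd
        mr_mean[m] = t.mr_mean
        mr_sd[m] = t.mr_sd
    return labels, ct_mean, ct_sd, mr_mean, mr_sd, empty


def _bias_field(shape: tuple[int, int], amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field in [1-a, 1+a] from low-pass white noise."""
    g = rng.standard_normal(shape)
    g = ndimage.gaussian_filter(g, sigma=shape[0] / 4.0)
    g = g - g.mean()
    peak = np.abs(g).max()
    if peak > 0:
        g = g / peak
    return 1.0 + amplitude * g


def generate_pair(spec: PhantomSpec) -> PhantomPair:
    """Generate one co-registered CT/MR pair from a spec.

    Deterministic given ``spec.seed``.  The painted tissue-mean maps are
    first blurred by the acquisition PSF (``psf_fwhm_px``; 0 disables it and
    restores the exact piecewise-constant limit).  CT = blurred mean +
    Gaussian with sigma = tissue SD + ``ct_noise_sigma``.  MR = (blurred
    mean + Gaussian tissue SD) × bias field, then Rician-corrupted
    (magnitude of the signal plus complex Gaussian of ``mr_noise_sigma``).
    If a misalignment is set, only the MR image is resampled through it; CT
    and labels stay fixed.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.image_size, spec.image_size)
    labels, ct_mean, ct_sd, mr_mean, mr_sd, empty = _paint_labels(spec)

    if spec.psf_fwhm_px > 0:
        # finite acquisition PSF: partial-volume averaging at tissue edges,
        # which smooths the intensity histogram the way clinical images are
        sigma = spec.psf_fwhm_px / 2.355
        ct_mean = ndimage.gaussian_filter(ct_mean, sigma)
        mr_mean = ndimage.gaussian_filter(mr_mean, sigma)

    sigma_ct = ct_sd + spec.ct_noise_sigma
    ct = ct_mean.copy()
    if sigma_ct.any():
        ct = ct + rng.standard_normal(shape) * sigma_ct

    mr = mr_mean.copy()
    if mr_sd.any():
        mr = mr + rng.standard_normal(shape) * mr_sd
    if spec.bias_field_amplitude > 0:
        mr = mr * _bias_field(shape, spec.bias_field_amplitude, rng)
    if spec.mr_noise_sigma > 0:
        re = mr + rng.standard_normal(shape) * spec.mr_noise_sigma
        im = rng.standard_normal(shape) * spec.mr_noise_sigma
        mr = np.sqrt(re ** 2 + im ** 2)

    misalign = spec.misalignment or RigidTransform2D.identity()
    mr_grid = ImageGrid(mr, modality="MR", units="arbitrary",
                        meta={"seed": spec.seed})
    if not misalign.is_identity:
        mr_grid = warp(mr_grid, misalign, fill=0.0)
    ct_grid = ImageGrid(ct, modality="CT", units="HU", meta={"seed": spec.seed})
    return PhantomPair(ct=ct_grid, mr=mr_grid, labels=labels,
                       true_misalignment=misalign, spec=spec,
                       empty_tissues=tuple(empty))


# --------------------------------------------------------------------------
# default head phantom and cohorts
# --------------------------------------------------------------------------


def head_phantom_spec(image_size: int = 64, seed: int = 0, *,
                      scale: float = 1.0, shift: tuple[float, float] = (0.0, 0.0),
                      mr_gain: float = 1.0, tissue_texture: float = 1.0,
                      bias_field_amplitude: float = 0.15,
                      mr_noise_sigma: float = 20.0,
                      ct_noise_sigma: float = 15.0,
                      psf_fwhm_px: float = 1.5,
                      misalignment: RigidTransform2D | None = None) -> PhantomSpec:
    """Schematic axial head slice.

    ``scale``/``shift`` jitter the anatomy (fractions of image size /
    pixels); ``mr_gain`` is a global scanner-gain factor on all MR means and
    SDs, the between-subject variability standardization removes.  Default
    noise levels are a few percent of the soft-tissue intensity for MR and
    ~15 HU for CT, typical of clinical head acquisitions.
    """
    n = float(image_size)
    cx = n / 2.0 + shift[0]
    cy = n / 2.0 + shift[1]
    s = scale * n
    g = mr_gain
    tx = tissue_texture  # scales the within-tissue intensity SDs

    def E(fx, fy, rx, ry, angle=0.0):
        return Ellipse(cx + (fx - 0.5) * s, cy + (fy - 0.5) * s,
                       rx * s, ry * s, angle)

    def A(fx, fy, rx, ry, th):
        return Annulus(cx + (fx - 0.5) * s, cy + (fy - 0.5) * s,
                       rx * s, ry * s, th * s)

    tissues = (
        TissueDef("air", -1000.0, 0.0, 30.0 * g, 5.0 * g * tx, FullField()),
        TissueDef("soft_tissue", 40.0, 10.0 * tx, 500.0 * g, 30.0 * g * tx,
                  E(0.5, 0.5, 0.33, 0.40)),
        TissueDef("fat", -100.0, 10.0 * tx, 180.0 * g, 20.0 * g * tx,
                  A(0.5, 0.5, 0.33, 0.40, 0.035)),
        TissueDef("bone", 1200.0, 80.0 * tx, 80.0 * g, 15.0 * g * tx,
                  A(0.5, 0.5, 0.295, 0.365, 0.05)),
        TissueDef("air", -1000.0, 0.0, 30.0 * g, 5.0 * g * tx,
                  E(0.5, 0.67, 0.07, 0.055)),
        TissueDef("csf", 15.0, 5.0 * tx, 950.0 * g, 40.0 * g * tx,
                  E(0.42, 0.42, 0.045, 0.085)),
        TissueDef("csf", 15.0, 5.0 * tx, 950.0 * g, 40.0 * g * tx,
                  E(0.58, 0.42, 0.045, 0.085)),
    )
    return PhantomSpec(image_size=image_size, tissue_set=tissues,
                       bias_field_amplitude=bias_field_amplitude,
                       mr_noise_sigma=mr_noise_sigma,
                       ct_noise_sigma=ct_noise_sigma,
                       psf_fwhm_px=psf_fwhm_px,
                       misalignment=misalignment, seed=seed)


@dataclass(frozen=True)
class CohortTemplate:
    """Ranges from which per-subject anatomy and gain jitter are drawn."""

    image_size: int = 64
    scale_range: tuple[float, float] = (0.9, 1.1)
    shift_range_px: float = 2.0
    mr_gain_range: tuple[float, float] = (0.75, 1.3)
    bias_field_amplitude: float = 0.15
    mr_noise_sigma: float = 20.0
    ct_noise_sigma: float = 15.0
    psf_fwhm_px: float = 1.5
    misalignment: RigidTransform2D | None = None


def subject_spec(template: CohortTemplate, subject_seed: int) -> PhantomSpec:
    """The spec a given per-subject seed deterministically produces."""
    rng = np.random.default_rng(subject_seed)
    scale = rng.uniform(*template.scale_range)
    shift = tuple(rng.uniform(-template.shift_range_px, template.shift_range_px,
                              size=2))
    gain = rng.uniform(*template.mr_gain_range)
    return head_phantom_spec(
        template.image_size, seed=subject_seed, scale=scale, shift=shift,
        mr_gain=gain, bias_field_amplitude=template.bias_field_amplitude,
        mr_noise_sigma=template.mr_noise_sigma,
        ct_noise_sigma=template.ct_noise_sigma,
        psf_fwhm_px=template.psf_fwhm_px,
        misalignment=template.misalignment)


def cohort(template: CohortTemplate, n_subjects: int, seed: int) -> list[PhantomPair]:
    """Generate ``n_subjects`` independent phantoms with reproducible seeds.

    Per-subject seeds are spawned from ``seed`` via a SeedSequence, so the
    cohort is bit-reproducible and each subject is independent of cohort
    size and position.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    root = np.random.SeedSequence(seed)
    pairs = []
    for child in root.spawn(n_subjects):
        subject_seed = int(child.generate_state(1)[0] % (2 ** 31))
        pairs.append(generate_pair(subject_spec(template, subject_seed)))
    return pairs


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------


def save_pair(pair: PhantomPair, outdir: str | Path, subject_id: str,
              previews: bool = False) -> None:
    """Write ct/mr NIfTI files plus a JSON sidecar with spec and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pair.ct.to_nifti(outdir / f"{subject_id}_ct.nii.gz")
    pair.mr.to_nifti(outdir / f"{subject_id}_mr.nii.gz")
    ImageGrid(pair.labels.astype(float), modality="CT", units="HU").to_nifti(
        outdir / f"{subject_id}_labels.nii.gz")
    sidecar = {
        "true_misalignment": {
            "rotation": pair.true_misalignment.rotation,
            "translation": list(pair.true_misalignment.translation)},
        "empty_tissues": list(pair.empty_tissues),
        "spec": None if pair.spec is None else pair.spec.to_dict(),
    }
    (outdir / f"{subject_id}_pair.json").write_text(json.dumps(sidecar, indent=2))
    if previews:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(1, 3, figsize=(9, 3))
        for ax, (img, title) in zip(axes, [(pair.ct.data, "CT (HU)"),
                                           (pair.mr.data, "T2 MR"),
                                           (pair.labels, "labels")]):
            ax.imshow(img, cmap="gray")
            ax.set_title(title)
            ax.axis("off")
        fig.savefig(outdir / f"{subject_id}_preview.png", dpi=100,
                    bbox_inches="tight")
        plt.close(fig)
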