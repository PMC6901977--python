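"""Image container shared by every pipeline stage.

An :class:`ImageGrid` is a 2-D scalar image (one axial slice) carrying the
metadata the pipeline needs to reason about it: pixel spacing, the modality
it came from (CT or MR) and the semantics of its values — Hounsfield units
for CT, arbitrary scanner units or cohort-standardized units for MR.
Thin stacks of slices are handled as lists of grids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: value semantics an image may carry
UNITS = ("HU", "arbitrary", "standardized")
MODALITIES = ("CT", "MR")

#: fill value used for out-of-field CT pixels (air)
AIR_HU = -1000.0


@dataclass
class ImageGrid:
    """A single 2-D scalar image with spacing, modality and unit tags.

    Parameters
    ----------
    data:
        2-D float array, row-major (y, x).
    spacing:
        pixel size (dy, dx) in millimetres.
    modality:
        ``"CT"`` or ``"MR"``.
    units:
        ``"HU"`` for CT; ``"arbitrary"`` or ``"standardized"`` for MR.
    meta:
        free-form provenance dictionary (seeds, config hashes, ...).
    """

    data: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    modality: str = "MR"
    units: str = "arbitrary"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"ImageGrid expects a 2-D array, got shape {self.data.shape}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.units not in UNITS:
            raise ValueError(f"units must be one of {UNITS}, got {self.units!r}")
        if self.modality == "CT" and self.units != "HU":
            raise ValueError("CT images must carry HU units")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, *, units: str | None = None) -> "ImageGrid":
        """Copy of this grid with new pixel data (and optionally new units)."""
        out = replace(self, data=np.asarray(data, dtype=np.float64))
        if units is not None:
            out.units = units
        out.meta = dict(self.meta)
        return out

    # ------------------------------------------------------------------ I/O

    def to_nifti(self, path: str | Path) -> None:
        """Write as a single-slice NIfTI volume (shape H×W×1)."""
        affine = np.diag([self.spacing[1], self.spacing[0], 1.0, 1.0])
        img = nib.Nifti1Image(self.data[:, :, None].astype(np.float32), affine)
        img.header.set_xyzt_units("mm")
        nib.save(img, str(path))
        sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz / .nii
        meta = {"modality": self.modality, "units": self.units, "spacing": list(self.spacing)}
        meta.update({k: v for k, v in self.meta.items() if _json_safe(v)})
        Path(str(sidecar) + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_nifti(cls, path: str | Path, modality: str | None = None,
                   units: str | None = None) -> "ImageGrid":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        if data.ndim == 3:
            if data.shape[2] != 1:
                raise ValueError("only single-slice volumes are supported; got "
                                 f"shape {data.shape}")
            data = data[:, :, 0]
        zooms = img.header.get_zooms()
        spacing = (float(zooms[1]), float(zooms[0]))
        sidecar = Path(str(Path(str(path)).with_suffix("").with_suffix("")) + ".json")
        meta: dict = {}
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        modality = modality or meta.get("modality", "MR")
        units = units or meta.get("units", "HU" if modality == "CT" else "arbitrary")
        return cls(data=data, spacing=spacing, modality=modality, units=units,
                   meta={k: v for k, v in meta.items()
                         if k not in ("modality", "units", "spacing")})


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
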