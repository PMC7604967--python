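"""Co-registered label masks: the pipeline's imaging input."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Arterial segments assessed for encasement: cavernous (C4) and clinoid (C5)
#: internal carotid, sphenoidal (M1) and insular (M2) middle cerebral,
#: precommunicating (A1) and postcommunicating (A2) anterior cerebral.
ARTERY_NAMES = ("C4", "C5", "M1", "M2", "A1", "A2")


@dataclass
class SegmentationSet:
    """Axis-aligned boolean label volumes sharing one grid and voxel spacing.

    Parameters
    ----------
    tumor_mask : ndarray of bool
        Tumor voxels.
    artery_masks : dict
        Map from artery segment name (subset of :data:`ARTERY_NAMES`) to a
        boolean volume of the same shape. Absent segments are treated
        downstream as "not involved".
    cs_mask : ndarray of bool
        Cavernous-sinus region.
    bone_mask : ndarray of bool
        Skull / bone.
    spacing_mm : tuple of float
        Voxel edge lengths along each axis, in millimetres. Physical
        coordinates are ``index * spacing`` (0-based indices; no affine
        orientation handling beyond axis-aligned spacing).
    """

    tumor_mask: np.ndarray
    artery_masks: dict[str, np.ndarray] = field(default_factory=dict)
    cs_mask: np.ndarray | None = None
    bone_mask: np.ndarray | None = None
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
        shape = self.tumor_mask.shape
        if self.tumor_mask.ndim != 3:
            raise ValueError("tumor_mask must be a 3D volume")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be 3 positive floats")
        for name in self.artery_masks:
            if name not in ARTERY_NAMES:
                raise ValueError(f"unknown artery name {name!r}; expected one of {ARTERY_NAMES}")
        self.artery_masks = {k: np.asarray(v, dtype=bool) for k, v in self.artery_masks.items()}
        if self.cs_mask is None:
            self.cs_mask = np.zeros(shape, dtype=bool)
        else:
            self.cs_mask = np.asarray(self.cs_mask, dtype=bool)
        if self.bone_mask is None:
            self.bone_mask = np.zeros(shape, dtype=bool)
        else:
            self.bone_mask = np.asarray(self.bone_mask, dtype=bool)
        for label, mask in self.iter_masks():
            if mask.shape != shape:
                raise ValueError(
                    f"mask {label!r} has shape {mask.shape}, expected {shape}"
                )

    def iter_masks(self):
        yield "tumor", self.tumor_mask
        for name, mask in self.artery_masks.items():
            yield name, mask
        yield "cs", self.cs_mask
        yield "bone", self.bone_mask

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tumor_mask.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))
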