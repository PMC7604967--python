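"""Pipeline configuration: every threshold that affects a score component."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field


@dataclass
class PipelineConfig:
    """Tunable thresholds and options for the full pipeline.

    Attributes
    ----------
    full_encirclement_deg : float
        Per-point angular coverage at or above which an artery counts as
        completely encircled. 355 deg rather than a literal 360 to tolerate
        voxelization of a radiologist's "complete (360deg)" judgment.
    narrowing_delta : float
        Relative caliber reduction versus the vessel's median radius that
        counts as lumen narrowing. Default 0.20.
    tau_cs_cm3, tau_bone_cm3 : float
        Tumor/structure overlap volume (cm^3) that must be *exceeded*
        (strict inequality) to flag cavernous-sinus involvement or bone
        invasion. Default 0.1 cm^3.
    probe_band_mm : float
        Radial extent of the angular-coverage probe shell outside the vessel
        surface. Default 2 mm: detects abutting tumor without counting
        distant tissue.
    band_cutoffs : (int, int)
        ``(lo, hi)``: total < lo predicts a Simpson I resection, lo <= total
        <= hi a Simpson II, total > hi a Simpson III or IV.
    regression_family : {"ordinal", "binary"}
        Family for adjusted odds ratios: proportional-odds ordinal logistic
        (default) or a dichotomized (grade I-II vs III-IV) fallback.
    discriminant_mode : {"resubstitution", "loo"}
        How discriminant accuracy is evaluated.
    """

    full_encirclement_deg: float = 355.0
    narrowing_delta: float = 0.20
    tau_cs_cm3: float = 0.1
    tau_bone_cm3: float = 0.1
    probe_band_mm: float = 2.0
    band_cutoffs: tuple[int, int] = (4, 7)
    regression_family: str = "ordinal"
    discriminant_mode: str = "resubstitution"
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.full_encirclement_deg <= 360):
            raise ValueError("full_encirclement_deg must be in (0, 360]")
        if not (0 <= self.narrowing_delta < 1):
            raise ValueError("narrowing_delta must be in [0, 1)")
        if self.tau_cs_cm3 < 0 or self.tau_bone_cm3 < 0:
            raise ValueError("overlap thresholds must be non-negative")
        if self.probe_band_mm <= 0:
            raise ValueError("probe_band_mm must be positive")
        lo, hi = self.band_cutoffs
        if not (1 <= lo <= hi <= 10):
            raise ValueError("band_cutoffs must satisfy 1 <= lo <= hi <= 10")
        if self.regression_family not in ("ordinal", "binary"):
            raise ValueError("regression_family must be 'ordinal' or 'binary'")
        if self.discriminant_mode not in ("resubstitution", "loo"):
            raise ValueError("discriminant_mode must be 'resubstitution' or 'loo'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_cutoffs"] = list(self.band_cutoffs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "band_cutoffs" in d:
            d["band_cutoffs"] = tuple(d["band_cutoffs"])
        return cls(**d)
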