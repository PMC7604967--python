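"""The 1-10 point score and its mapping to a predicted Simpson resection band.

Score = volume grade (1-3) + arterial encasement grade (0-4)
        + cavernous-sinus involvement (0 or 2) + bone invasion (0 or 1).

A total below 4 predicts a Simpson I resection, a total of 4-7 a Simpson II,
and a total above 7 a Simpson III or IV. The bands are tendencies observed
in the original cohort, not guarantees; III and IV are not separated.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import pandas as pd

from .features import RadiologicFeatures

CS_POINTS = 2
BONE_POINTS = 1


class SimpsonGrade(enum.IntEnum):
    """Intraoperative completeness of meningioma removal.

    I   - total resection with excision of dural attachment and abnormal bone
    II  - total resection with coagulation of dural attachments
    III - gross total resection without dural resection/coagulation
    IV  - partial removal, intradural tumor left in situ
    V   - simple decompression
    """

    I = 1
    II = 2
    III = 3
    IV = 4
    V = 5


class ResectionBand(enum.IntEnum):
    """Predicted resection tendency, ordered I < II < III/IV."""

    SIMPSON_I = 1
    SIMPSON_II = 2
    SIMPSON_III_OR_IV = 3


@dataclass
class ScoreResult:
    """Component breakdown of one patient's score."""

    volume_points: int
    arterial_points: int
    cs_points: int
    bone_points: int
    total: int
    predicted_band: ResectionBand

    def __post_init__(self) -> None:
        if self.volume_points not in (1, 2, 3):
            raise ValueError("volume_points must be 1-3")
        if self.arterial_points not in range(5):
            raise ValueError("arterial_points must be 0-4")
        if self.cs_points not in (0, CS_POINTS):
            raise ValueError(f"cs_points must be 0 or {CS_POINTS}")
        if self.bone_points not in (0, BONE_POINTS):
            raise ValueError(f"bone_points must be 0 or {BONE_POINTS}")
        if self.total != self.volume_points + self.arterial_points + self.cs_points + self.bone_points:
            raise ValueError("total must equal the sum of the four components")


def predict_resection_band(total: int, cutoffs: tuple[int, int] = (4, 7)) -> ResectionBand:
    """Map a total score to its predicted resection band.

    With the default cutoffs ``(4, 7)``: total < 4 -> Simpson I,
    4 <= total <= 7 -> Simpson II, total > 7 -> Simpson III or IV.
    """
    if not (1 <= total <= 10):
        raise ValueError(f"total score must lie in [1, 10], got {total}")
    lo, hi = cutoffs
    if total < lo:
        return ResectionBand.SIMPSON_I
    if total <= hi:
        return ResectionBand.SIMPSON_II
    return ResectionBand.SIMPSON_III_OR_IV


def total_score(
    features: RadiologicFeatures, cutoffs: tuple[int, int] = (4, 7)
) -> ScoreResult:
    """Combine the four graded features into the 1-10 score."""
    volume_points = features.volume_grade
    arterial_points = features.arterial_score
    cs_points = CS_POINTS if features.cs_involved else 0
    bone_points = BONE_POINTS if features.bone_invaded else 0
    total = volume_points + arterial_points + cs_points + bone_points
    return ScoreResult(
        volume_points=volume_points,
        arterial_points=arterial_points,
        cs_points=cs_points,
        bone_points=bone_points,
        total=total,
        predicted_band=predict_resection_band(total, cutoffs),
    )


def enumerate_score_space(cutoffs: tuple[int, int] = (4, 7)) -> pd.DataFrame:
    """All 60 component combinations (3 x 5 x 2 x 2) with totals and bands.

    Certifies that the score spans exactly 1-10 and that every total maps to
    a band.
    """
    rows = []
    for v, a, c, b in itertools.product((1, 2, 3), range(5), (0, CS_POINTS), (0, BONE_POINTS)):
        total = v + a + c + b
        rows.append(
            {
                "volume_points": v,
                "arterial_points": a,
                "cs_points": c,
                "bone_points": b,
                "total": total,
                "predicted_band": predict_resection_band(total, cutoffs).name,
            }
        )
    return pd.DataFrame(rows)
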