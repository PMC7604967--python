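"""File formats and the end-to-end pipeline runner.

Masks travel as NIfTI — either one file per structure or one multi-label
volume with a JSON label-table sidecar ``{"1": "tumor", "2": "C4", ...}``.
Cohorts travel as CSV with one row per patient: ``volume_grade`` (1-3),
``arterial_score`` (0-4), ``cs_involved`` (0/1), ``bone_invaded`` (0/1),
optional ``total_score`` (recomputed and cross-checked), optional
``simpson_grade`` (I-IV as 1-4) and ``outcome_grade`` (0-3). Reports are
JSON with fixed key order and 6-significant-digit floats for diffability.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .config import PipelineConfig
from .cohorts import COHORT_COLUMNS, CohortTable
from .features import RadiologicFeatures, extract_features
from .scoring import ScoreResult, total_score
from .segmentation import ARTERY_NAMES, SegmentationSet
from .stats import CohortScoreModel, StatsReport

logger = logging.getLogger(__name__)

STRUCTURE_NAMES = ("tumor", "cs", "bone") + ARTERY_NAMES


def _round6(x):
    if isinstance(x, float):
        return float(f"{x:.6g}")
    if isinstance(x, dict):
        return {k: _round6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round6(v) for v in x]
    return x


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def write_segmentation_set(seg: SegmentationSet, directory, multi_label: bool = False) -> dict:
    """Write masks as NIfTI; returns the mapping of structures to files.

    ``multi_label=True`` writes one volume plus a ``labels.json`` sidecar;
    otherwise one ``<structure>.nii.gz`` per non-empty structure.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(seg.spacing_mm)
    written = {}
    if multi_label:
        # structures may legitimately overlap (CS infiltration, bone
        # invasion share voxels with the tumor), so each structure gets one
        # bit; a voxel's value is the bitwise OR of the structures in it
        vol = np.zeros(seg.shape, dtype=np.uint16)
        table = {}
        for i, (label, mask) in enumerate(seg.iter_masks()):
            bit = 1 << i
            vol[mask] |= np.uint16(bit)
            table[str(bit)] = label
        path = directory / "segmentation.nii.gz"
        nib.save(nib.Nifti1Image(vol, aff), path)
        sidecar = directory / "labels.json"
        sidecar.write_text(json.dumps({"encoding": "bitmask", "bits": table}, indent=1))
        written = {"multi_label": str(path), "label_table": str(sidecar)}
    else:
        for label, mask in seg.iter_masks():
            if label != "tumor" and not mask.any():
                continue
            path = directory / f"{label}.nii.gz"
            nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff), path)
            written[label] = str(path)
    return written


def _load_mask(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj) > 0, spacing


def read_segmentation_set(
    paths: dict[str, str] | None = None,
    multi_label_path: str | None = None,
    label_table: dict[str, str] | str | None = None,
) -> SegmentationSet:
    """Read a segmentation set from per-structure files or a multi-label volume.

    Missing artery files are warnings (treated as not involved); shape or
    spacing mismatches between files are hard errors naming the file.
    """
    if multi_label_path is not None:
        if label_table is None:
            raise ValueError("multi-label input requires a label table")
        if isinstance(label_table, (str, Path)):
            label_table = json.loads(Path(label_table).read_text())
        img = nib.load(str(multi_label_path))
        vol = np.asarray(img.dataobj).astype(int)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        if label_table.get("encoding") == "bitmask":
            masks = {name: (vol & int(bit)) > 0 for bit, name in label_table["bits"].items()}
        else:  # plain exclusive labels
            masks = {name: vol == int(value) for value, name in label_table.items()}
    elif paths is not None:
        masks, spacing, ref_shape = {}, None, None
        for name in STRUCTURE_NAMES:
            if name not in paths:
                if name in ARTERY_NAMES:
                    logger.warning("artery %s mask missing; treated as absent", name)
                continue
            mask, sp = _load_mask(paths[name])
            if spacing is None:
                spacing, ref_shape = sp, mask.shape
            else:
                if not np.allclose(sp, spacing, rtol=1e-4):
                    raise ValueError(f"spacing mismatch in {paths[name]!r}: {sp} vs {spacing}")
                if mask.shape != ref_shape:
                    raise ValueError(
                        f"shape mismatch in {paths[name]!r}: {mask.shape} vs {ref_shape}"
                    )
            masks[name] = mask
    else:
        raise ValueError("provide per-structure paths or a multi-label volume")

    if "tumor" not in masks:
        raise ValueError("segmentation set requires a tumor mask")
    return SegmentationSet(
        tumor_mask=masks["tumor"],
        artery_masks={k: v for k, v in masks.items() if k in ARTERY_NAMES},
        cs_mask=masks.get("cs"),
        bone_mask=masks.get("bone"),
        spacing_mm=spacing,
    )


def features_to_dict(features: RadiologicFeatures) -> dict:
    d = {
        "tumor_volume_cm3": features.tumor_volume_cm3,
        "volume_grade": features.volume_grade,
        "arterial_score": features.arterial_score,
        "cs_involved": features.cs_involved,
        "bone_invaded": features.bone_invaded,
        "cs_overlap_cm3": features.cs_overlap_cm3,
        "bone_overlap_cm3": features.bone_overlap_cm3,
        "encasements": [dataclasses.asdict(e) for e in features.encasements],
    }
    return _round6(d)


def score_to_dict(score: ScoreResult) -> dict:
    d = dataclasses.asdict(score)
    d["predicted_band"] = score.predicted_band.name
    return d


def write_cohort_csv(cohort: CohortTable, path) -> None:
    df = cohort.data.copy()
    df["cs_involved"] = df["cs_involved"].astype(int)
    df["bone_invaded"] = df["bone_invaded"].astype(int)
    df.to_csv(path, index=False)


def read_cohort_csv(path, provenance: str = "user") -> CohortTable:
    """Read and validate a cohort CSV; a stored total inconsistent with the
    component sum is a hard error."""
    df = pd.read_csv(path)
    required = COHORT_COLUMNS[:4]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    df["cs_involved"] = df["cs_involved"].astype(bool)
    df["bone_invaded"] = df["bone_invaded"].astype(bool)
    computed = (
        df["volume_grade"]
        + df["arterial_score"]
        + 2 * df["cs_involved"].astype(int)
        + df["bone_invaded"].astype(int)
    )
    if "total_score" in df.columns:
        if not (df["total_score"] == computed).all():
            bad = df.index[df["total_score"] != computed].tolist()
            raise ValueError(f"total_score mismatch with component sum at rows {bad}")
    else:
        df["total_score"] = computed
    for col in ("simpson_grade", "outcome_grade"):
        if col not in df.columns:
            df[col] = np.nan
    return CohortTable(data=df, provenance=provenance)


def load_config(path) -> PipelineConfig:
    """Read a PipelineConfig from a YAML key-value file."""
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def run_pipeline(
    config: PipelineConfig,
    segmentations: list[SegmentationSet] | None = None,
    cohort: CohortTable | None = None,
) -> dict:
    """Score each segmentation and, when a cohort is supplied, run the battery.

    Per-patient failures are isolated: a failing case is reported under
    ``errors`` and the batch continues. The report echoes the full config
    (every threshold that affects a score component) for auditability.
    """
    if not segmentations and cohort is None:
        raise ValueError("nothing to do: supply segmentations and/or a cohort")
    report: dict = {
        "version": _version,
        "config": config.to_dict(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "patients": [],
        "errors": [],
    }
    for i, seg in enumerate(segmentations or []):
        try:
            feats = extract_features(seg, config)
            score = total_score(feats, cutoffs=config.band_cutoffs)
            report["patients"].append(
                {"index": i, "features": features_to_dict(feats), "score": score_to_dict(score)}
            )
        except Exception as exc:  # isolate per-patient failures
            logger.error("patient %d failed: %s", i, exc)
            report["errors"].append({"index": i, "error": str(exc)})
    if cohort is not None and len(cohort) >= 3:
        results = CohortScoreModel(cohort, config).fit()
        report["stats"] = _round6(dataclasses.asdict(results.report))
        report["summary"] = results.summary()
    return report


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=False) + "\n")
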