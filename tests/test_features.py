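"""Feature extraction: volumes, vessel geometry, coverage, overlaps."""

import numpy as np
import pytest

from sphenoscore.features import (
    NotATubeError,
    VesselGeometry,
    angular_coverage,
    assess_bone_invasion,
    assess_cs_involvement,
    compute_tumor_volume,
    detect_narrowing,
    extract_centerline,
    extract_features,
    grade_volume,
)
from sphenoscore.phantoms import PhantomSpec, make_phantom, straight_artery
from sphenoscore.segmentation import SegmentationSet


class TestVolume:
    def test_empty_mask_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert compute_tumor_volume(np.zeros((4, 4, 4), bool), (1, 1, 1)) == 0.0

    def test_solid_block(self):
        m = np.zeros((12, 12, 12), bool)
        m[1:11, 1:11, 1:11] = True
        assert compute_tumor_volume(m, (1, 1, 1)) == pytest.approx(1.0)

    def test_voxelized_sphere_matches_analytic(self, sphere_phantom_halfmm):
        seg, truth = sphere_phantom_halfmm
        v = compute_tumor_volume(seg.tumor_mask, seg.spacing_mm)
        assert v == pytest.approx(truth.analytic_tumor_volume_cm3, rel=0.02)
        assert truth.analytic_tumor_volume_cm3 == pytest.approx(4.18879, abs=1e-4)

    @pytest.mark.parametrize(
        "volume,grade",
        [(9.3, 1), (19.99, 1), (20.0, 2), (35.0, 2), (50.0, 2), (50.01, 3), (171.9, 3)],
    )
    def test_volume_grading(self, volume, grade):
        assert grade_volume(volume) == grade

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            grade_volume(-1.0)


class TestCenterline:
    def test_straight_cylinder(self, cylinder_mask):
        v = extract_centerline(cylinder_mask, (1, 1, 1), "C4")
        # centerline on the axis, radius within half a voxel of 3 mm
        assert np.abs(v.centerline_points[:, :2] - 20.0).max() < 1e-6
        assert np.all(np.abs(v.local_radius_mm - 3.0) <= 0.5)

    def test_quarter_torus_arc_length(self):
        x, y, z = np.mgrid[0:70, 0:70, 0:60].astype(float)
        R, cx, cy, cz = 25.0, 10.0, 10.0, 30.0
        rho = np.hypot(x - cx, y - cy)
        ang = np.arctan2(y - cy, x - cx)
        mask = (np.hypot(rho - R, z - cz) <= 3) & (ang >= 0) & (ang <= np.pi / 2)
        v = extract_centerline(mask, (1, 1, 1), "M1")
        analytic = np.pi / 2 * R
        assert v.arc_length_mm == pytest.approx(analytic, rel=0.05)

    def test_disjoint_tubes_rejected(self, cylinder_mask):
        two = cylinder_mask.copy()
        two[:, :, 25:32] = False
        with pytest.raises(NotATubeError, match="A1"):
            extract_centerline(two, (1, 1, 1), "A1")

    def test_empty_mask_rejected(self):
        with pytest.raises(NotATubeError):
            extract_centerline(np.zeros((8, 8, 8), bool), (1, 1, 1), "C5")


def _straight_geometry(n=20, radius=3.0):
    pts = np.column_stack([np.full(n, 10.0), np.full(n, 10.0), np.linspace(2, 21, n)])
    tans = np.tile([0.0, 0.0, 1.0], (n, 1))
    return VesselGeometry("M1", pts, tans, np.full(n, radius))


class TestNarrowing:
    def test_uniform_radius_is_not_narrowed(self):
        assert detect_narrowing(_straight_geometry()) is False

    def test_focal_reduction_detected(self):
        v = _straight_geometry()
        v.local_radius_mm[10] = 3.0 * 0.7  # 30% focal reduction
        assert detect_narrowing(v) is True

    def test_subthreshold_reduction_ignored(self):
        v = _straight_geometry()
        v.local_radius_mm[10] = 3.0 * 0.95  # 5% < default 20%
        assert detect_narrowing(v) is False

    def test_too_few_points(self):
        v = _straight_geometry(n=4)
        with pytest.raises(ValueError, match="insufficient geometry"):
            detect_narrowing(v)


@pytest.fixture(scope="module")
def wrap_segmentations():
    out = {}
    for wrap in (180, 360):
        spec = PhantomSpec(
            grid_shape=(96, 96, 96),
            tumor_kind="annular_wrap",
            arteries=[straight_artery("M1", 48, 48, (14, 82))],
            wrap_angle_deg=wrap,
        )
        out[wrap] = make_phantom(spec)[0]
    return out


class TestAngularCoverage:
    def test_half_wrap_measures_180(self, wrap_segmentations):
        seg = wrap_segmentations[180]
        v = extract_centerline(seg.artery_masks["M1"], seg.spacing_mm, "M1")
        enc = angular_coverage(seg.tumor_mask, v, seg.spacing_mm)
        assert enc.involved
        assert enc.max_coverage_deg == pytest.approx(180.0, abs=10.0)
        assert not enc.fully_encircled

    def test_full_wrap_is_encircled(self, wrap_segmentations):
        seg = wrap_segmentations[360]
        v = extract_centerline(seg.artery_masks["M1"], seg.spacing_mm, "M1")
        enc = angular_coverage(seg.tumor_mask, v, seg.spacing_mm)
        assert enc.fully_encircled
        assert enc.max_coverage_deg == pytest.approx(360.0, abs=10.0)

    def test_distant_tumor_not_involved(self, wrap_segmentations):
        seg = wrap_segmentations[180]
        far_tumor = np.zeros(seg.shape, bool)
        far_tumor[5:15, 5:15, 5:15] = True  # far outside the probe band
        v = extract_centerline(seg.artery_masks["M1"], seg.spacing_mm, "M1")
        enc = angular_coverage(far_tumor, v, seg.spacing_mm)
        assert not enc.involved
        assert enc.max_coverage_deg == 0.0

    def test_rotated_phantom_same_coverage(self, wrap_segmentations):
        """Coverage is rotation-invariant within 5 degrees for a 90-degree grid rotation."""
        seg = wrap_segmentations[180]
        v = extract_centerline(seg.artery_masks["M1"], seg.spacing_mm, "M1")
        base = angular_coverage(seg.tumor_mask, v, seg.spacing_mm).max_coverage_deg
        rot_tumor = np.rot90(seg.tumor_mask, axes=(0, 1)).copy()
        rot_artery = np.rot90(seg.artery_masks["M1"], axes=(0, 1)).copy()
        v_rot = extract_centerline(rot_artery, seg.spacing_mm, "M1")
        rot = angular_coverage(rot_tumor, v_rot, seg.spacing_mm).max_coverage_deg
        assert abs(rot - base) <= 5.0


class TestOverlaps:
    def test_disjoint_masks(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[:3], b[7:] = True, True
        assert assess_cs_involvement(a, b, (1, 1, 1)) is False
        invaded, overlap = assess_bone_invasion(a, b, (1, 1, 1))
        assert not invaded and overlap == 0.0

    def test_large_overlap(self):
        a = np.zeros((20, 20, 20), bool)
        a[:12] = True
        b = np.zeros((20, 20, 20), bool)
        b[10:] = True  # overlap 2*20*20 = 800 mm^3 = 0.8 cm^3
        assert assess_cs_involvement(a, b, (1, 1, 1)) is True

    def test_overlap_exactly_at_threshold_is_negative(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[0, :10, :10] = True
        b[0, :10, :10] = True  # exactly 100 voxels = 0.1 cm^3
        assert assess_cs_involvement(a, b, (1, 1, 1)) is False
        invaded, overlap = assess_bone_invasion(a, b, (1, 1, 1))
        assert not invaded and overlap == pytest.approx(0.1)

    def test_adjacent_without_shared_voxels(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[:5], b[5:] = True, True
        invaded, _ = assess_bone_invasion(a, b, (1, 1, 1))
        assert not invaded


class TestExtractFeatures:
    def test_phantom_round_trip(self, wrap180_phantom):
        seg, truth = wrap180_phantom
        feats = extract_features(seg)
        assert feats.volume_grade == 1
        enc = {e.artery_name: e for e in feats.encasements}["M1"]
        assert enc.involved and enc.narrowed and not enc.fully_encircled
        assert enc.max_coverage_deg == pytest.approx(180.0, abs=10.0)
        assert feats.arterial_score == truth.expected_arterial_score() == 2
        assert feats.cs_involved == truth.cs_involved
        assert feats.bone_invaded == truth.bone_invaded

    def test_empty_tumor(self):
        seg = SegmentationSet(tumor_mask=np.zeros((8, 8, 8), bool))
        with pytest.warns(UserWarning):
            feats = extract_features(seg)
        assert feats.tumor_volume_cm3 == 0.0
        assert feats.volume_grade == 1
        assert feats.arterial_score == 0
        assert not feats.cs_involved and not feats.bone_invaded
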