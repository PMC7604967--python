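"""Labeled 3D phantoms with analytically known feature ground truth.

Phantoms stand in for fused, co-registered patient segmentations. Arteries
are tubes swept along polyline centerlines, optionally narrowed by a smooth
cosine taper over a stated arc-length span. The tumor is either an ellipsoid
or an annular wrap built in the plane perpendicular to the local centerline
tangent, spanning exactly ``wrap_angle_deg`` around the vessel — so the
circumferential coverage the feature extractor should report is known by
construction. Cavernous-sinus overlap and bone contact are realised as
fixed voxel blocks shared between the tumor mask and the CS / bone masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .segmentation import ARTERY_NAMES, SegmentationSet
from .features import EncasementResult, arterial_involvement_score

#: Relative caliber reduction at which ground truth calls a vessel narrowed.
#: Matches the feature extractor's default detection threshold so that truth
#: and detector agree by construction.
NARROWING_TRUTH_DELTA = 0.20

#: Voxel volume added to the bone mask overlap when ``bone_contact`` is set
#: (0.3 cm^3 — comfortably above the 0.1 cm^3 invasion threshold).
BONE_CONTACT_CM3 = 0.3

#: Fixed rotation of the annular-wrap sector about the centerline. A generic
#: angle keeps the sector edges off the lattice planes, where rasterization
#: by voxel-center inclusion is one-sidedly biased.
WRAP_REFERENCE_OFFSET_DEG = 13.7


class PhantomOverflowError(ValueError):
    """A requested shape does not fit inside the phantom grid."""


class LabelCollisionError(ValueError):
    """Two artery labels occupy the same voxel."""


@dataclass
class ArterySpec:
    """One tubular arterial segment.

    ``narrowing_span_mm`` bounds the arc-length window of the taper; by
    default the middle third of the centerline. ``wrap_angle_deg`` overrides
    the phantom-level wrap angle for this artery (``None`` inherits it).
    """

    name: str
    control_points_mm: np.ndarray  # (k, 3)
    radius_mm: float = 3.0
    narrowing_fraction: float = 0.0
    narrowing_span_mm: tuple[float, float] | None = None
    wrap_angle_deg: float | None = None

    def __post_init__(self) -> None:
        if self.name not in ARTERY_NAMES:
            raise ValueError(f"unknown artery name {self.name!r}")
        self.control_points_mm = np.atleast_2d(np.asarray(self.control_points_mm, dtype=float))
        if len(self.control_points_mm) < 2:
            raise ValueError("need at least 2 centerline control points")
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")
        if not (0.0 <= self.narrowing_fraction < 1.0):
            raise ValueError("narrowing_fraction must lie in [0, 1)")


@dataclass
class PhantomSpec:
    """Full description of one phantom; all geometry in millimetres."""

    grid_shape: tuple[int, int, int] = (160, 160, 160)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_kind: str = "ellipsoid"  # or "annular_wrap"
    tumor_semiaxes_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    tumor_center_mm: tuple[float, float, float] | None = None
    wrap_angle_deg: float = 0.0
    wrap_thickness_mm: float = 3.0
    arteries: list[ArterySpec] = field(default_factory=list)
    cs_overlap_voxels: int = 0
    bone_contact: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.tumor_kind not in ("ellipsoid", "annular_wrap"):
            raise ValueError("tumor_kind must be 'ellipsoid' or 'annular_wrap'")
        if not (0.0 <= self.wrap_angle_deg <= 360.0):
            raise ValueError("wrap_angle_deg must lie in [0, 360]")
        if self.cs_overlap_voxels < 0:
            raise ValueError("cs_overlap_voxels must be non-negative")
        names = [a.name for a in self.arteries]
        if len(names) != len(set(names)):
            raise ValueError("artery names must be unique within a spec")

    def effective_wrap_deg(self, artery: ArterySpec) -> float:
        if artery.wrap_angle_deg is not None:
            return float(artery.wrap_angle_deg)
        if self.tumor_kind == "annular_wrap":
            return float(self.wrap_angle_deg)
        return 0.0


@dataclass
class PhantomTruth:
    """Analytic ground truth for every feature the pipeline measures."""

    analytic_tumor_volume_cm3: float
    arteries: dict[str, dict]  # name -> {involved, max_coverage_deg, narrowed}
    cs_involved: bool
    bone_invaded: bool

    def expected_encasements(self) -> list[EncasementResult]:
        out = []
        for name, t in self.arteries.items():
            involved = bool(t["involved"])
            out.append(
                EncasementResult(
                    artery_name=name,
                    involved=involved,
                    max_coverage_deg=float(t["max_coverage_deg"]) if involved else 0.0,
                    fully_encircled=involved and t["max_coverage_deg"] >= 355.0,
                    narrowed=involved and bool(t["narrowed"]),
                )
            )
        return out

    def expected_arterial_score(self) -> int:
        return arterial_involvement_score(self.expected_encasements())


def _densify(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at roughly uniform arc-length step."""
    out = [points[0]]
    for a, b in zip(points[:-1], points[1:]):
        seg = np.linalg.norm(b - a)
        n = max(1, int(math.ceil(seg / step)))
        for i in range(1, n + 1):
            out.append(a + (b - a) * (i / n))
    return np.asarray(out)


def _arc_length_param(samples: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(samples, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _radius_profile(artery: ArterySpec, s: np.ndarray) -> np.ndarray:
    """Local radius along arc length with a smooth cosine narrowing taper."""
    r = np.full_like(s, artery.radius_mm)
    f = artery.narrowing_fraction
    if f <= 0:
        return r
    total = s[-1] if s[-1] > 0 else 1.0
    if artery.narrowing_span_mm is not None:
        s0, s1 = artery.narrowing_span_mm
    else:
        s0, s1 = total / 3.0, 2.0 * total / 3.0
    span = max(s1 - s0, 1e-9)
    inside = (s >= s0) & (s <= s1)
    # raised-cosine bump: full reduction f at the span centre, 0 at the edges
    w = np.zeros_like(s)
    w[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (s[inside] - s0) / span))
    return r * (1.0 - f * np.minimum(w, 1.0))


def _tangents_of(samples: np.ndarray) -> np.ndarray:
    g = np.gradient(samples, axis=0)
    n = np.linalg.norm(g, axis=1)
    n[n == 0] = 1.0
    return g / n[:, None]


def _frame_of(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(float(np.dot(ref, tangent))) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n = ref - np.dot(ref, tangent) * tangent
    n /= np.linalg.norm(n)
    return n, np.cross(tangent, n)


def make_phantom(spec: PhantomSpec) -> tuple[SegmentationSet, PhantomTruth]:
    """Rasterize a phantom and return it with its analytic ground truth.

    Raises
    ------
    PhantomOverflowError
        If the tumor or any artery reaches the outermost voxel layer.
    LabelCollisionError
        If two artery tubes overlap.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm)
    step = float(spacing.min()) / 2.0

    idx = np.indices(shape).reshape(3, -1).T  # (N, 3) voxel indices
    coords = idx * spacing  # voxel centres, mm

    artery_masks: dict[str, np.ndarray] = {}
    artery_geometry: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    union = np.zeros(shape, dtype=bool)
    for artery in spec.arteries:
        samples = _densify(artery.control_points_mm, step)
        s = _arc_length_param(samples)
        radii = _radius_profile(artery, s)
        tangents = _tangents_of(samples)
        tree = cKDTree(samples)
        reach = float(radii.max()) + float(spacing.max())
        dist, nearest = tree.query(coords, distance_upper_bound=reach)
        hit = np.isfinite(dist) & (dist <= radii[np.minimum(nearest, len(radii) - 1)])
        mask = np.zeros(shape, dtype=bool)
        mask.ravel()[np.flatnonzero(hit)] = True
        if np.logical_and(mask, union).any():
            raise LabelCollisionError(f"artery {artery.name!r} overlaps another artery label")
        union |= mask
        artery_masks[artery.name] = mask
        artery_geometry[artery.name] = (samples, s, radii, tangents)

    tumor = np.zeros(shape, dtype=bool)
    if spec.tumor_kind == "ellipsoid":
        center = (
            np.asarray(spec.tumor_center_mm, dtype=float)
            if spec.tumor_center_mm is not None
            else (np.asarray(shape) - 1) * spacing / 2.0
        )
        semi = np.asarray(spec.tumor_semiaxes_mm, dtype=float)
        if np.any(semi <= 0):
            raise ValueError("tumor semiaxes must be positive")
        q = ((coords - center) / semi) ** 2
        tumor.ravel()[np.flatnonzero(q.sum(axis=1) <= 1.0)] = True
        analytic_volume = 4.0 / 3.0 * math.pi * float(np.prod(semi)) / 1000.0
    else:
        analytic_volume = 0.0
        for artery in spec.arteries:
            wrap = spec.effective_wrap_deg(artery)
            if wrap <= 0:
                continue
            samples, s, radii, tangents = artery_geometry[artery.name]
            tree = cKDTree(samples)
            outer = artery.radius_mm + spec.wrap_thickness_mm
            reach = outer + float(spacing.max())
            dist, nearest = tree.query(coords, distance_upper_bound=reach)
            ok = np.isfinite(dist)
            cand = np.flatnonzero(ok & (dist <= outer))
            half = math.radians(wrap) / 2.0
            # generic sector orientation: axis-aligned sector edges would sit
            # exactly on lattice planes, where center-inclusion rasterization
            # biases the material edge outward by a half voxel
            offset = math.radians(WRAP_REFERENCE_OFFSET_DEG)
            for vi in cand:
                j = int(nearest[vi])
                d = coords[vi] - samples[j]
                t = tangents[j]
                d_perp = d - np.dot(d, t) * t
                rho = float(np.linalg.norm(d_perp))
                if rho <= radii[j] or rho > outer:
                    continue
                n, b = _frame_of(t)
                ang = math.atan2(float(np.dot(d_perp, b)), float(np.dot(d_perp, n))) - offset
                if ang <= -math.pi:
                    ang += 2.0 * math.pi
                if -half <= ang <= half:
                    tumor.ravel()[vi] = True
            analytic_volume += (
                wrap / 360.0
                * math.pi
                * (outer**2 - artery.radius_mm**2)
                * float(s[-1])
                / 1000.0
            )
    tumor &= ~union  # arterial lumen is never tumor

    voxel_mm3 = float(np.prod(spacing))

    # cavernous sinus: a block in the low corner; the first
    # cs_overlap_voxels of it (lexicographic) are shared with the tumor
    cs = np.zeros(shape, dtype=bool)
    cs_extent = max(8, int(math.ceil((spec.cs_overlap_voxels * 2) ** (1 / 3))) + 2)
    cs[2 : 2 + cs_extent, 2 : 2 + cs_extent, 2 : 2 + cs_extent] = True
    cs &= ~union
    if spec.cs_overlap_voxels > 0:
        flat = np.flatnonzero(cs.ravel())
        if len(flat) < spec.cs_overlap_voxels:
            raise PhantomOverflowError("cs_overlap_voxels exceeds the CS region size")
        tumor.ravel()[flat[: spec.cs_overlap_voxels]] = True

    # bone: a slab against the high-x face; contact shares a fixed block
    bone = np.zeros(shape, dtype=bool)
    bone[shape[0] - 8 : shape[0] - 2, 2 : shape[1] - 2, 2 : shape[2] - 2] = True
    bone &= ~union
    if spec.bone_contact:
        n_contact = int(math.ceil(BONE_CONTACT_CM3 * 1000.0 / voxel_mm3))
        flat = np.flatnonzero(bone.ravel())
        if len(flat) < n_contact:
            raise PhantomOverflowError("bone slab too small for requested contact")
        tumor.ravel()[flat[:n_contact]] = True

    # overflow check: tumor or artery reaching the outermost voxel layer
    border = np.zeros(shape, dtype=bool)
    border[[0, -1], :, :] = True
    border[:, [0, -1], :] = True
    border[:, :, [0, -1]] = True
    for label, mask in [("tumor", tumor)] + list(artery_masks.items()):
        if np.logical_and(mask, border).any():
            raise PhantomOverflowError(f"phantom overflow: {label} reaches the grid boundary")

    truth_arteries = {}
    for artery in spec.arteries:
        wrap = spec.effective_wrap_deg(artery)
        involved = wrap > 0
        truth_arteries[artery.name] = {
            "involved": involved,
            "max_coverage_deg": wrap if involved else 0.0,
            "narrowed": involved and artery.narrowing_fraction >= NARROWING_TRUTH_DELTA,
        }

    # CS-overlap and bone-contact blocks are placed clear of the main tumor
    # body, so their volumes add to the analytic total
    cs_overlap_cm3 = spec.cs_overlap_voxels * voxel_mm3 / 1000.0
    if spec.bone_contact:
        n_contact = int(math.ceil(BONE_CONTACT_CM3 * 1000.0 / voxel_mm3))
        analytic_volume += n_contact * voxel_mm3 / 1000.0
    truth = PhantomTruth(
        analytic_tumor_volume_cm3=analytic_volume + cs_overlap_cm3,
        arteries=truth_arteries,
        cs_involved=cs_overlap_cm3 > 0.1,
        bone_invaded=bool(spec.bone_contact),
    )
    seg = SegmentationSet(
        tumor_mask=tumor,
        artery_masks=artery_masks,
        cs_mask=cs,
        bone_mask=bone,
        spacing_mm=tuple(spacing),
    )
    return seg, truth


def straight_artery(
    name: str,
    x_mm: float,
    y_mm: float,
    z_range_mm: tuple[float, float],
    radius_mm: float = 3.0,
    **kwargs,
) -> ArterySpec:
    """Convenience: a straight z-axis tube at a given (x, y) position."""
    z0, z1 = z_range_mm
    pts = np.array([[x_mm, y_mm, z0], [x_mm, y_mm, z1]])
    return ArterySpec(name=name, control_points_mm=pts, radius_mm=radius_mm, **kwargs)


def random_phantom_spec(seed: int, grid: int = 96) -> PhantomSpec:
    """A randomized annular-wrap phantom for ground-truth recovery tests.

    One to three parallel straight arteries, each with a wrap angle drawn
    from {0, 45, 90, 180, 270, 360} degrees and a narrowing fraction from
    {0, 0.05, 0.30}; random cavernous-sinus overlap and bone contact.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_art = int(rng.integers(1, 4))
    names = list(rng.choice(ARTERY_NAMES, size=n_art, replace=False))
    xs = [grid / 2.0 + (i - (n_art - 1) / 2.0) * 24.0 for i in range(n_art)]
    arteries = []
    any_wrap = False
    for name, x in zip(names, xs):
        wrap = float(rng.choice([0.0, 45.0, 90.0, 180.0, 270.0, 360.0]))
        any_wrap = any_wrap or wrap > 0
        arteries.append(
            straight_artery(
                name,
                x_mm=x,
                y_mm=grid / 2.0,
                z_range_mm=(14.0, grid - 14.0),
                radius_mm=3.0,
                narrowing_fraction=float(rng.choice([0.0, 0.05, 0.30])),
                wrap_angle_deg=wrap,
            )
        )
    if not any_wrap:  # guarantee at least one involved vessel
        arteries[0].wrap_angle_deg = float(rng.choice([45.0, 90.0, 180.0, 270.0, 360.0]))
    return PhantomSpec(
        grid_shape=(grid, grid, grid),
        spacing_mm=(1.0, 1.0, 1.0),
        tumor_kind="annular_wrap",
        arteries=arteries,
        cs_overlap_voxels=int(rng.choice([0, 250])),
        bone_contact=bool(rng.integers(0, 2)),
        seed=seed,
    )
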