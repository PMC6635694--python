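"""Rotational cross-section analysis of the metatarsal head's sesamoid grooves.

The two plantar grooves of the first metatarsal head are modelled as
patches of cylindrical surfaces.  Cutting the head with a plane shows
each groove as a concave arc; the arc's least-squares circle has a
well-defined curvature diameter (CD = 2r).  An oblique cut through a
cylinder always fits a *larger* circle than a perpendicular one, so
rotating the cutting plane in small angular steps and taking the
minimum CD recovers both the groove's true curvature diameter and the
orientation of its axis.  If the medial and the lateral groove reach
their minimal CD at the same rotation angle, the two groove axes are
parallel and flexion happens about a single axis; otherwise the grooves
are dis-parallel.

Conventions (all in the bone's body frame, see :mod:`boneframe.frame`):

* base-level search — the cutting plane *contains* the long axis and
  rotates about it; the orientation with maximal cross-section area is
  the base level;
* CD scan — the cutting plane contains the vertical (third) axis and
  rotates about it in 0.5-degree steps, pivoting on the groove arc's own
  centroid; angle 0 is the coronal orientation (plane normal along the
  long axis).  Positive angles are counter-clockwise looking down the
  rotation axis; pass ``clockwise_positive=True`` to flip the sign.
* medial = positive second-axis (u) coordinate.  An inertial frame
  cannot know anatomical sidedness, so ``flip_sides=True`` swaps labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from shapely.geometry import Point, Polygon

from .errors import (
    CollinearPointsError,
    DegeneracyWarning,
    EmptySectionError,
    GrooveNotFoundError,
    InputError,
)
from .frame import to_body_frame
from .mesh import BoneMesh

__all__ = [
    "CrossSection",
    "CircleFit",
    "GrooveFit",
    "ParallelismResult",
    "section_at",
    "cross_section_area",
    "find_base_level",
    "detect_groove_arcs",
    "fit_circle",
    "locate_grooves",
    "scan_groove_cd",
    "parallelism_test",
    "analyze_grooves",
    "section_to_svg",
]

DEFAULT_STEP = 0.5          # deg, the scan's angular resolution
DEFAULT_RANGE = 10.0        # deg, half-width of the CD scan
DEFAULT_TOLERANCE = 0.5     # deg, parallelism verdict tolerance
_RESAMPLE = 0.25            # mm, contour resampling spacing
_SMOOTH_MM = 0.5            # mm, Gaussian smoothing of the contour
_CURV_THRESHOLD = -0.05     # 1/mm, concavity threshold on signed curvature


# ---------------------------------------------------------------------------
# sections
# ---------------------------------------------------------------------------

@dataclass
class CrossSection:
    """Planar cut of a mesh: plane, in-plane basis and closed 2D contours.

    The in-plane basis is ``(u, v)`` with ``v`` along the rotation axis
    and ``u = axis x normal``, both unit; contour coordinates are
    relative to the pivot point.  ``area`` uses even-odd filling so
    nested contours count as holes.
    """

    plane_origin: np.ndarray
    plane_normal: np.ndarray
    u: np.ndarray
    v: np.ndarray
    contours: list = field(default_factory=list)
    area: float = 0.0
    angle: float = 0.0


def _reference_normal(axis: np.ndarray) -> np.ndarray:
    """Deterministic unit vector perpendicular to ``axis`` (the angle-zero
    plane normal): the global axis least aligned with ``axis``,
    orthogonalized."""
    k = int(np.argmin(np.abs(axis)))
    n0 = np.zeros(3)
    n0[k] = 1.0
    n0 -= axis * (n0 @ axis)
    return n0 / np.linalg.norm(n0)


def _rotate_about(vec: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    th = np.deg2rad(angle_deg)
    a = axis / np.linalg.norm(axis)
    return (
        vec * np.cos(th)
        + np.cross(a, vec) * np.sin(th)
        + a * (a @ vec) * (1.0 - np.cos(th))
    )


def cross_section_area(contours) -> float:
    """Even-odd area of a set of closed 2D contours (holes subtract)."""
    polys = []
    for c in contours:
        if len(c) >= 3:
            poly = Polygon(c)
            if poly.is_valid and poly.area > 0:
                polys.append(poly)
    total = 0.0
    for i, poly in enumerate(polys):
        # nesting depth via a boundary vertex: a contour's own vertex is
        # strictly inside every contour that truly encloses it, whereas an
        # interior representative point could also fall inside a *nested*
        # contour and miscount
        probe = Point(poly.exterior.coords[0])
        depth = sum(
            1 for j, other in enumerate(polys) if j != i and other.contains(probe)
        )
        total += poly.area if depth % 2 == 0 else -poly.area
    return float(total)


def section_at(
    mesh: BoneMesh,
    axis,
    angle: float = 0.0,
    plane_offset: float = 0.0,
    pivot=None,
) -> CrossSection:
    """Cut ``mesh`` with a plane containing ``axis`` rotated by ``angle``.

    The plane passes through ``pivot`` (default: the origin — i.e. the
    COM for a mesh in its body frame) shifted by ``plane_offset`` along
    the plane normal.  Raises :class:`EmptySectionError` when the plane
    misses the mesh.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    pivot = np.zeros(3) if pivot is None else np.asarray(pivot, dtype=float)
    normal = _rotate_about(_reference_normal(axis), axis, angle)
    origin = pivot + plane_offset * normal
    path = mesh.tri.section(plane_origin=origin, plane_normal=normal)
    if path is None or len(path.entities) == 0:
        raise EmptySectionError(
            f"plane (origin={origin.round(3)}, normal={normal.round(3)}) "
            "does not intersect the mesh"
        )
    v = axis
    u = np.cross(axis, normal)
    contours = []
    for curve in path.discrete:
        rel = np.asarray(curve) - origin
        c2 = np.column_stack([rel @ u, rel @ v])
        if len(c2) >= 3 and np.allclose(c2[0], c2[-1]):
            c2 = c2[:-1]
        contours.append(c2)
    return CrossSection(
        plane_origin=origin,
        plane_normal=normal,
        u=u,
        v=v,
        contours=contours,
        area=cross_section_area(contours),
        angle=float(angle),
    )


def find_base_level(
    mesh: BoneMesh, axis=None, angular_step: float = DEFAULT_STEP
) -> tuple[float, float]:
    """Angle (deg, in [0, 180)) of the maximal-area plane containing ``axis``.

    ``axis`` defaults to body x (the long axis).  Exact ties return the
    smallest angle with a :class:`DegeneracyWarning`.
    """
    if angular_step <= 0:
        raise InputError(f"angular_step must be > 0, got {angular_step}")
    axis = np.array([1.0, 0.0, 0.0]) if axis is None else np.asarray(axis, dtype=float)
    angles = np.arange(0.0, 180.0, angular_step)
    areas = np.empty(len(angles))
    for i, ang in enumerate(angles):
        try:
            areas[i] = section_at(mesh, axis, ang).area
        except EmptySectionError:
            areas[i] = 0.0
    best = int(np.argmax(areas))
    if np.isclose(areas, areas[best], rtol=1e-9).sum() > 1:
        warnings.warn("cross-section area tie; returning smallest angle",
                      DegeneracyWarning, stacklevel=2)
        best = int(np.flatnonzero(np.isclose(areas, areas[best], rtol=1e-9))[0])
    return float(angles[best]), float(areas[best])


# ---------------------------------------------------------------------------
# arcs and circles
# ---------------------------------------------------------------------------

def _resample_closed(points: np.ndarray, spacing: float):
    """Uniform arc-length resampling of a closed polyline."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(total / spacing), 16)
    si = np.linspace(0.0, total, n, endpoint=False)
    return np.column_stack(
        [np.interp(si, s, closed[:, 0]), np.interp(si, s, closed[:, 1])]
    ), total / n


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _signed_curvature(points: np.ndarray, h: float, sigma_mm: float = _SMOOTH_MM):
    """Discrete signed curvature of a CCW closed contour (concave < 0)."""
    sigma = max(sigma_mm / h, 0.5)
    x = gaussian_filter1d(points[:, 0], sigma, mode="wrap")
    y = gaussian_filter1d(points[:, 1], sigma, mode="wrap")
    dx, dy = np.gradient(x) / h, np.gradient(y) / h
    ddx, ddy = np.gradient(dx) / h, np.gradient(dy) / h
    speed = np.maximum((dx * dx + dy * dy) ** 1.5, 1e-12)
    return (dx * ddy - dy * ddx) / speed


def _concave_runs(mask: np.ndarray):
    """Circular index runs where ``mask`` holds."""
    n = len(mask)
    if mask.all():
        return [np.arange(n)]
    if not mask.any():
        return []
    # rotate so position 0 is outside a run, making runs non-wrapping
    start = int(np.flatnonzero(~mask)[0])
    rolled = np.roll(mask, -start)
    idx = np.flatnonzero(rolled)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    return [(run + start) % n for run in runs]


@dataclass
class GrooveArcs:
    """Detected concave plantar arcs of one cross-section (2D points in
    the section's (u, v) frame, plus their 3D world coordinates)."""

    medial: np.ndarray
    lateral: np.ndarray
    medial_3d: np.ndarray
    lateral_3d: np.ndarray
    plantar_sign: int


def detect_groove_arcs(
    section: CrossSection,
    min_arc_points: int = 5,
    curvature_threshold: float = _CURV_THRESHOLD,
    flip_sides: bool = False,
) -> GrooveArcs:
    """Find the medial and lateral groove arcs on a head cross-section.

    The longest closed contour is resampled uniformly, its signed
    curvature computed, and maximal runs of concavity (curvature below
    ``curvature_threshold``) extracted.  The plantar side is identified
    as the v-sign carrying the larger total concave arc length; the two
    longest concave runs on that side become the groove arcs, labelled
    medial/lateral by the sign of their u-centroid.
    """
    contour = max(section.contours, key=len)
    if len(contour) < 8:
        raise GrooveNotFoundError("section contour too short for arc detection")
    perimeter = float(
        np.linalg.norm(np.diff(np.vstack([contour, contour[:1]]), axis=0), axis=1).sum()
    )
    # resolution follows the contour size so small bones are not
    # undersampled: at least ~400 samples around the section
    spacing = min(_RESAMPLE, perimeter / 400.0)
    points, h = _resample_closed(contour, spacing)
    sigma_mm = 2.0 * spacing  # smoothing follows the sampling scale
    if _signed_area(points) < 0:
        points = points[::-1]
    kappa = _signed_curvature(points, h, sigma_mm=sigma_mm)
    runs = [r for r in _concave_runs(kappa < curvature_threshold)
            if len(r) >= min_arc_points]
    if len(runs) < 2:
        raise GrooveNotFoundError(
            f"found {len(runs)} concave arcs, need at least 2 grooves"
        )
    # classify relative to the contour's own centroid: the plane origin is
    # an arbitrary pivot (during CD scans it sits *on* one groove), so raw
    # (u, v) signs say nothing about anatomy
    centre = points.mean(axis=0)
    by_side: dict[int, list] = {1: [], -1: []}
    for run in runs:
        centroid_v = points[run, 1].mean() - centre[1]
        by_side[1 if centroid_v >= 0 else -1].append(run)
    lengths = {s: sum(len(r) for r in rs) for s, rs in by_side.items()}
    plantar = 1 if lengths[1] > lengths[-1] else -1
    plantar_runs = sorted(by_side[plantar], key=len, reverse=True)[:2]
    if len(plantar_runs) < 2:
        raise GrooveNotFoundError("fewer than 2 concave arcs on the plantar side")
    plantar_runs.sort(key=lambda r: points[r, 0].mean() - centre[0])  # ascending u
    neg_u, pos_u = plantar_runs

    def to3d(run):
        p2 = points[run]
        return (
            section.plane_origin
            + p2[:, :1] * section.u
            + p2[:, 1:2] * section.v
        )

    medial_run, lateral_run = (neg_u, pos_u) if flip_sides else (pos_u, neg_u)
    return GrooveArcs(
        medial=points[medial_run],
        lateral=points[lateral_run],
        medial_3d=to3d(medial_run),
        lateral_3d=to3d(lateral_run),
        plantar_sign=plantar,
    )


@dataclass
class CircleFit:
    center: np.ndarray
    radius: float
    rms_residual: float
    n_points: int

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


def fit_circle(points) -> CircleFit:
    """Algebraic least-squares circle (Kasa fit) through 2D points.

    Solves the linearized problem ``min sum (|p - c|^2 - r^2)^2``, which
    reduces to one 3x3 least-squares system; exact for points on a true
    circle (3 points give the circumscribed circle).  Raises
    :class:`CollinearPointsError` for degenerate input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise InputError("fit_circle needs an (n>=3, 2) point array")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones(len(x))])
    b = x * x + y * y
    scale = max(np.ptp(x), np.ptp(y), 1e-30)
    if np.linalg.matrix_rank(A - A.mean(axis=0), tol=1e-9 * scale) < 2:
        raise CollinearPointsError("points are collinear; no unique circle")
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = coef[0] / 2.0, coef[1] / 2.0
    r2 = coef[2] + cx * cx + cy * cy
    if r2 <= 0:
        raise CollinearPointsError("degenerate circle fit (non-positive radius)")
    radius = float(np.sqrt(r2))
    rms = float(np.sqrt(np.mean((np.hypot(x - cx, y - cy) - radius) ** 2)))
    return CircleFit(center=np.array([cx, cy]), radius=radius,
                     rms_residual=rms, n_points=len(pts))


# ---------------------------------------------------------------------------
# groove scanning
# ---------------------------------------------------------------------------

@dataclass
class GrooveFit:
    """Best curvature-circle fit for one groove over a rotational scan."""

    side: str                   # 'medial' | 'lateral'
    rotation_angle: float       # deg, signed, at the scan's optimum
    circle_center: np.ndarray   # 2D, section (u, v) frame
    curvature_diameter: float   # mm
    rms_residual: float         # mm
    arc_points: int
    scan_settings: dict = field(default_factory=dict, repr=False)
    trace: list = field(default_factory=list, repr=False)  # (angle, CD) pairs


@dataclass
class ParallelismResult:
    medial_fit: GrooveFit
    lateral_fit: GrooveFit
    angle_difference: float
    verdict: str                # 'parallel' | 'dis_parallel'
    tolerance: float

    @property
    def parallel(self) -> bool:
        return self.verdict == "parallel"


def locate_grooves(mesh: BoneMesh, flip_sides: bool = False, n_offsets: int = 40):
    """Find the coronal level and arc centroids of the two grooves.

    Scans planes perpendicular to the long axis along the bone and keeps
    the offset with the largest total groove arc length.  Returns
    ``{'medial': pivot, 'lateral': pivot, 'offset': x}`` with 3D pivot
    points (the arc centroids) in the mesh's coordinates.  The mesh must
    be in its body frame.
    """
    lo, hi = mesh.bounds[0][0], mesh.bounds[1][0]
    offsets = np.linspace(0.9 * lo, 0.9 * hi, n_offsets)
    best = None
    for off in offsets:
        try:
            sec = section_at(mesh, [0.0, 0.0, 1.0], 0.0, pivot=[off, 0.0, 0.0])
            arcs = detect_groove_arcs(sec, flip_sides=flip_sides)
        except (EmptySectionError, GrooveNotFoundError):
            continue
        score = len(arcs.medial) + len(arcs.lateral)
        if best is None or score > best[0]:
            best = (score, off, arcs)
    if best is None:
        raise GrooveNotFoundError("no cross-section with two groove arcs found")
    _, off, arcs = best
    return {
        "medial": arcs.medial_3d.mean(axis=0),
        "lateral": arcs.lateral_3d.mean(axis=0),
        "offset": float(off),
    }


def _refine_extremum(trace, step: float, scan: str) -> tuple[float, float]:
    """Angle of the scan extremum, stabilized against measurement noise.

    Around its optimum the CD-vs-angle curve of a cylindrical groove is
    a shallow parabola (an oblique cut of a cylinder fits a circle of
    radius r / cos^2(eps)), so surface noise makes the raw arg-extremum
    jitter by several steps.  A quadratic is fitted to the trace in a
    window around the raw extremum; its vertex is the continuous angle
    estimate.  Returns ``(continuous_angle, nearest_grid_angle)``; if
    the parabola is degenerate or bends the wrong way the raw extremum
    stands for both.
    """
    angles = np.array([t[0] for t in trace])
    cds = np.array([t[1] for t in trace])
    sign = 1.0 if scan == "min_cd" else -1.0
    raw = float(angles[int(np.argmin(sign * cds))])
    window = max(6.0 * step, 3.0)
    sel = np.abs(angles - raw) <= window + 1e-9
    if sel.sum() < 5:
        return raw, raw
    coef = np.polyfit(angles[sel], sign * cds[sel], 2)
    if coef[0] <= 0:
        return raw, raw
    vertex = float(-coef[1] / (2.0 * coef[0]))
    if abs(vertex - raw) > window:
        return raw, raw
    grid = angles[int(np.argmin(np.abs(angles - vertex)))]
    return vertex, float(grid)


def _trim_run(points: np.ndarray, fraction: float = 0.12) -> np.ndarray:
    """Drop the ends of an arc, where contour smoothing bleeds into the
    neighbouring convex surface."""
    k = int(len(points) * fraction)
    return points[k: len(points) - k] if len(points) > 2 * k + 5 else points


def _symmetric_arc_fit(points: np.ndarray, plantar_sign: int) -> CircleFit:
    """Circle fit on an arc symmetrized about the groove's deepest line.

    The detected concave run ends wherever the neighbouring convex
    surface takes over, which is generally asymmetric about the groove
    vertex and biases the fitted circle (and hence the angle at which
    the scan's CD minimum occurs).  The vertex — the arc point furthest
    towards the bone interior, i.e. opposite the plantar opening — does
    not depend on the run boundaries, so the fit is repeated on the
    largest point span symmetric about it.
    """
    fit0 = fit_circle(points)
    vertex = int(np.argmax(-plantar_sign * points[:, 1]))
    theta = np.arctan2(points[:, 1] - fit0.center[1], points[:, 0] - fit0.center[0])
    rel = np.unwrap(theta) - np.unwrap(theta)[vertex]
    span = min(-rel.min(), rel.max())
    if span <= 0:
        return fit0
    keep = np.abs(rel) <= span + 1e-12
    if keep.sum() < 5:
        return fit0
    return fit_circle(points[keep])


def scan_groove_cd(
    mesh: BoneMesh,
    side: str,
    scan: str = "min_cd",
    angle_range: float = DEFAULT_RANGE,
    step: float = DEFAULT_STEP,
    pivot=None,
    flip_sides: bool = False,
    clockwise_positive: bool = False,
    rotation_axis=None,
    n_offset_sections: int = 5,
    offset_span: float | None = None,
) -> GrooveFit:
    """Rotational CD scan of one groove (mesh in body frame).

    The cutting plane contains the rotation axis (default: body z, the
    vertical axis), pivots on the groove-arc centroid, and sweeps
    ``[-angle_range, +angle_range]`` around the coronal orientation in
    ``step`` increments.  Per angle the groove arc is re-detected and a
    circle fitted; the fit with minimal (``scan='min_cd'``) or maximal
    (``'max_cd'``) curvature diameter is returned, with its signed
    rotation angle.

    Because a groove is (a patch of) a cylinder, shifting the cutting
    plane along its own normal slides it along the groove without
    changing the ideal cross-section, so per angle the CD is averaged
    over ``n_offset_sections`` parallel planes spread across
    ``+-offset_span`` mm — mesh discretization noise decorrelates
    between the planes while the signal does not.  ``offset_span=None``
    picks half the groove radius estimated from a pilot fit at the base
    orientation, keeping the planes well inside the groove.
    """
    if step <= 0:
        raise InputError(f"step must be > 0, got {step}")
    if scan not in ("min_cd", "max_cd"):
        raise InputError(f"scan must be 'min_cd' or 'max_cd', got {scan!r}")
    if side not in ("medial", "lateral"):
        raise InputError(f"side must be 'medial' or 'lateral', got {side!r}")
    axis = np.array([0.0, 0.0, 1.0]) if rotation_axis is None else np.asarray(
        rotation_axis, dtype=float)
    if pivot is None:
        pivot = locate_grooves(mesh, flip_sides=flip_sides)[side]
    settings = {
        "scan": scan, "angle_range": float(angle_range), "step": float(step),
        "flip_sides": flip_sides, "clockwise_positive": clockwise_positive,
        "rotation_axis": tuple(np.round(axis, 12)),
    }
    if offset_span is None:
        try:
            sec0 = section_at(mesh, axis, 0.0, pivot=pivot)
            arcs0 = detect_groove_arcs(sec0, flip_sides=flip_sides)
            pilot = _symmetric_arc_fit(
                _trim_run(getattr(arcs0, side)), arcs0.plantar_sign
            )
            offset_span = 0.5 * pilot.radius
        except (EmptySectionError, GrooveNotFoundError, CollinearPointsError):
            offset_span = 1.0
    angles = np.arange(-angle_range, angle_range + 1e-9, step)
    offsets = (
        np.linspace(-offset_span, offset_span, n_offset_sections)
        if n_offset_sections > 1
        else np.array([0.0])
    )
    fits = {}
    trace = []
    for ang in angles:
        diameters = []
        central_fit = None
        for off in offsets:
            try:
                sec = section_at(mesh, axis, ang, plane_offset=off, pivot=pivot)
                arcs = detect_groove_arcs(sec, flip_sides=flip_sides)
                arc = _trim_run(getattr(arcs, side))
                fit = _symmetric_arc_fit(arc, arcs.plantar_sign)
            except (EmptySectionError, GrooveNotFoundError, CollinearPointsError):
                continue
            diameters.append(fit.diameter)
            if central_fit is None or abs(off) < central_fit[0]:
                central_fit = (abs(off), fit)
        if not diameters:
            continue
        trace.append((float(ang), float(np.mean(diameters))))
        fits[float(ang)] = central_fit[1]
    if not fits:
        raise GrooveNotFoundError(
            f"{side} groove not detected at any scanned angle"
        )
    ang, grid_ang = _refine_extremum(trace, step, scan)
    fit = fits[grid_ang]
    # the reported CD is the definitional scan extremum over the trace
    cds = [c for _, c in trace]
    cd = min(cds) if scan == "min_cd" else max(cds)
    signed = -ang if clockwise_positive else ang
    return GrooveFit(
        side=side,
        rotation_angle=signed,
        circle_center=fit.center,
        curvature_diameter=cd,
        rms_residual=fit.rms_residual,
        arc_points=fit.n_points,
        scan_settings=settings,
        trace=trace,
    )


def parallelism_test(
    medial: GrooveFit,
    lateral: GrooveFit,
    tolerance: float = DEFAULT_TOLERANCE,
) -> ParallelismResult:
    """Compare the min-CD rotation angles of the two grooves.

    The grooves are parallel iff both reach their smallest CD in the
    same cross-section orientation, i.e. the angle difference does not
    exceed ``tolerance`` (degrees).
    """
    if tolerance < 0:
        raise InputError(f"tolerance must be >= 0, got {tolerance}")
    if {medial.side, lateral.side} != {"medial", "lateral"}:
        raise InputError("parallelism_test needs one medial and one lateral fit")
    keys = ("scan", "step", "flip_sides", "clockwise_positive", "rotation_axis")
    for key in keys:
        if medial.scan_settings.get(key) != lateral.scan_settings.get(key):
            raise InputError(
                f"mismatched scan settings ({key!r}); both fits must come "
                "from the same scan configuration"
            )
    med = medial if medial.side == "medial" else lateral
    lat = lateral if lateral.side == "lateral" else medial
    diff = float(med.rotation_angle - lat.rotation_angle)
    verdict = "parallel" if abs(diff) <= tolerance + 1e-12 else "dis_parallel"
    return ParallelismResult(
        medial_fit=med,
        lateral_fit=lat,
        angle_difference=diff,
        verdict=verdict,
        tolerance=float(tolerance),
    )


def analyze_grooves(
    mesh: BoneMesh,
    angle_range: float = DEFAULT_RANGE,
    step: float = DEFAULT_STEP,
    tolerance: float = DEFAULT_TOLERANCE,
    flip_sides: bool = False,
    clockwise_positive: bool = False,
    in_body_frame: bool = False,
) -> ParallelismResult:
    """Full pipeline: body frame, locate grooves, min-CD scan both sides,
    parallelism verdict."""
    aligned = mesh if in_body_frame else to_body_frame(mesh)
    pivots = locate_grooves(aligned, flip_sides=flip_sides)
    fits = {
        side: scan_groove_cd(
            aligned, side,
            angle_range=angle_range, step=step, pivot=pivots[side],
            flip_sides=flip_sides, clockwise_positive=clockwise_positive,
        )
        for side in ("medial", "lateral")
    }
    return parallelism_test(fits["medial"], fits["lateral"], tolerance=tolerance)


def section_to_svg(section: CrossSection, path, scale: float = 10.0) -> None:
    """Write the section contours as a minimal standalone SVG."""
    allpts = np.vstack([c for c in section.contours])
    lo = allpts.min(axis=0) - 1
    hi = allpts.max(axis=0) + 1
    size = (hi - lo) * scale
    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size[0]:.0f}" '
        f'height="{size[1]:.0f}" viewBox="0 0 {size[0]:.2f} {size[1]:.2f}">'
    ]
    for c in section.contours:
        # flip v so plantar (v<0) plots downward
        pts = " ".join(
            f"{(p[0]-lo[0])*scale:.2f},{(hi[1]-p[1])*scale:.2f}" for p in c
        )
        lines.append(
            f'<polygon points="{pts}" fill="none" stroke="black" stroke-width="1"/>'
        )
    lines.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
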