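"""Parametric bone-like test solids with known ground truth.

The generator emulates the geometry the analysis modules care about: an
elongated shaft (an elliptical capsule, optionally with a smooth seeded
surface undulation so different seeds give different "individuals"), a
spherical articular head, and two sesamoid grooves carved into the
plantar side of the head as finite cylinders of known radius whose axes
are rotated ("skewed") about the vertical axis by a known angle.  A
damage operator removes a prescribed volume fraction and re-closes the
surface, mimicking a damaged fossil.

Solids are built as a continuous signed-distance CSG field sampled on a
regular grid and extracted with marching cubes at level 0, which keeps
the surface sub-voxel accurate — important because groove-curvature
recovery is tested at the few-percent level.  Ground-truth volume comes
from counting interior grid cells of the same field (an oracle
independent of the output mesh's surface integrals).

What this generator does *not* emulate: cortical/trabecular structure,
anatomical torsion, scanning noise or segmentation artefacts.  Tests
passing on these solids certify the geometry pipeline, not robustness to
real CT segmentations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError
from .mesh import BoneMesh
from .voxel import mesh_from_field, solid_occupancy

__all__ = ["BoneParams", "GroundTruth", "SubjectMeshes", "make_bone", "damage",
           "make_subject", "random_params"]


@dataclass
class BoneParams:
    """Geometry of one synthetic bone (all lengths in mm, angles in deg).

    ``shaft_taper`` flares the proximal base: the shaft radii are scaled
    by ``1 + shaft_taper`` at the base, falling linearly to 1 at the
    head end — long bones are wider at their base, and the flare also
    pins down the bone's position along its own axis (a perfectly
    cylindrical shaft would leave rigid registration under-determined
    longitudinally).  ``groove_skew_*`` is the rotation of the groove
    axis away from the long axis, about the vertical axis; 0 means the
    groove runs exactly along the bone.  ``mesh_resolution`` r sets the sampling pitch to
    ``head_radius / (10 * 2**r)`` (r=2 -> head_radius/40).
    ``surface_noise`` adds a smooth seeded undulation of that amplitude
    to the shaft/head surface (0 disables it; keep it well below the
    groove radius when grooves matter).
    """

    shaft_length: float = 60.0
    shaft_radii: tuple[float, float] = (9.0, 8.0)
    shaft_taper: float = 0.2
    head_radius: float = 10.0
    groove_radius_medial: float = 4.0
    groove_radius_lateral: float = 4.0
    groove_skew_medial: float = 0.0
    groove_skew_lateral: float = 0.0
    groove_offset_frac: float = 0.45
    groove_depth_frac: float = 0.85
    mesh_resolution: int = 2
    surface_noise: float = 0.0
    seed: int = 0
    name: str = "synthetic_bone"
    carve_grooves: bool = True

    def __post_init__(self) -> None:
        for key in ("shaft_length", "head_radius"):
            if getattr(self, key) <= 0:
                raise InputError(f"{key} must be > 0")
        if min(self.shaft_radii) <= 0:
            raise InputError("shaft radii must be > 0")
        if self.carve_grooves:
            for key in ("groove_radius_medial", "groove_radius_lateral"):
                r = getattr(self, key)
                if not 0 < r < self.head_radius:
                    raise InputError(f"{key} must be in (0, head_radius), got {r}")
        if self.mesh_resolution < 2:
            raise InputError("mesh_resolution must be >= 2")

    @property
    def pitch(self) -> float:
        return self.head_radius / (10.0 * 2**self.mesh_resolution)


@dataclass
class GroundTruth:
    """Construction-frame truth for a generated bone."""

    volume: float                      # mm^3, from the field's interior cells
    surface_area: float                # mm^2, from the extracted mesh
    extents: tuple[float, float, float]  # analytic bounding box (x, y, z)
    groove_cd_medial: float | None     # 2 * groove radius
    groove_cd_lateral: float | None
    groove_angle_medial: float | None  # deg, skew about the vertical axis
    groove_angle_lateral: float | None
    removed_fraction: float = 0.0      # set by :func:`damage`


@dataclass
class SubjectMeshes:
    metatarsal: BoneMesh
    proximal: BoneMesh
    distal: BoneMesh
    truth: dict[str, GroundTruth] = field(default_factory=dict)


def _groove_axes(p: BoneParams):
    """(point-on-axis, unit direction, radius, half-length) per groove.

    Grooves sit on the plantar (-z) side of the head, symmetric about the
    sagittal plane at y = +- offset_frac * head_radius; medial is +y.
    """
    head_c = np.array([p.shaft_length, 0.0, 0.0])
    out = []
    for sgn, r, skew in (
        (+1.0, p.groove_radius_medial, p.groove_skew_medial),
        (-1.0, p.groove_radius_lateral, p.groove_skew_lateral),
    ):
        th = np.deg2rad(skew)
        direction = np.array([np.cos(th), np.sin(th), 0.0])
        point = head_c + np.array(
            [0.0, sgn * p.groove_offset_frac * p.head_radius,
             -p.groove_depth_frac * p.head_radius]
        )
        out.append((point, direction, r, 1.2 * p.head_radius))
    return out


def _segment_distance(p0, d0, h0, p1, d1, h1) -> float:
    """Minimum distance between two line segments (centre/direction/half-length)."""
    ts = np.linspace(-h0, h0, 200)
    a = p0 + ts[:, None] * d0
    us = np.linspace(-h1, h1, 200)
    b = p1 + us[:, None] * d1
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def _bone_field(p: BoneParams, X, Y, Z):
    """Signed-distance-like CSG field (negative inside)."""
    ry, rz = p.shaft_radii
    t = np.clip(X, 0.0, p.shaft_length)
    flare = 1.0 + p.shaft_taper * (1.0 - t / p.shaft_length)
    ry, rz = ry * flare, rz * flare
    f_shaft = (
        np.sqrt((Y / ry) ** 2 + (Z / rz) ** 2 + ((X - t) / ry) ** 2) - 1.0
    ) * min(p.shaft_radii)
    f_head = np.sqrt((X - p.shaft_length) ** 2 + Y**2 + Z**2) - p.head_radius
    f = np.minimum(f_shaft, f_head)
    if p.surface_noise > 0:
        rng = np.random.default_rng(p.seed)
        wavelength = 0.6 * min(*p.shaft_radii, p.head_radius)
        for _ in range(4):
            k = rng.normal(size=3)
            k *= 2 * np.pi / (wavelength * np.linalg.norm(k))
            phase = rng.uniform(0, 2 * np.pi)
            f = f + (p.surface_noise / 4.0) * np.sin(k[0] * X + k[1] * Y + k[2] * Z + phase)
    if p.carve_grooves:
        grooves = _groove_axes(p)
        (q0, a0, r0, h0), (q1, a1, r1, h1) = grooves
        if _segment_distance(q0, a0, h0, q1, a1, h1) <= r0 + r1:
            raise InputError(
                "groove cylinders overlap; reduce radii/skews or increase head_radius"
            )
        for q, a, r, h in grooves:
            rel = np.stack([X - q[0], Y - q[1], Z - q[2]])
            dot = np.clip(rel[0] * a[0] + rel[1] * a[1] + rel[2] * a[2], -h, h)
            fg = (
                np.sqrt(
                    (rel[0] - dot * a[0]) ** 2
                    + (rel[1] - dot * a[1]) ** 2
                    + (rel[2] - dot * a[2]) ** 2
                )
                - r
            )
            f = np.maximum(f, -fg)
    return f


def make_bone(params: BoneParams | None = None, **kwargs) -> tuple[BoneMesh, GroundTruth]:
    """Sample the bone field on a grid and extract a watertight mesh.

    Deterministic for a given parameter set (including seed).  Returns
    the mesh in the construction frame: shaft along +x from 0, head
    centred at ``(shaft_length, 0, 0)``, grooves on the -z side.
    """
    p = params if params is not None else BoneParams(**kwargs)
    pitch = p.pitch
    ry, rz = p.shaft_radii
    ry_b, rz_b = ry * (1.0 + p.shaft_taper), rz * (1.0 + p.shaft_taper)
    pad = 2.0 * pitch + p.surface_noise
    # the shaft's rounded distal cap can poke past the head when ry > R
    tip = max(p.head_radius, ry)
    lo = np.array([-ry_b, -max(ry_b, p.head_radius), -max(rz_b, p.head_radius)]) - pad
    hi = np.array(
        [p.shaft_length + tip,
         max(ry_b, p.head_radius),
         max(rz_b, p.head_radius)]
    ) + pad
    xs, ys, zs = (np.arange(lo[k], hi[k] + pitch, pitch) for k in range(3))
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    f = _bone_field(p, X, Y, Z)
    mesh = mesh_from_field(f, (xs[0], ys[0], zs[0]), pitch, level=0.0, name=p.name)
    truth = GroundTruth(
        volume=float((f < 0).sum()) * pitch**3,
        surface_area=float(mesh.tri.area),
        extents=(
            p.shaft_length + tip + ry_b,
            2 * max(ry_b, p.head_radius),
            2 * max(rz_b, p.head_radius),
        ),
        groove_cd_medial=2 * p.groove_radius_medial if p.carve_grooves else None,
        groove_cd_lateral=2 * p.groove_radius_lateral if p.carve_grooves else None,
        groove_angle_medial=p.groove_skew_medial if p.carve_grooves else None,
        groove_angle_lateral=p.groove_skew_lateral if p.carve_grooves else None,
    )
    return mesh, truth


def damage(
    mesh: BoneMesh,
    mode: str = "plane_clip",
    fraction: float = 0.2,
    seed: int = 0,
    pitch: float = 0.25,
    direction=None,
) -> tuple[BoneMesh, float]:
    """Remove ~``fraction`` of the solid volume and re-close the surface.

    ``plane_clip`` removes everything beyond a plane placed so that the
    requested volume fraction lies on its far side; the plane normal
    points towards the long (+x at construction, head) end with a seeded
    angular jitter of up to ~25 degrees, unless an explicit ``direction``
    is given.  ``sphere_bite`` removes the
    intersection with a sphere centred on a seeded surface point, its
    radius bisected to match the fraction.  Both operate on a voxelized
    solid and re-extract the surface, so the result is watertight.
    """
    if not 0 < fraction < 0.5:
        raise InputError(f"damage fraction must be in (0, 0.5), got {fraction}")
    if mode not in ("plane_clip", "sphere_bite"):
        raise InputError(f"unknown damage mode {mode!r}")
    rng = np.random.default_rng(seed)
    occ, axes = solid_occupancy(mesh, pitch)
    xs, ys, zs = axes
    ii, jj, kk = np.nonzero(occ)
    pts = np.column_stack([xs[ii], ys[jj], zs[kk]])
    n_total = len(ii)

    if mode == "plane_clip":
        if direction is None:
            normal = np.array([1.0, 0.0, 0.0]) + 0.45 * rng.normal(size=3)
        else:
            normal = np.asarray(direction, dtype=float)
        normal = normal / np.linalg.norm(normal)
        proj = pts @ normal
        cut = np.quantile(proj, 1.0 - fraction)
        remove = proj > cut
    else:
        centre = mesh.vertices[rng.integers(len(mesh.vertices))]
        d = np.linalg.norm(pts - centre, axis=1)
        lo_r, hi_r = 0.0, float(d.max())
        for _ in range(40):
            mid = 0.5 * (lo_r + hi_r)
            if (d < mid).sum() / n_total < fraction:
                lo_r = mid
            else:
                hi_r = mid
        remove = d < 0.5 * (lo_r + hi_r)

    kept = occ.copy()
    kept[ii[remove], jj[remove], kk[remove]] = False
    removed_fraction = float(remove.sum()) / n_total
    from .voxel import mesh_from_occupancy

    out = mesh_from_occupancy(kept, axes, pitch, name=f"{mesh.name}_damaged")
    return out, removed_fraction


def make_subject(
    scale: float = 1.0,
    params: BoneParams | None = None,
    proximal_distal_ratio: float = 1.83,
    seed: int = 0,
) -> SubjectMeshes:
    """Three proportioned bones (metatarsal, proximal, distal phalanx).

    The metatarsal carries the sesamoid grooves; phalanges are plain
    capsule-and-head solids.  The distal phalanx is a uniformly rescaled
    rounder variant sized so proximal/distal volume ratio matches
    ``proximal_distal_ratio`` (default 1.83, the proportional volume
    distribution reported for well-preserved hominin first rays — far
    below the ~3x of modern athletes).
    """
    if scale <= 0:
        raise InputError(f"scale must be > 0, got {scale}")
    base = params if params is not None else BoneParams(seed=seed)
    mt_params = replace(
        base,
        shaft_length=base.shaft_length * scale,
        shaft_radii=(base.shaft_radii[0] * scale, base.shaft_radii[1] * scale),
        head_radius=base.head_radius * scale,
        groove_radius_medial=base.groove_radius_medial * scale,
        groove_radius_lateral=base.groove_radius_lateral * scale,
        name="metatarsal",
    )
    metatarsal, mt_truth = make_bone(mt_params)

    def phalanx(length_frac: float, radius_frac: float, head_frac: float, name: str,
                extra_scale: float = 1.0) -> tuple[BoneMesh, GroundTruth]:
        s = scale * extra_scale
        pp = replace(
            base,
            shaft_length=base.shaft_length * length_frac * s,
            shaft_radii=(
                base.shaft_radii[0] * radius_frac * s,
                base.shaft_radii[1] * radius_frac * s,
            ),
            head_radius=base.head_radius * head_frac * s,
            carve_grooves=False,
            surface_noise=base.surface_noise * s,
            name=name,
        )
        return make_bone(pp)

    proximal, pp_truth = phalanx(0.42, 0.85, 0.80, "proximal_phalanx")
    distal_trial, dt_truth = phalanx(0.30, 0.95, 0.90, "distal_phalanx")
    s_d = (pp_truth.volume / proximal_distal_ratio / dt_truth.volume) ** (1.0 / 3.0)
    distal, dp_truth = phalanx(0.30, 0.95, 0.90, "distal_phalanx", extra_scale=s_d)
    return SubjectMeshes(
        metatarsal=metatarsal,
        proximal=proximal,
        distal=distal,
        truth={"metatarsal": mt_truth, "proximal_phalanx": pp_truth,
               "distal_phalanx": dp_truth},
    )


def groove_truth_in_body_frame(params: BoneParams, body_frame) -> dict:
    """Ground-truth groove observables, expressed in a bone's body frame.

    The generator states groove axes in the construction frame, but the
    groove scanner labels sides and measures rotation angles in the
    inertial body frame, whose axes may be flipped relative to
    construction.  Given the :class:`~boneframe.frame.BodyFrame` actually
    computed for the generated mesh, this returns per body-frame side the
    expected curvature diameter and the expected min-CD rotation angle
    (the angle of the groove axis' xy-projection, folded to (-90, 90]).
    """
    A = np.asarray(body_frame.axes)
    origin = np.asarray(body_frame.origin)
    out = {}
    for sgn, r, skew in (
        (+1.0, params.groove_radius_medial, params.groove_skew_medial),
        (-1.0, params.groove_radius_lateral, params.groove_skew_lateral),
    ):
        th = np.deg2rad(skew)
        a_world = np.array([np.cos(th), np.sin(th), 0.0])
        p_world = np.array(
            [params.shaft_length,
             sgn * params.groove_offset_frac * params.head_radius,
             -params.groove_depth_frac * params.head_radius]
        )
        a_body = A @ a_world
        p_body = A @ (p_world - origin)
        angle = np.degrees(np.arctan2(a_body[1], a_body[0]))
        angle = (angle + 90.0) % 180.0 - 90.0  # axis direction is sign-free
        side = "medial" if p_body[1] > 0 else "lateral"
        out[side] = {"cd": 2.0 * r, "angle": float(angle)}
    return out


def skew_pair_params(seed: int, equal_skews: bool) -> BoneParams:
    """Default-geometry bone with seeded groove skews for parallelism tests.

    ``equal_skews=True`` draws one skew in (-3, 3) deg for both grooves
    (parallel axes); otherwise the two skews differ by 1-2 deg in a
    seeded direction (dis-parallel), with the common part kept small so
    the converging groove cylinders stay clear of each other.
    """
    rng = np.random.default_rng(seed)
    if equal_skews:
        d_med = d_lat = rng.uniform(-3.0, 3.0)
    else:
        d_med = rng.uniform(-1.5, 1.5)
        d_lat = d_med + (1.0 + rng.uniform(0.0, 1.0)) * rng.choice([-1.0, 1.0])
    return BoneParams(
        shaft_length=rng.uniform(57.0, 63.0),
        groove_skew_medial=float(d_med),
        groove_skew_lateral=float(d_lat),
        name=f"skew_pair_{seed}",
    )


def random_params(seed: int, surface_noise: float = 0.3,
                  mesh_resolution: int = 2) -> BoneParams:
    """Seeded, realistically-ranged parameters for property tests."""
    rng = np.random.default_rng(seed)
    head = rng.uniform(8.0, 12.0)
    # groove radii capped so the two cylinders (axis separation
    # 0.9*head, skews up to +-3 deg over a 1.2*head half-length) can
    # never intersect each other
    return BoneParams(
        shaft_length=rng.uniform(45.0, 70.0),
        shaft_radii=(rng.uniform(7.0, 10.0), rng.uniform(6.0, 9.0)),
        head_radius=head,
        groove_radius_medial=rng.uniform(0.28, 0.37) * head,
        groove_radius_lateral=rng.uniform(0.28, 0.37) * head,
        groove_skew_medial=rng.uniform(-3.0, 3.0),
        groove_skew_lateral=rng.uniform(-3.0, 3.0),
        mesh_resolution=mesh_resolution,
        surface_noise=surface_noise,
        seed=int(rng.integers(2**31 - 1)),
        name=f"random_bone_{seed}",
    )
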