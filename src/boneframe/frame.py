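"""Inertial body coordinate frames and size standardization.

Every bone gets an intrinsic "body frame": origin at the centre of mass
of the enclosed solid, axes along the principal axes of inertia.  The
axis with the *smallest* principal moment is the elongation (long) axis
and becomes body x; the remaining two follow in ascending-moment order
(for a typical metatarsal: x distal-proximal, y medial-lateral, z
dorsal-plantar).  Because eigenvectors are defined only up to sign, each
axis is oriented by a mesh-intrinsic convention (see
:func:`principal_frame`), which makes the frame deterministic without
anatomical landmarks.

Standardization rescales a subject's three-bone set uniformly so the
first metatarsal's body-frame length is exactly 100, removing body size
from all subsequent comparisons; linear measures then scale with s,
areas with s^2, volumes with s^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegeneracyWarning, InputError
from .mesh import BoneMesh, mass_properties

__all__ = [
    "BodyFrame",
    "StandardizedSet",
    "principal_frame",
    "to_body_frame",
    "extents",
    "standardize_subject",
]

#: relative eigenvalue gap below which principal directions are treated
#: as degenerate and replaced by the global axes
DEGENERACY_TOL = 1e-6


@dataclass
class BodyFrame:
    """Origin (COM, mm) and right-handed orthonormal axes (rows).

    ``axes[0]`` is the long axis (smallest principal moment),
    ``axes[1]`` and ``axes[2]`` follow in ascending-moment order.
    """

    origin: np.ndarray
    axes: np.ndarray
    principal_moments: np.ndarray
    degenerate: bool = False

    @property
    def long_axis(self) -> np.ndarray:
        return self.axes[0]

    def transform(self) -> np.ndarray:
        """4x4 world -> body homogeneous transform."""
        T = np.eye(4)
        T[:3, :3] = self.axes
        T[:3, 3] = -self.axes @ self.origin
        return T


@dataclass
class StandardizedSet:
    """A subject's three bones in their body frames, jointly rescaled so
    the metatarsal's body-frame length equals 100."""

    metatarsal: BoneMesh
    proximal: BoneMesh
    distal: BoneMesh
    scale: float
    original_lengths: tuple[float, float, float]

    @property
    def bones(self):
        return {
            "metatarsal": self.metatarsal,
            "proximal_phalanx": self.proximal,
            "distal_phalanx": self.distal,
        }


def _orient_axis(axis: np.ndarray, coords: np.ndarray, scale: float) -> np.ndarray:
    """Fix the sign of one principal axis.

    Primary rule: third central moment (skewness) of the vertex
    coordinates along the axis must be non-negative.  If the shape is
    symmetric enough that the skewness vanishes, fall back to making the
    coordinate of the farthest vertex positive (ties broken by lowest
    vertex index); if even that is ambiguous, make the axis' largest
    component positive.
    """
    c = coords - coords.mean()
    skew = float(np.mean(c**3))
    if abs(skew) > 1e-9 * scale**3:
        return axis if skew > 0 else -axis
    imax = int(np.argmax(np.abs(coords)))
    if abs(coords[imax]) > 1e-12 * scale:
        return axis if coords[imax] > 0 else -axis
    k = int(np.argmax(np.abs(axis)))
    return axis if axis[k] >= 0 else -axis


def principal_frame(mesh: BoneMesh) -> BodyFrame:
    """Diagonalize the inertia tensor into a deterministic body frame.

    Axes are ordered by ascending principal moment and sign-fixed by
    :func:`_orient_axis` applied to the first two axes; the third is
    their cross product, which guarantees a right-handed frame.  If the
    smallest relative eigenvalue gap is below ``DEGENERACY_TOL`` the
    shape has no well-defined principal directions (sphere, cube, ...);
    the global axes are returned instead with a :class:`DegeneracyWarning`.
    """
    mp = mass_properties(mesh)
    evals, evecs = np.linalg.eigh(mp.inertia)
    gaps = np.diff(evals) / max(evals[-1], 1e-300)
    if np.any(gaps < DEGENERACY_TOL):
        warnings.warn(
            "near-degenerate principal moments; falling back to global axes",
            DegeneracyWarning,
            stacklevel=2,
        )
        return BodyFrame(
            origin=mp.com, axes=np.eye(3), principal_moments=evals, degenerate=True
        )
    rel = mesh.vertices - mp.com
    scale = float(np.abs(rel).max())
    a0 = _orient_axis(evecs[:, 0], rel @ evecs[:, 0], scale)
    a1 = _orient_axis(evecs[:, 1], rel @ evecs[:, 1], scale)
    a2 = np.cross(a0, a1)
    return BodyFrame(origin=mp.com, axes=np.vstack([a0, a1, a2]), principal_moments=evals)


def to_body_frame(mesh: BoneMesh, return_transform: bool = False):
    """Rigidly move ``mesh`` into its body frame (COM at origin, long axis
    on global x).  Idempotent: re-applying changes vertices only at
    floating-point level."""
    bf = principal_frame(mesh)
    T = bf.transform()
    out = mesh.apply_transform(T)
    if return_transform:
        return out, T
    return out


def extents(mesh: BoneMesh) -> tuple[float, float, float]:
    """(length, width, height): bounding-box extents along body x/y/z.

    The mesh must already be in its body frame (e.g. via
    :func:`to_body_frame`); the values are then invariant to any rigid
    motion applied beforehand.
    """
    e = mesh.extents_raw
    return float(e[0]), float(e[1]), float(e[2])


def standardize_subject(
    metatarsal: BoneMesh, proximal: BoneMesh, distal: BoneMesh
) -> StandardizedSet:
    """Align all three bones into their body frames and rescale the set
    uniformly so the metatarsal length becomes exactly 100."""
    mt = to_body_frame(metatarsal)
    pp = to_body_frame(proximal)
    dp = to_body_frame(distal)
    lengths = (extents(mt)[0], extents(pp)[0], extents(dp)[0])
    if lengths[0] <= 0:
        raise InputError(f"metatarsal length must be > 0, got {lengths[0]}")
    s = 100.0 / lengths[0]
    return StandardizedSet(
        metatarsal=mt.apply_scale(s),
        proximal=pp.apply_scale(s),
        distal=dp.apply_scale(s),
        scale=s,
        original_lengths=lengths,
    )
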