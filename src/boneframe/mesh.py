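"""Mesh ingestion, validation and mass properties of closed bone surfaces.

A :class:`BoneMesh` is a thin wrapper around a :class:`trimesh.Trimesh`
carrying a name and fixed millimetre units.  All downstream analysis
(body frames, morphometry, reconstruction, groove scanning) assumes the
surface encloses a uniform-density solid, so loading repairs face
orientation and records watertightness, and :func:`mass_properties`
refuses open surfaces.

Volume, centre of mass and the inertia tensor are evaluated by trimesh's
exact surface integrals over the enclosed solid (divergence theorem);
:mod:`boneframe.voxel` provides an independent voxel-counting oracle used
by the test-suite to cross-check them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import InputError, MeshLoadError, MeshValidationError

__all__ = [
    "BoneMesh",
    "MassProperties",
    "load_mesh",
    "mass_properties",
    "box",
    "unit_cube",
    "icosphere",
    "cylinder",
]

_FORMATS = ("stl", "ply", "obj")


@dataclass
class BoneMesh:
    """A closed triangular bone surface in millimetres.

    Parameters
    ----------
    tri:
        Backing triangle mesh.  Faces are repaired to consistent outward
        orientation on construction; degenerate (zero-area) faces are
        dropped with a warning.
    name:
        Free-text label (subject/bone), carried through transforms.
    """

    tri: trimesh.Trimesh
    name: str = ""
    units: str = field(default="mm", repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.tri, trimesh.Trimesh):
            self.tri = trimesh.Trimesh(
                vertices=np.asarray(self.tri[0], dtype=float),
                faces=np.asarray(self.tri[1], dtype=int),
                process=False,
            )
        _validate_indices(self.tri)
        _drop_degenerate_faces(self.tri)
        _repair_orientation(self.tri)

    @classmethod
    def _wrap(cls, tri: trimesh.Trimesh, name: str = "") -> "BoneMesh":
        """Wrap an already-validated trimesh without re-running repair."""
        obj = object.__new__(cls)
        obj.tri, obj.name, obj.units = tri, name, "mm"
        return obj

    # -- array views -------------------------------------------------
    @property
    def vertices(self) -> np.ndarray:
        return self.tri.vertices.view(np.ndarray)

    @property
    def faces(self) -> np.ndarray:
        return self.tri.faces.view(np.ndarray)

    @property
    def is_watertight(self) -> bool:
        return bool(self.tri.is_watertight)

    @property
    def bounds(self) -> np.ndarray:
        return self.tri.bounds.view(np.ndarray)

    @property
    def extents_raw(self) -> np.ndarray:
        """Axis-aligned bounding-box extents in the current coordinates."""
        return self.tri.extents.view(np.ndarray)

    def copy(self, name: str | None = None) -> "BoneMesh":
        return BoneMesh._wrap(self.tri.copy(), name=self.name if name is None else name)

    def apply_transform(self, matrix: np.ndarray) -> "BoneMesh":
        """Return a copy transformed by a 4x4 homogeneous matrix."""
        out = self.tri.copy()
        out.apply_transform(np.asarray(matrix, dtype=float))
        if out.volume < 0:  # reflections flip orientation
            out.invert()
        return BoneMesh._wrap(out, name=self.name)

    def apply_scale(self, factor: float) -> "BoneMesh":
        if factor <= 0:
            raise InputError(f"scale factor must be > 0, got {factor}")
        out = self.tri.copy()
        out.apply_scale(float(factor))
        return BoneMesh._wrap(out, name=self.name)

    def save(self, path: str | Path) -> None:
        self.tri.export(str(path))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"BoneMesh(name={self.name!r}, vertices={len(self.vertices)}, "
            f"faces={len(self.faces)}, watertight={self.is_watertight})"
        )


@dataclass
class MassProperties:
    """Uniform-density (rho = 1) mass properties of the enclosed solid.

    ``inertia`` is the 3x3 tensor about the centre of mass in mm^5
    (length^5 because density is dimensionless 1).
    """

    volume: float
    surface_area: float
    com: np.ndarray
    inertia: np.ndarray

    @property
    def principal_moments(self) -> np.ndarray:
        """Eigenvalues of the inertia tensor, ascending."""
        return np.linalg.eigvalsh(self.inertia)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "volume_mm3": float(self.volume),
            "surface_area_mm2": float(self.surface_area),
            "com_mm": [float(v) for v in self.com],
            "inertia_mm5": [[float(v) for v in row] for row in self.inertia],
            "principal_moments_mm5": [float(v) for v in self.principal_moments],
            "density": 1.0,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _validate_indices(tri: trimesh.Trimesh) -> None:
    if len(tri.faces) == 0 or len(tri.vertices) == 0:
        raise MeshValidationError("mesh has no faces or no vertices")
    if tri.faces.min() < 0 or tri.faces.max() >= len(tri.vertices):
        raise MeshValidationError(
            f"face index {int(tri.faces.max())} out of range for "
            f"{len(tri.vertices)} vertices"
        )


def _drop_degenerate_faces(tri: trimesh.Trimesh) -> None:
    """Collapse coincident vertices and drop zero-content faces.

    Faces whose three positions are not distinct are geometric nulls:
    after merging coincident vertices they have a repeated index and can
    be removed without opening the surface (their duplicated edge pair
    cancels).  Zero-area faces spanning *distinct* vertices (exact
    slivers) are left in place — removing those would tear the mesh.
    """
    if (tri.area_faces <= 0).any():
        tri.merge_vertices()
    f = tri.faces
    deg = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
    bad = int(deg.sum())
    if bad:
        warnings.warn(f"dropping {bad} degenerate faces", stacklevel=3)
        tri.update_faces(~deg)
    if len(tri.faces) == 0:
        raise MeshValidationError("mesh has no non-degenerate faces")


def _repair_orientation(tri: trimesh.Trimesh) -> None:
    """Make winding consistent and normals outward (signed volume > 0)."""
    if not tri.is_winding_consistent:
        trimesh.repair.fix_normals(tri)
    if tri.is_winding_consistent and tri.volume < 0:
        tri.invert()


def load_mesh(path: str | Path, fmt: str = "auto", name: str | None = None) -> BoneMesh:
    """Load an STL/PLY/OBJ surface and return a repaired :class:`BoneMesh`.

    ``fmt='auto'`` infers the format from the file extension.  Duplicate
    vertices are merged so that watertightness of a well-formed closed
    surface is recognised (STL stores one vertex copy per face).
    """
    p = Path(path)
    if not p.is_file():
        raise MeshLoadError(f"mesh file not found: {p}")
    if fmt == "auto":
        fmt = p.suffix.lower().lstrip(".")
    if fmt not in _FORMATS:
        raise MeshLoadError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    try:
        tri = trimesh.load(str(p), file_type=fmt, force="mesh", process=False)
    except Exception as exc:  # trimesh raises a zoo of parse errors
        raise MeshLoadError(f"could not parse {p} as {fmt}: {exc}") from exc
    if not isinstance(tri, trimesh.Trimesh) or len(tri.vertices) == 0:
        raise MeshValidationError(f"{p} contains no triangle geometry")
    _validate_indices(tri)
    tri.merge_vertices()
    return BoneMesh(tri, name=name if name is not None else p.stem)


def boundary_edge_count(mesh: BoneMesh) -> int:
    """Number of edges referenced by exactly one face (0 when watertight)."""
    groups = trimesh.grouping.group_rows(mesh.tri.edges_sorted, require_count=1)
    return len(groups)


def mass_properties(mesh: BoneMesh) -> MassProperties:
    """Volume, area, COM and inertia of the uniform solid enclosed by ``mesh``.

    Raises
    ------
    MeshValidationError
        If the surface is not watertight (naming the open edge count) or
        its winding is inconsistent.
    """
    if not mesh.is_watertight:
        raise MeshValidationError(
            f"mass properties need a watertight mesh; "
            f"{boundary_edge_count(mesh)} open boundary edges found"
        )
    if not mesh.tri.is_winding_consistent:
        raise MeshValidationError("mesh winding is inconsistent after repair")
    tri = mesh.tri
    vol = float(tri.volume)
    if vol <= 0:
        raise MeshValidationError(f"enclosed volume is non-positive ({vol:.3g} mm^3)")
    return MassProperties(
        volume=vol,
        surface_area=float(tri.area),
        com=np.asarray(tri.center_mass, dtype=float),
        inertia=np.asarray(tri.moment_inertia, dtype=float),
    )


# ---------------------------------------------------------------------------
# primitive fixtures
# ---------------------------------------------------------------------------

def _require_positive(**dims: float) -> None:
    for key, val in dims.items():
        if not np.all(np.asarray(val, dtype=float) > 0):
            raise InputError(f"{key} must be positive, got {val}")


def box(extents=(1.0, 1.0, 1.0), name: str = "box") -> BoneMesh:
    """Axis-aligned solid box centred at the origin."""
    _require_positive(extents=extents)
    return BoneMesh(trimesh.creation.box(extents=np.asarray(extents, dtype=float)), name=name)


def unit_cube() -> BoneMesh:
    """Unit cube with vertices in [0, 1]^3 (8 vertices, 12 faces)."""
    tri = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    tri.apply_translation((0.5, 0.5, 0.5))
    return BoneMesh(tri, name="unit_cube")


def icosphere(radius: float = 1.0, subdivisions: int = 3, name: str = "icosphere") -> BoneMesh:
    _require_positive(radius=radius)
    if subdivisions < 0:
        raise InputError(f"subdivisions must be >= 0, got {subdivisions}")
    return BoneMesh(trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius), name=name)


def cylinder(radius: float, height: float, sections: int = 128, name: str = "cylinder") -> BoneMesh:
    _require_positive(radius=radius, height=height)
    return BoneMesh(
        trimesh.creation.cylinder(radius=radius, height=height, sections=sections), name=name
    )
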