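"""Serial-section 3D reconstruction by contour extrusion.

Each traced contour on section *i* is extruded into a right prism spanning the
slab ``[i*t, (i+1)*t)`` where *t* is the section thickness, and the prisms are
collected into one triangle mesh per compartment.  With few thick sections the
result visibly resembles a stack of cylinders; as the number of sections
grows the shape converges to the true object, and the mesh volume is by
construction exactly ``sum(contour area * t)`` — the Cavalieri sum — making
the 3D and point-counting volumes directly commensurable.

Reported surface area is the *external* surface of the prism union: lateral
faces plus the exposed parts of the slab-interface caps (overlap between
consecutive sections' footprints is interior and excluded).  Volume is always
the exact per-prism sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from glomorph.geometry import Compartment, Contour, DegenerateGeometryError


class NoGeometryError(ValueError):
    """The stack (or mesh) contains no geometry."""


class UndefinedRatioError(ZeroDivisionError):
    """Total tuft area is zero; the mesangial/total ratio is undefined."""


@dataclass(frozen=True)
class ContourStack:
    """Ordered, aligned contours with uniform section thickness.

    ``sections`` is a list of ``(section_index, [Contour, ...])`` with strictly
    increasing indices; ``aligned`` records whether an alignment chain has
    been applied (meshing assumes it has).
    """

    sections: list
    thickness_um: float
    aligned: bool = True

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("thickness_um must be positive")
        idx = [i for i, _ in self.sections]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("section indices must be strictly increasing")

    def contours(self, compartment: Compartment | None = None):
        for i, cs in self.sections:
            for c in cs:
                if compartment is None or c.compartment == compartment:
                    yield i, c

    def section_area(self, compartment: Compartment) -> dict[int, float]:
        out: dict[int, float] = {}
        for i, c in self.contours(compartment):
            out[i] = out.get(i, 0.0) + c.area()
        return out


@dataclass
class SurfaceMesh:
    """Watertight triangle mesh of one compartment with derived metrics."""

    vertices: np.ndarray
    faces: np.ndarray
    volume_um3: float
    surface_area_um2: float
    compartment: Compartment

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @property
    def is_watertight(self) -> bool:
        return self.as_trimesh().is_watertight

    def signed_volume(self) -> float:
        """Divergence-theorem volume from the triangle soup."""
        return float(self.as_trimesh().volume)


@dataclass(frozen=True)
class MorphometricsRecord:
    """Per-glomerulus summary metrics mirroring the reconstruction output."""

    specimen_id: str
    glomerulus_id: str
    mesangial_volume_um3: float
    mesangial_surface_um2: float
    mesangial_area_um2: float
    tuft_area_um2: float
    mes_to_total_ratio: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mes_to_total_ratio <= 1.0 + 1e-12:
            raise ValueError("mes_to_total_ratio must lie in [0, 1]")


# ---------------------------------------------------------------------------
# polygon triangulation (ear clipping, no Steiner points: caps reuse the ring
# vertices so the prism is watertight by construction)

def _triangulate_ring(v: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate a CCW simple polygon into index triangles over its vertices.

    Convex rings get a fan; general rings are ear-clipped with a vectorized
    containment test.  No Steiner points are introduced, so prism caps share
    the ring vertices and the prism stays watertight by construction.
    """
    n = v.shape[0]
    if n < 3:
        raise DegenerateGeometryError("cannot triangulate a ring with < 3 vertices")

    edge = np.roll(v, -1, axis=0) - v
    turn = edge[:, 0] * np.roll(edge, -1, axis=0)[:, 1] - edge[:, 1] * np.roll(edge, -1, axis=0)[:, 0]
    if np.all(turn >= 0):  # convex: fan from vertex 0, skipping collinear slivers
        return [
            (0, i, i + 1)
            for i in range(1, n - 1)
            if (v[i, 0] - v[0, 0]) * (v[i + 1, 1] - v[0, 1])
            - (v[i, 1] - v[0, 1]) * (v[i + 1, 0] - v[0, 0])
            != 0.0
        ]

    idx = list(range(n))
    tris: list[tuple[int, int, int]] = []

    def cross(o, a, b):
        return (v[a, 0] - v[o, 0]) * (v[b, 1] - v[o, 1]) - (v[a, 1] - v[o, 1]) * (v[b, 0] - v[o, 0])

    def ear_contains_other(i0, i1, i2, others):
        if others.size == 0:
            return False
        p = v[others]
        d0 = (v[i1, 0] - v[i0, 0]) * (p[:, 1] - v[i0, 1]) - (v[i1, 1] - v[i0, 1]) * (p[:, 0] - v[i0, 0])
        d1 = (v[i2, 0] - v[i1, 0]) * (p[:, 1] - v[i1, 1]) - (v[i2, 1] - v[i1, 1]) * (p[:, 0] - v[i1, 0])
        d2 = (v[i0, 0] - v[i2, 0]) * (p[:, 1] - v[i2, 1]) - (v[i0, 1] - v[i2, 1]) * (p[:, 0] - v[i2, 0])
        return bool(np.any((d0 > 0) & (d1 > 0) & (d2 > 0)))

    guard = 0
    while len(idx) > 3:
        m = len(idx)
        arr = np.asarray(idx)
        clipped = False
        for k in range(m):
            i0, i1, i2 = idx[k - 1], idx[k], idx[(k + 1) % m]
            c = cross(i0, i1, i2)
            if c < 0:
                continue  # reflex vertex, not an ear
            others = arr[(arr != i0) & (arr != i1) & (arr != i2)]
            if not ear_contains_other(i0, i1, i2, others):
                if c > 0:
                    tris.append((i0, i1, i2))
                # zero-area ears are clipped silently
                del idx[k]
                clipped = True
                break
        if not clipped:
            guard += 1
            if guard > 2:
                raise DegenerateGeometryError("ear clipping failed; polygon may self-intersect")
            # numerical stalemate: drop the flattest near-degenerate vertex
            worst = min(range(len(idx)), key=lambda k: abs(cross(idx[k - 1], idx[k], idx[(k + 1) % len(idx)])))
            del idx[worst]
    if len(idx) == 3 and cross(*idx) > 0:
        tris.append(tuple(idx))
    return tris


def _extrude_contour(contour: Contour, z0: float, z1: float):
    """Vertices and outward-oriented faces of the prism ``contour x [z0, z1]``."""
    ring = contour.vertices  # CCW guaranteed
    n = ring.shape[0]
    bottom = np.column_stack([ring, np.full(n, z0)])
    top = np.column_stack([ring, np.full(n, z1)])
    verts = np.vstack([bottom, top])
    faces: list[tuple[int, int, int]] = []
    for i in range(n):
        j = (i + 1) % n
        faces.append((i, j, n + j))
        faces.append((i, n + j, n + i))
    caps = _triangulate_ring(ring)
    for a, b, c in caps:
        faces.append((n + a, n + b, n + c))  # top, normal +z
        faces.append((c, b, a))              # bottom, normal -z
    return verts, np.asarray(faces, dtype=np.int64)


def _section_union(contours: list[Contour]):
    polys = [c.polygon for c in contours]
    u = unary_union(polys) if polys else Polygon()
    return u


def _external_surface_area(stack: ContourStack, compartment: Compartment, t: float) -> float:
    """Lateral area + exposed cap area at every slab interface plane."""
    per_section: dict[int, list[Contour]] = {}
    for i, c in stack.contours(compartment):
        per_section.setdefault(i, []).append(c)
    if not per_section:
        return 0.0
    lateral = sum(c.perimeter() * t for cs in per_section.values() for c in cs)
    unions = {i: _section_union(cs) for i, cs in per_section.items()}
    indices = sorted(unions)
    caps = unions[indices[0]].area + unions[indices[-1]].area  # outermost caps
    for a, b in zip(indices, indices[1:]):
        ua, ub = unions[a], unions[b]
        if b == a + 1:
            overlap = ua.intersection(ub).area
            caps += ua.area + ub.area - 2.0 * overlap
        else:  # gap in the series: both caps fully exposed
            caps += ua.area + ub.area
    return float(lateral + caps)


def reconstruct_mesh(stack: ContourStack, compartment: Compartment = Compartment.MESANGIUM) -> SurfaceMesh:
    """Build the watertight extruded-prism mesh of one compartment.

    The contour measured on section *i* represents the slab
    ``[i*t, (i+1)*t)``; each contour becomes a right prism of height *t* and
    disjoint contours are kept as separate bodies of one mesh.  The recorded
    ``volume_um3`` is the exact per-prism sum ``sum(area * t)`` (it agrees
    with the divergence-theorem volume of the mesh to floating-point);
    ``surface_area_um2`` is the external (boolean-union) surface.

    Raises
    ------
    NoGeometryError
        If the stack holds no contour of the requested compartment.
    """
    t = stack.thickness_um
    all_verts: list[np.ndarray] = []
    all_faces: list[np.ndarray] = []
    volume = 0.0
    offset = 0
    for i, c in stack.contours(compartment):
        v, f = _extrude_contour(c, i * t, (i + 1) * t)
        all_verts.append(v)
        all_faces.append(f + offset)
        offset += v.shape[0]
        volume += c.area() * t
    if not all_verts:
        raise NoGeometryError(f"stack holds no {compartment.value} contours")
    verts = np.vstack(all_verts)
    faces = np.vstack(all_faces)
    surface = _external_surface_area(stack, compartment, t)
    return SurfaceMesh(verts, faces, float(volume), surface, compartment)


def compute_morphometrics(
    stack: ContourStack,
    mesh_mes: SurfaceMesh | None = None,
    mesh_tuft: SurfaceMesh | None = None,
    specimen_id: str = "",
    glomerulus_id: str = "",
) -> MorphometricsRecord:
    """Summarize a stack: volumes from the meshes, areas and their ratio.

    The mesangial/total ratio is ``sum(mesangial areas) / sum(tuft areas)``
    over all sections.  Meshes are rebuilt from the stack when not supplied;
    a stack with no mesangial contours yields zero volume and ratio 0.
    """
    mes_areas = stack.section_area(Compartment.MESANGIUM)
    tuft_areas = stack.section_area(Compartment.TUFT)
    mes_total = float(sum(mes_areas.values()))
    tuft_total = float(sum(tuft_areas.values()))
    if tuft_total <= 0.0:
        raise UndefinedRatioError("total tuft area is zero; ratio undefined")
    if mesh_mes is None and mes_total > 0.0:
        mesh_mes = reconstruct_mesh(stack, Compartment.MESANGIUM)
    return MorphometricsRecord(
        specimen_id=specimen_id,
        glomerulus_id=glomerulus_id,
        mesangial_volume_um3=mesh_mes.volume_um3 if mesh_mes else 0.0,
        mesangial_surface_um2=mesh_mes.surface_area_um2 if mesh_mes else 0.0,
        mesangial_area_um2=mes_total,
        tuft_area_um2=tuft_total,
        mes_to_total_ratio=min(mes_total / tuft_total, 1.0),
    )


def export_mesh(mesh: SurfaceMesh, path, fmt: str | None = None) -> None:
    """Write a mesh as OBJ or STL (inferred from the extension when omitted)."""
    if mesh.faces is None or len(mesh.faces) == 0:
        raise NoGeometryError("refusing to export an empty mesh")
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    fmt = fmt.lower()
    if fmt not in ("obj", "stl"):
        raise ValueError(f"unsupported mesh format: {fmt}")
    tm = mesh.as_trimesh()
    if fmt == "stl":
        tm.export(path, file_type="stl_ascii")
    else:
        tm.export(path, file_type="obj")


def import_mesh(path, compartment: Compartment = Compartment.OTHER) -> SurfaceMesh:
    """Load an OBJ/STL mesh back into a :class:`SurfaceMesh`."""
    tm = trimesh.load_mesh(str(path), process=False)
    return SurfaceMesh(
        np.asarray(tm.vertices), np.asarray(tm.faces),
        float(tm.volume), float(tm.area), compartment,
    )
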