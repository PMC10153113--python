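"""Core triangle-mesh container, topology bookkeeping and scalar transfer.

Vertices live in voxel units in the array-axis order of the source volume
(z, y, x for a multi-page TIFF).  Every representation of a surface —
Cartesian input, smooth reference, unit sphere, topographic (d, u, v) mesh
and flattened plane — is carried by the same :class:`SurfaceMesh` type,
distinguished only by its ``representation_tag``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import trimesh

log = logging.getLogger(__name__)

REPRESENTATIONS = ("cartesian", "reference", "sphere", "topographic", "plane")

_DEGENERATE_AREA = 1e-12


@dataclass
class SurfaceMesh:
    """Triangle mesh with a representation tag and named per-vertex fields."""

    vertices: np.ndarray
    faces: np.ndarray
    representation_tag: str = "cartesian"
    scalar_fields: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        if self.representation_tag not in REPRESENTATIONS:
            raise ValueError(f"unknown representation {self.representation_tag!r}")
        for name, f in self.scalar_fields.items():
            f = np.asarray(f)
            if f.shape[0] != len(self.vertices):
                raise ValueError(f"scalar field {name!r} length mismatch")
            self.scalar_fields[name] = f

    # ------------------------------------------------------------------ basic
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self, vertices: Optional[np.ndarray] = None,
             representation_tag: Optional[str] = None) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy() if vertices is None else np.asarray(vertices, float),
            self.faces.copy(),
            representation_tag or self.representation_tag,
            {k: np.array(v) for k, v in self.scalar_fields.items()},
        )

    def face_corners(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        c = self.face_corners()
        n = np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0])
        a2 = np.linalg.norm(n, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(a2[:, None] > 0, n / np.maximum(a2, 1e-300)[:, None], 0.0)
        return unit, 0.5 * a2

    def face_areas(self) -> np.ndarray:
        return self.face_normals_areas()[1]

    def area(self) -> float:
        return float(self.face_areas().sum())

    def edge_lengths(self) -> np.ndarray:
        c = self.face_corners()
        return np.linalg.norm(np.roll(c, -1, axis=1) - c, axis=2).ravel()

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex area: one third of incident face area."""
        a = self.face_areas()
        va = np.zeros(self.n_vertices)
        np.add.at(va, self.faces.ravel(), np.repeat(a / 3.0, 3))
        return va

    def vertex_normals(self) -> np.ndarray:
        """Angle-weighted average of incident face normals (unit length)."""
        c = self.face_corners()
        fn, _ = self.face_normals_areas()
        out = np.zeros_like(self.vertices)
        for k in range(3):
            e1 = c[:, (k + 1) % 3] - c[:, k]
            e2 = c[:, (k + 2) % 3] - c[:, k]
            n1 = np.linalg.norm(e1, axis=1)
            n2 = np.linalg.norm(e2, axis=1)
            cosang = np.einsum("ij,ij->i", e1, e2) / np.maximum(n1 * n2, 1e-300)
            ang = np.arccos(np.clip(cosang, -1.0, 1.0))
            np.add.at(out, self.faces[:, k], fn * ang[:, None])
        norm = np.linalg.norm(out, axis=1, keepdims=True)
        return out / np.maximum(norm, 1e-300)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    # ------------------------------------------------------------------ io
    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.to_trimesh().export(path)
        if self.scalar_fields:
            side = path.with_suffix(path.suffix + ".fields.csv")
            names = sorted(self.scalar_fields)
            cols = np.column_stack([np.asarray(self.scalar_fields[n], float)
                                    for n in names])
            header = "vertex," + ",".join(names)
            data = np.column_stack([np.arange(self.n_vertices), cols])
            np.savetxt(side, data, delimiter=",", header=header, comments="")

    @classmethod
    def load(cls, path: str | Path, representation_tag: str = "cartesian") -> "SurfaceMesh":
        tm = trimesh.load_mesh(str(path), process=False)
        mesh = cls(np.asarray(tm.vertices, float), np.asarray(tm.faces, int),
                   representation_tag)
        side = Path(str(path) + ".fields.csv")
        if side.exists():
            raw = np.genfromtxt(side, delimiter=",", names=True)
            for name in raw.dtype.names:
                if name != "vertex":
                    mesh.scalar_fields[name] = np.asarray(raw[name], float)
        return clean_mesh(mesh)


def clean_mesh(mesh: SurfaceMesh) -> SurfaceMesh:
    """Drop degenerate (area < 1e-12) faces; count is logged."""
    areas = mesh.face_areas()
    distinct = (
        (mesh.faces[:, 0] != mesh.faces[:, 1])
        & (mesh.faces[:, 1] != mesh.faces[:, 2])
        & (mesh.faces[:, 0] != mesh.faces[:, 2])
    )
    keep = (areas > _DEGENERATE_AREA) & distinct
    dropped = int((~keep).sum())
    if dropped:
        log.info("removed %d degenerate faces", dropped)
        mesh = SurfaceMesh(mesh.vertices, mesh.faces[keep],
                           mesh.representation_tag, mesh.scalar_fields)
    return mesh


# ---------------------------------------------------------------------- topology
@dataclass
class TopologyReport:
    n_vertices: int
    n_edges: int
    n_faces: int
    euler_characteristic: int
    genus: Optional[int]
    boundary_loops: int
    watertight: bool
    manifold: bool

    def to_json(self) -> str:
        d = dict(self.__dict__)
        return json.dumps(d, indent=2)


def _boundary_loop_count(boundary_edges: np.ndarray) -> int:
    """Count closed loops among undirected boundary edges."""
    if len(boundary_edges) == 0:
        return 0
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    verts = np.unique(boundary_edges)
    remap = {v: i for i, v in enumerate(verts)}
    i = np.array([remap[v] for v in boundary_edges[:, 0]])
    j = np.array([remap[v] for v in boundary_edges[:, 1]])
    g = sp.coo_matrix((np.ones(len(i)), (i, j)), shape=(len(verts),) * 2)
    n, _ = connected_components(g, directed=False)
    return int(n)


def surface_topology(mesh: SurfaceMesh) -> TopologyReport:
    """Euler characteristic, genus and boundary structure of a triangle mesh.

    For a closed orientable surface chi = 2 - 2 g = #V - #E + #F; with b
    boundary loops chi = 2 - 2 g - b.  Genus is undefined (None) on
    non-manifold meshes (an edge shared by more than two faces).
    """
    edges = np.sort(
        np.concatenate([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]],
                        mesh.faces[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    n_v = int(len(np.unique(mesh.faces)))
    n_e = int(len(uniq))
    n_f = mesh.n_faces
    chi = n_v - n_e + n_f
    manifold = bool((counts <= 2).all())
    boundary = uniq[counts == 1]
    b = _boundary_loop_count(boundary)
    genus: Optional[int] = None
    if manifold:
        genus = (2 - chi - b) // 2
    watertight = manifold and b == 0 and bool((counts == 2).all())
    return TopologyReport(n_v, n_e, n_f, chi, genus, b, watertight, manifold)


def boundary_loop(mesh: SurfaceMesh) -> np.ndarray:
    """Ordered vertex indices of the single boundary loop of an open mesh."""
    edges = np.concatenate([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]],
                            mesh.faces[:, [2, 0]]])
    und = np.sort(edges, axis=1)
    uniq, inv, counts = np.unique(und, axis=0, return_inverse=True,
                                  return_counts=True)
    bmask = counts[inv] == 1
    bedges = edges[bmask]  # directed, consistent winding
    if len(bedges) == 0:
        raise ValueError("mesh is closed: no boundary loop")
    nxt = dict(zip(bedges[:, 0].tolist(), bedges[:, 1].tolist()))
    if len(nxt) != len(bedges):
        raise ValueError("mesh has a non-simple boundary")
    start = bedges[0, 0]
    loop = [start]
    cur = nxt[start]
    while cur != start:
        loop.append(cur)
        cur = nxt[cur]
        if len(loop) > len(bedges):
            raise ValueError("boundary does not close into a single loop")
    if len(loop) != len(bedges):
        raise ValueError("mesh has more than one boundary loop")
    return np.asarray(loop, dtype=np.int64)


# ---------------------------------------------------------------------- transfer
def nearest_triangle(mesh: SurfaceMesh, points: np.ndarray,
                     k_candidates: int = 12
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Closest surface point and face index for each query point.

    Candidate faces come from a KD-tree over face centroids (an AABB-tree
    equivalent for near-uniform meshes); the exact closest point on each
    candidate triangle decides the winner.
    """
    from scipy.spatial import cKDTree

    pts = np.asarray(points, dtype=float)
    tris = mesh.face_corners()
    k = min(k_candidates, mesh.n_faces)
    _, cand = cKDTree(tris.mean(axis=1)).query(pts, k=k)
    if k == 1:
        cand = cand[:, None]
    n = len(pts)
    flat_tris = tris[cand.ravel()]
    flat_pts = np.repeat(pts, k, axis=0)
    closest = trimesh.triangles.closest_point(flat_tris, flat_pts)
    d2 = ((closest - flat_pts) ** 2).sum(axis=1).reshape(n, k)
    best = d2.argmin(axis=1)
    rows = np.arange(n)
    return (closest.reshape(n, k, 3)[rows, best],
            cand[rows, best])


def transfer_scalars(src: SurfaceMesh, dst: SurfaceMesh, field: np.ndarray,
                     method: str = "barycentric") -> np.ndarray:
    """Interpolate a per-vertex field of ``src`` onto the vertices of ``dst``.

    ``barycentric`` locates the nearest point on the source surface for each
    destination vertex and blends the three corner values convexly;
    ``nearest`` copies the value of the nearest source vertex.
    """
    fld = np.asarray(field, dtype=float)
    if fld.shape[0] != src.n_vertices:
        raise ValueError("field length does not match source mesh")
    if fld.size == 0:
        raise ValueError("empty field")
    if method == "nearest":
        from scipy.spatial import cKDTree

        _, idx = cKDTree(src.vertices).query(dst.vertices)
        return fld[idx]
    if method != "barycentric":
        raise ValueError(f"unknown method {method!r}")
    closest, tri_id = nearest_triangle(src, dst.vertices)
    tri = src.faces[tri_id]
    bary = trimesh.triangles.points_to_barycentric(src.vertices[tri], closest)
    bary = np.clip(bary, 0.0, 1.0)
    bary /= bary.sum(axis=1, keepdims=True)
    vals = fld[tri]
    if vals.ndim == 2:
        return np.einsum("ij,ij->i", bary, vals)
    return np.einsum("ij,ij...->i...", bary, vals)
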