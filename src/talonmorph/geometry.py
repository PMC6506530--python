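"""Surface and volume mesh containers.

Meshes live in a canonical anatomical frame: x = medio-lateral,
y = dorso-ventral (ventral is -y), z = proximo-distal (tip at +z).
Grip force acts along -z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh


@dataclass
class TriMesh:
    """Triangulated surface: ``vertices`` (V, 3) mm, ``faces`` (F, 3) 0-based."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = (v[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


@dataclass
class TetMesh:
    """4-node tetrahedral volume mesh.

    ``nodes`` (N, 3) in mm; ``tets`` (T, 4) 0-based with positive signed
    volume under the (n0, n1, n2, n3) ordering; ``node_sets`` name the
    anatomical index sets used for restraints and loads (tip,
    cotyla_medial/lateral, tubercle_medial/lateral).
    """

    nodes: np.ndarray
    tets: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.node_sets = {k: np.asarray(v, dtype=np.int64) for k, v in self.node_sets.items()}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        """Signed volumes; positive for correctly oriented elements."""
        p = self.nodes[self.tets]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        d3 = p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", np.cross(d1, d2), d3) / 6.0

    def tet_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def boundary_faces(self) -> np.ndarray:
        """Outward-oriented boundary triangles (faces on exactly one tet)."""
        # the face opposite each local node, ordered for outward normals
        loc = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
        faces = self.tets[:, loc].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return faces[counts[inv] == 1]

    def surface(self) -> TriMesh:
        return TriMesh(self.nodes, self.boundary_faces())

    def surface_area(self) -> float:
        return self.surface().area()

    def fix_orientation(self) -> int:
        """Swap vertex order of negative-volume tets in place; return count."""
        bad = self.tet_volumes() < 0
        n = int(bad.sum())
        if n:
            self.tets[bad] = self.tets[bad][:, [0, 2, 1, 3]]
        return n

    def scaled(self, k: float) -> "TetMesh":
        return TetMesh(self.nodes * k, self.tets.copy(),
                       {n: s.copy() for n, s in self.node_sets.items()})


def structured_box_mesh(nx: int, ny: int, nz: int,
                        lx: float, ly: float, lz: float) -> TetMesh:
    """Structured tet mesh of a box: (nx, ny, nz) cells, each split into
    six tets along the Kuhn triangulation (conforming across cells).

    Node sets: face sets x0/x1/y0/y1/z0/z1 (all nodes on each face).
    """
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    # Kuhn: one tet per permutation of the unit steps
    perms = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
    steps = np.eye(3, dtype=int)
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                base = np.array([i, j, k])
                for p in perms:
                    c0 = base
                    c1 = c0 + steps[p[0]]
                    c2 = c1 + steps[p[1]]
                    c3 = c2 + steps[p[2]]
                    tets.append([nid(*c0), nid(*c1), nid(*c2), nid(*c3)])
    mesh = TetMesh(nodes, np.asarray(tets, np.int64))
    mesh.fix_orientation()
    eps = 1e-12
    mesh.node_sets = {
        "x0": np.where(np.abs(nodes[:, 0]) < eps)[0],
        "x1": np.where(np.abs(nodes[:, 0] - lx) < eps)[0],
        "y0": np.where(np.abs(nodes[:, 1]) < eps)[0],
        "y1": np.where(np.abs(nodes[:, 1] - ly) < eps)[0],
        "z0": np.where(np.abs(nodes[:, 2]) < eps)[0],
        "z1": np.where(np.abs(nodes[:, 2] - lz) < eps)[0],
    }
    return mesh


def _closest_on_triangles(p: np.ndarray, a, b, c) -> np.ndarray:
    """Closest point to p on each triangle (a, b, c); all (..., 3)."""
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    out = a + v[..., None] * ab + w[..., None] * ac  # interior case

    # edge/vertex regions (Ericson's region tests)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        t_bc = np.where((d4 - d3) + (d5 - d6) != 0,
                        (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    e_ab = a + np.clip(t_ab, 0, 1)[..., None] * ab
    e_ac = a + np.clip(t_ac, 0, 1)[..., None] * ac
    e_bc = b + np.clip(t_bc, 0, 1)[..., None] * (c - b)

    out = np.where(((vc <= 0) & (d1 >= 0) & (d3 <= 0))[..., None], e_ab, out)
    out = np.where(((vb <= 0) & (d2 >= 0) & (d6 <= 0))[..., None], e_ac, out)
    out = np.where(((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0))[..., None], e_bc, out)
    out = np.where(((d1 <= 0) & (d2 <= 0))[..., None], np.broadcast_to(a, out.shape), out)
    out = np.where(((d3 >= 0) & (d4 <= d3))[..., None], np.broadcast_to(b, out.shape), out)
    out = np.where(((d6 >= 0) & (d5 <= d6))[..., None], np.broadcast_to(c, out.shape), out)
    return out


def closest_point_on_mesh(mesh: TriMesh, points: np.ndarray, k: int = 32
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Project points to their nearest location on a triangle mesh.

    Candidate triangles come from the k nearest triangle centroids
    (KD-tree); the exact point-triangle distance picks the winner.
    Returns (projected points, distances).
    """
    from scipy.spatial import cKDTree

    points = np.atleast_2d(np.asarray(points, float))
    tris = mesh.vertices[mesh.faces]          # (F, 3, 3)
    tree = cKDTree(tris.mean(axis=1))
    k = min(k, len(tris))
    _, cand = tree.query(points, k=k)
    cand = np.atleast_2d(cand)
    a, b, c = tris[cand, 0], tris[cand, 1], tris[cand, 2]   # (n, k, 3)
    closest = _closest_on_triangles(points[:, None, :], a, b, c)
    d2 = np.einsum("nki,nki->nk", closest - points[:, None, :],
                   closest - points[:, None, :])
    best = np.argmin(d2, axis=1)
    rows = np.arange(len(points))
    return closest[rows, best], np.sqrt(d2[rows, best])
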