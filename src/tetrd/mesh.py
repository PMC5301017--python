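"""Tetrahedral mesh container, geometry tables, cuboid generation and I/O.

Meshes are stored as flat NumPy arrays: ``vertices`` (n_verts, 3) in μm and
``tets`` (n_tets, 4) zero-based vertex indices.  Face-neighbor connectivity is
always rebuilt from the tet list (never trusted from a file): for each tet,
local face ``f`` is the face opposite local vertex ``f``, and ``neighbors[i, f]``
is the adjacent tet sharing that face (``-1`` on the domain boundary), with
``neighbor_faces[i, f]`` the matching local face index on the neighbor side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

import numpy as np

__all__ = [
    "TetMesh",
    "GeomTables",
    "MeshQualityError",
    "MeshFormatError",
    "generate_cuboid_mesh",
    "compute_geometry",
    "load_mesh",
    "save_mesh",
]

#: tets thinner than this volume (μm³) are treated as degenerate
DEGENERATE_VOLUME = 1e-12

# local face f is opposite local vertex f
_FACE_VERTS = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]], dtype=np.int64)


class MeshQualityError(ValueError):
    """A tet is degenerate or the connectivity is non-conforming."""


class MeshFormatError(ValueError):
    """A mesh file could not be parsed under the requested dialect."""


@dataclass
class TetMesh:
    vertices: np.ndarray  # (n_verts, 3) float64, μm
    tets: np.ndarray  # (n_tets, 4) int64, zero-based
    neighbors: np.ndarray = field(init=False)  # (n_tets, 4) int64, -1 = boundary
    neighbor_faces: np.ndarray = field(init=False)  # (n_tets, 4) int64, -1 = boundary

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (n, 3) array")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise MeshFormatError("tets must be an (n, 4) array")
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= len(self.vertices)):
            raise MeshFormatError("tet vertex index out of range")
        self._fix_orientation()
        self._build_neighbors()

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def n_verts(self) -> int:
        return len(self.vertices)

    def _signed_volumes(self) -> np.ndarray:
        v = self.vertices[self.tets]
        a, b, c = v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def _fix_orientation(self) -> None:
        # make every tet positively oriented; degenerate tets are caught later
        sv = self._signed_volumes()
        flip = sv < 0
        if flip.any():
            self.tets[flip, 2:] = self.tets[flip, 3:1:-1]

    def _build_neighbors(self) -> None:
        n = self.n_tets
        self.neighbors = np.full((n, 4), -1, dtype=np.int64)
        self.neighbor_faces = np.full((n, 4), -1, dtype=np.int64)
        face_map: dict[tuple[int, int, int], tuple[int, int]] = {}
        for i in range(n):
            for f in range(4):
                key = tuple(sorted(self.tets[i, _FACE_VERTS[f]]))
                if key in face_map:
                    j, g = face_map.pop(key)
                    if self.neighbors[i, f] != -1 or self.neighbors[j, g] != -1:
                        raise MeshQualityError(
                            f"face {key} shared by more than two tets"
                        )
                    self.neighbors[i, f], self.neighbor_faces[i, f] = j, g
                    self.neighbors[j, g], self.neighbor_faces[j, g] = i, f
                else:
                    face_map[key] = (i, f)

    def validate(self) -> None:
        """Check positive volumes and neighbor symmetry; raise on failure."""
        sv = self._signed_volumes()
        bad = np.flatnonzero(np.abs(sv) < DEGENERATE_VOLUME)
        if bad.size:
            raise MeshQualityError(f"degenerate tetrahedron {bad[0]} (|V| < {DEGENERATE_VOLUME})")
        for i in range(self.n_tets):
            for f in range(4):
                j = self.neighbors[i, f]
                if j < 0:
                    continue
                g = self.neighbor_faces[i, f]
                if self.neighbors[j, g] != i or self.neighbor_faces[j, g] != f:
                    raise MeshQualityError(f"asymmetric neighbor relation at tet {i} face {f}")


@dataclass
class GeomTables:
    """Per-tet geometry feeding the diffusion discretization.

    ``face_areas[i, f]`` (μm²) and ``bary_dist[i, f]`` (μm) are populated only
    for interior faces (neighbor present); boundary entries are 0.
    """

    volumes: np.ndarray  # (n_tets,) μm³
    barycenters: np.ndarray  # (n_tets, 3) μm
    face_areas: np.ndarray  # (n_tets, 4) μm²
    bary_dist: np.ndarray  # (n_tets, 4) μm


def compute_geometry(mesh: TetMesh) -> GeomTables:
    """Volumes, barycenters, interior-face areas and barycenter distances."""
    mesh.validate()
    v = mesh.vertices[mesh.tets]
    a, b, c = v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]
    volumes = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0
    bad = np.flatnonzero(volumes < DEGENERATE_VOLUME)
    if bad.size:
        raise MeshQualityError(f"degenerate tetrahedron {bad[0]} (V < {DEGENERATE_VOLUME} μm³)")
    barycenters = v.mean(axis=1)

    face_areas = np.zeros((mesh.n_tets, 4))
    bary_dist = np.zeros((mesh.n_tets, 4))
    for f in range(4):
        tri = mesh.vertices[mesh.tets[:, _FACE_VERTS[f]]]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        area = 0.5 * np.linalg.norm(cross, axis=1)
        nb = mesh.neighbors[:, f]
        interior = nb >= 0
        face_areas[interior, f] = area[interior]
        d = np.linalg.norm(barycenters[nb[interior]] - barycenters[interior], axis=1)
        bary_dist[interior, f] = d
    return GeomTables(volumes, barycenters, face_areas, bary_dist)


def generate_cuboid_mesh(dims, counts) -> TetMesh:
    """Structured cuboid mesh: each grid cell split into 6 tets (Kuhn subdivision).

    The Kuhn split uses the same main diagonal in every cell, so shared cell
    faces carry matching triangulations and the mesh is conforming.

    Parameters
    ----------
    dims : 3 floats, box extents in μm (all > 0)
    counts : 3 ints, cells per axis (all >= 1)
    """
    dims = tuple(float(x) for x in dims)
    counts = tuple(int(x) for x in counts)
    if len(dims) != 3 or len(counts) != 3:
        raise ValueError("dims and counts must have length 3")
    if any(d <= 0 for d in dims):
        raise ValueError(f"box extents must be positive, got {dims}")
    if any(c < 1 for c in counts):
        raise ValueError(f"cell counts must be >= 1, got {counts}")
    nx, ny, nz = counts
    xs = np.linspace(0.0, dims[0], nx + 1)
    ys = np.linspace(0.0, dims[1], ny + 1)
    zs = np.linspace(0.0, dims[2], nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    vertices = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    # 6 tets per cell: walk the cube edges in each axis permutation, all
    # sharing the main diagonal (0,0,0)-(1,1,1)
    corner_paths = []
    for perm in permutations(range(3)):
        path = [(0, 0, 0)]
        cur = [0, 0, 0]
        for ax in perm:
            cur[ax] = 1
            path.append(tuple(cur))
        corner_paths.append(path)

    tets = np.empty((nx * ny * nz * 6, 4), dtype=np.int64)
    idx = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                for path in corner_paths:
                    for m, (di, dj, dk) in enumerate(path):
                        tets[idx, m] = vid(i + di, j + dj, k + dk)
                    idx += 1
    return TetMesh(vertices, tets)


# ---------------------------------------------------------------------------
# I/O: native text format and Gmsh MSH v2 ASCII


def save_mesh(mesh: TetMesh, path) -> None:
    """Write the native text format: header ``ntets nverts``, then vertex
    lines ``x y z``, then tet lines of 4 zero-based vertex indices."""
    path = Path(path)
    lines = [f"{mesh.n_tets} {mesh.n_verts}"]
    lines += [f"{float(x)!r} {float(y)!r} {float(z)!r}" for x, y, z in mesh.vertices]
    lines += [" ".join(str(int(i)) for i in row) for row in mesh.tets]
    path.write_text("\n".join(lines) + "\n")


def _load_native(path: Path) -> TetMesh:
    lines = path.read_text().splitlines()
    if not lines:
        raise MeshFormatError(f"{path}: empty file")
    try:
        ntets, nverts = (int(x) for x in lines[0].split())
    except ValueError as exc:
        raise MeshFormatError(f"{path}:1: expected header 'ntets nverts'") from exc
    if len(lines) < 1 + nverts + ntets:
        raise MeshFormatError(f"{path}: truncated ({len(lines)} lines, need {1 + nverts + ntets})")
    verts = np.empty((nverts, 3))
    for n in range(nverts):
        parts = lines[1 + n].split()
        if len(parts) != 3:
            raise MeshFormatError(f"{path}:{n + 2}: expected 3 coordinates, got {len(parts)}")
        verts[n] = [float(p) for p in parts]
    tets = np.empty((ntets, 4), dtype=np.int64)
    for n in range(ntets):
        lineno = 1 + nverts + n
        parts = lines[lineno].split()
        if len(parts) != 4:
            raise MeshFormatError(f"{path}:{lineno + 1}: expected 4 vertex indices, got {len(parts)}")
        tets[n] = [int(p) for p in parts]
    return TetMesh(verts, tets)


def _load_msh2(path: Path) -> TetMesh:
    """Gmsh MSH v2 ASCII: $Nodes and $Elements sections; element type 4 = tet.

    One-based node ids (possibly sparse) are remapped to dense zero-based
    indices.  Lower-dimensional elements (points, lines, triangles) are
    ignored; any other element type is rejected.
    """
    lines = path.read_text().splitlines()
    it = iter(enumerate(lines, start=1))
    node_ids: list[int] = []
    coords: list[list[float]] = []
    tets: list[list[int]] = []
    saw_nodes = saw_elements = False
    for lineno, line in it:
        token = line.strip()
        if token == "$Nodes":
            saw_nodes = True
            _, count_line = next(it)
            n_nodes = int(count_line)
            for _ in range(n_nodes):
                _, row = next(it)
                parts = row.split()
                node_ids.append(int(parts[0]))
                coords.append([float(x) for x in parts[1:4]])
            _, end = next(it)
            if end.strip() != "$EndNodes":
                raise MeshFormatError(f"{path}: $Nodes section not terminated")
        elif token == "$Elements":
            saw_elements = True
            _, count_line = next(it)
            n_elem = int(count_line)
            for _ in range(n_elem):
                lineno, row = next(it)
                parts = [int(x) for x in row.split()]
                etype, ntags = parts[1], parts[2]
                conn = parts[3 + ntags:]
                if etype == 4:
                    tets.append(conn)
                elif etype in (15, 1, 2):  # point, line, triangle: surface clutter
                    continue
                else:
                    raise MeshFormatError(
                        f"{path}:{lineno}: unsupported MSH element type {etype}"
                    )
            _, end = next(it)
            if end.strip() != "$EndElements":
                raise MeshFormatError(f"{path}: $Elements section not terminated")
    if not saw_nodes or not saw_elements:
        raise MeshFormatError(f"{path}: missing $Nodes or $Elements section")
    if not tets:
        raise MeshFormatError(f"{path}: no tetrahedral elements (type 4) found")
    remap = {nid: n for n, nid in enumerate(node_ids)}
    try:
        tet_arr = np.array([[remap[v] for v in row] for row in tets], dtype=np.int64)
    except KeyError as exc:
        raise MeshFormatError(f"{path}: element references unknown node {exc}") from exc
    return TetMesh(np.array(coords), tet_arr)


def load_mesh(path, format: str = "native-text") -> TetMesh:
    """Read a mesh; connectivity is rebuilt from the tet list on load."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "native-text":
        return _load_native(path)
    if format == "msh2":
        return _load_msh2(path)
    raise MeshFormatError(f"unknown mesh format {format!r}")
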