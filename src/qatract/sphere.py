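"""Icosphere tessellations for sampling orientation distribution functions.

Spin distribution functions (SDFs) and ODFs are sampled on a discrete set of
unit vectors.  The standard construction is the subdivided icosahedron
projected onto the unit sphere, which at subdivision level ``k`` has
``10 * 4**k + 2`` vertices (level 3 gives the common 642-direction set).
Diffusion is antipodally symmetric, so functions are evaluated on one
hemisphere representative per antipodal vertex pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SphereTessellation", "build_tessellation", "angular_resolution"]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Regular icosahedron (12 vertices, 20 faces), antipodally symmetric."""
    p = _GOLDEN
    verts = np.array(
        [
            [-1, p, 0], [1, p, 0], [-1, -p, 0], [1, -p, 0],
            [0, -1, p], [0, 1, p], [0, -1, -p], [0, 1, -p],
            [p, 0, -1], [p, 0, 1], [-p, 0, -1], [-p, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One round of midpoint (Loop-style) subdivision with re-projection."""
    verts = list(verts)
    midpoint_cache: dict[tuple[int, int], int] = {}

    def midpoint(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        idx = midpoint_cache.get(key)
        if idx is None:
            m = verts[i] + verts[j]
            m /= np.linalg.norm(m)
            idx = len(verts)
            verts.append(m)
            midpoint_cache[key] = idx
        return idx

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces.extend([[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]])
    return np.asarray(verts), np.asarray(new_faces, dtype=np.int64)


def _edges_from_faces(faces: np.ndarray) -> np.ndarray:
    """Unique undirected edges of a triangulation, as an (E, 2) index array."""
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


@dataclass(frozen=True)
class SphereTessellation:
    """Antipodally symmetric sampling of the unit sphere.

    Attributes
    ----------
    vertices : (n, 3) float array of unit vectors (full sphere).
    faces : (m, 3) int array of triangles.
    edges : (e, 2) int array of unique undirected edges.
    adjacency : tuple of int tuples; 1-ring neighbors of each vertex.
    antipode : (n,) int array; ``vertices[antipode[i]] == -vertices[i]``.
    hemisphere : (n/2,) int array of representative vertex indices, one per
        antipodal pair (the member whose last nonzero coordinate is positive).
    hemi_index : (n,) int array mapping each vertex to the position of its
        pair's representative within ``hemisphere``.
    level : subdivision level used to build the tessellation.
    """

    vertices: np.ndarray
    faces: np.ndarray
    edges: np.ndarray
    adjacency: tuple[tuple[int, ...], ...]
    antipode: np.ndarray
    hemisphere: np.ndarray
    hemi_index: np.ndarray
    level: int = field(default=0)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def hemisphere_vertices(self) -> np.ndarray:
        """Unit vectors of the hemisphere representatives, shape (n/2, 3)."""
        return self.vertices[self.hemisphere]

    def hemisphere_adjacency(self) -> tuple[tuple[int, ...], ...]:
        """1-ring neighbors of each hemisphere representative, expressed as
        hemisphere indices (antipodal neighbors collapse onto their pair)."""
        out = []
        for h in self.hemisphere:
            nbrs = {int(self.hemi_index[j]) for j in self.adjacency[h]}
            nbrs.discard(int(self.hemi_index[h]))
            out.append(tuple(sorted(nbrs)))
        return tuple(out)

    def to_text(self) -> str:
        """Plain-text vertex/edge dump for debugging."""
        lines = [f"# icosphere level={self.level} vertices={self.n_vertices}"]
        for v in self.vertices:
            lines.append(f"v {v[0]:.9f} {v[1]:.9f} {v[2]:.9f}")
        for a, b in self.edges:
            lines.append(f"e {a} {b}")
        return "\n".join(lines)


def _hemisphere_representatives(vertices: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """True for the canonical member of each antipodal pair (z > 0, ties
    broken by y then x)."""
    x, y, z = vertices.T
    return (z > tol) | ((np.abs(z) <= tol) & (y > tol)) | (
        (np.abs(z) <= tol) & (np.abs(y) <= tol) & (x > tol)
    )


def build_tessellation(subdivision_level: int = 3) -> SphereTessellation:
    """Build an icosphere by midpoint subdivision with unit-sphere projection.

    Parameters
    ----------
    subdivision_level : number of subdivision rounds, 0 <= level <= 6.
        Level 0 is the icosahedron (12 vertices); level 3 yields the
        642-direction set commonly used for ODF sampling.
    """
    level = int(subdivision_level)
    if level < 0:
        raise ValueError("subdivision_level must be non-negative")
    if level > 6:
        raise ValueError("subdivision_level above 6 is not supported")

    verts, faces = _icosahedron()
    for _ in range(level):
        verts, faces = _subdivide(verts, faces)

    edges = _edges_from_faces(faces)
    n = len(verts)
    adjacency: list[set[int]] = [set() for _ in range(n)]
    for a, b in edges:
        adjacency[a].add(int(b))
        adjacency[b].add(int(a))

    # Antipodes are exact up to rounding: match -v against a keyed grid.
    key = {tuple(np.round(v, 9)): i for i, v in enumerate(verts)}
    antipode = np.empty(n, dtype=np.int64)
    for i, v in enumerate(verts):
        j = key.get(tuple(np.round(-v, 9)))
        if j is None:  # pragma: no cover - construction guarantees symmetry
            raise RuntimeError("tessellation lost antipodal symmetry")
        antipode[i] = j

    rep_mask = _hemisphere_representatives(verts)
    hemisphere = np.flatnonzero(rep_mask)
    pos = {int(v): k for k, v in enumerate(hemisphere)}
    hemi_index = np.empty(n, dtype=np.int64)
    for i in range(n):
        hemi_index[i] = pos[i] if rep_mask[i] else pos[int(antipode[i])]

    return SphereTessellation(
        vertices=verts,
        faces=faces,
        edges=edges,
        adjacency=tuple(tuple(sorted(s)) for s in adjacency),
        antipode=antipode,
        hemisphere=hemisphere,
        hemi_index=hemi_index,
        level=level,
    )


def angular_resolution(tess: SphereTessellation, stat: str = "mean") -> float:
    """Angular spacing of a tessellation, in degrees.

    Computed over all edge-connected vertex pairs as the great-circle arc
    between them; ``stat`` selects the mean (default, used for reporting) or
    the max.
    """
    u = tess.vertices[tess.edges[:, 0]]
    v = tess.vertices[tess.edges[:, 1]]
    dots = np.clip(np.einsum("ij,ij->i", u, v), -1.0, 1.0)
    ang = np.degrees(np.arccos(dots))
    if stat == "mean":
        return float(ang.mean())
    if stat == "max":
        return float(ang.max())
    raise ValueError(f"unknown stat {stat!r}")
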