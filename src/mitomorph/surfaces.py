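"""Triangle-mesh membrane surfaces and spatial queries against them.

Membrane segmentations arrive as triangulated surfaces; every analysis stage
only needs per-triangle attributes (centroid, unit normal, area) plus named
boolean label sets over triangles (e.g. ``"crista_associated"``).  Meshes are
kept indexed (vertices + faces) so adjacency can be rebuilt from shared edges
when connected components are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree


__all__ = [
    "TriangleSurface",
    "nearest_triangle",
    "sample_on_triangles",
    "icosphere",
]


@dataclass
class TriangleSurface:
    """Indexed triangle mesh with derived per-triangle attributes.

    Vertices are Angstrom coordinates in the tomogram frame.  Normals are
    recomputed from the winding and, for closed surfaces, oriented outward
    (positive signed volume).  ``labels`` maps a set name to a boolean mask
    over triangles.
    """

    vertices: np.ndarray
    faces: np.ndarray
    surface_id: str = "OMM"
    tomogram_id: str = "tomo"
    labels: dict = field(default_factory=dict)

    centroids: np.ndarray = field(init=False, repr=False)
    normals: np.ndarray = field(init=False, repr=False)
    areas: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indexes out of range")
        self._recompute()
        self._tree = None

    def _recompute(self) -> None:
        tri = self.vertices[self.faces]  # (n, 3, 3)
        self.centroids = tri.mean(axis=1)
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norms = np.linalg.norm(cross, axis=1)
        self.areas = 0.5 * norms
        with np.errstate(invalid="ignore", divide="ignore"):
            self.normals = np.where(norms[:, None] > 0, cross / np.where(norms[:, None] == 0, 1, norms[:, None]), 0.0)

    @property
    def n_triangles(self) -> int:
        return len(self.faces)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def kdtree(self) -> cKDTree:
        """KD-tree over triangle centroids (built lazily, cached)."""
        if self._tree is None:
            self._tree = cKDTree(self.centroids)
        return self._tree

    def drop_degenerate(self) -> int:
        """Remove zero-area triangles in place; returns how many were dropped."""
        bad = self.areas <= 0
        n_bad = int(bad.sum())
        if n_bad:
            keep = ~bad
            self.faces = self.faces[keep]
            self.labels = {k: np.asarray(v)[keep] for k, v in self.labels.items()}
            self._recompute()
            self._tree = None
        return n_bad

    def signed_volume(self) -> float:
        """Signed volume by the divergence theorem; > 0 for outward normals."""
        tri = self.vertices[self.faces]
        return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)

    def orient_outward(self) -> None:
        """Flip all face windings if the signed volume is negative."""
        if self.signed_volume() < 0:
            self.faces = self.faces[:, ::-1]
            self._recompute()
            self._tree = None

    def set_label(self, name: str, mask) -> None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_triangles,):
            raise ValueError("label mask length must equal the triangle count")
        self.labels[name] = mask

    def triangle_adjacency(self):
        """Sparse triangle-triangle adjacency via shared edges."""
        f = self.faces
        edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        edges = np.sort(edges, axis=1)
        tri_ids = np.tile(np.arange(len(f)), 3)
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        edges, tri_ids = edges[order], tri_ids[order]
        same = np.all(edges[1:] == edges[:-1], axis=1)
        a, b = tri_ids[:-1][same], tri_ids[1:][same]
        n = len(f)
        return coo_matrix(
            (np.ones(2 * len(a)), (np.concatenate([a, b]), np.concatenate([b, a]))),
            shape=(n, n),
        ).tocsr()

    def label_components(self, mask) -> list[np.ndarray]:
        """Connected components (by shared edges) of a triangle subset."""
        mask = np.asarray(mask, dtype=bool)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return []
        sub = self.triangle_adjacency()[np.ix_(idx, idx)]
        n_comp, lab = connected_components(sub, directed=False)
        return [idx[lab == i] for i in range(n_comp)]


def nearest_triangle(points, surface: TriangleSurface, exact: bool = False):
    """Nearest OMM/IMM triangle for each query point.

    Distance is point-to-centroid (the convention used throughout; an exact
    point-to-triangle mode exists behind ``exact=True``).  Ties on equal
    distance resolve to the lowest triangle index, matching an exhaustive
    scan.

    Returns ``(ids, distances)``; scalar inputs give scalar outputs.
    """
    if surface.n_triangles == 0:
        raise ValueError("surface has no triangles")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if exact:
        d2 = _point_triangle_sq_distance(pts, surface)
        ids = np.argmin(d2, axis=1)
        dist = np.sqrt(d2[np.arange(len(pts)), ids])
    else:
        tree = surface.kdtree()
        dist, ids = tree.query(pts, k=1)
        # enforce lowest-index tie-break: re-scan the candidate shell
        for i in range(len(pts)):
            cand = tree.query_ball_point(pts[i], dist[i] * (1 + 1e-12) + 1e-12)
            if len(cand) > 1:
                cd = np.linalg.norm(surface.centroids[cand] - pts[i], axis=1)
                best = cd.min()
                tied = sorted(c for c, d in zip(cand, cd) if d <= best + 1e-9 * max(best, 1.0))
                ids[i], dist[i] = tied[0], best
    if np.asarray(points).ndim == 1:
        return int(ids[0]), float(dist[0])
    return ids.astype(np.int64), dist


def _point_triangle_sq_distance(points: np.ndarray, surface: TriangleSurface) -> np.ndarray:
    """Squared distance from each point to each triangle (exact projection).

    Vectorized Voronoi-region case analysis (vertex / edge / face regions);
    O(points x triangles) memory, intended for small meshes.
    """
    tri = surface.vertices[surface.faces]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, bc = b - a, c - a, c - b
    p = points[:, None, :]
    ap, bp, cp = p - a[None], p - b[None], p - c[None]
    d1 = np.einsum("pti,ti->pt", ap, ab)
    d2 = np.einsum("pti,ti->pt", ap, ac)
    d3 = np.einsum("pti,ti->pt", bp, ab)
    d4 = np.einsum("pti,ti->pt", bp, ac)
    d5 = np.einsum("pti,ti->pt", cp, ab)
    d6 = np.einsum("pti,ti->pt", cp, ac)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = va + vb + vc
        v_face = np.where(denom != 0, vb / np.where(denom == 0, 1, denom), 0.0)
        w_face = np.where(denom != 0, vc / np.where(denom == 0, 1, denom), 0.0)
        t_ab = np.where(d1 != d3, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0.0)
        t_ac = np.where(d2 != d6, d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0.0)
        den_bc = (d4 - d3) + (d5 - d6)
        t_bc = np.where(den_bc != 0, (d4 - d3) / np.where(den_bc == 0, 1, den_bc), 0.0)

    closest = a[None] + v_face[..., None] * ab[None] + w_face[..., None] * ac[None]
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    closest = np.where(on_bc[..., None], b[None] + np.clip(t_bc, 0, 1)[..., None] * bc[None], closest)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    closest = np.where(on_ac[..., None], a[None] + np.clip(t_ac, 0, 1)[..., None] * ac[None], closest)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    closest = np.where(on_ab[..., None], a[None] + np.clip(t_ab, 0, 1)[..., None] * ab[None], closest)
    at_c = (d6 >= 0) & (d5 <= d6)
    closest = np.where(at_c[..., None], c[None] + np.zeros_like(closest), closest)
    at_b = (d3 >= 0) & (d4 <= d3)
    closest = np.where(at_b[..., None], b[None] + np.zeros_like(closest), closest)
    at_a = (d1 <= 0) & (d2 <= 0)
    closest = np.where(at_a[..., None], a[None] + np.zeros_like(closest), closest)
    return np.sum((p - closest) ** 2, axis=2)


def sample_on_triangles(surface: TriangleSurface, n: int, rng, mask=None, standoff: float = 0.0):
    """Area-weighted uniform samples on (a subset of) a surface.

    Picks triangles with probability proportional to area and a uniform point
    inside each via the square-root barycentric trick; ``standoff`` displaces
    each sample along the triangle's outward normal.

    Returns ``(points (n,3), triangle_ids (n,))``.
    """
    areas = surface.areas
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        areas = np.where(mask, areas, 0.0)
    total = areas.sum()
    if total <= 0:
        raise ValueError("no area available to sample from")
    tri_ids = rng.choice(surface.n_triangles, size=n, p=areas / total)
    tri = surface.vertices[surface.faces[tri_ids]]
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    pts = (
        (1 - r1)[:, None] * tri[:, 0]
        + (r1 * (1 - r2))[:, None] * tri[:, 1]
        + (r1 * r2)[:, None] * tri[:, 2]
    )
    if standoff:
        pts = pts + standoff * surface.normals[tri_ids]
    return pts, tri_ids


# ---------------------------------------------------------------------------
# icosphere construction (used by the synthetic scene generator)

_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        [-1, _ICO_T, 0], [1, _ICO_T, 0], [-1, -_ICO_T, 0], [1, -_ICO_T, 0],
        [0, -1, _ICO_T], [0, 1, _ICO_T], [0, -1, -_ICO_T], [0, 1, -_ICO_T],
        [_ICO_T, 0, -1], [_ICO_T, 0, 1], [-_ICO_T, 0, -1], [-_ICO_T, 0, 1],
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


def icosphere(radius: float = 1.0, subdivisions: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosahedron subdivided ``subdivisions`` times, scaled to ``radius``.

    Returns ``(vertices, faces)`` with vertices on the sphere and outward
    winding.  Triangle count is 20 * 4**subdivisions.
    """
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    faces = _ICO_FACES.copy()
    for _ in range(subdivisions):
        edge_mid: dict[tuple[int, int], int] = {}
        new_verts = [verts]
        next_idx = len(verts)

        def midpoint(i: int, j: int) -> int:
            nonlocal next_idx
            key = (min(i, j), max(i, j))
            if key not in edge_mid:
                m = verts[i] + verts[j]
                m /= np.linalg.norm(m)
                new_verts.append(m[None])
                edge_mid[key] = next_idx
                next_idx += 1
            return edge_mid[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces.extend([[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]])
        verts = np.concatenate(new_verts)
        faces = np.asarray(new_faces, dtype=np.int64)
    return verts * radius, faces
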