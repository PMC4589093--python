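"""Simplicial meshes for optical tomography domains.

Triangulations of discs (2D) and tetrahedralizations of cylinders (3D),
conforming longest-edge-bisection refinement guided by a prior image, and
the point-location / barycentric queries used to place sources and
detectors.  Coordinates are millimetres; node and element indices are
0-based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .errors import InvalidParameterError, NotFoundError

log = logging.getLogger(__name__)

__all__ = [
    "Mesh",
    "Circle",
    "CylinderRegion",
    "PriorImage",
    "build_disc_mesh",
    "build_cylinder_mesh",
    "adaptive_refine",
    "locate",
    "boundary_interpolator",
    "breadth_first_order",
]


# ---------------------------------------------------------------------------
# geometric regions (shared with the phantom factory)


@dataclass(frozen=True)
class Circle:
    """Disc region in the z=0 plane."""

    center: tuple[float, float]
    radius: float

    def contains(self, pts: np.ndarray, dilation: float = 0.0) -> np.ndarray:
        pts = np.atleast_2d(pts)
        d = pts[:, :2] - np.asarray(self.center)[None, :]
        return (d * d).sum(axis=1) <= (self.radius + dilation) ** 2

    def dilated(self, margin: float) -> "Circle":
        return Circle(self.center, self.radius + margin)


@dataclass(frozen=True)
class CylinderRegion:
    """Axis-aligned (z) cylindrical region; ``center`` is the mid-height point."""

    center: tuple[float, float, float]
    radius: float
    height: float

    def contains(self, pts: np.ndarray, dilation: float = 0.0) -> np.ndarray:
        pts = np.atleast_2d(pts)
        c = np.asarray(self.center)
        d = pts[:, :2] - c[None, :2]
        in_r = (d * d).sum(axis=1) <= (self.radius + dilation) ** 2
        dz = np.abs(pts[:, 2] - c[2])
        return in_r & (dz <= self.height / 2.0 + dilation)

    def dilated(self, margin: float) -> "CylinderRegion":
        return CylinderRegion(self.center, self.radius + margin, self.height + 2 * margin)


@dataclass
class PriorImage:
    """Suspected inclusion support used to steer adaptive refinement."""

    regions: list = field(default_factory=list)
    dilation_mm: float = 0.0

    def __post_init__(self):
        if self.dilation_mm < 0:
            raise InvalidParameterError("dilation_mm must be >= 0")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        mask = np.zeros(len(pts), dtype=bool)
        for r in self.regions:
            mask |= r.contains(pts, dilation=self.dilation_mm)
        return mask


# ---------------------------------------------------------------------------
# mesh container


@dataclass
class Mesh:
    """Conforming simplicial mesh.

    nodes : (N, dim) float array, mm
    elements : (P, dim+1) int array, positively oriented simplices
    boundary_facets : (F, dim) int array; each facet belongs to exactly one
        element and the facets jointly enclose the domain.
    """

    dimension: int
    nodes: np.ndarray
    elements: np.ndarray
    boundary_facets: np.ndarray

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.intp)
        self.boundary_facets = np.ascontiguousarray(self.boundary_facets, dtype=np.intp)
        if self.dimension not in (2, 3):
            raise InvalidParameterError("dimension must be 2 or 3")
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= self.N
        ):
            raise InvalidParameterError("element node index out of range")
        self._orient()
        self._bary_cache = None

    @property
    def N(self) -> int:
        return self.nodes.shape[0]

    @property
    def P(self) -> int:
        return self.elements.shape[0]

    def _orient(self) -> None:
        """Flip node order so all signed areas/volumes are positive."""
        vol = self.signed_measures()
        neg = vol < 0
        if np.any(neg):
            el = self.elements.copy()
            el[neg, 0], el[neg, 1] = self.elements[neg, 1], self.elements[neg, 0]
            self.elements = el

    def signed_measures(self) -> np.ndarray:
        p = self.nodes[self.elements]
        e = p[:, 1:, :] - p[:, :1, :]
        if self.dimension == 2:
            return 0.5 * np.linalg.det(e)
        return np.linalg.det(e) / 6.0

    def element_measures(self) -> np.ndarray:
        """Areas (2D) or volumes (3D); positive after orientation."""
        return np.abs(self.signed_measures())

    def facet_measures(self) -> np.ndarray:
        p = self.nodes[self.boundary_facets]
        if self.dimension == 2:
            return np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
        cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as sorted (a, b) pairs."""
        nv = self.dimension + 1
        pairs = [(i, j) for i in range(nv) for j in range(i + 1, nv)]
        e = np.concatenate([self.elements[:, p] for p in pairs])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def node_adjacency(self):
        """Sparse node-to-node adjacency (for BFS orderings)."""
        from scipy.sparse import coo_matrix

        e = self.edges()
        n = self.N
        i = np.concatenate([e[:, 0], e[:, 1]])
        j = np.concatenate([e[:, 1], e[:, 0]])
        return coo_matrix((np.ones_like(i), (i, j)), shape=(n, n)).tocsr()


def _extract_boundary(elements: np.ndarray, dim: int) -> np.ndarray:
    """Facets that appear in exactly one element."""
    if dim == 2:
        local = [(0, 1), (1, 2), (2, 0)]
    else:
        local = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    f = np.concatenate([elements[:, p] for p in local])
    key = np.sort(f, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return f[idx[counts == 1]]


# ---------------------------------------------------------------------------
# built-in generators


def _disc_points(radius: float, target_edge: float) -> np.ndarray:
    n_r = max(1, int(round(radius / target_edge)))
    pts = [np.zeros((1, 2))]
    for k in range(1, n_r + 1):
        r = radius * k / n_r
        n_t = max(6, int(round(2 * math.pi * r / target_edge)))
        t = 2 * math.pi * np.arange(n_t) / n_t
        pts.append(np.column_stack([r * np.cos(t), r * np.sin(t)]))
    p = np.concatenate(pts)
    # pin outer-ring nodes exactly on the circle
    rr = np.linalg.norm(p, axis=1)
    outer = rr > radius * (1 - 1e-12)
    p[outer] *= (radius / rr[outer])[:, None]
    return p


def build_disc_mesh(radius_mm: float, target_edge_mm: float) -> Mesh:
    """Triangulate a disc of given radius centred at the origin."""
    if radius_mm <= 0 or target_edge_mm <= 0 or target_edge_mm >= radius_mm:
        raise InvalidParameterError(
            "require radius_mm > 0 and 0 < target_edge_mm < radius_mm"
        )
    pts = _disc_points(radius_mm, target_edge_mm)
    tri = Delaunay(pts)
    elements = tri.simplices.copy()
    # drop degenerate slivers (collinear boundary points)
    p = pts[elements]
    area = 0.5 * np.abs(
        np.linalg.det(p[:, 1:, :] - p[:, :1, :])
    )
    elements = elements[area > 1e-12 * radius_mm**2]
    bf = _extract_boundary(elements, 2)
    return Mesh(2, pts, elements, bf)


def _split_prism(v: tuple) -> list[tuple]:
    """Split prism (bottom v0 v1 v2, top v3 v4 v5) into three tetrahedra.

    Every quad face is cut by the diagonal through its smallest global
    vertex index, so neighbouring prisms agree on shared faces and the
    extruded mesh is conforming.
    """
    # rotate so the smallest index sits at corner 0
    rotations = [(0, 1, 2, 3, 4, 5), (1, 2, 0, 4, 5, 3), (2, 0, 1, 5, 3, 4),
                 (3, 5, 4, 0, 2, 1), (4, 3, 5, 1, 0, 2), (5, 4, 3, 2, 1, 0)]
    k = min(range(6), key=lambda i: v[i])
    rot = next(r for r in rotations if r[0] == k)
    p = [v[i] for i in rot]
    # quad face (p1, p2, p5, p4) does not contain p0: diagonal through its
    # smallest-indexed corner
    if min(p[1], p[5]) < min(p[2], p[4]):
        return [
            (p[0], p[1], p[2], p[5]),
            (p[0], p[1], p[5], p[4]),
            (p[0], p[4], p[5], p[3]),
        ]
    return [
        (p[0], p[1], p[2], p[4]),
        (p[0], p[4], p[2], p[5]),
        (p[0], p[4], p[5], p[3]),
    ]


def build_cylinder_mesh(radius_mm: float, height_mm: float, target_edge_mm: float) -> Mesh:
    """Tetrahedralize a cylinder (axis = z, base at z = 0).

    A disc triangulation is extruded into prism layers; each prism is split
    into three tetrahedra with face diagonals chosen by global vertex index,
    which keeps the mesh conforming and the elements well shaped.
    """
    if radius_mm <= 0 or height_mm <= 0 or target_edge_mm <= 0:
        raise InvalidParameterError("all cylinder mesh arguments must be > 0")
    disc = build_disc_mesh(radius_mm, target_edge_mm)
    n2d = disc.N
    n_z = max(1, int(round(height_mm / target_edge_mm)))
    layers = [
        np.column_stack([disc.nodes, np.full(n2d, height_mm * kz / n_z)])
        for kz in range(n_z + 1)
    ]
    pts3 = np.concatenate(layers)
    tets = []
    for kz in range(n_z):
        lo, hi = kz * n2d, (kz + 1) * n2d
        for (a, b, c) in disc.elements:
            tets.extend(_split_prism((lo + a, lo + b, lo + c, hi + a, hi + b, hi + c)))
    elements = np.asarray(tets, dtype=np.intp)
    bf = _extract_boundary(elements, 3)
    return Mesh(3, pts3, elements, bf)


# ---------------------------------------------------------------------------
# adaptive refinement (conforming longest-edge bisection)


def _edge_key(mesh_nodes, a, b):
    a, b = (a, b) if a < b else (b, a)
    return (a, b)


def _bisect_simplex(elem, edge, mid):
    """Split a simplex along one of its edges at node ``mid``."""
    a, b = edge
    rest = [v for v in elem if v != a and v != b]
    return (
        tuple([a, mid] + rest),
        tuple([mid, b] + rest),
    )


def _refine_cells(cells, split_edges, midpoint, nodes):
    """Recursively bisect every cell containing a split edge.

    The bisection edge is always the cell's *longest* split edge (ties broken
    by node index), which makes the induced triangulation of shared facets
    identical on both sides, preserving conformity in 2D and 3D.
    """

    def edge_len2(e):
        d = nodes[e[0]] - nodes[e[1]]
        return float(d @ d)

    out = []
    stack = list(cells)
    while stack:
        cell = stack.pop()
        present = []
        nv = len(cell)
        for i in range(nv):
            for j in range(i + 1, nv):
                k = _edge_key(nodes, cell[i], cell[j])
                if k in split_edges:
                    present.append(k)
        if not present:
            out.append(cell)
            continue
        pick = min(present, key=lambda e: (-edge_len2(e), e))
        c1, c2 = _bisect_simplex(cell, pick, midpoint[pick])
        stack.append(c1)
        stack.append(c2)
    return out


def adaptive_refine(mesh: Mesh, prior: PriorImage, node_budget: int) -> Mesh:
    """Refine elements intersecting the (dilated) prior regions.

    Rounds of conforming longest-edge bisection are applied to every element
    whose vertex or centroid lies inside a dilated prior region, stopping
    before a round would push the node count past ``node_budget``.  Existing
    nodes are never moved, so node sets are nested across rounds.
    """
    if node_budget <= mesh.N:
        log.warning(
            "adaptive_refine: node_budget %d <= current N %d; returning input",
            node_budget,
            mesh.N,
        )
        return mesh
    if not prior.regions:
        return mesh

    coords = [tuple(p) for p in mesh.nodes]
    elements = [tuple(e) for e in mesh.elements]
    facets = [tuple(f) for f in mesh.boundary_facets]

    while True:
        pts = np.asarray(coords)
        el = np.asarray(elements)
        cent = pts[el].mean(axis=1)
        marked = prior.contains(cent)
        for v in range(el.shape[1]):
            marked |= prior.contains(pts[el[:, v]])
        if not marked.any():
            break

        # longest edge of each marked element
        split_edges = set()
        for e in el[marked]:
            best, best_l = None, -1.0
            nv = len(e)
            for i in range(nv):
                for j in range(i + 1, nv):
                    d = pts[e[i]] - pts[e[j]]
                    l2 = float(d @ d)
                    k = _edge_key(pts, e[i], e[j])
                    if l2 > best_l or (l2 == best_l and k < best):
                        best, best_l = k, l2
            split_edges.add(best)

        if len(coords) + len(split_edges) > node_budget:
            break

        midpoint = {}
        for (a, b) in split_edges:
            m = 0.5 * (np.asarray(coords[a]) + np.asarray(coords[b]))
            midpoint[(a, b)] = len(coords)
            coords.append(tuple(m))

        coords_arr = np.asarray(coords)
        elements = _refine_cells(elements, split_edges, midpoint, coords_arr)
        facets = _refine_cells(facets, split_edges, midpoint, coords_arr)

    return Mesh(
        mesh.dimension,
        np.asarray(coords, dtype=float),
        np.asarray(elements, dtype=np.intp),
        np.asarray(facets, dtype=np.intp),
    )


# ---------------------------------------------------------------------------
# point location


def _barycentric_maps(mesh: Mesh):
    """Per-element affine maps p -> barycentric weights (cached on the mesh)."""
    if mesh._bary_cache is None:
        p = mesh.nodes[mesh.elements]
        T = np.swapaxes(p[:, 1:, :] - p[:, :1, :], 1, 2)  # (P, dim, dim)
        Tinv = np.linalg.inv(T)
        mesh._bary_cache = (p[:, 0, :], Tinv)
    return mesh._bary_cache


def _all_barycentric(mesh: Mesh, point: np.ndarray) -> np.ndarray:
    p0, Tinv = _barycentric_maps(mesh)
    lam = np.einsum("pij,pj->pi", Tinv, point[None, :] - p0)
    w0 = 1.0 - lam.sum(axis=1)
    return np.column_stack([w0, lam])


def locate(mesh: Mesh, point, tol: float = 1e-8):
    """Find the element containing ``point`` and its barycentric weights.

    Weights are clipped to [0, 1] and renormalized (only ever by amounts
    below ``tol``); raises :class:`NotFoundError` if the point lies outside
    every element by more than ``tol``.
    """
    point = np.asarray(point, dtype=float)
    w = _all_barycentric(mesh, point)
    worst = w.min(axis=1)
    k = int(np.argmax(worst))
    scale = max(1.0, float(np.abs(mesh.nodes).max()))
    if worst[k] < -tol * scale:
        raise NotFoundError(f"point {point.tolist()} is outside the mesh")
    weights = np.clip(w[k], 0.0, None)
    weights /= weights.sum()
    return k, weights


def boundary_interpolator(mesh: Mesh, point) -> tuple[np.ndarray, np.ndarray]:
    """Sampling weights for a point on (or near) the boundary surface.

    Projects the point onto the closest boundary facet and returns
    ``(facet node indices, barycentric weights)`` of the projection, so
    detectors specified on the exact curved boundary sample the adjacent
    polygonal facet.
    """
    point = np.asarray(point, dtype=float)
    f = mesh.boundary_facets
    p = mesh.nodes[f]
    if mesh.dimension == 2:
        a, b = p[:, 0], p[:, 1]
        ab = b - a
        t = np.einsum("ij,ij->i", point[None, :] - a, ab) / np.einsum("ij,ij->i", ab, ab)
        t = np.clip(t, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d2 = ((proj - point) ** 2).sum(axis=1)
        k = int(np.argmin(d2))
        return f[k], np.array([1.0 - t[k], t[k]])
    # 3D: barycentric projection onto triangle planes, clamped
    a, b, c = p[:, 0], p[:, 1], p[:, 2]
    ab, ac = b - a, c - a
    ap = point[None, :] - a
    d00 = np.einsum("ij,ij->i", ab, ab)
    d01 = np.einsum("ij,ij->i", ab, ac)
    d11 = np.einsum("ij,ij->i", ac, ac)
    d20 = np.einsum("ij,ij->i", ap, ab)
    d21 = np.einsum("ij,ij->i", ap, ac)
    den = d00 * d11 - d01 * d01
    v = (d11 * d20 - d01 * d21) / den
    w = (d00 * d21 - d01 * d20) / den
    v = np.clip(v, 0.0, 1.0)
    w = np.clip(w, 0.0, 1.0)
    s = v + w
    over = s > 1.0
    v[over] /= s[over]
    w[over] /= s[over]
    proj = a + v[:, None] * ab + w[:, None] * ac
    d2 = ((proj - point) ** 2).sum(axis=1)
    k = int(np.argmin(d2))
    return f[k], np.array([1.0 - v[k] - w[k], v[k], w[k]])


def breadth_first_order(mesh: Mesh) -> np.ndarray:
    """Node permutation from a BFS rooted at the node nearest the centroid.

    Spatially adjacent nodes tend to become index-adjacent, which is the
    ordering assumed when a 1D wavelet transform is applied to nodal vectors.
    """
    from scipy.sparse.csgraph import breadth_first_order as _bfs

    center = mesh.nodes.mean(axis=0)
    root = int(np.argmin(((mesh.nodes - center) ** 2).sum(axis=1)))
    adj = mesh.node_adjacency()
    order, _ = _bfs(adj, root, directed=False, return_predecessors=True)
    order = np.asarray(order, dtype=np.intp)
    if order.size < mesh.N:  # disconnected safety net
        rest = np.setdiff1d(np.arange(mesh.N), order)
        order = np.concatenate([order, rest])
    return order
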