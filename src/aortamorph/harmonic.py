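"""Harmonic (heat-conduction) parameterisation of a tubular surface.

A Laplace problem is solved on the vessel wall with Dirichlet conditions
"temperature" 1 on the inlet ring and 0 on the outlet ring.  Level sets
(isolines) of the resulting field are closed contours wrapping the tube,
approximately orthogonal to the vessel axis; they drive both the
isoline-centroid centerline and the inner/outer curvature-line construction.

The discretisation is the cotangent-weight (linear FEM) Laplacian, so the
isoline geometry converges to that of the smooth harmonic function under mesh
refinement rather than depending on triangulation density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .core import Landmark, TriSurface, polyline_centroid

log = logging.getLogger(__name__)

__all__ = ["HarmonicField", "IsolineSet", "solve_harmonic", "extract_isolines",
           "cotangent_laplacian"]


def cotangent_laplacian(surface: TriSurface) -> sparse.csr_matrix:
    """Symmetric cotangent-weight Laplacian L (positive semi-definite).

    ``L[i, j] = -0.5 * (cot alpha_ij + cot beta_ij)`` for an edge ij with
    opposite angles alpha, beta; diagonal makes rows sum to zero.
    """
    v = surface.vertices
    f = surface.faces
    n = len(v)
    rows, cols, vals = [], [], []
    for k in range(3):
        i = f[:, k]
        j = f[:, (k + 1) % 3]
        o = f[:, (k + 2) % 3]  # vertex opposite edge ij
        e1 = v[i] - v[o]
        e2 = v[j] - v[o]
        cos = np.einsum("ij,ij->i", e1, e2)
        sin = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = cos / np.maximum(sin, 1e-12)
        w = 0.5 * cot
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([-w, -w])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    L = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    L = L - sparse.diags(np.asarray(L.sum(axis=1)).ravel())
    return L.tocsr()


@dataclass
class HarmonicField:
    """Per-vertex scalar in [0, 1]: 1 on the inlet loop, 0 on the outlet loop."""

    surface: TriSurface
    values: np.ndarray
    inlet_loop: int
    outlet_loop: int

    @property
    def inlet_centroid(self) -> np.ndarray:
        return self.surface.loop_centroid(self.inlet_loop)

    @property
    def outlet_centroid(self) -> np.ndarray:
        return self.surface.loop_centroid(self.outlet_loop)


def solve_harmonic(surface: TriSurface, inlet_seed: Landmark,
                   outlet_seed: Landmark) -> HarmonicField:
    """Solve the Laplace problem with inlet = 1 and outlet = 0.

    The inlet (outlet) boundary loop is the one whose centroid is nearest the
    inlet (outlet) seed point; the two must be distinct loops.
    """
    loops = surface.boundary_loops
    if len(loops) < 2:
        raise ValueError(
            f"not an open tube: surface has {len(loops)} boundary loops (need >= 2)")
    centroids = np.array([surface.loop_centroid(i) for i in range(len(loops))])
    inlet = int(np.argmin(np.linalg.norm(centroids - inlet_seed.position, axis=1)))
    outlet = int(np.argmin(np.linalg.norm(centroids - outlet_seed.position, axis=1)))
    if inlet == outlet:
        raise ValueError("inlet and outlet seeds select the same boundary loop")

    n = len(surface.vertices)
    values = np.zeros(n)
    fixed = np.zeros(n, dtype=bool)
    values[loops[inlet]] = 1.0
    fixed[loops[inlet]] = True
    fixed[loops[outlet]] = True
    # any additional boundary loops are left free (natural/Neumann)

    L = cotangent_laplacian(surface)
    free = ~fixed
    A = L[free][:, free]
    rhs = -L[free][:, fixed] @ values[fixed]
    values[free] = spsolve(A.tocsc(), rhs)

    residual = np.linalg.norm(L[free] @ values)
    if residual > 1e-8 * max(1.0, np.linalg.norm(values)):
        log.warning("harmonic solve residual %.3e above tolerance", residual)
    return HarmonicField(surface=surface, values=values,
                         inlet_loop=inlet, outlet_loop=outlet)


@dataclass
class IsolineSet:
    """Closed level-set contours of a harmonic field, at decreasing levels."""

    levels: np.ndarray
    contours: list[np.ndarray]  # one (k_i, 3) closed polyline per level

    def __len__(self) -> int:
        return len(self.levels)

    def centroids(self) -> np.ndarray:
        return np.array([polyline_centroid(c, closed=True) for c in self.contours])


def extract_isolines(field: HarmonicField, n_levels: int = 100) -> IsolineSet:
    """Extract ``n_levels`` equidistant closed contours of the field.

    Levels are ``k / (n_levels + 1)`` for ``k = n_levels .. 1`` (decreasing,
    i.e. ordered from the inlet toward the outlet).  Contour points are
    linear interpolations on the mesh edges crossing each level, chained
    face-to-face into a closed polyline; if a level yields several closed
    components (non-tubular bulge) the longest one is kept with a warning.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    levels = np.array([k / (n_levels + 1.0) for k in range(n_levels, 0, -1)])
    contours = [_contour_at_level(field, lv) for lv in levels]
    return IsolineSet(levels=levels, contours=contours)


def _contour_at_level(field: HarmonicField, level: float) -> np.ndarray:
    vals = field.values
    if np.any(np.abs(vals - level) < 1e-12):
        level = level + 1e-12  # deterministic tie-break off vertex values
    v = field.surface.vertices
    f = field.surface.faces

    side = vals > level
    fs = side[f]
    crossing = (fs.sum(axis=1) % 3) != 0  # 1 or 2 vertices above
    faces = f[crossing]
    if len(faces) == 0:
        raise ValueError(f"no contour found at level {level}")

    # for each crossing face, its two crossed edges (keyed by sorted pair)
    seg_pts = {}

    def edge_point(a, b):
        key = (a, b) if a < b else (b, a)
        if key not in seg_pts:
            t = (level - vals[a]) / (vals[b] - vals[a])
            seg_pts[key] = v[a] + t * (v[b] - v[a])
        return key

    face_edges = []
    for tri in faces:
        keys = []
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            if side[a] != side[b]:
                keys.append(edge_point(int(a), int(b)))
        if len(keys) != 2:  # pragma: no cover - excluded by the parity test
            raise ValueError(f"degenerate crossing at level {level}")
        face_edges.append(tuple(keys))

    # chain faces: edge-key -> incident faces
    from collections import defaultdict
    incident = defaultdict(list)
    for fi, (k1, k2) in enumerate(face_edges):
        incident[k1].append(fi)
        incident[k2].append(fi)

    unvisited = set(range(len(face_edges)))
    components = []
    while unvisited:
        start = min(unvisited)
        order = [face_edges[start][0]]
        fi = start
        while True:
            unvisited.discard(fi)
            k1, k2 = face_edges[fi]
            nxt_key = k2 if order[-1] == k1 else k1
            if nxt_key == order[0]:
                break  # closed the loop
            order.append(nxt_key)
            nbrs = [g for g in incident[nxt_key] if g != fi]
            if not nbrs or nbrs[0] not in unvisited:
                raise ValueError(
                    f"open contour at level {level}: chaining failed")
            fi = nbrs[0]
        components.append(np.array([seg_pts[k] for k in order]))

    if len(components) > 1:
        log.warning("level %.4f has %d contour components; keeping longest",
                    level, len(components))
        components.sort(key=_closed_length, reverse=True)
    return components[0]


def _closed_length(points: np.ndarray) -> float:
    d = np.diff(np.vstack([points, points[:1]]), axis=0)
    return float(np.linalg.norm(d, axis=1).sum())


def contour_perimeter(points: np.ndarray) -> float:
    """Perimeter of a closed contour polyline."""
    return _closed_length(points)
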