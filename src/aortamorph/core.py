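"""Core geometric domain types and ingestion.

Everything downstream works on two containers: :class:`TriSurface`, a cleaned
triangle mesh in world millimetres with explicit boundary-loop bookkeeping,
and :class:`LabelVolume`, an integer segmentation grid with a voxel-to-world
affine.  Surfaces come either from mesh files (STL/PLY/OBJ/VTP) or from a
label volume via marching cubes followed by volume-preserving Taubin
smoothing.  The separating surface between two labelled structures (e.g. the
left ventricle and left atrium, where the mitral valve sits) is extracted as
an :class:`InterfaceSurface` whose area-weighted centroid anchors the cardiac
axes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh

from . import vtp

log = logging.getLogger(__name__)

__all__ = [
    "MeshValidationError",
    "TriSurface",
    "LabelVolume",
    "Landmark",
    "InterfaceSurface",
    "load_surface",
    "save_surface",
    "mask_to_surface",
    "interface_surface",
    "clip_with_plane",
    "load_landmarks",
    "save_landmarks",
]

#: vertices closer than this (mm) are merged on ingestion
MERGE_TOLERANCE = 1e-6


class MeshValidationError(ValueError):
    """Raised when a mesh violates the manifold / topology contract."""


def _merge_duplicate_vertices(vertices: np.ndarray, faces: np.ndarray,
                              tol: float = MERGE_TOLERANCE):
    """Merge vertices closer than ``tol`` (grid snapping), remap faces."""
    keys = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True,
                                  return_inverse=True)
    return vertices[first], inverse[faces]


def _drop_degenerate_faces(vertices: np.ndarray, faces: np.ndarray):
    """Remove faces with repeated indices or (numerically) zero area."""
    distinct = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    faces = faces[distinct]
    v = vertices[faces]
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    area2 = np.linalg.norm(cross, axis=1)
    return faces[area2 > 1e-12]


def _boundary_loops(faces: np.ndarray, n_vertices: int) -> list[np.ndarray]:
    """Ordered closed vertex cycles of the open (count-1) edges.

    Uses the winding of the single face adjacent to each boundary edge, so
    loops inherit a consistent orientation.
    """
    directed = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]],
                               faces[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    _, inv, counts = np.unique(und, axis=0, return_inverse=True,
                               return_counts=True)
    boundary = directed[counts[inv] == 1]
    if len(boundary) == 0:
        return []
    nxt: dict[int, int] = {}
    for u, v in boundary:
        if u in nxt:
            raise MeshValidationError(
                f"non-manifold boundary vertex {u}: two outgoing boundary edges"
            )
        nxt[int(u)] = int(v)
    loops = []
    remaining = set(nxt)
    while remaining:
        start = min(remaining)
        loop = [start]
        cur = nxt[start]
        remaining.discard(start)
        while cur != start:
            loop.append(cur)
            remaining.discard(cur)
            cur = nxt[cur]
        loops.append(np.asarray(loop, dtype=np.int64))
    return loops


@dataclass
class TriSurface:
    """Triangle mesh in world millimetres.

    Attributes
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Ordered vertex-index triples; consistent winding is assumed.
    boundary_loops : list of int arrays
        Ordered closed vertex cycles of the boundary edges.  A closed surface
        has zero loops; an open tube has (at least) two.
    """

    vertices: np.ndarray
    faces: np.ndarray
    boundary_loops: list[np.ndarray] = field(default_factory=list)

    @classmethod
    def from_arrays(cls, vertices, faces, clean: bool = True,
                    validate_manifold: bool = True) -> "TriSurface":
        vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        faces = np.ascontiguousarray(faces, dtype=np.int64)
        if faces.size and faces.max() >= len(vertices):
            raise MeshValidationError("face index out of range")
        if clean:
            vertices, faces = _merge_duplicate_vertices(vertices, faces)
            faces = _drop_degenerate_faces(vertices, faces)
            # drop unreferenced vertices
            used = np.unique(faces)
            remap = -np.ones(len(vertices), dtype=np.int64)
            remap[used] = np.arange(len(used))
            vertices, faces = vertices[used], remap[faces]
        if validate_manifold:
            loops = cls._validated_loops(vertices, faces)
        else:
            try:
                loops = _boundary_loops(faces, len(vertices))
            except MeshValidationError:
                loops = []
        return cls(vertices=vertices, faces=faces, boundary_loops=loops)

    @staticmethod
    def _validated_loops(vertices, faces):
        und = np.sort(np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]],
                                      faces[:, [2, 0]]]), axis=1)
        edges, counts = np.unique(und, axis=0, return_counts=True)
        bad = edges[counts > 2]
        if len(bad):
            raise MeshValidationError(
                f"{len(bad)} non-manifold edges (shared by >2 faces), "
                f"e.g. {bad[:5].tolist()}"
            )
        return _boundary_loops(faces, len(vertices))

    # -- geometry ---------------------------------------------------------
    @property
    def face_areas(self) -> np.ndarray:
        v = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)

    @property
    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas.sum())

    @property
    def area_centroid(self) -> np.ndarray:
        """Area-weighted mean of triangle centroids."""
        a = self.face_areas
        return (self.face_centroids * a[:, None]).sum(axis=0) / a.sum()

    @property
    def is_closed(self) -> bool:
        return len(self.boundary_loops) == 0

    def enclosed_volume(self) -> float:
        """Signed volume by divergence theorem (meaningful for closed meshes)."""
        v = self.vertices[self.faces]
        return float(np.einsum("ij,ij->", v[:, 0],
                               np.cross(v[:, 1], v[:, 2])) / 6.0)

    def loop_points(self, loop_index: int) -> np.ndarray:
        return self.vertices[self.boundary_loops[loop_index]]

    def loop_centroid(self, loop_index: int) -> np.ndarray:
        """Arc-length-weighted centroid of a boundary loop polyline."""
        return polyline_centroid(self.loop_points(loop_index), closed=True)

    def transformed(self, matrix: np.ndarray) -> "TriSurface":
        """Apply a 4x4 homogeneous transform (no re-cleaning)."""
        matrix = np.asarray(matrix, dtype=np.float64)
        v = self.vertices @ matrix[:3, :3].T + matrix[:3, 3]
        return TriSurface(vertices=v, faces=self.faces.copy(),
                          boundary_loops=[l.copy() for l in self.boundary_loops])

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)


def polyline_centroid(points: np.ndarray, closed: bool = False) -> np.ndarray:
    """Arc-length-weighted centroid of a polyline (robust to uneven sampling)."""
    pts = np.asarray(points, dtype=np.float64)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = pts[1:] - pts[:-1]
    w = np.linalg.norm(seg, axis=1)
    if w.sum() < 1e-12:
        return pts.mean(axis=0)
    mid = 0.5 * (pts[1:] + pts[:-1])
    return (mid * w[:, None]).sum(axis=0) / w.sum()


@dataclass
class LabelVolume:
    """Integer segmentation grid with voxel-index -> world-mm affine."""

    voxels: np.ndarray
    affine: np.ndarray
    label_map: dict[str, int]

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    def mask(self, label: str) -> np.ndarray:
        if label not in self.label_map:
            raise KeyError(f"unknown label {label!r}; have {sorted(self.label_map)}")
        return self.voxels == self.label_map[label]

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=np.float64)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def to_nifti(self, path) -> None:
        path = Path(path)
        img = nib.Nifti1Image(self.voxels.astype(np.int16), self.affine)
        nib.save(img, path)
        sidecar = path.with_name(path.name.split(".")[0] + ".labels.json")
        sidecar.write_text(json.dumps(self.label_map, indent=2))

    @classmethod
    def from_nifti(cls, path, label_map: dict[str, int] | None = None) -> "LabelVolume":
        path = Path(path)
        img = nib.load(path)
        if label_map is None:
            sidecar = path.with_name(path.name.split(".")[0] + ".labels.json")
            if not sidecar.exists():
                raise FileNotFoundError(
                    f"no label_map given and sidecar {sidecar} not found")
            label_map = {k: int(v) for k, v in json.loads(sidecar.read_text()).items()}
        return cls(voxels=np.asanyarray(img.dataobj).astype(np.int32),
                   affine=img.affine, label_map=label_map)


@dataclass
class Landmark:
    """Named anatomical point in world mm (apex seed, inlet seed, ...)."""

    name: str
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=np.float64)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"landmark {self.name!r}: position must be finite 3D")


def load_landmarks(path) -> dict[str, Landmark]:
    data = json.loads(Path(path).read_text())
    return {name: Landmark(name, np.asarray(pos, dtype=float))
            for name, pos in data.items()}


def save_landmarks(landmarks: dict[str, Landmark], path) -> None:
    Path(path).write_text(json.dumps(
        {lm.name: [float(x) for x in lm.position] for lm in landmarks.values()},
        indent=2))


@dataclass
class InterfaceSurface:
    """Triangulated separating surface between two labelled structures."""

    parent_labels: tuple[str, str]
    patch: TriSurface
    centroid: np.ndarray

    def __post_init__(self):
        if self.patch.area <= 0:
            raise ValueError("interface patch has zero area")


# ---------------------------------------------------------------------------
# I/O

_TRIMESH_FORMATS = {"stl", "ply", "obj"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _TRIMESH_FORMATS | {"vtp"}:
        return suffix
    raise ValueError(f"cannot infer mesh format from {path.name!r}")


def load_surface(path, fmt: str | None = None, clean: bool = True) -> TriSurface:
    """Load a triangle mesh and normalise it into a :class:`TriSurface`.

    Duplicate vertices are merged at 1e-6 mm, degenerate faces dropped and
    boundary loops computed.  Raises :class:`MeshValidationError` if the
    cleaned mesh is not edge-manifold.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "vtp":
        points, polys = vtp.read_polydata(path)
        if polys is None:
            raise ValueError(f"{path}: VTP file contains no polygons")
        return TriSurface.from_arrays(points, polys, clean=clean)
    mesh = trimesh.load(str(path), file_type=fmt, force="mesh", process=False)
    return TriSurface.from_arrays(mesh.vertices, mesh.faces, clean=clean)


def save_surface(surface: TriSurface, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "vtp":
        vtp.write_polydata(path, surface.vertices, polys=surface.faces)
        return
    surface.to_trimesh().export(str(path), file_type=fmt)


# ---------------------------------------------------------------------------
# Label volume -> surface

def _taubin_smooth(vertices: np.ndarray, faces: np.ndarray,
                   iterations: int, lamb: float = 0.5,
                   mu: float = -0.53) -> np.ndarray:
    """Volume-preserving Taubin smoothing with uniform umbrella weights."""
    n = len(vertices)
    und = np.sort(np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]],
                                  faces[:, [2, 0]]]), axis=1)
    edges = np.unique(und, axis=0)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    from scipy import sparse
    adj = sparse.csr_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    v = vertices.copy()
    for _ in range(iterations):
        for factor in (lamb, mu):
            lap = adj @ v / deg[:, None] - v
            v = v + factor * lap
    return v


def mask_to_surface(vol: LabelVolume, label: str,
                    smoothing_iters: int = 10) -> TriSurface:
    """Marching-cubes isosurface of a label, in world mm, Taubin-smoothed.

    The isosurface is taken at level 0.5 of the binarised label and mapped
    through the volume affine.  Smoothing uses the volume-preserving Taubin
    filter (lambda = 0.5, mu = -0.53); for closed surfaces the enclosed
    volume changes by < 2%.  A label touching the grid border produces an
    open surface (logged as a warning).
    """
    from skimage import measure

    mask = vol.mask(label)
    if not mask.any():
        raise ValueError(f"label {label!r} is empty")
    border = (mask[0].any() or mask[-1].any() or mask[:, 0].any()
              or mask[:, -1].any() or mask[:, :, 0].any() or mask[:, :, -1].any())
    if border:
        log.warning("label %r touches the grid border; surface may be open", label)
    verts, faces, _, _ = measure.marching_cubes(mask.astype(np.float32), level=0.5)
    verts = vol.index_to_world(verts)
    if smoothing_iters > 0:
        verts = _taubin_smooth(verts, faces, smoothing_iters)
    return TriSurface.from_arrays(verts, faces)


# ---------------------------------------------------------------------------
# Interface between two labels

_FACE_OFFSETS = {  # axis -> in-plane half-step index offsets of the 4 corners
    0: np.array([[0.0, -0.5, -0.5], [0.0, 0.5, -0.5],
                 [0.0, 0.5, 0.5], [0.0, -0.5, 0.5]]),
    1: np.array([[-0.5, 0.0, -0.5], [0.5, 0.0, -0.5],
                 [0.5, 0.0, 0.5], [-0.5, 0.0, 0.5]]),
    2: np.array([[-0.5, -0.5, 0.0], [0.5, -0.5, 0.0],
                 [0.5, 0.5, 0.0], [-0.5, 0.5, 0.0]]),
}


def interface_surface(vol: LabelVolume, label_a: str, label_b: str) -> InterfaceSurface:
    """Triangulated shared boundary between two labels (6-connectivity).

    Every voxel face where ``label_a`` and ``label_b`` touch contributes a
    square (two triangles) in world coordinates; the centroid is the
    area-weighted mean of the triangle centroids.
    """
    a, b = vol.mask(label_a), vol.mask(label_b)
    if not a.any():
        raise ValueError(f"label {label_a!r} is empty")
    if not b.any():
        raise ValueError(f"label {label_b!r} is empty")
    quads = []
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
        for lo, hi in ((a, b), (b, a)):
            adj = lo[sl_lo] & hi[sl_hi]
            idx = np.argwhere(adj).astype(np.float64)
            if len(idx) == 0:
                continue
            centers = idx.copy()
            centers[:, axis] += 0.5  # face midpoint between the two voxels
            corners = centers[:, None, :] + _FACE_OFFSETS[axis][None, :, :]
            quads.append(corners.reshape(-1, 4, 3))
    if not quads:
        raise ValueError(
            f"no shared interface between {label_a!r} and {label_b!r}")
    corners = np.concatenate(quads)  # (q, 4, 3) in index space
    world = vol.index_to_world(corners.reshape(-1, 3)).reshape(-1, 4, 3)
    nq = len(world)
    vidx = np.arange(4 * nq).reshape(nq, 4)
    tris = np.concatenate([vidx[:, [0, 1, 2]], vidx[:, [0, 2, 3]]])
    patch = TriSurface.from_arrays(world.reshape(-1, 3), tris,
                                   validate_manifold=False)
    return InterfaceSurface(parent_labels=(label_a, label_b), patch=patch,
                            centroid=patch.area_centroid)


# ---------------------------------------------------------------------------
# Plane clipping (used to open capped vessel ends)

def clip_with_plane(surface: TriSurface, origin, normal) -> TriSurface:
    """Keep the faces whose centroid lies on the positive side of a plane.

    Coarse (whole-face) clipping: the cut is jagged at the triangle scale,
    which is adequate for opening a capped vessel end so the harmonic solver
    sees an inlet/outlet ring.
    """
    origin = np.asarray(origin, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    keep = (surface.face_centroids - origin) @ normal >= 0
    if not keep.any():
        raise ValueError("clip plane removes the whole surface")
    faces = surface.faces[keep]
    # jagged cuts can pinch the new boundary at single vertices; peel faces
    # incident to such bowtie vertices until the rim is manifold
    for _ in range(20):
        bow = _bowtie_boundary_vertices(faces)
        if len(bow) == 0:
            break
        faces = faces[~np.isin(faces, bow).any(axis=1)]
        if len(faces) == 0:
            raise ValueError("clip plane left no manifold surface")
    return TriSurface.from_arrays(surface.vertices, faces)


def _bowtie_boundary_vertices(faces: np.ndarray) -> np.ndarray:
    """Vertices with more than two incident boundary edges."""
    und = np.sort(np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]],
                                  faces[:, [2, 0]]]), axis=1)
    edges, counts = np.unique(und, axis=0, return_counts=True)
    boundary = edges[counts == 1]
    if len(boundary) == 0:
        return np.empty(0, dtype=np.int64)
    verts, deg = np.unique(boundary, return_counts=True)
    return verts[deg > 2]
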