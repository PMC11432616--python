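"""Vessel centerline from isoline centroids, and its geometric metrics.

The raw centerline is the sweep of isoline centroids ordered from the inlet
(level -> 1) to the outlet (level -> 0), with the inlet and outlet ring
centroids prepended/appended.  It is smoothed with a local-quadratic
(Savitzky-Golay) filter over an arc-length window and resampled at a uniform
step.  Per-point
cross-section areas come from intersecting the wall with the plane orthogonal
to the local tangent; an equivalent circular diameter is derived as
``D = 2 * sqrt(A / pi)``.  The tortuosity of a segment is ``T = L / D - 1``
with L the centerline arc length and D the straight-line endpoint distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon

from .core import TriSurface
from .harmonic import HarmonicField, IsolineSet

log = logging.getLogger(__name__)

__all__ = ["Centerline", "SegmentMetrics", "compute_centerline",
           "cross_section_areas", "equivalent_diameter", "segment_metrics"]


@dataclass
class Centerline:
    """Ordered polyline (inlet end first) with arc length and section areas."""

    points: np.ndarray                      # (n, 3) mm
    arc_length: np.ndarray                  # (n,) cumulative, arc_length[0] = 0
    cross_section_area: np.ndarray | None = None   # (n,) mm^2, NaN = missing

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Linear interpolation of the polyline at arc length ``s``."""
        s = float(np.clip(s, 0.0, self.total_length))
        return np.array([np.interp(s, self.arc_length, self.points[:, k])
                         for k in range(3)])

    def tangents(self) -> np.ndarray:
        """Unit tangents by central differences (one-sided at the ends)."""
        t = np.gradient(self.points, self.arc_length, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)


@dataclass
class SegmentMetrics:
    """Length, endpoint distance, tortuosity and mean diameter of a segment.

    The source material uses the symbol D both for the endpoint distance in
    the tortuosity index and for the vessel diameter; the two are kept as
    separate fields here.
    """

    length_L: float
    endpoint_distance_D: float
    tortuosity_T: float
    mean_diameter: float

    def as_dict(self) -> dict:
        return {
            "centerline_length_mm": self.length_L,
            "endpoint_distance_mm": self.endpoint_distance_D,
            "tortuosity": self.tortuosity_T,
            "mean_diameter_mm": self.mean_diameter,
        }


def _cumulative_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _smooth_polyline(points: np.ndarray, s: np.ndarray, window: float,
                     step: float) -> np.ndarray:
    """Local-quadratic (Savitzky-Golay) smoothing over an arc-length window.

    The polyline is first resampled uniformly at ``step`` so the filter
    window corresponds to a fixed arc length.  A local quadratic fit keeps
    circular arcs to second order, so — unlike a plain moving average — it
    does not contract curved centerlines by O((window / bend radius)^2),
    which would bias tortuosity on typical aortic curvature radii.
    """
    from scipy.signal import savgol_filter

    uniform, _ = _resample(points, s, step)
    if window <= 0 or len(uniform) < 5:
        return uniform
    wlen = int(round(window / step))
    wlen = max(5, wlen + 1 - wlen % 2)  # odd, at least 5 samples
    if wlen >= len(uniform):
        wlen = len(uniform) - 1 - (len(uniform) % 2)
        if wlen < 5:
            return uniform
    return savgol_filter(uniform, wlen, polyorder=2, axis=0, mode="interp")


def _resample(points: np.ndarray, s: np.ndarray, step: float):
    """Sample a polyline at uniform arc-length steps along the curve.

    Returns the sampled points and their positions *along the source
    polyline* — the natural arc-length coordinate of the resampled curve.
    """
    total = s[-1]
    n = max(int(np.floor(total / step)), 1)
    targets = np.arange(n + 1) * step
    if total - targets[-1] > 1e-9:
        targets = np.append(targets, total)  # keep the true endpoint
    pts = np.column_stack([np.interp(targets, s, points[:, k])
                           for k in range(3)])
    return pts, targets


def compute_centerline(field: HarmonicField, isolines: IsolineSet,
                       smooth_window: float = 10.0,
                       resample_step: float = 0.5) -> Centerline:
    """Isoline-centroid centerline, smoothed and uniformly resampled.

    Parameters
    ----------
    smooth_window : float
        Width (mm, in arc length) of the local-quadratic smoothing filter.
    resample_step : float
        Uniform spacing (mm) of the output polyline.
    """
    if len(isolines) < 2:
        raise ValueError("need at least 2 isolines to build a centerline")
    if resample_step <= 0:
        raise ValueError("resample_step must be positive")
    raw = np.vstack([field.inlet_centroid,
                     isolines.centroids(),
                     field.outlet_centroid])
    s = _cumulative_arclength(raw)
    smoothed = _smooth_polyline(raw, s, smooth_window, resample_step)
    s2 = _cumulative_arclength(smoothed)
    pts, arc = _resample(smoothed, s2, resample_step)
    return Centerline(points=pts, arc_length=arc)


# ---------------------------------------------------------------------------
# Cross sections

def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    return u, np.cross(normal, u)


def _chain_segments(segments: np.ndarray) -> list[np.ndarray]:
    """Chain (k, 2, 3) plane-intersection segments into closed polylines."""
    def key(p):
        return tuple(np.round(p, 7))

    from collections import defaultdict
    adj = defaultdict(list)
    for a, b in segments:
        adj[key(a)].append(tuple(b))
        adj[key(b)].append(tuple(a))
    visited = set()
    loops = []
    for start_key in list(adj):
        if start_key in visited or len(adj[start_key]) != 2:
            continue
        loop = [np.array(start_key)]
        visited.add(start_key)
        cur = adj[start_key][0]
        closed = False
        while True:
            k = key(cur)
            if k == start_key:
                closed = True
                break
            if k in visited or len(adj[k]) != 2:
                break
            visited.add(k)
            loop.append(np.asarray(cur))
            nbrs = [n for n in adj[k] if key(np.asarray(n)) != key(loop[-2])]
            if not nbrs:
                break
            cur = nbrs[0]
        if closed and len(loop) >= 3:
            loops.append(np.asarray(loop))
    return loops


def cross_section_areas(centerline: Centerline, surface: TriSurface) -> Centerline:
    """Fill per-point cross-section areas by plane/wall intersection.

    At each centerline point the wall is cut by the plane orthogonal to the
    local tangent; among the closed intersection loops, the one enclosing the
    centerline point (planar winding test) is kept and its polygon area
    recorded.  Points with no enclosing closed loop get NaN and a log entry.
    """
    import trimesh

    mesh = surface.to_trimesh()
    tangents = centerline.tangents()
    areas = np.full(len(centerline.points), np.nan)
    for i, (p, t) in enumerate(zip(centerline.points, tangents)):
        segs = trimesh.intersections.mesh_plane(mesh, plane_normal=t,
                                                plane_origin=p)
        if len(segs) == 0:
            continue
        u, w = _plane_basis(t)
        for loop in _chain_segments(np.asarray(segs)):
            xy = np.column_stack([(loop - p) @ u, (loop - p) @ w])
            poly = Polygon(xy)
            if poly.is_valid and poly.contains(Point(0.0, 0.0)):
                areas[i] = poly.area
                break
        if np.isnan(areas[i]):
            log.info("no enclosing section loop at s=%.2f mm",
                     centerline.arc_length[i])
    out = Centerline(points=centerline.points, arc_length=centerline.arc_length,
                     cross_section_area=areas)
    return out


def equivalent_diameter(area) -> np.ndarray | float:
    """Diameter of the circle with the given area: ``2 * sqrt(A / pi)``."""
    arr = np.asarray(area, dtype=float)
    if np.any(arr[np.isfinite(arr)] <= 0):
        raise ValueError("area must be positive")
    out = 2.0 * np.sqrt(arr / np.pi)
    return float(out) if out.ndim == 0 else out


def segment_metrics(centerline: Centerline, s_start: float,
                    s_end: float) -> SegmentMetrics:
    """Length, endpoint distance, tortuosity and mean diameter over [s_start, s_end]."""
    if not (0.0 <= s_start < s_end <= centerline.total_length + 1e-9):
        raise ValueError(
            f"invalid segment [{s_start}, {s_end}] on centerline of length "
            f"{centerline.total_length:.2f}")
    p0 = centerline.point_at(s_start)
    p1 = centerline.point_at(s_end)
    L = s_end - s_start
    D = float(np.linalg.norm(p1 - p0))
    if D < 1e-9:
        raise ValueError("segment endpoints coincide (D = 0)")
    mean_d = float("nan")
    if centerline.cross_section_area is not None:
        sel = (centerline.arc_length >= s_start - 1e-9) & \
              (centerline.arc_length <= s_end + 1e-9)
        areas = centerline.cross_section_area[sel]
        areas = areas[np.isfinite(areas)]
        if len(areas):
            mean_d = float(np.mean(equivalent_diameter(areas)))
    return SegmentMetrics(length_L=L, endpoint_distance_D=D,
                          tortuosity_T=L / D - 1.0, mean_diameter=mean_d)
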