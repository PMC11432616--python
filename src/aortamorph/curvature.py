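"""Outer and inner curvature-line lengths of a bent vessel segment.

Each harmonic isoline is resampled to a fixed number of equally spaced
candidate nodes and the contours are put into angular correspondence (loops
oriented consistently, starting offsets aligned layer to layer).  Connecting
corresponding nodes across the contour stack yields one wall-following
polyline per angular position; the longest of these is the outer curvature
line, the shortest the inner one.  On a circular bend of radius R and tube
radius r spanning an angle theta, these converge to (R + r) * theta and
(R - r) * theta.

An unconstrained maximum-cost path over complete layer-to-layer bipartite
graphs is deliberately avoided: such a path zigzags across the lumen to
accumulate length and does not measure the wall curvature at all.  The
correspondence construction keeps both extremal paths geometrically on the
wall while remaining deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .harmonic import HarmonicField, IsolineSet

__all__ = ["CurvaturePath", "PathKind", "extremal_paths", "path_length",
           "resample_closed"]


class PathKind(str, Enum):
    OUTER = "outer"
    INNER = "inner"


@dataclass
class CurvaturePath:
    """Wall-following polyline with one point per contour layer."""

    kind: PathKind
    points: np.ndarray  # (layers, 3)
    length: float


def path_length(points: np.ndarray) -> float:
    """Sum of consecutive Euclidean distances along an open polyline."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("polyline needs at least 2 points")
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def resample_closed(points: np.ndarray, n: int,
                    phase: float = 0.0) -> np.ndarray:
    """Resample a closed polyline to ``n`` equally spaced points.

    ``phase`` (in fractions of the perimeter) shifts where sampling starts,
    which lets consecutive contours be put into *continuous* angular
    correspondence rather than being limited to whole-sample shifts.
    """
    pts = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < 1e-12:
        raise ValueError("degenerate (zero-length) contour")
    targets = ((np.arange(n) / n + phase) % 1.0) * total
    return np.column_stack([np.interp(targets, s, pts[:, k]) for k in range(3)])


def _newell_normal(points: np.ndarray) -> np.ndarray:
    pts = np.vstack([points, points[:1]])
    a, b = pts[:-1], pts[1:]
    n = np.array([
        np.sum((a[:, 1] - b[:, 1]) * (a[:, 2] + b[:, 2])),
        np.sum((a[:, 2] - b[:, 2]) * (a[:, 0] + b[:, 0])),
        np.sum((a[:, 0] - b[:, 0]) * (a[:, 1] + b[:, 1])),
    ])
    norm = np.linalg.norm(n)
    return n / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])


def _align_to_previous(prev: np.ndarray, ring: np.ndarray, n: int) -> np.ndarray:
    """Resample ``ring`` with the phase minimising distance to ``prev``.

    A coarse discrete scan over whole-sample shifts is refined by a bounded
    continuous search; without the sub-sample refinement the rounding
    residual accumulates across the contour stack into a systematic twist.
    """
    from scipy.optimize import minimize_scalar

    def cost(phase: float) -> float:
        return float(np.sum((resample_closed(ring, n, phase) - prev) ** 2))

    shifts = np.arange(n) / n
    coarse = [cost(p) for p in shifts]
    best = shifts[int(np.argmin(coarse))]
    res = minimize_scalar(cost, bounds=(best - 1.0 / n, best + 1.0 / n),
                          method="bounded", options={"xatol": 1e-6})
    return resample_closed(ring, n, float(res.x))


def correspondence_stack(isolines: IsolineSet, field: HarmonicField,
                         samples_per_contour: int = 64) -> np.ndarray:
    """(layers, samples, 3) node array with consistent angular correspondence.

    Layer 0 is the inlet boundary ring, the last layer the outlet ring; in
    between sit the isoline contours ordered by decreasing level.  All loops
    are oriented with a consistent winding (Newell normal aligned with the
    local travel direction) before the start-offset alignment.
    """
    if len(isolines) < 2:
        raise ValueError("need at least 2 isolines")
    if samples_per_contour < 8:
        raise ValueError("samples_per_contour must be >= 8")
    for lv, c in zip(isolines.levels, isolines.contours):
        if len(c) == 0:
            raise ValueError(f"empty contour at level {lv}")

    surface = field.surface
    rings = [surface.loop_points(field.inlet_loop)]
    rings += list(isolines.contours)
    rings.append(surface.loop_points(field.outlet_loop))
    from .core import polyline_centroid
    centroids = np.array([polyline_centroid(r, closed=True) for r in rings])

    layers = []
    for i, ring in enumerate(rings):
        # orient the loop winding consistently with the travel direction
        lo, hi = max(i - 1, 0), min(i + 1, len(rings) - 1)
        direction = centroids[hi] - centroids[lo]
        if _newell_normal(ring) @ direction < 0:
            ring = ring[::-1]
        if layers:
            res = _align_to_previous(layers[-1], ring, samples_per_contour)
        else:
            res = resample_closed(ring, samples_per_contour)
        layers.append(res)
    return np.asarray(layers)


def extremal_paths(isolines: IsolineSet, field: HarmonicField,
                   samples_per_contour: int = 64) -> tuple[CurvaturePath, CurvaturePath]:
    """Outer (maximum-length) and inner (minimum-length) curvature lines.

    Returns ``(outer, inner)``.  Ties in total length are broken by the
    smallest angular index, so the result is deterministic.
    """
    stack = correspondence_stack(isolines, field, samples_per_contour)
    seg = np.linalg.norm(np.diff(stack, axis=0), axis=2)  # (layers-1, samples)
    lengths = seg.sum(axis=0)
    j_out = int(np.argmax(lengths))
    j_in = int(np.argmin(lengths))
    outer = CurvaturePath(PathKind.OUTER, stack[:, j_out, :],
                          float(lengths[j_out]))
    inner = CurvaturePath(PathKind.INNER, stack[:, j_in, :],
                          float(lengths[j_in]))
    return outer, inner
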