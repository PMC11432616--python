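"""Aortic and left-ventricular axes, the aorto-septal angle (AoSA) and the
ascending-aorta inclination (AAI).

The aortic axis runs from the centroid of the left-ventricular outflow tract
(LVOT) interface to the first centerline point at the sinotubular junction.
The ventricular axis runs from the apex landmark to the centroid of the
mitral interface (the separating surface between left ventricle and left
atrium).  The AoSA is the angle between the two directions after projection
onto a measurement plane; with the default automatic plane (the plane spanned
by the two directions) the projection is exact and the AoSA equals the direct
3-D angle.  The AAI is the mean angle, over the first ``window_mm`` of
centerline arc length, between chords from the centerline origin and the
aortic axis.

Repeatability of the semi-automatic protocol is emulated by re-running the
angle measurement with the manually placed apex seed perturbed by a seeded
isotropic jitter, mirroring an observer repeating the selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .centerline import Centerline
from .core import InterfaceSurface, Landmark, TriSurface

__all__ = ["Axis", "AxisPair", "InclinationResult", "aortic_axis",
           "ventricular_axis", "aosa", "ascending_inclination",
           "repeat_measurement", "apex_fallback"]


@dataclass
class Axis:
    """Oriented line: origin plus unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("axis direction is degenerate (zero length)")
        self.direction = d / n


@dataclass
class AxisPair:
    """The two cardiac axes, the projection plane and the resulting angle."""

    aortic_axis: Axis
    ventricular_axis: Axis
    plane_normal: np.ndarray | None
    aosa_deg: float


@dataclass
class InclinationResult:
    """Mean +/- SD chord angle to the aortic axis over an arc-length window."""

    aai_deg: float
    aai_sd_deg: float
    window_mm: float


def aortic_axis(centerline: Centerline, lvot_interface: InterfaceSurface) -> Axis:
    """Axis from the LVOT interface centroid to the first centerline point.

    The first centerline point sits at the sinotubular junction end of the
    vessel, so the direction points out of the ventricle into the aorta.
    """
    stj = centerline.points[0]
    origin = lvot_interface.centroid
    if np.linalg.norm(stj - origin) < 1e-9:
        raise ValueError("sinotubular junction coincides with the LVOT centroid")
    return Axis(origin=origin, direction=stj - origin)


def ventricular_axis(apex: Landmark, mitral_interface: InterfaceSurface) -> Axis:
    """Axis from the apex landmark to the mitral interface centroid."""
    target = mitral_interface.centroid
    if np.linalg.norm(target - apex.position) < 1e-9:
        raise ValueError("apex coincides with the mitral interface centroid")
    return Axis(origin=apex.position, direction=target - apex.position)


def apex_fallback(lv_surface: TriSurface,
                  mitral_interface: InterfaceSurface) -> Landmark:
    """Automatic apex seed: the LV vertex farthest from the mitral centroid.

    The left ventricle is elongated, so the farthest-point rule lands at the
    apical pole; it replaces the manual apex click when no landmark is given.
    """
    d = np.linalg.norm(lv_surface.vertices - mitral_interface.centroid, axis=1)
    return Landmark("apex_seed", lv_surface.vertices[int(np.argmax(d))])


def _project(direction: np.ndarray, normal: np.ndarray) -> np.ndarray:
    proj = direction - (direction @ normal) * normal
    n = np.linalg.norm(proj)
    if n < 1e-9:
        raise ValueError("axis degenerate in plane (parallel to plane normal)")
    return proj / n


def aosa(aortic: Axis, ventricular: Axis,
         plane_normal: np.ndarray | None = None) -> AxisPair:
    """Aorto-septal angle between the two axis directions, in degrees.

    Both directions are projected onto the plane orthogonal to
    ``plane_normal`` and the angle is ``arccos`` of their dot product.  With
    ``plane_normal=None`` (automatic) the plane is the one spanned by the two
    directions, so the projection is lossless and the result equals the
    direct 3-D angle.  Angles are reported in [0, 180] degrees without
    supplementary-angle folding (the anatomical AoSA is obtuse).
    """
    d1, d2 = aortic.direction, ventricular.direction
    if plane_normal is None:
        cross = np.cross(d1, d2)
        n = np.linalg.norm(cross)
        if n < 1e-12:
            # parallel axes: plane undefined, angle is 0 or 180 exactly
            angle = 0.0 if d1 @ d2 > 0 else 180.0
            return AxisPair(aortic, ventricular, None, angle)
        normal = cross / n
    else:
        normal = np.asarray(plane_normal, dtype=float)
        nn = np.linalg.norm(normal)
        if abs(nn - 1.0) > 1e-6:
            raise ValueError("plane_normal must be a unit vector")
        normal = normal / nn
    p1 = _project(d1, normal)
    p2 = _project(d2, normal)
    angle = float(np.degrees(np.arccos(np.clip(p1 @ p2, -1.0, 1.0))))
    return AxisPair(aortic, ventricular, normal, angle)


def ascending_inclination(centerline: Centerline, aortic: Axis,
                          window_mm: float = 20.0) -> InclinationResult:
    """Inclination of the first ``window_mm`` of vessel relative to the axis.

    For every resampled centerline point with ``0 < s <= window_mm`` the
    chord direction from the centerline origin is compared with the aortic
    axis; the mean and SD of those angles (degrees) are returned.
    """
    if window_mm <= 0:
        raise ValueError("window_mm must be positive")
    if centerline.total_length < window_mm:
        raise ValueError(
            f"centerline ({centerline.total_length:.1f} mm) shorter than the "
            f"{window_mm:.1f} mm window")
    sel = (centerline.arc_length > 0) & (centerline.arc_length <= window_mm + 1e-9)
    chords = centerline.points[sel] - centerline.points[0]
    chords /= np.linalg.norm(chords, axis=1, keepdims=True)
    angles = np.degrees(np.arccos(np.clip(chords @ aortic.direction, -1.0, 1.0)))
    return InclinationResult(aai_deg=float(np.mean(angles)),
                             aai_sd_deg=float(np.std(angles, ddof=1))
                             if len(angles) > 1 else 0.0,
                             window_mm=float(window_mm))


def repeat_measurement(protocol: Callable[[Landmark], float],
                       apex: Landmark, n_repeats: int = 5,
                       jitter_mm: float = 2.0, seed: int = 0) -> list[float]:
    """Repeat an angle measurement with a jittered apex seed.

    ``protocol`` maps an apex landmark to an angle (degrees); it is called
    ``n_repeats`` times with the apex position perturbed by isotropic
    Gaussian jitter of SD ``jitter_mm``.  The jitter stream is seeded, so the
    emulated five manual repeats of the measurement are reproducible.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_repeats):
        offset = rng.normal(0.0, jitter_mm, size=3) if jitter_mm > 0 else np.zeros(3)
        jittered = Landmark(apex.name, apex.position + offset)
        values.append(float(protocol(jittered)))
    return values
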