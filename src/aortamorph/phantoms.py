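"""Synthetic aorta-tube and two-chamber heart phantoms with closed-form truth.

The tube phantom sweeps a circular cross-section of radius ``r`` along a
planar centerline made of straight runs and circular arcs (bend radius ``R``,
angle ``theta``, all bending the same way in one plane).  Every quantity the
measurement pipeline reports then has a closed form:

* centerline length  ``L = sum(straight) + sum(R * theta)``
* tortuosity         ``T = L / |end - start| - 1``
* equivalent diameter ``2 r``
* outer curvature line ``sum(straight) + sum((R + r) * theta)``
* inner curvature line ``sum(straight) + sum((R - r) * theta)``

The heart phantom couples a prolate-ellipsoid left ventricle (apex at the
lower pole), a spherical left atrium abutting the base (their overlap region
defines the mitral interface on the chamber axis) and a straight aortic tube
anchored on the ventricular axis, tilted so the constructed aortic/ventricular
axis angle equals ``aosa_deg_true`` exactly.  It can also be voxelised into a
:class:`~aortamorph.core.LabelVolume` to exercise the mask -> surface ->
interface path end to end.

All constructions are deterministic: the same spec (and seed) reproduces
bit-identical meshes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .core import InterfaceSurface, LabelVolume, Landmark, TriSurface

__all__ = ["Straight", "Arc", "TubePhantomSpec", "HeartPhantomSpec",
           "PhantomTruth", "HeartPhantom", "make_tube", "make_heart"]

_Y = np.array([0.0, 1.0, 0.0])  # binormal of the centerline plane (x-z)


@dataclass(frozen=True)
class Straight:
    """Straight centerline run of a given length (mm)."""

    length: float

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("straight segment length must be positive")


@dataclass(frozen=True)
class Arc:
    """Planar circular bend: radius ``bend_radius`` (mm) over ``angle_rad``."""

    bend_radius: float
    angle_rad: float

    def __post_init__(self):
        if self.bend_radius <= 0 or not (0 < self.angle_rad < 2 * np.pi):
            raise ValueError("arc needs bend_radius > 0 and 0 < angle < 2*pi")


@dataclass(frozen=True)
class TubePhantomSpec:
    """Swept-tube phantom: piecewise straight/arc planar centerline."""

    segments: tuple
    tube_radius: float = 15.0
    mesh_step: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.tube_radius <= 0 or self.mesh_step <= 0:
            raise ValueError("tube_radius and mesh_step must be positive")
        if not self.segments:
            raise ValueError("spec needs at least one segment")
        for seg in self.segments:
            if isinstance(seg, Arc) and seg.bend_radius <= self.tube_radius:
                raise ValueError(
                    f"self-intersecting sweep: bend radius {seg.bend_radius} "
                    f"<= tube radius {self.tube_radius}")


@dataclass
class PhantomTruth:
    """Closed-form ground truth for a phantom."""

    centerline_points: np.ndarray
    total_length: float
    tortuosity: float
    diameter: float
    outer_length: float
    inner_length: float
    aosa_deg: float | None = None

    def as_dict(self) -> dict:
        return {
            "centerline_length_mm": self.total_length,
            "tortuosity": self.tortuosity,
            "diameter_mm": self.diameter,
            "outer_line_length_mm": self.outer_length,
            "inner_line_length_mm": self.inner_length,
            **({"aosa_deg": self.aosa_deg} if self.aosa_deg is not None else {}),
        }


def _centerline_stations(spec: TubePhantomSpec):
    """Sample the analytic centerline; returns points, tangents, in-plane normals."""
    p = np.zeros(3)
    t = np.array([0.0, 0.0, 1.0])
    pts, tans = [p], [t]
    for seg in spec.segments:
        if isinstance(seg, Straight):
            n_sub = max(int(np.ceil(seg.length / spec.mesh_step)), 1)
            for k in range(1, n_sub + 1):
                pts.append(p + t * seg.length * k / n_sub)
                tans.append(t)
            p = pts[-1]
        else:
            R, theta = seg.bend_radius, seg.angle_rad
            n = np.cross(_Y, t)
            center = p + R * n
            n_sub = max(int(np.ceil(R * theta / spec.mesh_step)), 2)
            for k in range(1, n_sub + 1):
                phi = theta * k / n_sub
                pts.append(center - R * n * np.cos(phi) + R * t * np.sin(phi))
                tans.append(t * np.cos(phi) + n * np.sin(phi))
            p = pts[-1]
            t = tans[-1]
    pts = np.asarray(pts)
    tans = np.asarray(tans)
    normals = np.cross(np.broadcast_to(_Y, pts.shape), tans)
    return pts, tans, normals


def _sweep(points, normals, radius, mesh_step) -> TriSurface:
    m = max(12, int(np.ceil(2 * np.pi * radius / mesh_step)))
    alphas = 2 * np.pi * np.arange(m) / m
    rings = (points[:, None, :]
             + radius * np.cos(alphas)[None, :, None] * normals[:, None, :]
             + radius * np.sin(alphas)[None, :, None] * _Y[None, None, :])
    n_rings = len(points)
    verts = rings.reshape(-1, 3)
    j = np.arange(m)
    j1 = (j + 1) % m
    tris = []
    for i in range(n_rings - 1):
        a, b = i * m, (i + 1) * m
        tris.append(np.column_stack([a + j, a + j1, b + j]))
        tris.append(np.column_stack([b + j, a + j1, b + j1]))
    return TriSurface.from_arrays(verts, np.concatenate(tris))


def make_tube(spec: TubePhantomSpec) -> tuple[TriSurface, PhantomTruth]:
    """Open swept-tube mesh plus its closed-form truth.

    The first centerline point is at the origin heading +z; the inlet is the
    *first* ring (use the truth centerline endpoints as inlet/outlet seeds).
    """
    pts, tans, normals = _centerline_stations(spec)
    surface = _sweep(pts, normals, spec.tube_radius, spec.mesh_step)
    L = outer = inner = 0.0
    for seg in spec.segments:
        if isinstance(seg, Straight):
            L += seg.length
            outer += seg.length
            inner += seg.length
        else:
            L += seg.bend_radius * seg.angle_rad
            outer += (seg.bend_radius + spec.tube_radius) * seg.angle_rad
            inner += (seg.bend_radius - spec.tube_radius) * seg.angle_rad
    D = float(np.linalg.norm(pts[-1] - pts[0]))
    truth = PhantomTruth(
        centerline_points=pts, total_length=L,
        tortuosity=L / D - 1.0, diameter=2 * spec.tube_radius,
        outer_length=outer, inner_length=inner)
    return surface, truth


# ---------------------------------------------------------------------------
# Two-chamber heart phantom

@dataclass(frozen=True)
class HeartPhantomSpec:
    """Two-chamber phantom with a prescribed aorto-septal angle.

    ``lv_semi_axes`` are (long, mid, minor) semi-axes of the left-ventricle
    ellipsoid; the long axis is the ventricular axis.  The aorta is a
    straight tube of ``aorta_radius`` anchored on the ventricular axis at
    ``anchor_frac`` of the long semi-axis above the LV centre, tilted by
    ``aosa_deg_true`` from the ventricular direction.
    """

    aosa_deg_true: float = 117.25
    lv_semi_axes: tuple[float, float, float] = (40.0, 25.0, 25.0)
    atrium_radius: float = 20.0
    aorta_radius: float = 14.0
    aorta_length: float = 75.0
    anchor_frac: float = 0.25
    mesh_step: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.aosa_deg_true < 180):
            raise ValueError("aosa_deg_true must be in (0, 180)")
        a, b, c = self.lv_semi_axes
        if min(a, b, c) <= 0 or self.atrium_radius <= 0 or self.aorta_radius <= 0:
            raise ValueError("all phantom dimensions must be positive")
        if self.aorta_radius >= min(b, c):
            raise ValueError("aorta wider than the ventricle cross-section")


@dataclass
class HeartPhantom:
    """Everything the measurement pipeline needs, plus ground truth."""

    aorta: TriSurface            # open tube, inlet ring at the STJ end
    left_ventricle: TriSurface
    left_atrium: TriSurface
    lvot_interface: InterfaceSurface
    mitral_interface: InterfaceSurface
    landmarks: dict[str, Landmark]
    truth: PhantomTruth
    volume: LabelVolume | None = None


def _disc_patch(center, normal, radius, n=64) -> TriSurface:
    """Triangulated disc (fan) used as a synthetic interface patch."""
    center = np.asarray(center, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    helper = _Y if abs(normal @ _Y) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    w = np.cross(normal, u)
    ang = 2 * np.pi * np.arange(n) / n
    rim = center + radius * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * w)
    verts = np.vstack([center, rim])
    j = np.arange(n)
    tris = np.column_stack([np.zeros(n, dtype=int), j + 1, (j + 1) % n + 1])
    return TriSurface.from_arrays(verts, tris)


def _ellipsoid_mesh(semi_axes, subdivisions=4) -> TriSurface:
    """Ellipsoid with semi-axes (x, y, z) from a subdivided icosphere."""
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = sphere.vertices * np.asarray(semi_axes)
    return TriSurface.from_arrays(v, sphere.faces)


def make_heart(spec: HeartPhantomSpec,
               voxelize: bool = False,
               voxel_mm: float = 1.0) -> HeartPhantom:
    """Build the two-chamber phantom (optionally with a label volume).

    Geometry (all in one plane of symmetry, y = 0):

    * LV ellipsoid centred at the origin, long axis +z, apex at (0,0,-a);
    * LA sphere centred on +z so it overlaps the basal pole — the mitral
      interface is the ellipsoid cap inside the sphere, centroid on the axis;
    * aortic tube anchored at ``(0, 0, anchor_frac * a)``, axis direction
      ``(sin aosa, 0, cos aosa)`` so the angle between the aortic axis
      (LVOT -> STJ) and the ventricular axis (apex -> mitral) is exact.
    """
    a_long, b_mid, c_min = spec.lv_semi_axes
    semi_xyz = np.array([b_mid, c_min, a_long])  # long axis along z
    alpha = np.radians(spec.aosa_deg_true)
    da = np.array([np.sin(alpha), 0.0, np.cos(alpha)])
    anchor = np.array([0.0, 0.0, spec.anchor_frac * a_long])

    # ventricular side
    apex = np.array([0.0, 0.0, -a_long])
    la_center = np.array([0.0, 0.0, a_long + 0.5 * spec.atrium_radius])
    # mitral interface: ellipsoid cap inside the LA sphere; its centroid is
    # on the z axis by symmetry.  Synthetic patch: disc at the cap's
    # area-weighted height (computed from the analytic cap below).
    z_cap = _cap_centroid_height(semi_xyz, la_center[2], spec.atrium_radius)
    mitral = InterfaceSurface(
        parent_labels=("left_ventricle", "left_atrium"),
        patch=_disc_patch([0, 0, z_cap], [0, 0, 1.0],
                          0.45 * min(b_mid, c_min)),
        centroid=np.array([0.0, 0.0, z_cap]))

    # aortic side: tube from just outside the LV out to the STJ
    t_exit = _ray_exit_ellipsoid(anchor, da, semi_xyz)
    t_start = t_exit + 2.0 * spec.mesh_step
    t_end = t_start + spec.aorta_length
    tube_spec = TubePhantomSpec(segments=(Straight(spec.aorta_length),),
                                tube_radius=spec.aorta_radius,
                                mesh_step=spec.mesh_step, seed=spec.seed)
    aorta, tube_truth = make_tube(tube_spec)
    # sweep starts at origin heading +z: rotate +z onto da, translate to start
    rot = trimesh.geometry.align_vectors([0, 0, 1.0], da)
    xf = np.eye(4)
    xf[:3, :3] = rot[:3, :3]
    xf[:3, 3] = anchor + t_start * da
    aorta = aorta.transformed(xf)

    lvot = InterfaceSurface(
        parent_labels=("aorta", "left_ventricle"),
        patch=_disc_patch(anchor, da, spec.aorta_radius),
        centroid=anchor.copy())

    # the tube's proximal ring (just outside the ventricle) is the
    # sinotubular junction: the centerline starts there and runs distally
    stj = anchor + t_start * da
    distal = anchor + t_end * da
    landmarks = {
        "apex_seed": Landmark("apex_seed", apex),
        "inlet_seed": Landmark("inlet_seed", stj),
        "outlet_seed": Landmark("outlet_seed", distal),
        "stj_point": Landmark("stj_point", stj),
    }

    truth = PhantomTruth(
        centerline_points=np.vstack([stj, distal]),
        total_length=spec.aorta_length,
        tortuosity=0.0,
        diameter=2 * spec.aorta_radius,
        outer_length=spec.aorta_length,
        inner_length=spec.aorta_length,
        aosa_deg=spec.aosa_deg_true)

    lv_mesh = _ellipsoid_mesh(semi_xyz)
    la_sphere = trimesh.creation.icosphere(subdivisions=3,
                                           radius=spec.atrium_radius)
    la_mesh = TriSurface.from_arrays(la_sphere.vertices + la_center,
                                     la_sphere.faces)

    volume = None
    if voxelize:
        volume = _voxelize_heart(spec, semi_xyz, la_center, anchor, da,
                                 t_start, t_end, voxel_mm)

    return HeartPhantom(aorta=aorta, left_ventricle=lv_mesh,
                        left_atrium=la_mesh, lvot_interface=lvot,
                        mitral_interface=mitral, landmarks=landmarks,
                        truth=truth, volume=volume)


def _ray_exit_ellipsoid(origin, direction, semi_xyz) -> float:
    """Positive ray parameter where origin + t*direction leaves the ellipsoid."""
    o = origin / semi_xyz
    d = direction / semi_xyz
    a = d @ d
    b = 2 * o @ d
    c = o @ o - 1.0
    disc = b * b - 4 * a * c
    if disc <= 0:
        raise ValueError("aorta anchor lies outside the ventricle")
    return (-b + np.sqrt(disc)) / (2 * a)


def _cap_centroid_height(semi_xyz, sphere_z, sphere_r) -> float:
    """Area-weighted z of the ellipsoid cap inside the atrial sphere (numeric)."""
    b, c, a = semi_xyz[0], semi_xyz[1], semi_xyz[2]
    # parametrize the ellipsoid by polar angle from +z; find the cap rim
    thetas = np.linspace(0.0, np.pi / 2, 2000)
    pts_z = a * np.cos(thetas)
    pts_r = np.sqrt((b * np.sin(thetas)) ** 2 + (c * np.sin(thetas)) ** 2) / np.sqrt(2)
    inside = pts_r ** 2 + (pts_z - sphere_z) ** 2 <= sphere_r ** 2
    if not inside.any():
        raise ValueError("atrium sphere does not reach the ventricle")
    th = thetas[inside]
    # area element of a surface of revolution ~ r(theta) * ds; adequate for
    # the mildly anisotropic caps used here
    r = np.sqrt((b * np.sin(th)) ** 2 + (c * np.sin(th)) ** 2) / np.sqrt(2)
    z = a * np.cos(th)
    ds = np.sqrt(np.gradient(r) ** 2 + np.gradient(z) ** 2)
    w = r * ds
    return float((z * w).sum() / w.sum())


def _voxelize_heart(spec, semi_xyz, la_center, anchor, da, t_start, t_end,
                    voxel_mm) -> LabelVolume:
    """Analytic voxelisation with a two-voxel sleeve gap around the aorta.

    The gap removes any lateral LV/aorta contact, so the shared interface is
    exactly the flat disc where the tube meets the ventricle; a planar patch
    voxelises without orientation bias in its area-weighted centroid.
    """
    margin = 6.0
    apex = np.array([0.0, 0.0, -semi_xyz[2]])
    stj = anchor + t_end * da
    corners = np.vstack([
        -semi_xyz - margin, semi_xyz + margin,
        la_center - spec.atrium_radius - margin,
        la_center + spec.atrium_radius + margin,
        stj - spec.aorta_radius - margin, stj + spec.aorta_radius + margin,
        apex - margin,
    ])
    lo = corners.min(axis=0)
    hi = corners.max(axis=0)
    shape = np.ceil((hi - lo) / voxel_mm).astype(int) + 1
    idx = np.indices(shape).reshape(3, -1).T.astype(np.float64)
    world = idx * voxel_mm + lo

    inside_lv = np.sum((world / semi_xyz) ** 2, axis=1) <= 1.0
    inside_la = np.linalg.norm(world - la_center, axis=1) <= spec.atrium_radius
    rel = world - anchor
    t = rel @ da
    rho = np.linalg.norm(rel - t[:, None] * da[None, :], axis=1)
    in_tube = (rho <= spec.aorta_radius) & (t >= 0) & (t <= t_end)
    sleeve = (rho <= spec.aorta_radius + 2 * voxel_mm) & (t >= 0)

    labels = np.zeros(len(world), dtype=np.int32)
    labels[inside_lv & ~sleeve] = 1
    labels[inside_la & ~inside_lv & ~sleeve] = 2
    labels[in_tube & ~inside_la] = 3
    # LV voxels directly under the disc (t < 0 within the tube footprint)
    # stay LV: adjacency across t = 0 forms the LVOT interface.

    affine = np.eye(4)
    affine[:3, :3] *= voxel_mm
    affine[:3, 3] = lo
    return LabelVolume(voxels=labels.reshape(shape), affine=affine,
                      label_map={"left_ventricle": 1, "left_atrium": 2,
                                 "aorta": 3})
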