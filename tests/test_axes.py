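"""Cardiac axes, the aorto-septal angle and the ascending-aorta inclination."""

import numpy as np
import pytest
import trimesh

import aortamorph as am
from aortamorph.axes import (Axis, aortic_axis, aosa, apex_fallback,
                             ascending_inclination, repeat_measurement,
                             ventricular_axis)
from aortamorph.centerline import Centerline, _cumulative_arclength
from aortamorph.phantoms import _disc_patch


def line_centerline(direction, length=60.0, n=121, origin=(0.0, 0.0, 0.0)):
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    s = np.linspace(0, length, n)
    pts = np.asarray(origin) + s[:, None] * direction
    return Centerline(points=pts, arc_length=_cumulative_arclength(pts))


def disc_interface(center, normal, radius=10.0):
    return am.InterfaceSurface(parent_labels=("a", "b"),
                               patch=_disc_patch(center, normal, radius),
                               centroid=np.asarray(center, dtype=float))


class TestAxes:
    def test_aortic_axis_from_stj_and_lvot(self):
        cl = line_centerline([0, 0, 1], origin=(0, 0, 10.0))
        ax = aortic_axis(cl, disc_interface([0, 0, 0], [0, 0, 1]))
        assert np.allclose(ax.direction, [0, 0, 1])
        assert np.allclose(ax.origin, [0, 0, 0])

    def test_translation_invariance_of_direction(self):
        t = np.array([3.0, -7.0, 12.0])
        cl = line_centerline([0, 1, 1], origin=(0, 0, 5.0))
        cl2 = Centerline(points=cl.points + t, arc_length=cl.arc_length)
        a1 = aortic_axis(cl, disc_interface([0, 0, 0], [0, 0, 1]))
        a2 = aortic_axis(cl2, disc_interface(t, [0, 0, 1]))
        assert np.allclose(a1.direction, a2.direction, atol=1e-12)

    def test_ventricular_axis_apex_to_mitral(self):
        ax = ventricular_axis(am.Landmark("apex_seed", [0, 0, -80.0]),
                              disc_interface([0, 0, 0], [0, 0, 1]))
        assert np.allclose(ax.direction, [0, 0, 1])

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        apex = np.array([5.0, -3.0, -70.0])
        mitral = np.array([1.0, 2.0, 4.0])
        a1 = ventricular_axis(am.Landmark("apex_seed", apex),
                              disc_interface(mitral, [0, 0, 1]))
        a2 = ventricular_axis(am.Landmark("apex_seed", q @ apex),
                              disc_interface(q @ mitral, q @ [0, 0, 1]))
        assert np.allclose(a2.direction, q @ a1.direction, atol=1e-10)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError, match="coincides"):
            ventricular_axis(am.Landmark("apex_seed", [0, 0, 0]),
                             disc_interface([0, 0, 0], [0, 0, 1]))

    def test_apex_fallback_finds_ellipsoid_pole(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        lv = am.TriSurface.from_arrays(sphere.vertices * [25, 25, 40],
                                       sphere.faces)
        mitral = disc_interface([0, 0, 38.0], [0, 0, 1])
        apex = apex_fallback(lv, mitral)
        assert np.linalg.norm(apex.position - [0, 0, -40.0]) < 2.0


class TestAosa:
    def test_parallel_axes_zero(self):
        pair = aosa(Axis([0, 0, 0], [0, 0, 1]), Axis([1, 0, 0], [0, 0, 1]))
        assert pair.aosa_deg == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("d2,expected", [
        ((0, 1, 0), 90.0),
        ((0, 1 / np.sqrt(2), 1 / np.sqrt(2)), 45.0),
        ((0, 0, -1), 180.0),
    ])
    def test_known_angles_with_auto_plane(self, d2, expected):
        pair = aosa(Axis([0, 0, 0], [0, 0, 1]), Axis([0, 0, 0], d2))
        assert pair.aosa_deg == pytest.approx(expected, abs=1e-9)

    def test_symmetric_in_its_axes(self):
        a = Axis([0, 0, 0], [0.2, -0.3, 0.9])
        b = Axis([0, 0, 0], [-0.5, 0.1, 0.8])
        assert aosa(a, b).aosa_deg == pytest.approx(aosa(b, a).aosa_deg,
                                                    abs=1e-12)

    def test_auto_plane_equals_direct_3d_angle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            d1, d2 = rng.normal(size=(2, 3))
            pair = aosa(Axis([0, 0, 0], d1), Axis([0, 0, 0], d2))
            direct = np.degrees(np.arccos(np.clip(
                (d1 / np.linalg.norm(d1)) @ (d2 / np.linalg.norm(d2)), -1, 1)))
            assert pair.aosa_deg == pytest.approx(direct, abs=1e-9)

    def test_rigid_rotation_invariance(self):
        rng = np.random.default_rng(4)
        d1, d2 = rng.normal(size=(2, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        base = aosa(Axis([0, 0, 0], d1), Axis([0, 0, 0], d2)).aosa_deg
        moved = aosa(Axis([0, 0, 0], q @ d1), Axis([0, 0, 0], q @ d2)).aosa_deg
        assert moved == pytest.approx(base, abs=1e-9)

    def test_explicit_plane_projection(self):
        # projecting (1,0,1) and (0,1,1) onto the z=const plane gives 90 deg
        pair = aosa(Axis([0, 0, 0], [1, 0, 1]), Axis([0, 0, 0], [0, 1, 1]),
                    plane_normal=np.array([0.0, 0.0, 1.0]))
        assert pair.aosa_deg == pytest.approx(90.0, abs=1e-9)

    def test_axis_parallel_to_plane_normal_rejected(self):
        with pytest.raises(ValueError, match="degenerate in plane"):
            aosa(Axis([0, 0, 0], [0, 0, 1]), Axis([0, 0, 0], [0, 1, 0]),
                 plane_normal=np.array([0.0, 0.0, 1.0]))


class TestAscendingInclination:
    def test_collinear_tube_zero_inclination(self):
        cl = line_centerline([0, 0, 1])
        res = ascending_inclination(cl, Axis([0, 0, -10], [0, 0, 1]))
        assert res.aai_deg == pytest.approx(0.0, abs=1e-9)
        assert res.aai_sd_deg == pytest.approx(0.0, abs=1e-9)

    def test_straight_tube_at_fifteen_degrees(self):
        tilt = np.radians(15.0)
        cl = line_centerline([np.sin(tilt), 0, np.cos(tilt)])
        res = ascending_inclination(cl, Axis([0, 0, 0], [0, 0, 1]))
        assert res.aai_deg == pytest.approx(15.0, abs=1e-6)
        assert res.aai_sd_deg == pytest.approx(0.0, abs=1e-6)

    def test_circular_arc_matches_chord_angle_integral(self):
        """On a circular arc the chord from s=0 makes the inscribed angle
        s / (2R) with the initial tangent; the mean over the window must
        match that closed form."""
        R = 60.0
        s = np.linspace(0, 40.0, 401)
        th = s / R
        pts = np.column_stack([R * np.sin(th), 1 - np.cos(th) * R + R,
                               np.zeros_like(th)])
        pts[:, 1] -= pts[0, 1]
        cl = Centerline(points=pts, arc_length=_cumulative_arclength(pts))
        res = ascending_inclination(cl, Axis(pts[0], [1, 0, 0]), window_mm=20.0)
        s_win = cl.arc_length[(cl.arc_length > 0) & (cl.arc_length <= 20.0)]
        expected = np.degrees(s_win / (2 * R)).mean()
        assert res.aai_deg == pytest.approx(expected, abs=1.0)

    def test_window_longer_than_centerline_rejected(self):
        cl = line_centerline([0, 0, 1], length=10.0)
        with pytest.raises(ValueError, match="shorter"):
            ascending_inclination(cl, Axis([0, 0, 0], [0, 0, 1]), window_mm=20.0)


class TestRepeatMeasurement:
    @staticmethod
    def _protocol(mitral):
        # obtuse anatomical configuration (~117 degrees to the chamber axis)
        tilt = np.radians(117.0)
        aortic = Axis([0, 0, 0], [np.sin(tilt), 0, np.cos(tilt)])

        def protocol(apex):
            return aosa(aortic, ventricular_axis(apex, mitral)).aosa_deg
        return protocol

    def test_zero_jitter_identical_repeats(self):
        mitral = disc_interface([0, 0, 0], [0, 0, 1])
        vals = repeat_measurement(self._protocol(mitral),
                                  am.Landmark("apex_seed", [0, 0, -80.0]),
                                  n_repeats=5, jitter_mm=0.0, seed=9)
        assert len(set(vals)) == 1

    def test_same_seed_reproduces_list(self):
        mitral = disc_interface([0, 0, 0], [0, 0, 1])
        apex = am.Landmark("apex_seed", [0, 0, -80.0])
        a = repeat_measurement(self._protocol(mitral), apex, 5, 2.0, seed=123)
        b = repeat_measurement(self._protocol(mitral), apex, 5, 2.0, seed=123)
        assert a == b

    def test_jitter_produces_subpercent_cv(self):
        """2 mm apex jitter on an 80 mm ventricle keeps CV in the ~1% regime."""
        mitral = disc_interface([0, 0, 0], [0, 0, 1])
        apex = am.Landmark("apex_seed", [0, 0, -80.0])
        vals = repeat_measurement(self._protocol(mitral), apex, 5, 2.0, seed=5)
        cv = am.coefficient_of_variation(vals)
        assert 0.0 < cv < 2.0
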