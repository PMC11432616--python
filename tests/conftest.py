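"""Shared fixtures: phantom meshes and their solved pipeline products.

The expensive objects (harmonic solves, isoline stacks) are session-scoped
so the geometric tests share them instead of re-solving per test.
"""

from __future__ import annotations

import numpy as np
import pytest

import aortamorph as am
from aortamorph.centerline import compute_centerline, cross_section_areas
from aortamorph.harmonic import extract_isolines, solve_harmonic


def solve_phantom(spec: am.TubePhantomSpec, n_levels: int = 100,
                  with_areas: bool = True) -> dict:
    """Run the geometric pipeline on a tube phantom; returns all stages."""
    surf, truth = am.make_tube(spec)
    inlet = am.Landmark("inlet_seed", truth.centerline_points[0])
    outlet = am.Landmark("outlet_seed", truth.centerline_points[-1])
    fld = solve_harmonic(surf, inlet, outlet)
    iso = extract_isolines(fld, n_levels)
    cl = compute_centerline(fld, iso)
    if with_areas:
        cl = cross_section_areas(cl, surf)
    return {"spec": spec, "surface": surf, "truth": truth, "field": fld,
            "isolines": iso, "centerline": cl}


@pytest.fixture(scope="session")
def cylinder():
    """Straight tube, radius 15 mm, height 80 mm (axis +z, inlet at z=0)."""
    return solve_phantom(am.TubePhantomSpec((am.Straight(80.0),),
                                            tube_radius=15.0, mesh_step=1.0))


@pytest.fixture(scope="session")
def bend():
    """Quarter-circle bend: R = 40 mm, tube radius 10 mm."""
    return solve_phantom(am.TubePhantomSpec((am.Arc(40.0, np.pi / 2),),
                                            tube_radius=10.0, mesh_step=1.0))


@pytest.fixture(scope="session")
def heart():
    """Two-chamber phantom at the study-range angle 117.25 degrees."""
    return am.make_heart(am.HeartPhantomSpec(aosa_deg_true=117.25,
                                             mesh_step=1.5))
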