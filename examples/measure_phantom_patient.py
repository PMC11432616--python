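"""Measure a synthetic two-chamber 'patient' end to end.

Builds a heart phantom whose aorto-septal angle is 117.25 degrees by
construction, runs the full measurement pipeline (harmonic field ->
isolines -> centerline -> curvature lines -> axes), and repeats the angle
measurement five times with a seeded 2 mm apex jitter, emulating an
observer re-placing the apical landmark.
"""

import aortamorph as am
from aortamorph.pipeline import RunConfig, measure_geometry

phantom = am.make_heart(am.HeartPhantomSpec(aosa_deg_true=117.25,
                                            mesh_step=1.5))
config = RunConfig(jitter_mm=2.0, n_repeats=5, seed=42)
report = measure_geometry(
    phantom.aorta,
    phantom.landmarks["inlet_seed"], phantom.landmarks["outlet_seed"],
    phantom.lvot_interface, phantom.mitral_interface,
    apex=phantom.landmarks["apex_seed"], config=config)

print(f"constructed AoSA      : {phantom.truth.aosa_deg:.2f} deg")
print(f"measured AoSA         : {report.aosa_deg_mean:.2f} "
      f"+/- {report.aosa_deg_sd:.2f} deg (mean of 5 jittered repeats)")
print(f"repeatability CV      : {report.cv_percent:.2f} %")
print(f"ascending inclination : {report.aai_deg:.2f} "
      f"+/- {report.aai_sd_deg:.2f} deg")
print(f"centerline length     : {report.centerline_length_mm:.1f} mm "
      f"(truth {phantom.truth.total_length:.1f})")
print(f"mean diameter         : {report.mean_diameter_mm:.1f} mm "
      f"(truth {phantom.truth.diameter:.1f})")
# The CV sits in the ~1% regime of careful manual repeats: the apex sits
# ~80 mm from the mitral plane, so a 2 mm jitter moves the axis by ~1 degree.
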