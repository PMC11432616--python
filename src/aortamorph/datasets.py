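"""Bundled measurement tables from a five-patient TEVAR imaging cohort.

Four small CSVs ship with the package: per-patient aorto-septal angle
measurements (mean of five repeats, with per-acquisition coefficients of
variation), ascending-aorta geometry pre/post treatment, the ten paired
inter-observer angle readings, and cohort characteristics.  They feed the
statistics layer and the worked examples; all values are stored verbatim as
printed in the source tables (including their rounding).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_aosa_table", "load_geometry_table", "load_interobserver_table",
           "load_cohort_table"]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("aortamorph").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_aosa_table() -> pd.DataFrame:
    """Per-patient AoSA (degrees): mean/SD of five repeats, pre and post TEVAR.

    Columns: patient, pathology, aosa_pre_mean, aosa_pre_sd, aosa_post_mean,
    aosa_post_sd, percent_change, cv_pre, cv_post.  The percent-change and CV
    columns are the printed values; they may differ in the last digit from
    what the mean/SD columns recompute.
    """
    return _read("aosa_measurements.csv")


def load_geometry_table() -> pd.DataFrame:
    """Ascending-aorta geometry per patient and phase.

    Columns: patient, phase (pre/post), aai_mean, aai_sd (degrees), diameter
    (mm), tortuosity (dimensionless), centerline_length, outer_line,
    inner_line (mm).
    """
    return _read("ascending_aorta_geometry.csv")


def load_interobserver_table() -> pd.DataFrame:
    """Ten paired AoSA readings (5 patients x 2 phases) by two observers."""
    return _read("interobserver_angles.csv")


def load_cohort_table() -> pd.DataFrame:
    """Demographics, risk factors and treatment details of the five patients."""
    return _read("cohort_characteristics.csv")
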