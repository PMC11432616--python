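"""End-to-end orchestration: per-patient geometry run and study statistics.

``measure_geometry`` chains the stages — harmonic field, isolines,
centerline, cross sections, curvature lines, cardiac axes, repeated
aorto-septal angle — into one report; ``run_measure`` wraps it with file
loading from a :class:`RunConfig`.  ``run_stats`` turns the bundled
measurement tables into the study-level aggregates (group means, paired
tests, repeatability and reliability statistics).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .axes import (Axis, aortic_axis, aosa, apex_fallback,
                   ascending_inclination, repeat_measurement, ventricular_axis)
from .centerline import (compute_centerline, cross_section_areas,
                         segment_metrics)
from .core import (InterfaceSurface, LabelVolume, Landmark, TriSurface,
                   interface_surface, load_landmarks, load_surface,
                   mask_to_surface)
from .curvature import extremal_paths
from .harmonic import extract_isolines, solve_harmonic
from .stats import (coefficient_of_variation, icc_two_way_random, paired_t,
                    percent_change)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PatientReport", "measure_geometry", "run_measure",
           "run_stats"]


@dataclass
class RunConfig:
    """Resolved configuration of a per-patient geometry run."""

    aorta_mesh: str | None = None
    volume: str | None = None
    lv_mesh: str | None = None
    landmarks: str | None = None
    aorta_label: str = "aorta"
    lv_label: str = "left_ventricle"
    la_label: str = "left_atrium"
    n_levels: int = 100
    samples_per_contour: int = 64
    smooth_window_mm: float = 10.0
    resample_step_mm: float = 0.5
    aai_window_mm: float = 20.0
    segment_mm: tuple[float, float] | None = None
    n_repeats: int = 5
    jitter_mm: float = 2.0
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        for name in ("n_levels", "samples_per_contour", "smooth_window_mm",
                     "resample_step_mm", "aai_window_mm", "n_repeats"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.jitter_mm < 0:
            raise ValueError("jitter_mm must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "segment_mm" in data and data["segment_mm"] is not None:
            data["segment_mm"] = tuple(data["segment_mm"])
        return cls(**data)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["segment_mm"] is not None:
            d["segment_mm"] = list(d["segment_mm"])
        return d


@dataclass
class PatientReport:
    """Per-patient geometric measurements plus a provenance manifest."""

    aosa_deg_mean: float
    aosa_deg_sd: float
    cv_percent: float
    aosa_repeats: list[float]
    aai_deg: float
    aai_sd_deg: float
    mean_diameter_mm: float
    tortuosity: float
    centerline_length_mm: float
    outer_line_length_mm: float
    inner_line_length_mm: float
    manifest: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2,
                                         sort_keys=True))


def measure_geometry(aorta: TriSurface,
                     inlet_seed: Landmark,
                     outlet_seed: Landmark,
                     lvot_interface: InterfaceSurface,
                     mitral_interface: InterfaceSurface,
                     apex: Landmark | None = None,
                     lv_surface: TriSurface | None = None,
                     config: RunConfig | None = None) -> PatientReport:
    """Run the full geometric pipeline on prepared inputs.

    The aorta must be an open (branch-free) tube; the inlet seed marks the
    sinotubular-junction end.  If no apex landmark is given, the fallback
    picks the LV surface vertex farthest from the mitral centroid (requires
    ``lv_surface``).
    """
    cfg = config or RunConfig()
    manifest = {"config": cfg.as_dict(), "version": __version__}

    if apex is None:
        if lv_surface is None:
            raise ValueError("need either an apex landmark or an LV surface")
        apex = apex_fallback(lv_surface, mitral_interface)
        manifest["apex_fallback"] = True
        log.info("apex landmark not given; using farthest-vertex fallback")

    fld = solve_harmonic(aorta, inlet_seed, outlet_seed)
    iso = extract_isolines(fld, cfg.n_levels)
    cl = compute_centerline(fld, iso, cfg.smooth_window_mm, cfg.resample_step_mm)
    cl = cross_section_areas(cl, aorta)
    s0, s1 = cfg.segment_mm if cfg.segment_mm else (0.0, cl.total_length)
    s1 = min(s1, cl.total_length)
    seg = segment_metrics(cl, s0, s1)
    outer, inner = extremal_paths(iso, fld, cfg.samples_per_contour)
    ax_a = aortic_axis(cl, lvot_interface)
    ax_v = ventricular_axis(apex, mitral_interface)

    def protocol(jittered_apex: Landmark) -> float:
        return aosa(ax_a, ventricular_axis(jittered_apex, mitral_interface)).aosa_deg

    repeats = repeat_measurement(protocol, apex, n_repeats=cfg.n_repeats,
                                 jitter_mm=cfg.jitter_mm, seed=cfg.seed)
    mean = float(np.mean(repeats))
    sd = float(np.std(repeats, ddof=1))
    cv = coefficient_of_variation(repeats) if sd > 0 else 0.0
    aai = ascending_inclination(cl, ax_a, cfg.aai_window_mm)

    return PatientReport(
        aosa_deg_mean=mean, aosa_deg_sd=sd, cv_percent=cv,
        aosa_repeats=[float(v) for v in repeats],
        aai_deg=aai.aai_deg, aai_sd_deg=aai.aai_sd_deg,
        mean_diameter_mm=seg.mean_diameter,
        tortuosity=seg.tortuosity_T,
        centerline_length_mm=seg.length_L,
        outer_line_length_mm=outer.length,
        inner_line_length_mm=inner.length,
        manifest=manifest)


def run_measure(config: RunConfig) -> PatientReport:
    """File-based entry point: load inputs per the config, then measure.

    Inputs are either an open aortic surface mesh (``aorta_mesh``) plus a
    label volume for the chamber interfaces, or a label volume alone (the
    aortic surface is then extracted from the ``aorta`` label — note the
    caller is responsible for an open, branch-free aortic tube).
    """
    if config.landmarks is None:
        raise ValueError("config.landmarks (JSON file) is required")
    lms = load_landmarks(config.landmarks)
    for required in ("inlet_seed", "outlet_seed"):
        if required not in lms:
            raise ValueError(f"landmark {required!r} missing")

    vol = LabelVolume.from_nifti(config.volume) if config.volume else None
    if config.aorta_mesh:
        aorta = load_surface(config.aorta_mesh)
    elif vol is not None:
        aorta = mask_to_surface(vol, config.aorta_label)
    else:
        raise ValueError("config needs aorta_mesh or volume")
    if vol is None:
        raise ValueError("config.volume is required for the chamber interfaces")

    lvot = interface_surface(vol, config.aorta_label, config.lv_label)
    mitral = interface_surface(vol, config.lv_label, config.la_label)
    lv_surface = (load_surface(config.lv_mesh) if config.lv_mesh
                  else mask_to_surface(vol, config.lv_label))
    report = measure_geometry(aorta, lms["inlet_seed"], lms["outlet_seed"],
                              lvot, mitral, apex=lms.get("apex_seed"),
                              lv_surface=lv_surface, config=config)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
    return report


# ---------------------------------------------------------------------------
# Study statistics

def run_stats(aosa_table: pd.DataFrame,
              geometry_table: pd.DataFrame | None = None,
              interobserver_table: pd.DataFrame | None = None) -> dict:
    """Study-level aggregates from per-patient measurement tables.

    ``aosa_table`` columns: patient, pathology, aosa_pre_mean, aosa_pre_sd,
    aosa_post_mean, aosa_post_sd, cv_pre, cv_post.
    ``geometry_table`` columns: patient, phase, aai_mean, aai_sd, diameter,
    tortuosity, centerline_length, outer_line, inner_line.
    ``interobserver_table`` columns: subject, plus one column per observer.
    """
    out: dict = {}

    by_path = {}
    for pathology, grp in aosa_table.groupby("pathology"):
        # group change = mean of per-patient percent changes (each patient's
        # change is relative to their own pre-operative angle)
        per_patient = [percent_change(pre, post) for pre, post in
                       zip(grp["aosa_pre_mean"], grp["aosa_post_mean"])]
        entry = {
            "n": int(len(grp)),
            "pre_mean": float(grp["aosa_pre_mean"].mean()),
            "pre_sd": float(grp["aosa_pre_mean"].std(ddof=1)),
            "post_mean": float(grp["aosa_post_mean"].mean()),
            "post_sd": float(grp["aosa_post_mean"].std(ddof=1)),
            "percent_change": float(np.mean(per_patient)),
        }
        if len(grp) >= 2:
            cmp = paired_t(grp["aosa_pre_mean"], grp["aosa_post_mean"],
                           metric_name=f"aosa[{pathology}]")
            entry.update(t_stat=cmp.t_stat, p_value=cmp.p_value)
        by_path[pathology] = entry
    out["aosa_by_pathology"] = by_path
    out["cv"] = {
        "pre_mean": float(aosa_table["cv_pre"].mean()),
        "pre_sd": float(aosa_table["cv_pre"].std(ddof=1)),
        "post_mean": float(aosa_table["cv_post"].mean()),
        "post_sd": float(aosa_table["cv_post"].std(ddof=1)),
    }

    if geometry_table is not None:
        metrics = ["aai_mean", "diameter", "tortuosity", "centerline_length",
                   "outer_line", "inner_line"]
        wide = geometry_table.pivot(index="patient", columns="phase")
        geo = {}
        for m in metrics:
            pre = wide[(m, "pre")]
            post = wide[(m, "post")]
            geo[m] = paired_t(pre, post, metric_name=m).as_dict()
        out["ascending_aorta"] = geo

    if interobserver_table is not None:
        obs_cols = [c for c in interobserver_table.columns
                    if c.startswith("observer")]
        if not obs_cols:
            obs_cols = [c for c in interobserver_table.columns
                        if c not in ("subject", "patient", "phase")]
        long = interobserver_table.melt(id_vars="subject", value_vars=obs_cols,
                                        var_name="rater", value_name="value")
        rep = icc_two_way_random(long, form="single")
        out["interobserver"] = {"icc": rep.icc, "icc_ci95": list(rep.icc_ci95),
                                "model": rep.model}
    return out
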