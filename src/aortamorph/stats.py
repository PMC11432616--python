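"""Reliability and cohort statistics for repeated geometric measurements.

Covers the study-level statistics layer: the coefficient of variation of
repeated measurements (intra-observer repeatability), the two-way
random-effects intraclass correlation with absolute agreement
(inter-observer reliability, single or averaged-rating form), paired
t-tests for pre/post-treatment comparisons, the percent-change formula, and
grouped mean +/- SD cohort summaries.

Conventions: sample statistics use the n-1 denominator throughout, and
percent change defaults to the signed form ``100 * (post - pre) / pre`` so
that increases are positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = ["MeasurementTable", "ReliabilityReport", "PairedComparison",
           "coefficient_of_variation", "icc_two_way_random", "paired_t",
           "percent_change", "cohort_summary"]

_COLUMNS = ["patient", "phase", "observer", "repeat", "metric", "value"]


@dataclass
class MeasurementTable:
    """Long-format repeated measurements: patient x phase x observer x repeat."""

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"measurement table missing columns: {missing}")
        if self.data.duplicated(subset=_COLUMNS[:-1]).any():
            raise ValueError(
                "(patient, phase, observer, repeat, metric) must be unique")
        if not np.all(np.isfinite(self.data["value"])):
            raise ValueError("measurement values must be finite")

    @classmethod
    def from_csv(cls, path) -> "MeasurementTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data[_COLUMNS].to_csv(path, index=False)

    def subset(self, **filters) -> "MeasurementTable":
        d = self.data
        for col, val in filters.items():
            d = d[d[col].isin(val if isinstance(val, (list, tuple, set)) else [val])]
        return MeasurementTable(d.reset_index(drop=True))


@dataclass
class ReliabilityReport:
    """ICC point estimate with its F-based 95% confidence interval."""

    icc: float
    icc_ci95: tuple[float, float]
    model: str

    def __post_init__(self):
        lo, hi = self.icc_ci95
        if not (lo <= self.icc + 1e-9 and self.icc <= hi + 1e-9):
            raise ValueError("ICC point estimate outside its own CI")


@dataclass
class PairedComparison:
    """Two-sided paired t-test on post - pre plus descriptive summaries."""

    metric_name: str
    n_pairs: int
    mean_pre: float
    sd_pre: float
    mean_post: float
    sd_post: float
    mean_diff: float
    t_stat: float
    p_value: float
    percent_change: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "metric_name", "n_pairs", "mean_pre", "sd_pre", "mean_post",
            "sd_post", "mean_diff", "t_stat", "p_value", "percent_change")}


def coefficient_of_variation(values) -> float:
    """CV in percent: ``100 * sample SD / mean`` (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("CV needs at least 2 values")
    mean = v.mean()
    if abs(mean) < 1e-12:
        raise ValueError("CV undefined for zero-mean data")
    return float(100.0 * v.std(ddof=1) / mean)


def icc_two_way_random(ratings: pd.DataFrame, form: str = "single") -> ReliabilityReport:
    """Two-way random-effects, absolute-agreement ICC.

    Parameters
    ----------
    ratings : DataFrame
        Long format with columns ``subject``, ``rater``, ``value`` forming a
        complete two-way layout (every subject rated once by every rater).
    form : {"single", "mean_k"}
        ICC(2,1) for single ratings or ICC(2,k) for the mean of the k raters.
    """
    if form not in ("single", "mean_k"):
        raise ValueError("form must be 'single' or 'mean_k'")
    for col in ("subject", "rater", "value"):
        if col not in ratings.columns:
            raise ValueError(f"ratings table missing column {col!r}")
    pivot = ratings.pivot(index="subject", columns="rater", values="value")
    if pivot.isna().any().any():
        raise ValueError("incomplete two-way layout (missing subject x rater cells)")
    n, k = pivot.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    with np.errstate(invalid="ignore", divide="ignore"):
        # degenerate layouts (zero residual variance) trip harmless
        # division warnings inside the F-statistic computation
        res = pg.intraclass_corr(data=ratings, targets="subject",
                                 raters="rater", ratings="value")
    # two-way random, absolute agreement: labelled ICC2/ICC2k or ICC(A,1)/(A,k)
    wanted = {"ICC2", "ICC(A,1)"} if form == "single" else {"ICC2k", "ICC(A,k)"}
    row = res[res["Type"].isin(wanted)].iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = (float(x) for x in row[ci_col])
    icc = float(row["ICC"])
    if not (np.isfinite(lo) and np.isfinite(hi)):
        # zero residual variance: the F-based interval degenerates
        lo = hi = icc
    # the F-based bounds are an approximation and can leave [-1, 1] (or even
    # cross) on very small layouts; normalise so the interval is a valid ICC
    # range containing the point estimate
    lo, hi = np.clip(sorted((lo, hi)), -1.0, 1.0)
    lo, hi = min(lo, icc), max(hi, icc)
    model = ("two-way random effects, absolute agreement, "
             + ("single rating" if form == "single" else f"mean of k={k} ratings"))
    return ReliabilityReport(icc=icc, icc_ci95=(float(lo), float(hi)),
                             model=model)


def paired_t(pre, post, metric_name: str = "") -> PairedComparison:
    """Two-sided paired t-test on ``post - pre`` with summary statistics."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D arrays of equal length")
    if len(pre) < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    diff = post - pre
    if diff.std(ddof=1) < 1e-12:
        raise ValueError("zero-variance differences: t statistic undefined")
    t_res = sps.ttest_rel(post, pre)
    return PairedComparison(
        metric_name=metric_name,
        n_pairs=len(pre),
        mean_pre=float(pre.mean()), sd_pre=float(pre.std(ddof=1)),
        mean_post=float(post.mean()), sd_post=float(post.std(ddof=1)),
        mean_diff=float(diff.mean()),
        t_stat=float(t_res.statistic), p_value=float(t_res.pvalue),
        percent_change=percent_change(float(pre.mean()), float(post.mean())),
    )


def percent_change(pre: float, post: float,
                   convention: str = "signed_post_minus_pre") -> float:
    """Percent change of a pre/post pair.

    ``signed_post_minus_pre`` (default) returns ``100 * (post - pre) / pre``
    so increases are positive; ``pre_minus_post`` returns the opposite sign
    (``100 * (pre - post) / pre``).
    """
    if abs(pre) < 1e-12:
        raise ValueError("percent change undefined for pre = 0")
    if convention == "signed_post_minus_pre":
        return 100.0 * (post - pre) / pre
    if convention == "pre_minus_post":
        return 100.0 * (pre - post) / pre
    raise ValueError(f"unknown convention {convention!r}")


def cohort_summary(df: pd.DataFrame, value_col: str,
                   group_cols: list[str]) -> pd.DataFrame:
    """Per-group mean, sample SD (n-1) and count of ``value_col``.

    Groups of size one get ``NaN`` SD (flagged in ``sd_defined``); empty
    input raises.
    """
    if df.empty:
        raise ValueError("empty table")
    for c in [value_col, *group_cols]:
        if c not in df.columns:
            raise ValueError(f"missing column {c!r}")
    g = df.groupby(group_cols, sort=True)[value_col]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["sd_defined"] = out["n"] > 1
    return out
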