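"""Stage-level summaries and the nucleus-size vs DNA-content correlation.

A :class:`StageSummary` mirrors one row of the published-style table: per
stage it reports nucleus counts, mean relative nucleus size, both DNA
content estimators (the peak-class mean and the all-nuclei mean), the main
C-class against a 1C reference, flags for minor higher-ploidy
subpopulations, and the ratio of the stage mean to the reference.

The correlation report quantifies the coupling between relative nucleus
size and DNA content across stages and exposes, per stage group, the signed
residual from the pooled regression -- the statistic in which the
male-gametophyte anomaly (zoospore-sized nuclei carrying ~2.6x the DNA)
shows up as a large positive value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ploidy import (
    CValueCall,
    FrequencyDistribution,
    all_nuclei_mean,
    assign_c_class,
    build_frequency_distribution,
    class_fraction_flags,
    peak_class_mean,
    stage_ratio,
)

logger = logging.getLogger(__name__)

__all__ = ["StageSummary", "CorrelationReport", "summarize_stage", "size_content_correlation"]


@dataclass
class StageSummary:
    """One table row: DNA-content and size summary of a single stage."""

    stage: str
    n_nuclei: int
    nrs_mean: float
    nrs_sd: float
    peak_mean_pg: float
    peak_sd_pg: float
    peak_n_included: int
    all_mean_pg: float
    all_sd_pg: float
    main_c_class: int
    flags: dict[int, str]
    ratio_to_reference: float
    reference_1C: float
    n_sources: int | None = None
    distribution: FrequencyDistribution | None = field(default=None, repr=False)

    def to_row(self) -> dict:
        """Rounded report row (pg to 2 decimals, ratios to 1)."""
        flag_s = " ".join(f"{c}C:{f}" for c, f in self.flags.items() if f) or "-"
        return {
            "stage": self.stage,
            "n_sources": self.n_sources if self.n_sources is not None else "",
            "n_nuclei": self.n_nuclei,
            "nrs_mean": round(self.nrs_mean, 3) if np.isfinite(self.nrs_mean) else "",
            "nrs_sd": round(self.nrs_sd, 3) if np.isfinite(self.nrs_sd) else "",
            "peak_mean_pg": round(self.peak_mean_pg, 2),
            "peak_sd_pg": round(self.peak_sd_pg, 2),
            "all_mean_pg": round(self.all_mean_pg, 2),
            "all_sd_pg": round(self.all_sd_pg, 2),
            "main_c_class": f"{self.main_c_class}C",
            "higher_class_flags": flag_s,
            "ratio_to_reference": self.ratio_to_reference,
        }


@dataclass
class CorrelationReport:
    """Pooled per-nucleus size-content correlation plus per-group structure."""

    pearson_r: float
    spearman_rho: float
    n: int
    group_means: pd.DataFrame  # columns: stage, nrs_mean, pg_mean, n
    slope: float
    intercept: float
    group_residuals: pd.DataFrame  # columns: stage, mean_residual_pg

    def to_dict(self) -> dict:
        return {
            "pearson_r": None if not np.isfinite(self.pearson_r) else self.pearson_r,
            "spearman_rho": None if not np.isfinite(self.spearman_rho) else self.spearman_rho,
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
            "group_means": self.group_means.to_dict(orient="records"),
            "group_residuals": self.group_residuals.to_dict(orient="records"),
        }


def summarize_stage(
    records: pd.DataFrame,
    stage: str,
    class_width: float = 0.1,
    reference_1C: float | None = None,
    plus_threshold: float = 0.05,
    tolerance: float = 0.25,
    n_sources: int | None = None,
) -> StageSummary:
    """Summarise one stage from per-nucleus records.

    ``records`` needs a ``pg`` column and optionally ``nrs``; rows must all
    belong to ``stage``.  ``reference_1C`` anchors the C-class ladder (when
    omitted, the stage's own peak-class mean is used, i.e. the stage is
    reported relative to itself).  With a single nucleus, SDs are reported
    as zero and a warning is logged.
    """
    if len(records) == 0:
        raise ValueError(f"no records for stage {stage!r}")
    pg = records["pg"].to_numpy(dtype=float)
    if len(pg) == 1:
        logger.warning("stage %r has a single nucleus; SDs reported as 0", stage)
    dist = build_frequency_distribution(pg, class_width=class_width)
    est = peak_class_mean(dist)
    a_mean, a_sd = all_nuclei_mean(pg)
    ref = reference_1C if reference_1C is not None else est.mean_pg
    main_call = assign_c_class(est.mean_pg, ref, tolerance=tolerance)
    calls = [assign_c_class(v, ref, tolerance=tolerance) for v in pg]
    flags = class_fraction_flags(calls, main_call.c_class, plus_threshold=plus_threshold)
    if "nrs" in records.columns and records["nrs"].notna().any():
        nrs = records["nrs"].to_numpy(dtype=float)
        nrs_mean = float(np.nanmean(nrs))
        nrs_sd = float(np.nanstd(nrs, ddof=1)) if len(nrs) > 1 else 0.0
    else:
        nrs_mean = float("nan")
        nrs_sd = float("nan")
    return StageSummary(
        stage=stage,
        n_nuclei=len(pg),
        nrs_mean=nrs_mean,
        nrs_sd=nrs_sd,
        peak_mean_pg=est.mean_pg,
        peak_sd_pg=est.sd_pg,
        peak_n_included=est.n_included,
        all_mean_pg=a_mean,
        all_sd_pg=a_sd,
        main_c_class=main_call.c_class,
        flags=flags,
        ratio_to_reference=stage_ratio(est.mean_pg, ref),
        reference_1C=ref,
        n_sources=n_sources,
        distribution=dist,
    )


def size_content_correlation(records: pd.DataFrame) -> CorrelationReport:
    """Correlate relative nucleus size with DNA content across all records.

    ``records`` needs columns ``nrs``, ``pg`` and ``stage``.  Pearson and
    Spearman coefficients are computed per nucleus; when either variable has
    zero variance the coefficients are reported as NaN (undefined), never
    forced to 0.  Per-stage mean residuals from the pooled least-squares fit
    of pg on nrs expose groups that break the coupling.
    """
    need = {"nrs", "pg", "stage"}
    if not need.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(need)}")
    df = records.dropna(subset=["nrs", "pg"])
    if len(df) < 3:
        raise ValueError("need at least 3 records with nrs and pg")
    x = df["nrs"].to_numpy(dtype=float)
    y = df["pg"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        pearson = spearman = float("nan")
        slope, intercept = 0.0, float(np.mean(y))
        logger.warning("zero variance in nrs or pg; correlation undefined")
    else:
        pearson = float(stats.pearsonr(x, y).statistic)
        spearman = float(stats.spearmanr(x, y).statistic)
        slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
    resid = y - (slope * x + intercept)
    tmp = df.assign(_resid=resid)
    gm = (
        tmp.groupby("stage", sort=True)
        .agg(nrs_mean=("nrs", "mean"), pg_mean=("pg", "mean"), n=("pg", "size"))
        .reset_index()
    )
    gr = (
        tmp.groupby("stage", sort=True)
        .agg(mean_residual_pg=("_resid", "mean"))
        .reset_index()
    )
    return CorrelationReport(
        pearson_r=pearson,
        spearman_rho=spearman,
        n=len(df),
        group_means=gm,
        slope=slope,
        intercept=intercept,
        group_residuals=gr,
    )
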