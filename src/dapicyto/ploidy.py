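"""Frequency distributions of DNA content, the peak-class mean, and C-class calls.

The headline statistic works on an equal-width histogram of per-nucleus DNA
contents: identify the peak frequency class, include every contiguous
neighbouring class whose frequency exceeds 50% of the peak's, and average
the raw values falling in the included classes.  This trims stray high- and
low-C nuclei (dividing cells, endopolyploid outliers, debris) without
fitting any mixture model.

C-classes are assigned on the 1C-2C-4C-8C-16C ladder by nearest class in
log2 space relative to a 1C reference (by convention the released-zoospore
peak-class mean of the same run).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyDistribution",
    "PeakClassEstimate",
    "CValueCall",
    "LADDER",
    "build_frequency_distribution",
    "peak_class_mean",
    "all_nuclei_mean",
    "assign_c_class",
    "class_fraction_flags",
    "pg_to_mb",
    "stage_ratio",
    "freedman_diaconis_width",
]

LADDER = (1, 2, 4, 8, 16)

#: megabase pairs per picogram of DNA
MB_PER_PG = 980.0

_EPS = 1e-9


@dataclass
class FrequencyDistribution:
    """Equal-width, half-open DNA-content classes ``[e_i, e_i+1)``.

    Stores the class edges, per-class counts, the underlying values and each
    value's class index, so estimators can average raw values per class.
    """

    edges: np.ndarray
    counts: np.ndarray
    values: np.ndarray
    class_index: np.ndarray

    @property
    def class_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_left": self.edges[:-1],
                "class_right": self.edges[1:],
                "count": self.counts,
            }
        )


@dataclass
class PeakClassEstimate:
    """Result of the peak-class averaging rule."""

    included_class_indices: tuple[int, int]  # inclusive (lo, hi)
    mean_pg: float
    sd_pg: float
    n_included: int
    n_total: int
    fraction_included: float


@dataclass
class CValueCall:
    """A single nucleus (or stage mean) placed on the C-value ladder."""

    pg: float
    ratio_to_1C: float
    c_class: int
    in_tolerance: bool

    @property
    def c_label(self) -> str:
        return f"{self.c_class}C"


def build_frequency_distribution(values, class_width: float = 0.1) -> FrequencyDistribution:
    """Bin DNA contents into equal-width classes starting at ``floor(min/width)*width``."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("values must be nonempty")
    if not class_width > 0:
        raise ValueError("class_width must be > 0")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    k0 = math.floor(values.min() / class_width + _EPS)
    idx = np.floor(values / class_width + _EPS).astype(int) - k0
    n_classes = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_classes)
    edges = (k0 + np.arange(n_classes + 1)) * class_width
    return FrequencyDistribution(
        edges=edges, counts=counts, values=values, class_index=idx
    )


def freedman_diaconis_width(values) -> float:
    """Freedman-Diaconis class width, for ``class_width="auto"``."""
    values = np.asarray(values, dtype=float)
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    if iqr == 0:
        return max(1e-6, float(values.std()) or 1e-6)
    return 2.0 * iqr / len(values) ** (1.0 / 3.0)


def peak_class_mean(
    dist: FrequencyDistribution, use_midpoints: bool = False
) -> PeakClassEstimate:
    """Mean +/- SD over the peak class and its >50%-of-peak neighbours.

    The peak region is the set of all tied maximum-count classes and any
    classes between them; it then grows contiguously left and right while
    the neighbouring class's count strictly exceeds half the peak count.
    The mean is computed over the raw values in the included classes
    (``use_midpoints=True`` switches to a count-weighted mean of class
    midpoints, for comparison).
    """
    counts = np.asarray(dist.counts)
    peak = int(counts.max())
    maxima = np.flatnonzero(counts == peak)
    lo, hi = int(maxima.min()), int(maxima.max())
    thr = 0.5 * peak
    while lo - 1 >= 0 and counts[lo - 1] > thr:
        lo -= 1
    while hi + 1 < len(counts) and counts[hi + 1] > thr:
        hi += 1

    sel = (dist.class_index >= lo) & (dist.class_index <= hi)
    vals = dist.values[sel]
    n_inc = int(sel.sum())
    if use_midpoints:
        centers = dist.centers[lo : hi + 1]
        w = counts[lo : hi + 1]
        mean = float(np.average(centers, weights=w))
        var = float(np.average((centers - mean) ** 2, weights=w))
        sd = math.sqrt(var * n_inc / (n_inc - 1)) if n_inc > 1 else 0.0
    else:
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n_inc > 1 else 0.0
    return PeakClassEstimate(
        included_class_indices=(lo, hi),
        mean_pg=mean,
        sd_pg=sd,
        n_included=n_inc,
        n_total=int(counts.sum()),
        fraction_included=n_inc / int(counts.sum()),
    )


def all_nuclei_mean(values) -> tuple[float, float]:
    """Arithmetic mean and sample SD over every nucleus."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("values must be nonempty")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return mean, sd


def assign_c_class(
    pg: float, reference_1C: float, tolerance: float = 0.25
) -> CValueCall:
    """Place a DNA content on the 1C..16C ladder relative to a 1C reference.

    The class is the nearest ladder point in log2 distance, i.e. class
    boundaries sit at the geometric midpoints sqrt(2)*1C, 2*sqrt(2)*1C, ...;
    exact midpoints resolve upward.  ``in_tolerance`` records whether the
    log2 deviation from the called class is within ``tolerance``.
    """
    if not reference_1C > 0:
        raise ValueError("reference_1C must be > 0")
    if not pg > 0:
        raise ValueError("pg must be > 0")
    ratio = pg / reference_1C
    l2 = math.log2(ratio)
    best = LADDER[0]
    best_d = abs(l2 - 0.0)
    for c in LADDER[1:]:
        d = abs(l2 - math.log2(c))
        if d <= best_d + 1e-12:  # ties resolve to the higher class
            best, best_d = c, d
    return CValueCall(
        pg=float(pg),
        ratio_to_1C=float(ratio),
        c_class=int(best),
        in_tolerance=abs(l2 - math.log2(best)) <= tolerance,
    )


def class_fraction_flags(
    calls: list[CValueCall], main_class: int, plus_threshold: float = 0.05
) -> dict[int, str]:
    """Flag minor higher-ploidy subpopulations: "" absent, "+" minor, "++" abundant.

    For each ladder class above ``main_class``: "" if no nucleus was called
    there, "+" if the fraction is positive but at most ``plus_threshold``,
    "++" if it exceeds it.
    """
    if not calls:
        raise ValueError("calls must be nonempty")
    if main_class not in LADDER:
        raise ValueError(f"main_class must be one of {LADDER}")
    total = len(calls)
    flags: dict[int, str] = {}
    for c in LADDER:
        if c <= main_class:
            continue
        frac = sum(1 for call in calls if call.c_class == c) / total
        flags[c] = "" if frac == 0 else ("+" if frac <= plus_threshold else "++")
    return flags


def pg_to_mb(pg):
    """Convert picograms of DNA to megabase pairs (1 pg = 980 Mb)."""
    arr = np.asarray(pg, dtype=float)
    if np.any(arr < 0):
        raise ValueError("pg must be >= 0")
    mb = MB_PER_PG * arr
    return float(mb) if np.ndim(pg) == 0 else mb


def stage_ratio(mean_a: float, mean_b: float) -> float:
    """Ratio of two stage means rounded to one decimal (half away from zero)."""
    if not mean_b > 0:
        raise ValueError("mean_b must be > 0")
    q = Decimal(repr(mean_a / mean_b)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(q)
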