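"""Intensity-to-picogram calibration against a constant-DNA internal standard.

The method is single-ratio by construction: co-stained erythrocyte nuclei of
known, constant DNA content (2.4 pg for chicken) provide a mean IOD, and any
sample IOD converts to picograms as ``standard_pg * iod / mean_iod``.  No
multi-point curve is fitted because DAPI fluorescence is linear in DNA
amount over the measured range.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["CalibrationStandard", "CalibrationError", "fit_standard", "to_picograms"]


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationStandard:
    """The fitted reference population: its known pg and mean IOD."""

    standard_pg: float
    iods: list[float]
    mean_iod: float
    cv: float
    n: int
    trim: float = 0.1
    provenance: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationStandard":
        return cls(**json.loads(Path(path).read_text()))


def fit_standard(
    measurements,
    standard_pg: float = 2.4,
    trim: float = 0.1,
) -> CalibrationStandard:
    """Fit the calibration standard from measured nuclei.

    ``measurements`` is either a list of objects with ``iod`` and
    ``is_standard`` attributes (only flagged ones are used), or a plain
    sequence/array of standard IODs.  The mean IOD is a two-sided trimmed
    mean (10% by default) to damp the occasional mis-segmented standard.
    """
    seq = list(measurements) if not np.isscalar(measurements) else [measurements]
    if seq and hasattr(seq[0], "iod"):
        iods = [float(m.iod) for m in seq if getattr(m, "is_standard", False)]
        if not iods:
            raise CalibrationError(
                "no measurements flagged is_standard; cannot calibrate"
            )
    else:
        iods = [float(x) for x in seq]
        if not iods:
            raise CalibrationError("empty standard IOD list; cannot calibrate")

    arr = np.asarray(iods, dtype=float)
    if len(arr) == 1:
        logger.warning("calibrating from a single standard nucleus; cv undefined")
        mean_iod = float(arr[0])
        cv = 0.0
    else:
        mean_iod = float(stats.trim_mean(arr, proportiontocut=trim))
        cv = float(np.std(arr, ddof=1) / np.mean(arr))
    if not mean_iod > 0:
        raise CalibrationError(f"standard mean IOD must be > 0, got {mean_iod}")
    if not standard_pg > 0:
        raise CalibrationError("standard_pg must be > 0")
    return CalibrationStandard(
        standard_pg=float(standard_pg),
        iods=iods,
        mean_iod=mean_iod,
        cv=cv,
        n=len(iods),
        trim=trim,
    )


def to_picograms(iod, cal: CalibrationStandard):
    """Convert IOD(s) to picograms: ``pg = standard_pg * iod / mean_iod``.

    Exactly linear and homogeneous; negative IODs are clipped to zero with a
    warning (they can only arise from over-subtracted background).
    """
    if not cal.mean_iod > 0:
        raise CalibrationError("calibration has non-positive mean IOD")
    arr = np.asarray(iod, dtype=float)
    if np.any(arr < 0):
        logger.warning("negative IOD(s) clipped to 0 before conversion")
        arr = np.clip(arr, 0.0, None)
    pg = cal.standard_pg * arr / cal.mean_iod
    if np.isscalar(iod) or np.ndim(iod) == 0:
        return float(pg)
    return pg
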