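"""Colony-size to cell-number calibration and day-0 anchoring.

Colony area in pixels maps to cell number through a log-log linear model,

    log10(cells) = slope * log10(size_px) + intercept,

fitted to hemacytometer counts of excised colonies.  The published
coefficients (slope 1.46397, intercept 3.19251) ship as
:data:`PUBLISHED_CALIBRATION` so the conversion is reproducible bit-exactly
without recalibrating.  Every colony's day-0 size is anchored to the mean
pinned size (57 px, 579,506 cells): the imaging software zeroes out colonies
it cannot segment, and those records must be adjudicated (small-but-present
vs. absent) by an explicit flag before fitness estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationModel",
    "PUBLISHED_CALIBRATION",
    "Status",
    "fit_calibration",
    "size_to_cells",
    "cells_to_size",
    "anchor_day0",
]


class Status(str, Enum):
    """QC status of one colony observation."""

    OK = "OK"
    RESET_TO_DAY0 = "RESET_TO_DAY0"
    DISCARD = "DISCARD"


@dataclass(frozen=True)
class CalibrationModel:
    """log10(cells) = slope*log10(size_px) + intercept, plus day-0 anchors.

    Parameters
    ----------
    slope
        log10-cells per log10-pixel; must be positive (more pixels, more cells).
    intercept
        log10 cells at 1 px.
    r_squared
        Coefficient of determination of the fit (NaN if unknown).
    day0_size
        Mean colony size at pinning, pixels.
    """

    slope: float
    intercept: float
    r_squared: float = float("nan")
    day0_size: float = 57.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope}")
        if not self.day0_size > 0:
            raise ValueError("day0_size must be positive")

    @property
    def day0_cells(self) -> float:
        """Cell number at the day-0 anchor size, from the regression."""
        return float(size_to_cells(self.day0_size, self))

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "day0_size": self.day0_size,
            "day0_cells": self.day0_cells,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            r_squared=float(d.get("r_squared", float("nan"))),
            day0_size=float(d.get("day0_size", 57.0)),
        )


#: Published calibration: log10(Cells) = log10(Size)*1.46397 + 3.19251,
#: with a 57-px day-0 anchor (579,506 cells).  R^2 as reported for the
#: original calibration data set.
PUBLISHED_CALIBRATION = CalibrationModel(
    slope=1.46397, intercept=3.19251, r_squared=0.9689, day0_size=57.0
)


def fit_calibration(
    sizes, cells, day0_size: float = 57.0
) -> CalibrationModel:
    """OLS of log10(cells) on log10(size_px).

    Requires at least 3 strictly positive (size, cells) pairs.
    """
    sizes = np.asarray(sizes, dtype=float)
    cells = np.asarray(cells, dtype=float)
    if sizes.shape != cells.shape or sizes.ndim != 1:
        raise ValueError("sizes and cells must be 1-d arrays of equal length")
    if sizes.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.any(sizes <= 0) or np.any(cells <= 0):
        raise ValueError("calibration sizes and cell counts must be positive")
    res = stats.linregress(np.log10(sizes), np.log10(cells))
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        day0_size=day0_size,
    )


def size_to_cells(size, model: CalibrationModel = PUBLISHED_CALIBRATION):
    """Convert colony size in pixels to cell number (strictly increasing)."""
    size = np.asarray(size, dtype=float)
    if np.any(size <= 0):
        raise ValueError("size must be positive; anchor/QC zero-size records first")
    out = 10.0 ** (np.log10(size) * model.slope + model.intercept)
    return float(out) if out.ndim == 0 else out


def cells_to_size(cells, model: CalibrationModel = PUBLISHED_CALIBRATION):
    """Inverse of :func:`size_to_cells` along the same regression line."""
    cells = np.asarray(cells, dtype=float)
    if np.any(cells <= 0):
        raise ValueError("cell counts must be positive")
    out = 10.0 ** ((np.log10(cells) - model.intercept) / model.slope)
    return float(out) if out.ndim == 0 else out


# Long-format colony table columns used throughout the package.
COLONY_COLUMNS = [
    "plate_id", "condition", "day", "row", "col", "strain", "replicate",
    "size_px", "status",
]

#: zero_flag values accepted for size-0 records: the record is re-incorporated
#: at the day-0 size if a small colony was visually present, or the whole
#: trajectory is discarded if the colony was absent or morphologically
#: complicated.
ZERO_FLAGS = {"present", "absent", "complicated"}


def anchor_day0(
    observations: pd.DataFrame, model: CalibrationModel = PUBLISHED_CALIBRATION
) -> pd.DataFrame:
    """Anchor day-0 sizes and adjudicate zero-size records.

    Rules, applied per colony (plate_id, condition, row, col):

    * every day-0 record's size is set to ``model.day0_size``;
    * a later-day size-0 record flagged ``present`` is reset to the day-0
      size with status ``RESET_TO_DAY0``;
    * a size-0 record flagged ``absent`` or ``complicated`` marks the whole
      colony trajectory ``DISCARD`` (excluded from downstream fitness);
    * an unflagged size-0 record is an error — the adjudication is a manual
      call this software refuses to guess.

    Returns a copy; input order is preserved.
    """
    df = observations.copy()
    if "status" not in df:
        df["status"] = Status.OK.value
    if "zero_flag" not in df:
        df["zero_flag"] = None
    df["size_px"] = df["size_px"].astype(float)

    zero = df["size_px"] == 0
    unflagged = zero & ~df["zero_flag"].isin(ZERO_FLAGS)
    if unflagged.any():
        idx = df.index[unflagged][0]
        raise ValueError(
            f"size-0 record at index {idx} has no valid zero_flag "
            f"(expected one of {sorted(ZERO_FLAGS)}); adjudicate before anchoring"
        )
    bad_flag = ~zero & df["zero_flag"].isin({"absent", "complicated"})
    if bad_flag.any():
        idx = df.index[bad_flag][0]
        raise ValueError(
            f"record at index {idx} has size > 0 but an absent/complicated flag; "
            "conflicting flags rejected"
        )

    present = zero & (df["zero_flag"] == "present")
    df.loc[present, "size_px"] = model.day0_size
    df.loc[present, "status"] = Status.RESET_TO_DAY0.value

    gone = zero & df["zero_flag"].isin({"absent", "complicated"})
    if gone.any():
        colony_keys = ["plate_id", "condition", "row", "col"]
        bad = df.loc[gone, colony_keys].drop_duplicates()
        merged = df[colony_keys].merge(bad.assign(_discard=True), how="left",
                                       on=colony_keys)
        df.loc[merged["_discard"].eq(True).to_numpy(), "status"] = (
            Status.DISCARD.value
        )

    day0 = (df["day"] == 0) & (df["status"] != Status.DISCARD.value)
    df.loc[day0, "size_px"] = model.day0_size
    return df
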