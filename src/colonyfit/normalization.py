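"""Spatial (edge-effect) normalization of plate colony sizes.

Colonies at the plate perimeter grow larger than interior replicates.  The
default correction scales each colony multiplicatively to the plate-wide
grand statistic, first by row then by column (statistics recomputed between
passes); a per-layer variant and an additive row/column variant are also
provided.  Residual spatial structure is quantified as one-way-ANOVA variance
explained, and per-layer deviation from the plate center is tested with
two-sample t-tests under Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .plate import PlateFormat, get_format, is_plate_corner, max_layer
from .stats import bh_fdr

__all__ = [
    "SizeMatrix",
    "rowcol_normalize",
    "layer_normalize",
    "variance_explained",
    "layer_effect_test",
]


class NormalizationError(ValueError):
    """A row, column or layer cannot support the requested normalization."""


@dataclass
class SizeMatrix:
    """Per-plate, per-day colony sizes on the plate grid.

    ``values[r, c]`` is the size in pixels; ``mask[r, c]`` True marks a
    position excluded from all statistics (corners, discarded colonies,
    empty wells).
    """

    format: PlateFormat
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.format = get_format(self.format)
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.format.n_rows, self.format.n_cols)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != format {expected}")
        if self.mask is None:
            self.mask = np.zeros(expected, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != expected:
            raise ValueError("mask shape does not match format")

    @property
    def masked_values(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=self.mask)

    def layer_indices(self) -> np.ndarray:
        r = np.arange(self.format.n_rows)[:, None]
        c = np.arange(self.format.n_cols)[None, :]
        return np.minimum.reduce(
            [np.broadcast_to(r, self.values.shape),
             np.broadcast_to(c, self.values.shape),
             np.broadcast_to(self.format.n_rows - 1 - r, self.values.shape),
             np.broadcast_to(self.format.n_cols - 1 - c, self.values.shape)]
        )

    def copy(self) -> "SizeMatrix":
        return SizeMatrix(self.format, self.values.copy(), self.mask.copy())

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        fmt: "PlateFormat | str | int",
        exclude_corners: bool = True,
        exclude_discard: bool = True,
    ) -> "SizeMatrix":
        """Build from a long-format table holding one plate-day."""
        fmt = get_format(fmt)
        values = np.full((fmt.n_rows, fmt.n_cols), np.nan)
        mask = np.ones((fmt.n_rows, fmt.n_cols), dtype=bool)
        for _, rec in df.iterrows():
            r, c = int(rec["row"]), int(rec["col"])
            values[r, c] = float(rec["size_px"])
            discard = exclude_discard and str(rec.get("status", "OK")) == "DISCARD"
            corner = exclude_corners and is_plate_corner(r, c, fmt)
            mask[r, c] = discard or corner
        return cls(fmt, values, mask)


def _axis_stat(ma: np.ma.MaskedArray, axis: int, stat: str) -> np.ndarray:
    if stat == "mean":
        return np.ma.mean(ma, axis=axis)
    if stat == "median":
        return np.ma.median(ma, axis=axis)
    raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")


def _grand_stat(ma: np.ma.MaskedArray, stat: str) -> float:
    return float(np.ma.mean(ma) if stat == "mean" else np.ma.median(ma))


def _one_pass(m: SizeMatrix, axis: int, stat: str) -> SizeMatrix:
    """Scale each line (row if axis=1, column if axis=0) to the grand stat."""
    ma = m.masked_values
    line = _axis_stat(ma, axis=axis, stat=stat)
    kind = "row" if axis == 1 else "column"
    counts = (~m.mask).sum(axis=axis)
    empty = np.where(counts == 0)[0]
    if empty.size:
        raise NormalizationError(f"{kind} {empty[0]} is entirely masked")
    zero = np.where(np.asarray(line) == 0)[0]
    if zero.size:
        raise NormalizationError(f"{kind} {zero[0]} has zero {stat}; cannot rescale")
    grand = _grand_stat(ma, stat)
    factors = grand / np.asarray(line, dtype=float)
    out = m.values * (factors[:, None] if axis == 1 else factors[None, :])
    return SizeMatrix(m.format, out, m.mask.copy())


def rowcol_normalize(
    m: SizeMatrix, stat: str = "mean", method: str = "multiplicative"
) -> SizeMatrix:
    """Normalize colony sizes to the row- and column-wide plate statistic.

    Two sequential passes: each value is scaled by grand/row statistic of its
    row, then (statistics recomputed) by grand/column statistic of its column.
    With ``stat='mean'`` the output column means equal the output grand mean
    exactly.  ``method='additive'`` instead subtracts row and column means and
    adds back the grand mean in one step.
    """
    if method == "additive":
        ma = m.masked_values
        grand = _grand_stat(ma, "mean")
        row = np.asarray(np.ma.mean(ma, axis=1), dtype=float)
        col = np.asarray(np.ma.mean(ma, axis=0), dtype=float)
        if np.isnan(row).any() or np.isnan(col).any():
            raise NormalizationError("a row or column is entirely masked")
        out = m.values - row[:, None] - col[None, :] + grand
        return SizeMatrix(m.format, out, m.mask.copy())
    if method != "multiplicative":
        raise ValueError("method must be 'multiplicative' or 'additive'")
    return _one_pass(_one_pass(m, axis=1, stat=stat), axis=0, stat=stat)


def layer_normalize(m: SizeMatrix) -> SizeMatrix:
    """Scale each value by grand-mean / mean of its concentric layer."""
    layers = m.layer_indices()
    ma = m.masked_values
    grand = float(np.ma.mean(ma))
    out = m.values.copy()
    for layer in range(max_layer(m.format) + 1):
        sel = (layers == layer) & ~m.mask
        if not sel.any():
            raise NormalizationError(f"layer {layer} is entirely masked")
        lmean = m.values[sel].mean()
        if lmean == 0:
            raise NormalizationError(f"layer {layer} has zero mean")
        out[layers == layer] *= grand / lmean
    return SizeMatrix(m.format, out, m.mask.copy())


def variance_explained(values, labels) -> float:
    """One-way ANOVA R^2 = SS_between / SS_total of values grouped by label."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be 1-d and the same length")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 groups")
    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())
    if ss_total == 0:
        raise ValueError("zero total variance")
    group_means = pd.Series(values).groupby(pd.Series(labels)).transform("mean")
    ss_within = float(((values - group_means.to_numpy()) ** 2).sum())
    return 1.0 - ss_within / ss_total


def layer_effect_test(m: SizeMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Welch two-sample t-test of each outer layer against the center layer.

    Returns one row per non-center layer with columns
    ``layer, n, center_n, mean, center_mean, t, p, q, significant, testable``;
    q-values are Benjamini-Hochberg over the testable layers.  A layer with
    fewer than 2 unmasked values is reported untestable rather than dropped.
    """
    layers = m.layer_indices()
    center = max_layer(m.format)
    center_vals = m.values[(layers == center) & ~m.mask]
    if center_vals.size < 2:
        raise ValueError("center layer needs at least 2 unmasked values")
    if np.ptp(m.values[~m.mask]) == 0:
        raise ValueError("plate has zero variance; layer test undefined")
    rows = []
    for layer in range(center):
        vals = m.values[(layers == layer) & ~m.mask]
        testable = vals.size >= 2
        if testable:
            t, p = stats.ttest_ind(vals, center_vals, equal_var=False)
        else:
            t, p = np.nan, np.nan
        rows.append(
            {"layer": layer, "n": int(vals.size), "center_n": int(center_vals.size),
             "mean": vals.mean() if vals.size else np.nan,
             "center_mean": center_vals.mean(), "t": float(t), "p": float(p),
             "testable": testable}
        )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    ok = out["testable"]
    if ok.any():
        out.loc[ok, "q"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out
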