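"""Selection coefficients from colony-size trajectories.

Normalized colony sizes are converted to cell numbers and regressed, on a
log scale, against the number of *ancestor generations* — the cumulative
doublings log2(N_i/N_0) of the ancestor strains on the same plate and
condition, averaged over ancestor replicates per day.  The slope of that
regression is the strain's per-generation Malthusian growth rate; the
fitness difference of an evolved replicate (its selection coefficient) is
its slope minus the mean slope of the evolved strain's ancestor pair.

With the natural-log response (default) the slope is directly comparable to
the competitive assay's ln(strain/reference)-per-generation slope; with
``base='log2'`` an ancestor regressed on its own axis has slope exactly 1,
so a slope difference reads as a per-generation doubling advantage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationModel, PUBLISHED_CALIBRATION, Status, size_to_cells

__all__ = [
    "generations",
    "GenerationAxis",
    "FitnessEstimate",
    "sizes_to_cells",
    "analyze_plate",
    "build_generation_axis",
    "malthusian_slope",
    "fitness_difference",
    "fitness_table",
    "fitness_by_day_window",
    "size_ratio_fitness_relation",
]

_LOG = {"ln": math.log, "log2": math.log2}


def generations(n_i, n_0):
    """Ancestor generations elapsed between two population sizes: log2(n_i/n_0)."""
    n_i = np.asarray(n_i, dtype=float)
    n_0 = np.asarray(n_0, dtype=float)
    if np.any(n_i <= 0) or np.any(n_0 <= 0):
        raise ValueError("cell counts must be positive")
    out = np.log2(n_i / n_0)
    return float(out) if out.ndim == 0 else out


@dataclass
class GenerationAxis:
    """Shared time axis in ancestor doublings for one plate/condition."""

    condition: str
    g_by_day: dict[int, float]
    ancestor_strains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if 0 not in self.g_by_day or abs(self.g_by_day[0]) > 1e-12:
            raise ValueError("generation axis must start at g(0) = 0")

    def g(self, days) -> np.ndarray:
        return np.array([self.g_by_day[int(d)] for d in days], dtype=float)


@dataclass
class FitnessEstimate:
    """Per-replicate selection coefficient and the slopes it came from."""

    strain: str
    condition: str
    replicate: int
    s: float
    evolved_slope: float
    ancestor_mean_slope: float
    n_days: int
    log_base: str


def sizes_to_cells(
    df: pd.DataFrame, model: CalibrationModel = PUBLISHED_CALIBRATION
) -> pd.DataFrame:
    """Add a ``cells`` column to a long colony table; DISCARD rows get NaN."""
    out = df.copy()
    keep = out.get("status", pd.Series(Status.OK.value, index=out.index)) != (
        Status.DISCARD.value
    )
    out["cells"] = np.nan
    out.loc[keep, "cells"] = size_to_cells(out.loc[keep, "size_px"].to_numpy(), model)
    return out


def _trajectories(df: pd.DataFrame) -> "pd.core.groupby.DataFrameGroupBy":
    keys = ["plate_id", "row", "col"]
    return df.groupby(keys, sort=True)


def build_generation_axis(ancestors: pd.DataFrame, condition: str = "") -> GenerationAxis:
    """Average per-replicate log2(N_day/N_0) over all ancestor trajectories.

    ``ancestors`` is a long cells table (columns day, cells plus the colony
    identity columns plate_id/row/col/strain) holding only ancestor-strain
    rows with valid cells.  Both members of the ancestor pair are pooled.
    """
    anc = ancestors.dropna(subset=["cells"])
    if anc.empty:
        raise ValueError("no ancestor data to build a generation axis from")
    per_day: dict[int, list[float]] = {}
    n_multi = 0
    for _, traj in _trajectories(anc):
        traj = traj.sort_values("day")
        days = traj["day"].to_numpy(dtype=int)
        if days[0] != 0:
            raise ValueError("every ancestor trajectory needs a day-0 record")
        cells = traj["cells"].to_numpy(dtype=float)
        if len(days) >= 2:
            n_multi += 1
        g = generations(cells, cells[0])
        for d, gi in zip(days, np.atleast_1d(g)):
            per_day.setdefault(int(d), []).append(float(gi))
    if n_multi < 1:
        raise ValueError("need at least one ancestor trajectory with >= 2 days")
    g_by_day = {d: float(np.mean(v)) for d, v in sorted(per_day.items())}
    return GenerationAxis(
        condition=condition, g_by_day=g_by_day,
        ancestor_strains=tuple(sorted(anc["strain"].unique())),
    )


def malthusian_slope(
    days, cells, axis: GenerationAxis, base: str = "ln"
) -> float:
    """OLS slope of log(cells) on ancestor generations for one trajectory.

    An ancestor regressed on its own exact axis has slope ln 2 (base='ln')
    or 1 (base='log2').
    """
    if base not in _LOG:
        raise ValueError("base must be 'ln' or 'log2'")
    days = np.asarray(days, dtype=int)
    cells = np.asarray(cells, dtype=float)
    g = axis.g(days)
    if len(np.unique(g)) < 2:
        raise ValueError("degenerate generation axis: fewer than 2 distinct g values")
    logc = np.log(cells) if base == "ln" else np.log2(cells)
    return float(stats.linregress(g, logc).slope)


def _one_trajectory_slope(traj: pd.DataFrame, axis: GenerationAxis,
                          base: str, last_day: "int | None") -> "float | None":
    traj = traj.dropna(subset=["cells"]).sort_values("day")
    if last_day is not None:
        traj = traj[traj["day"] <= last_day]
    if len(traj) < 2:
        return None
    return malthusian_slope(traj["day"], traj["cells"], axis, base=base)


def fitness_difference(
    evolved: pd.DataFrame,
    ancestors: pd.DataFrame,
    base: str = "ln",
    axis: "GenerationAxis | None" = None,
    last_day: "int | None" = None,
) -> FitnessEstimate:
    """Selection coefficient of a single evolved trajectory vs its ancestors.

    ``evolved`` holds one colony's rows; ``ancestors`` holds all ancestor
    trajectories of the same plate/condition.  s = evolved slope minus the
    mean of the per-replicate ancestor slopes.
    """
    if axis is None:
        axis = build_generation_axis(ancestors)
    anc_slopes = [
        sl for _, traj in _trajectories(ancestors)
        if (sl := _one_trajectory_slope(traj, axis, base, last_day)) is not None
    ]
    if not anc_slopes:
        raise ValueError("no usable ancestor trajectory")
    ev = evolved.dropna(subset=["cells"])
    if ev.empty or (ev.get("status") == Status.DISCARD.value).all():
        raise ValueError("evolved trajectory discarded; no estimate")
    slope = _one_trajectory_slope(ev, axis, base, last_day)
    if slope is None:
        raise ValueError("evolved trajectory has fewer than 2 usable days")
    anc_mean = float(np.mean(anc_slopes))
    n_days = int(ev["day"].nunique() if last_day is None
                 else ev[ev["day"] <= last_day]["day"].nunique())
    return FitnessEstimate(
        strain=str(ev["strain"].iloc[0]),
        condition=str(ev["condition"].iloc[0]) if "condition" in ev else "",
        replicate=int(ev["replicate"].iloc[0]) if "replicate" in ev else 1,
        s=slope - anc_mean,
        evolved_slope=slope,
        ancestor_mean_slope=anc_mean,
        n_days=n_days,
        log_base=base,
    )


def fitness_table(
    cells_df: pd.DataFrame,
    ancestor_strains: "list[str] | tuple[str, ...]",
    base: str = "ln",
    last_day: "int | None" = None,
) -> pd.DataFrame:
    """Per-replicate selection coefficients for every evolved colony.

    Groups the long cells table by (plate_id, condition); within each group
    the ancestor strains define the generation axis and the mean ancestor
    slope, and each non-ancestor colony yields one row.
    """
    ancestor_strains = {str(s) for s in ancestor_strains}
    rows = []
    for (plate, cond), grp in cells_df.groupby(["plate_id", "condition"], sort=True):
        ok = grp[grp.get("status", "OK") != Status.DISCARD.value].dropna(
            subset=["cells"])
        anc = ok[ok["strain"].isin(ancestor_strains)]
        axis = build_generation_axis(anc, condition=str(cond))
        anc_slopes = [
            sl for _, traj in _trajectories(anc)
            if (sl := _one_trajectory_slope(traj, axis, base, last_day)) is not None
        ]
        anc_mean = float(np.mean(anc_slopes))
        for _, traj in _trajectories(ok[~ok["strain"].isin(ancestor_strains)]):
            slope = _one_trajectory_slope(traj, axis, base, last_day)
            if slope is None:
                continue
            rows.append(
                {"plate_id": plate, "condition": cond,
                 "strain": str(traj["strain"].iloc[0]),
                 "replicate": int(traj["replicate"].iloc[0])
                 if "replicate" in traj else 1,
                 "row": int(traj["row"].iloc[0]), "col": int(traj["col"].iloc[0]),
                 "s": slope - anc_mean, "evolved_slope": slope,
                 "ancestor_mean_slope": anc_mean,
                 "days_used": int(traj["day"].nunique() if last_day is None
                                  else traj[traj["day"] <= last_day]["day"].nunique()),
                 "log_base": base}
            )
    if not rows:
        raise ValueError("no evolved trajectories with >= 2 usable days")
    return pd.DataFrame(rows)


def fitness_by_day_window(
    cells_df: pd.DataFrame,
    ancestor_strains,
    last_day: int,
    base: str = "ln",
) -> pd.DataFrame:
    """Selection coefficients restricted to days 0..last_day (1-4)."""
    if not 1 <= int(last_day):
        raise ValueError("last_day must be >= 1")
    return fitness_table(cells_df, ancestor_strains, base=base, last_day=int(last_day))


def analyze_plate(
    observations: pd.DataFrame,
    ancestor_strains,
    fmt: str = "384",
    model: CalibrationModel = PUBLISHED_CALIBRATION,
    normalize: "str | None" = "rowcol-mean",
    exclude_corners: bool = True,
    base: str = "ln",
    last_day: "int | None" = None,
) -> pd.DataFrame:
    """Full colony pipeline: anchor -> (normalize) -> corners out -> cells -> s.

    ``normalize`` is one of 'rowcol-mean', 'rowcol-median', 'layer' or None
    (skip spatial correction).  Returns the per-replicate fitness table.
    """
    from .calibration import anchor_day0
    from .normalization import SizeMatrix, layer_normalize, rowcol_normalize
    from .plate import is_plate_corner

    df = anchor_day0(observations, model)
    pieces = []
    for _, grp in df.groupby(["plate_id", "condition", "day"], sort=True):
        grp = grp.copy()
        if normalize is not None:
            m = SizeMatrix.from_long(grp, fmt, exclude_corners=exclude_corners)
            if normalize == "layer":
                nm = layer_normalize(m)
            elif normalize in ("rowcol-mean", "rowcol-median"):
                nm = rowcol_normalize(m, stat=normalize.split("-")[1])
            else:
                raise ValueError(f"unknown normalization {normalize!r}")
            grp["size_px"] = [nm.values[int(r), int(c)]
                              for r, c in zip(grp["row"], grp["col"])]
        if exclude_corners:
            keep = [not is_plate_corner(int(r), int(c), fmt)
                    for r, c in zip(grp["row"], grp["col"])]
            grp = grp[keep]
        pieces.append(grp)
    cells = sizes_to_cells(pd.concat(pieces, ignore_index=True), model)
    return fitness_table(cells, ancestor_strains, base=base, last_day=last_day)


def size_ratio_fitness_relation(
    fitness_df: pd.DataFrame,
    sizes_df: pd.DataFrame,
    ancestor_strains,
    day: int = 4,
) -> pd.DataFrame:
    """Per-condition regression of s on the log evolved/ancestor size ratio.

    The log ratio divides each evolved replicate's day-``day`` colony size by
    the mean ancestor size on the same plate/condition.  Fitness measured per
    generation is expected to be linear in this ratio, with a steeper slope
    where the ancestors completed fewer generations.
    """
    ancestor_strains = {str(s) for s in ancestor_strains}
    day_sizes = sizes_df[(sizes_df["day"] == day)
                         & (sizes_df.get("status", "OK") != Status.DISCARD.value)]
    rows = []
    for (plate, cond), grp in day_sizes.groupby(["plate_id", "condition"]):
        anc_mean = grp[grp["strain"].isin(ancestor_strains)]["size_px"].mean()
        ev = grp[~grp["strain"].isin(ancestor_strains)].copy()
        ev["log_size_ratio"] = np.log(ev["size_px"] / anc_mean)
        rows.append(ev[["plate_id", "condition", "row", "col", "log_size_ratio"]])
    ratios = pd.concat(rows, ignore_index=True)
    merged = fitness_df.merge(ratios, on=["plate_id", "condition", "row", "col"])
    out = []
    for cond, grp in merged.groupby("condition"):
        if len(grp) < 3:
            raise ValueError(f"condition {cond!r} has fewer than 3 replicate points")
        if np.ptp(grp["log_size_ratio"].to_numpy()) == 0:
            raise ValueError(f"condition {cond!r} has zero spread in size ratios")
        res = stats.linregress(grp["log_size_ratio"], grp["s"])
        out.append({"condition": cond, "slope": float(res.slope),
                    "intercept": float(res.intercept),
                    "r_squared": float(res.rvalue**2), "n": len(grp)})
    return pd.DataFrame(out)
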