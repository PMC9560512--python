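"""Competitive fitness from flow cytometry against a YFP-marked reference.

Each strain is co-cultured with a common YFP-expressing reference and
sampled daily.  Events pass two ellipse gates — a 99% Mahalanobis ellipse on
log10(SSC-A) x log10(FSC-A) that removes debris, then a 95% ellipse on
FSC-H x Width that removes doublets — before YFP classification against a
threshold set at the midpoint between the two largest peaks of the log10
YFP-A histogram (and then held constant across samples).  Reference-only
controls estimate the fraction f of marked cells falling below the
threshold, and the unmarked:reference ratio is corrected as

    strain/reference = Total * (1 - f) / P - 1        (P = YFP-positive count)

since the true number of marked cells is P/(1-f).  The selection
coefficient is the OLS slope of ln(strain/reference) on cumulative
generations, with generations per daily 1/1000-dilution cycle computed from
the change in cell concentration as log2(conc_end / (conc_prev_end * dilution)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GateSet",
    "CompetitionSeries",
    "ellipse_gate",
    "fit_ellipse",
    "apply_ellipse",
    "yfp_threshold",
    "fit_gates",
    "apply_gates",
    "false_negative_fraction",
    "strain_ratio",
    "generations_elapsed",
    "cumulative_generations",
    "selection_coefficient",
    "analyze_competition",
]

FLOW_CHANNELS = ["fsc_a", "ssc_a", "fsc_h", "width", "yfp_a"]


class GatingError(ValueError):
    """Raised when a gate cannot be constructed or applied."""


def fit_ellipse(x, y, robust: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Sample mean and covariance of a 2-d cloud (MCD-free 'robust' trims 1%)."""
    pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    if len(pts) < 10:
        raise GatingError("need at least 10 events to fit an ellipse gate")
    if not np.all(np.isfinite(pts)):
        raise GatingError("non-finite channel values; transform/clean first")
    if robust:
        med = np.median(pts, axis=0)
        d = np.linalg.norm(pts - med, axis=1)
        pts = pts[d <= np.quantile(d, 0.99)]
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    if np.linalg.det(cov) <= np.finfo(float).tiny:
        raise GatingError("singular covariance (constant channel?); cannot gate")
    return mean, cov


def apply_ellipse(x, y, mean, cov, level: float) -> np.ndarray:
    """Mask of events inside the chi-square(2) Mahalanobis ellipse at `level`."""
    if not 0 < level < 1:
        raise GatingError("ellipse level must lie in (0, 1)")
    pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    diff = pts - np.asarray(mean, float)
    inv = np.linalg.inv(np.asarray(cov, float))
    d2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
    return d2 <= stats.chi2.ppf(level, df=2)


def ellipse_gate(x, y, level: float, robust: bool = False) -> np.ndarray:
    """Fit an ellipse to (x, y) and return the keep-mask at `level`."""
    mean, cov = fit_ellipse(x, y, robust=robust)
    return apply_ellipse(x, y, mean, cov, level)


def yfp_threshold(log_yfp, bins: int = 256, smooth: int = 9,
                  min_prominence: float = 0.05) -> float:
    """Midpoint between the two largest histogram peaks of log10 YFP-A.

    The histogram is smoothed with a centered moving average (``smooth``
    bins) so that Poisson bin noise does not split one population into
    several local maxima; candidate peaks must reach ``min_prominence`` of
    the tallest peak to rule out tail bumps.  The two largest remaining
    maxima must be separated by more than one bin.  A unimodal histogram
    raises — set the threshold manually in that case, as was done for the
    original instrument data.
    """
    log_yfp = np.asarray(log_yfp, dtype=float)
    if log_yfp.size < 100:
        raise GatingError("need at least 100 events to place a YFP threshold")
    counts, edges = np.histogram(log_yfp, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        counts = np.convolve(counts.astype(float), kernel, mode="same")
    inner = (counts[1:-1] > counts[:-2]) & (counts[1:-1] >= counts[2:])
    peaks = np.where(inner)[0] + 1
    peaks = peaks[counts[peaks] >= min_prominence * counts.max()]
    if len(peaks) < 2:
        raise GatingError("YFP histogram looks unimodal; supply a manual threshold")
    top = peaks[np.argsort(counts[peaks])[::-1]]
    first = top[0]
    second = None
    for cand in top[1:]:
        if abs(cand - first) <= 1:
            continue
        lo, hi = sorted((first, cand))
        valley = counts[lo:hi + 1].min()
        # a genuine second population has a real dip between the two modes
        if valley < 0.5 * min(counts[first], counts[cand]):
            second = cand
            break
    if second is None:
        raise GatingError(
            "no two distinct populations separated by a valley; "
            "supply a manual threshold"
        )
    return float(0.5 * (centers[first] + centers[second]))


@dataclass
class GateSet:
    """Fitted gates: scatter ellipse, singlet ellipse and YFP threshold."""

    scatter_mean: np.ndarray
    scatter_cov: np.ndarray
    singlet_mean: np.ndarray
    singlet_cov: np.ndarray
    yfp_threshold: float
    scatter_level: float = 0.99
    singlet_level: float = 0.95


def _scatter_xy(events: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    ssc = events["ssc_a"].to_numpy(dtype=float)
    fsc = events["fsc_a"].to_numpy(dtype=float)
    if np.any(ssc <= 0) or np.any(fsc <= 0):
        raise GatingError("scatter channels must be positive for log10 gating")
    return np.log10(ssc), np.log10(fsc)


def fit_gates(
    pooled: pd.DataFrame,
    yfp_thresh: "float | None" = None,
    bins: int = 256,
    scatter_level: float = 0.99,
    singlet_level: float = 0.95,
    robust: bool = False,
) -> GateSet:
    """Fit the full gate set on pooled events of one day and condition.

    The scatter ellipse is fitted on log10(SSC-A) x log10(FSC-A) of all
    events; the singlet ellipse on FSC-H x Width of the scatter survivors;
    the YFP threshold is detected on the log10 YFP-A histogram of the doubly
    gated events unless ``yfp_thresh`` overrides it (the threshold is then
    held constant across the experiment's samples).
    """
    lx, ly = _scatter_xy(pooled)
    smean, scov = fit_ellipse(lx, ly, robust=robust)
    keep = apply_ellipse(lx, ly, smean, scov, scatter_level)
    survivors = pooled[keep]
    gmean, gcov = fit_ellipse(survivors["fsc_h"], survivors["width"], robust=robust)
    keep2 = apply_ellipse(survivors["fsc_h"], survivors["width"], gmean, gcov,
                          singlet_level)
    gated = survivors[keep2]
    if yfp_thresh is None:
        yfp = gated["yfp_a"].to_numpy(dtype=float)
        if np.any(yfp <= 0):
            raise GatingError("yfp_a must be positive for log10 thresholding")
        yfp_thresh = yfp_threshold(np.log10(yfp), bins=bins)
    return GateSet(smean, scov, gmean, gcov, float(yfp_thresh),
                   scatter_level, singlet_level)


def apply_gates(events: pd.DataFrame, gates: GateSet) -> pd.DataFrame:
    """Events surviving both the scatter and singlet ellipses."""
    lx, ly = _scatter_xy(events)
    keep = apply_ellipse(lx, ly, gates.scatter_mean, gates.scatter_cov,
                         gates.scatter_level)
    out = events[keep]
    keep2 = apply_ellipse(out["fsc_h"], out["width"], gates.singlet_mean,
                          gates.singlet_cov, gates.singlet_level)
    return out[keep2]


def false_negative_fraction(reference_only: pd.DataFrame, gates: GateSet) -> float:
    """Fraction of gated reference-only events below the YFP threshold.

    Reference-only controls typically show a few percent of dim cells; a
    value above 0.5 is flagged as an implausible control.
    """
    gated = apply_gates(reference_only, gates)
    if len(gated) < 100:
        raise GatingError(
            f"only {len(gated)} gated reference-only events; need >= 100"
        )
    f = float((np.log10(gated["yfp_a"]) < gates.yfp_threshold).mean())
    if f > 0.5:
        warnings.warn(
            f"false-negative fraction {f:.2f} > 0.5: implausible reference control",
            stacklevel=2,
        )
    return f


def strain_ratio(total: float, p: float, f: float) -> float:
    """Unmarked-strain : reference ratio, Total*(1-f)/P - 1.

    ``total`` is the gated event count, ``p`` the YFP-positive count and
    ``f`` the control-estimated false-negative fraction; the true marked
    count is p/(1-f).
    """
    if not 0 <= f < 1:
        raise ValueError("f must lie in [0, 1)")
    if p <= 0:
        raise ValueError("no YFP-positive events; ratio undefined")
    if p > total:
        raise ValueError("positive count exceeds total")
    ratio = total * (1.0 - f) / p - 1.0
    if ratio < 0:
        raise ValueError(
            f"corrected ratio {ratio:.4f} < 0 (P > (1-f)*Total): "
            "inconsistent false-negative control"
        )
    return float(ratio)


def generations_elapsed(
    conc_prev_end: float, conc_end: float, dilution: float = 1e-3
) -> float:
    """Doublings in one daily cycle: log2(conc_end / (conc_prev_end * dilution))."""
    if conc_prev_end <= 0 or conc_end <= 0:
        raise ValueError("concentrations must be positive")
    if not 0 < dilution < 1:
        raise ValueError("dilution must lie in (0, 1)")
    return float(np.log2(conc_end / (conc_prev_end * dilution)))


def cumulative_generations(concentrations, dilution: float = 1e-3) -> np.ndarray:
    """Running generation axis from successive end-of-cycle concentrations.

    ``concentrations[0]`` is the pre-first-cycle (day 0) culture; the axis
    starts at 0 there.
    """
    conc = np.asarray(concentrations, dtype=float)
    g = [0.0]
    for prev, cur in zip(conc[:-1], conc[1:]):
        g.append(g[-1] + generations_elapsed(prev, cur, dilution))
    return np.array(g)


def selection_coefficient(ratios, gens) -> float:
    """OLS slope of ln(strain/reference) on cumulative generations."""
    ratios = np.asarray(ratios, dtype=float)
    gens = np.asarray(gens, dtype=float)
    if ratios.size != gens.size or ratios.size < 2:
        raise ValueError("need >= 2 matched (ratio, generations) points")
    if np.any(ratios <= 0):
        raise ValueError("ratios must be positive to take logs")
    if len(np.unique(gens)) < 2:
        raise ValueError("degenerate generation axis")
    return float(stats.linregress(gens, np.log(ratios)).slope)


@dataclass
class CompetitionSeries:
    """Per-day gated counts and derived quantities for one competition culture."""

    days: np.ndarray
    total: np.ndarray
    positive: np.ndarray
    f: np.ndarray
    concentration: np.ndarray
    generations: np.ndarray

    def ratios(self) -> np.ndarray:
        return np.array([strain_ratio(t, p, fi)
                         for t, p, fi in zip(self.total, self.positive, self.f)])

    def s(self) -> float:
        return selection_coefficient(self.ratios(), self.generations)


def analyze_competition(
    mix_by_day: "dict[int, pd.DataFrame]",
    ref_by_day: "dict[int, pd.DataFrame]",
    volume_ul: float,
    dilution: float = 1e-3,
    yfp_thresh: "float | None" = None,
    concentrations: "dict[int, float] | None" = None,
) -> CompetitionSeries:
    """Full per-culture pipeline: gates -> f -> corrected ratios -> generations.

    Gates are fitted per day on the pooled mixed-culture and reference-only
    events of that day; the YFP threshold is set on the first day and held
    constant.  ``concentrations`` (events/uL of the reference culture) may be
    supplied directly; otherwise they are estimated as gated events / volume.
    """
    if volume_ul <= 0:
        raise ValueError("acquisition volume must be positive")
    days = sorted(mix_by_day)
    if sorted(ref_by_day) != days:
        raise ValueError("mixed and reference-only samples must cover the same days")
    totals, positives, fs, concs = [], [], [], []
    thresh = yfp_thresh
    for day in days:
        pooled = pd.concat([mix_by_day[day], ref_by_day[day]], ignore_index=True)
        gates = fit_gates(pooled, yfp_thresh=thresh)
        if thresh is None:
            thresh = gates.yfp_threshold  # held constant from the first day on
        f = false_negative_fraction(ref_by_day[day], gates)
        gated = apply_gates(mix_by_day[day], gates)
        totals.append(len(gated))
        positives.append(int((np.log10(gated["yfp_a"]) >= gates.yfp_threshold).sum()))
        fs.append(f)
        if concentrations is not None:
            concs.append(float(concentrations[day]))
        else:
            concs.append(len(gated) / volume_ul)
    gens = cumulative_generations(concs, dilution)
    return CompetitionSeries(
        days=np.array(days), total=np.array(totals), positive=np.array(positives),
        f=np.array(fs), concentration=np.array(concs), generations=gens,
    )
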