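"""Synthetic plates, growth curves and flow-cytometry experiments with known truth.

Every generator is a deterministic function of its config and seed, and
emits exactly the tables the analysis modules consume, so each pipeline
stage can be validated by parameter recovery without external data.

Plate model: colony cells on day d are

    cells = day0_cells * 2**(g(d) * (1 + s_strain)) * edge(layer, d) * e^(sigma*Z)

where g(d) is the ancestor generation schedule, s_strain the strain's true
per-generation doubling advantage, ``edge`` a multiplicative edge-effect
profile that deepens with incubation time (weaker on trimmed plates), and Z
standard normal.  Sizes are the inverse of the size-to-cells calibration.
On this convention an estimator using the log2 response recovers s on its
own scale; the natural-log response recovers s * ln 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, PUBLISHED_CALIBRATION, cells_to_size
from .flow import FLOW_CHANNELS
from .liquid_growth import GrowthCurve
from .plate import PlateLayout, get_format, layer_index, make_snake_layout

__all__ = [
    "PlateSimConfig",
    "FlowSimConfig",
    "edge_profile",
    "simulate_plate",
    "simulate_growth_curve",
    "simulate_flow_experiment",
]

#: Default ancestor generation schedule on rich medium: ~6 doublings over
#: four days (day-4 colonies near 3.8e7 cells from a 5.8e5-cell pin), with
#: growth slowing as colonies become nutrient-limited.
DEFAULT_G_BY_DAY = (0.0, 3.0, 4.8, 5.7, 6.03)

EDGE_DEPTH = 4  # layers; edge effects reach ~4 layers deep by day 2


def edge_profile(layer: int, day: int, trimmed: bool) -> float:
    """Multiplicative edge-effect factor for a layer at a given day.

    Linear ramp over the outer EDGE_DEPTH layers, growing with incubation
    time; trimming the excess agar reduces the amplitude about four-fold.
    """
    weight = max(0, EDGE_DEPTH - layer) / EDGE_DEPTH
    amplitude = (0.03 if trimmed else 0.12) * day
    return 1.0 + amplitude * weight


@dataclass
class PlateSimConfig:
    """Ground truth for one simulated plate/condition.

    ``strain_s`` maps strain id to its true per-generation doubling
    advantage; strains listed in ``ancestors`` must have s = 0 (they define
    the generation axis).  ``sigma`` is the SD of the lognormal (natural-log)
    size noise applied to cells, per colony per day.
    """

    strain_s: dict[str, float]
    ancestors: tuple[str, str] = ("anc1", "anc2")
    format: str = "384"
    g_by_day: tuple[float, ...] = DEFAULT_G_BY_DAY
    day0_cells: float = PUBLISHED_CALIBRATION.day0_cells
    sigma: float = 0.05
    trimmed: bool = True
    seed: int = 0
    condition: str = "CM"
    plate_id: str = "sim1"
    reshuffle_each_cycle: bool = False
    calibration: CalibrationModel = field(default=PUBLISHED_CALIBRATION)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.g_by_day[0] != 0:
            raise ValueError("generation schedule must start at 0")
        for a in self.ancestors:
            if a not in self.strain_s:
                raise ValueError(f"ancestor {a!r} missing from strain_s")
            if self.strain_s[a] != 0:
                raise ValueError(f"ancestor {a!r} must have true s = 0")


def simulate_plate(cfg: PlateSimConfig) -> tuple[PlateLayout, pd.DataFrame]:
    """Simulate colony sizes for days 0..len(g_by_day)-1 on a snake layout.

    Returns the layout and a long-format colony table (one row per colony
    per day) with columns plate_id, condition, day, row, col, strain,
    replicate, size_px, status, zero_flag.
    """
    fmt = get_format(cfg.format)
    layout = make_snake_layout(
        sorted(cfg.strain_s), fmt, seed=cfg.seed, trimmed=cfg.trimmed,
        plate_id=cfg.plate_id, reshuffle_each_cycle=cfg.reshuffle_each_cycle,
    )
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    for (r, c), (strain, rep) in sorted(layout.assignment.items()):
        s = cfg.strain_s[strain]
        layer = layer_index(r, c, fmt)
        for day, g in enumerate(cfg.g_by_day):
            cells = (
                cfg.day0_cells
                * 2.0 ** (g * (1.0 + s))
                * edge_profile(layer, day, cfg.trimmed)
                * np.exp(cfg.sigma * rng.standard_normal())
            )
            rows.append(
                {"plate_id": cfg.plate_id, "condition": cfg.condition, "day": day,
                 "row": r, "col": c, "strain": strain, "replicate": rep,
                 "size_px": cells_to_size(cells, cfg.calibration),
                 "status": "OK", "zero_flag": None}
            )
    return layout, pd.DataFrame(rows)


def simulate_growth_curve(
    lag: float,
    rate: float,
    k: float,
    od0: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_end: float = 24.0,
    dt: float = 4.0 / 60.0,
) -> GrowthCurve:
    """Lag + logistic OD600 curve on the 4-minute grid.

    OD sits at ``od0`` until ``lag`` hours, then follows a logistic approach
    to carrying capacity ``k`` whose *maximum ln-slope* equals ``rate``
    (h^-1).  Gaussian noise of SD ``noise_sd`` is added and the result is
    floored at 1e-3 OD to keep logs defined.
    """
    if rate <= 0 or not k >= od0 > 0:
        raise ValueError("need rate > 0 and k >= od0 > 0")
    if lag < 0 or noise_sd < 0:
        raise ValueError("lag and noise_sd must be non-negative")
    t = np.arange(0.0, t_end + 1e-9, dt)
    tau = np.maximum(t - lag, 0.0)
    if k == od0:  # inoculated at capacity: flat curve
        od = np.full_like(t, od0)
    else:
        # internal logistic rate chosen so d(ln OD)/dt at the lag boundary = rate
        r_int = rate / (1.0 - od0 / k)
        # numerically stable logistic: od = K / (1 + ((K-od0)/od0) e^(-r tau))
        od = k / (1.0 + ((k - od0) / od0) * np.exp(-r_int * tau))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    return GrowthCurve(times=t, od=np.maximum(od, 1e-3))


@dataclass
class FlowSimConfig:
    """Ground truth for one simulated competition replicate.

    The strain:reference ratio follows r0 * exp(s_true * g) along the
    cumulative generation axis; ``f_true`` is the fraction of reference
    cells drawn dim (below the YFP threshold), within the 0-0.2 band seen
    in reference-only controls.  Debris and doublet clusters lie outside
    the scatter and singlet gates respectively.
    """

    s_true: float = 0.0
    r0: float = 1.0
    f_true: float = 0.05
    n_events: int = 20000
    n_days: int = 3
    gen_per_day: float = np.log2(1000.0)  # regrowth after a 1/1000 dilution
    dilution: float = 1e-3
    volume_ul: float = 14.0
    debris_frac: float = 0.02
    doublet_frac: float = 0.03
    conc_noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.f_true <= 0.2:
            raise ValueError("f_true outside the plausible control band [0, 0.2]")
        if self.n_events < 100 or self.n_days < 1:
            raise ValueError("need >= 100 events and >= 1 day")
        if not 0 < self.dilution < 1:
            raise ValueError("dilution must lie in (0, 1)")


def _draw_events(rng, n: int, strain_frac: float, f_true: float,
                 debris_frac: float, doublet_frac: float) -> pd.DataFrame:
    """One sample's event table: cells + debris + doublets, linear units."""
    n_debris = rng.binomial(n, debris_frac)
    n_doublet = rng.binomial(n - n_debris, doublet_frac)
    n_cells = n - n_debris - n_doublet

    def scatter(m_ssc, m_fsc, sd, count):
        cov = np.array([[sd**2, 0.6 * sd**2], [0.6 * sd**2, sd**2]])
        ls, lf = rng.multivariate_normal([m_ssc, m_fsc], cov, size=count).T
        return 10.0**ls, 10.0**lf

    def yfp(count, frac_bright):
        bright = rng.random(count) < frac_bright
        logy = np.where(bright, rng.normal(4.0, 0.15, count),
                        rng.normal(2.0, 0.15, count))
        return 10.0**logy, bright

    # single cells: strain (dim) vs reference (bright except f_true dim)
    ssc, fsc = scatter(4.2, 5.0, 0.15, n_cells)
    is_strain = rng.random(n_cells) < strain_frac
    frac_bright_ref = 1.0 - f_true
    logy = np.where(
        is_strain,
        rng.normal(2.0, 0.15, n_cells),
        np.where(rng.random(n_cells) < frac_bright_ref,
                 rng.normal(4.0, 0.15, n_cells), rng.normal(2.0, 0.15, n_cells)),
    )
    cells = pd.DataFrame({
        "ssc_a": ssc, "fsc_a": fsc,
        "fsc_h": fsc * rng.normal(1.0, 0.04, n_cells),
        "width": rng.normal(60.0, 4.0, n_cells),
        "yfp_a": 10.0**logy,
    })
    # debris: small scatter, dim
    dssc, dfsc = scatter(3.1, 3.7, 0.2, n_debris)
    debris = pd.DataFrame({
        "ssc_a": dssc, "fsc_a": dfsc,
        "fsc_h": dfsc * rng.normal(1.0, 0.1, n_debris),
        "width": rng.normal(55.0, 6.0, n_debris),
        "yfp_a": 10.0 ** rng.normal(1.5, 0.3, n_debris),
    })
    # doublets: cell-like scatter, double area, wide pulse
    bssc, bfsc = scatter(4.5, 5.3, 0.15, n_doublet)
    y2, _ = yfp(n_doublet, 0.5)
    doublets = pd.DataFrame({
        "ssc_a": bssc, "fsc_a": bfsc,
        "fsc_h": bfsc * rng.normal(0.55, 0.05, n_doublet),
        "width": rng.normal(115.0, 6.0, n_doublet),
        "yfp_a": y2,
    })
    out = pd.concat([cells, debris, doublets], ignore_index=True)
    return out.sample(frac=1.0, random_state=int(rng.integers(2**31)))[
        FLOW_CHANNELS
    ].reset_index(drop=True)


def simulate_flow_experiment(cfg: FlowSimConfig) -> dict:
    """Simulate a daily competition: mixed cultures + reference-only controls.

    Returns a dict with ``mix_by_day`` and ``ref_by_day`` (event tables for
    days 0..n_days, day 0 being the initial mix), ``concentrations``
    (events/uL of the culture at each sampling), ``true_generations`` and
    ``true_ratios``.
    """
    rng = np.random.default_rng(cfg.seed)
    days = list(range(cfg.n_days + 1))
    g_true = np.array([d * cfg.gen_per_day for d in days])
    ratios = cfg.r0 * np.exp(cfg.s_true * g_true)
    base_conc = 1500.0
    mix_by_day, ref_by_day, conc = {}, {}, {}
    for day, ratio in zip(days, ratios):
        strain_frac = ratio / (1.0 + ratio)
        mix_by_day[day] = _draw_events(
            rng, cfg.n_events, strain_frac, cfg.f_true,
            cfg.debris_frac, cfg.doublet_frac,
        )
        ref_by_day[day] = _draw_events(
            rng, cfg.n_events, 0.0, cfg.f_true,
            cfg.debris_frac, cfg.doublet_frac,
        )
        # cultures saturate each cycle: end concentration ~constant up to
        # measurement noise, so each 1/1000 cycle yields ~log2(1000) doublings
        conc[day] = float(base_conc * np.exp(rng.normal(0.0, cfg.conc_noise_sd)))
    return {
        "mix_by_day": mix_by_day,
        "ref_by_day": ref_by_day,
        "concentrations": conc,
        "true_generations": g_true,
        "true_ratios": ratios,
        "config": cfg,
    }
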