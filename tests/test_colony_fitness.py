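"""Generation axes, Malthusian slopes and selection-coefficient estimation."""

import numpy as np
import pandas as pd
import pytest

from colonyfit import (
    GenerationAxis,
    PUBLISHED_CALIBRATION,
    analyze_plate,
    build_generation_axis,
    fitness_difference,
    fitness_table,
    generations,
    malthusian_slope,
    size_ratio_fitness_relation,
    sizes_to_cells,
)
from colonyfit.simulate import DEFAULT_G_BY_DAY, PlateSimConfig, simulate_plate

LN2 = np.log(2.0)


def cells_table(trajs, condition="CM", plate="p1"):
    """trajs: {(row, col, strain): {day: cells}} -> long cells DataFrame."""
    rows = []
    for (r, c, strain), series in trajs.items():
        for day, cells in series.items():
            rows.append({"plate_id": plate, "condition": condition, "day": day,
                         "row": r, "col": c, "strain": strain, "replicate": 1,
                         "status": "OK", "cells": float(cells)})
    return pd.DataFrame(rows)


def exponential_traj(g_by_day, s=0.0, n0=1e5):
    return {day: n0 * 2 ** (g * (1 + s)) for day, g in enumerate(g_by_day)}


def test_generations_closed_forms():
    assert generations(100, 100) == 0.0
    assert generations(800, 100) == pytest.approx(3.0)
    assert generations(3.79e7, 579506) == pytest.approx(6.03, abs=0.01)
    with pytest.raises(ValueError):
        generations(0, 10)


def test_generation_axis_means_ancestor_replicates():
    """Axis day value is the mean of per-replicate log2 ratios."""
    t1 = {0: 1e5, 4: 1e5 * 2**5.8}
    t2 = {0: 2e5, 4: 2e5 * 2**6.2}
    df = cells_table({(0, 0, "anc1"): t1, (0, 1, "anc2"): t2})
    axis = build_generation_axis(df)
    assert axis.g_by_day[0] == 0.0
    assert axis.g_by_day[4] == pytest.approx(6.0)
    assert axis.ancestor_strains == ("anc1", "anc2")


def test_generation_axis_daily_doubling():
    df = cells_table({(0, 0, "anc1"): {d: 1000 * 2**d for d in range(5)}})
    axis = build_generation_axis(df)
    assert [axis.g_by_day[d] for d in range(5)] == pytest.approx([0, 1, 2, 3, 4])


def test_malthusian_slope_of_ancestor_is_log2_or_ln2():
    traj = exponential_traj(DEFAULT_G_BY_DAY)
    df = cells_table({(0, 0, "anc1"): traj})
    axis = build_generation_axis(df)
    days, cells = list(traj), list(traj.values())
    assert malthusian_slope(days, cells, axis, base="log2") == pytest.approx(1.0)
    assert malthusian_slope(days, cells, axis, base="ln") == pytest.approx(
        LN2, abs=1e-9
    )


def test_malthusian_slope_degenerate_axis_rejected():
    axis = GenerationAxis("CM", {0: 0.0, 1: 0.0, 2: 0.0})
    with pytest.raises(ValueError, match="degenerate"):
        malthusian_slope([0, 1, 2], [1e5, 1e5, 1e5], axis)


def test_fitness_difference_closed_form():
    """A strain growing 2^(1.05 g) vs exact ancestors: s = 0.05 ln 2 (ln base)."""
    anc = cells_table({(0, 0, "anc1"): exponential_traj(DEFAULT_G_BY_DAY),
                       (0, 1, "anc2"): exponential_traj(DEFAULT_G_BY_DAY)})
    ev = cells_table({(1, 1, "ev"): exponential_traj(DEFAULT_G_BY_DAY, s=0.05)})
    est_ln = fitness_difference(ev, anc, base="ln")
    est_l2 = fitness_difference(ev, anc, base="log2")
    assert est_ln.s == pytest.approx(0.05 * LN2, abs=1e-9)
    assert est_l2.s == pytest.approx(0.05, abs=1e-9)
    # the two bases differ by exactly ln 2
    assert est_ln.s / est_l2.s == pytest.approx(LN2)
    assert est_ln.s == pytest.approx(est_ln.evolved_slope
                                     - est_ln.ancestor_mean_slope)


def test_fitness_zero_for_identical_trajectories():
    anc = cells_table({(0, 0, "anc1"): exponential_traj(DEFAULT_G_BY_DAY)})
    ev = cells_table({(1, 1, "ev"): exponential_traj(DEFAULT_G_BY_DAY)})
    assert fitness_difference(ev, anc).s == pytest.approx(0.0, abs=1e-12)


def test_fitness_invariant_to_common_rescaling():
    """Day-0 anchoring makes s ratio-based: scaling all cells cancels."""
    anc = cells_table({(0, 0, "anc1"): exponential_traj(DEFAULT_G_BY_DAY)})
    ev = cells_table({(1, 1, "ev"): exponential_traj(DEFAULT_G_BY_DAY, s=0.03)})
    s1 = fitness_difference(ev, anc).s
    anc["cells"] *= 7.3
    ev["cells"] *= 7.3
    assert fitness_difference(ev, anc).s == pytest.approx(s1, abs=1e-12)


def test_discarded_trajectory_gives_no_estimate():
    anc = cells_table({(0, 0, "anc1"): exponential_traj(DEFAULT_G_BY_DAY)})
    ev = cells_table({(1, 1, "ev"): exponential_traj(DEFAULT_G_BY_DAY)})
    ev["status"] = "DISCARD"
    ev["cells"] = np.nan
    with pytest.raises(ValueError, match="discard|usable"):
        fitness_difference(ev, anc)


def test_window_consistency_noiseless():
    """Exact exponential growth: every day-window returns the same s."""
    anc = cells_table({(0, 0, "anc1"): exponential_traj(DEFAULT_G_BY_DAY),
                       (0, 1, "anc2"): exponential_traj(DEFAULT_G_BY_DAY)})
    ev = cells_table({(1, 1, "ev"): exponential_traj(DEFAULT_G_BY_DAY, s=0.08)})
    full = fitness_difference(ev, anc, base="log2").s
    for last_day in (1, 2, 3, 4):
        est = fitness_difference(ev, anc, base="log2", last_day=last_day)
        assert est.s == pytest.approx(full, abs=1e-10)
        assert est.s == pytest.approx(0.08, abs=1e-10)


def test_window_precision_improves_with_more_days():
    """Replicate SD of s shrinks as the regression window extends to day 4."""
    rng = np.random.default_rng(9)
    sigma = 0.05 / LN2  # size noise in log2-cells units
    g = np.array(DEFAULT_G_BY_DAY)
    sds = []
    for last_day in (1, 2, 3, 4):
        ests = []
        for _ in range(200):
            anc_cells = 1e5 * 2 ** (g + rng.normal(0, sigma, 5))
            ev_cells = 1e5 * 2 ** (g * 1.05 + rng.normal(0, sigma, 5))
            anc = cells_table({(0, 0, "anc1"): dict(enumerate(anc_cells))})
            ev = cells_table({(1, 1, "ev"): dict(enumerate(ev_cells))})
            ests.append(fitness_difference(ev, anc, base="log2",
                                           last_day=last_day).s)
        sds.append(np.std(ests, ddof=1))
    assert sds[0] > sds[1] > sds[2] > sds[3]


def test_parameter_recovery_on_simulated_plates():
    """Anchored pipeline recovers s in {0.01, 0.05, 0.10} within 2 SE."""
    cfg = PlateSimConfig(
        strain_s={"anc1": 0.0, "anc2": 0.0, "ev001": 0.01, "ev005": 0.05,
                  "ev010": 0.10, "ev000": 0.0},
        sigma=0.05, trimmed=True, seed=5,
    )
    _, obs = simulate_plate(cfg)
    fit = analyze_plate(obs, ["anc1", "anc2"], normalize=None, base="log2")
    for strain, truth in [("ev000", 0.0), ("ev001", 0.01), ("ev005", 0.05),
                          ("ev010", 0.10)]:
        vals = fit.loc[fit["strain"] == strain, "s"].to_numpy()
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - truth) < 2 * se


def test_normalized_pipeline_shrinks_extreme_effects_slightly():
    """Row/column mean normalization attenuates the evolved-ancestor slope
    difference by ~(1 - 1/k)(1/n_cols + 1/n_rows) (~10% on a 384 plate),
    because row and column means contain the focal strain's own signal."""
    cfg = PlateSimConfig(
        strain_s={"anc1": 0.0, "anc2": 0.0, "ev010": 0.10, "ev005": 0.05,
                  "ev000": 0.0, "ev001": 0.01},
        sigma=0.0, trimmed=True, seed=5, reshuffle_each_cycle=True,
    )
    _, obs = simulate_plate(cfg)
    fit = analyze_plate(obs, ["anc1", "anc2"], normalize="rowcol-mean",
                        base="log2")
    mean10 = fit.loc[fit["strain"] == "ev010", "s"].mean()
    assert 0.085 < mean10 < 0.100  # shrunk, but by no more than ~15%


def test_size_ratio_fitness_relation_deterministic():
    """Noise-free: s is an exact linear function of the log day-4 size ratio,
    and the slope is steeper when the ancestors complete fewer generations."""
    slopes = {}
    for label, scale in [("lowstress", 1.0), ("highstress", 0.5)]:
        g = tuple(x * scale for x in DEFAULT_G_BY_DAY)
        cfg = PlateSimConfig(
            strain_s={"anc1": 0.0, "anc2": 0.0, "ev2": 0.02, "ev5": 0.05,
                      "ev8": 0.08, "ev11": 0.11},
            g_by_day=g, sigma=0.0, trimmed=True, seed=3, condition=label,
        )
        _, obs = simulate_plate(cfg)
        fit = analyze_plate(obs, ["anc1", "anc2"], normalize=None, base="ln")
        from colonyfit.calibration import anchor_day0

        rel = size_ratio_fitness_relation(fit, anchor_day0(obs),
                                          ["anc1", "anc2"], day=4)
        assert rel["r_squared"].iloc[0] > 0.99
        slopes[label] = rel["slope"].iloc[0]
    assert slopes["highstress"] > slopes["lowstress"]


def test_fitness_table_groups_by_plate_condition(six_strain_plate):
    _, _, obs = six_strain_plate
    fit = analyze_plate(obs, ["anc1", "anc2"], normalize=None)
    assert set(fit["strain"]) == {"ev000", "ev001", "ev005", "ev010"}
    assert (fit["log_base"] == "ln").all()
    # 4 evolved strains x 64 positions, minus excluded corner colonies
    assert len(fit) >= 4 * 62


def test_sizes_to_cells_skips_discarded():
    df = pd.DataFrame({
        "plate_id": ["p"] * 2, "condition": ["CM"] * 2, "day": [1, 1],
        "row": [0, 0], "col": [0, 1], "strain": ["a", "b"],
        "size_px": [100.0, 100.0], "status": ["OK", "DISCARD"],
    })
    out = sizes_to_cells(df, PUBLISHED_CALIBRATION)
    assert np.isfinite(out["cells"].iloc[0])
    assert np.isnan(out["cells"].iloc[1])
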