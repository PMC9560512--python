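"""Flow gating, false-negative correction and competitive selection coefficients."""

import numpy as np
import pandas as pd
import pytest

from colonyfit import (
    FlowSimConfig,
    analyze_competition,
    apply_gates,
    cumulative_generations,
    ellipse_gate,
    false_negative_fraction,
    fit_gates,
    generations_elapsed,
    selection_coefficient,
    simulate_flow_experiment,
    strain_ratio,
    yfp_threshold,
)
from colonyfit.flow import GatingError


def test_ellipse_gate_chi2_coverage():
    """99% ellipse on bivariate normal data keeps 99.0 +- 0.3% of events."""
    rng = np.random.default_rng(1)
    pts = rng.multivariate_normal([3, 5], [[1.0, 0.4], [0.4, 0.8]], size=100_000)
    mask = ellipse_gate(pts[:, 0], pts[:, 1], level=0.99)
    assert mask.mean() == pytest.approx(0.990, abs=0.003)
    mask95 = ellipse_gate(pts[:, 0], pts[:, 1], level=0.95)
    assert mask95.mean() == pytest.approx(0.950, abs=0.005)


def test_ellipse_gate_affine_invariant():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, 5000)
    y = 0.5 * x + rng.normal(0, 1, 5000)
    m1 = ellipse_gate(x, y, 0.95)
    m2 = ellipse_gate(3.0 * x - 7.0, -0.25 * y + 2.0, 0.95)
    assert np.array_equal(m1, m2)


def test_ellipse_gate_rejects_singular():
    with pytest.raises(GatingError, match="singular|ellipse"):
        ellipse_gate(np.full(100, 2.0), np.full(100, 3.0), 0.99)


@pytest.mark.parametrize("weights", [(0.5, 0.5), (0.9, 0.1)])
def test_yfp_threshold_midpoint_of_two_populations(weights):
    """Mixture of N(2, 0.1) and N(4, 0.1): threshold at 3.0 regardless of
    the mixing proportions (peak locations do not move)."""
    rng = np.random.default_rng(3)
    n = 10_000
    n1 = int(weights[0] * n)
    vals = np.concatenate([rng.normal(2, 0.1, n1), rng.normal(4, 0.1, n - n1)])
    assert yfp_threshold(vals) == pytest.approx(3.0, abs=0.1)


def test_yfp_threshold_rejects_unimodal():
    rng = np.random.default_rng(4)
    with pytest.raises(GatingError, match="unimodal|manual"):
        yfp_threshold(rng.normal(3, 0.2, 10_000))


def test_false_negative_fraction_recovers_dim_fraction():
    sim = simulate_flow_experiment(FlowSimConfig(s_true=0.0, f_true=0.05, seed=8))
    ref = sim["ref_by_day"][1]
    gates = fit_gates(pd.concat([sim["mix_by_day"][1], ref], ignore_index=True))
    f = false_negative_fraction(ref, gates)
    assert f == pytest.approx(0.05, abs=0.01)


def test_false_negative_fraction_implausible_control_flagged():
    sim = simulate_flow_experiment(FlowSimConfig(s_true=0.0, seed=9))
    mix = sim["mix_by_day"][1]  # ~50% dim: not a credible reference control
    gates = fit_gates(pd.concat([mix, sim["ref_by_day"][1]], ignore_index=True))
    with pytest.warns(UserWarning, match="implausible"):
        false_negative_fraction(mix, gates)


@pytest.mark.parametrize(
    "total,p,f,expected",
    [(2000, 1000, 0.0, 1.0), (10_000, 4500, 0.1, 1.0), (1000, 1000, 0.0, 0.0)],
)
def test_strain_ratio_arithmetic(total, p, f, expected):
    assert strain_ratio(total, p, f) == pytest.approx(expected)


def test_strain_ratio_pure_reference_with_f():
    # p = (1-f) * total: everything is reference
    assert strain_ratio(1000, 900, 0.1) == pytest.approx(0.0)


def test_strain_ratio_rejections():
    with pytest.raises(ValueError):
        strain_ratio(1000, 0, 0.0)
    with pytest.raises(ValueError, match="inconsistent"):
        strain_ratio(1000, 990, 0.1)  # P > (1-f) * Total


def test_eq1_oracle_corrected_vs_uncorrected():
    """The corrected ratio recovers truth with < 1% bias at 1e5 events
    (mean over draws), while the uncorrected estimate converges to the
    analytic (R + f)/(1 - f) inflation."""
    rng = np.random.default_rng(10)
    n = 100_000
    for f in (0.0, 0.05, 0.19):
        for true_ratio in (0.5, 1.0, 2.0):
            p_strain = true_ratio / (1 + true_ratio)
            ests, naive = [], []
            for _ in range(20):
                is_strain = rng.random(n) < p_strain
                is_dim_ref = ~is_strain & (rng.random(n) < f)
                p_bright = int((~is_strain & ~is_dim_ref).sum())
                ests.append(strain_ratio(n, p_bright, f))
                naive.append(strain_ratio(n, p_bright, 0.0))
            assert np.mean(ests) == pytest.approx(true_ratio, rel=0.01)
            predicted = (true_ratio + f) / (1 - f)
            assert np.mean(naive) == pytest.approx(predicted, rel=0.01)


def test_generations_elapsed_closed_forms():
    assert generations_elapsed(1500, 1500, 1e-3) == pytest.approx(
        np.log2(1000), abs=1e-9
    )
    assert generations_elapsed(1500, 1.5, 1e-3) == pytest.approx(0.0)
    g = cumulative_generations([1500, 1500, 1500], 1e-3)
    assert g == pytest.approx([0, np.log2(1000), 2 * np.log2(1000)])
    with pytest.raises(ValueError):
        generations_elapsed(0, 1500)


def test_selection_coefficient_closed_form():
    gens = np.array([0.0, 10.0, 20.0, 30.0])
    assert selection_coefficient(np.ones(4), gens) == pytest.approx(0.0)
    ratios = np.exp(0.02 * gens)
    assert selection_coefficient(ratios, gens) == pytest.approx(0.02, abs=1e-9)
    with pytest.raises(ValueError, match="degenerate"):
        selection_coefficient([1.0, 2.0], [5.0, 5.0])


def test_gating_retention_band():
    """Scatter+singlet gates keep 85-99.9% of simulated events."""
    sim = simulate_flow_experiment(FlowSimConfig(s_true=0.0, seed=11))
    for day in (0, 1):
        mix = sim["mix_by_day"][day]
        gates = fit_gates(pd.concat([mix, sim["ref_by_day"][day]],
                                    ignore_index=True))
        kept = len(apply_gates(mix, gates)) / len(mix)
        assert 0.85 <= kept <= 0.999


def test_competition_s_invariant_to_concentration_scale():
    sim = simulate_flow_experiment(FlowSimConfig(s_true=0.03, seed=12))
    conc = sim["concentrations"]
    s1 = analyze_competition(sim["mix_by_day"], sim["ref_by_day"], 14.0,
                             concentrations=conc).s()
    s2 = analyze_competition(sim["mix_by_day"], sim["ref_by_day"], 14.0,
                             concentrations={d: 5.0 * v for d, v in conc.items()}).s()
    assert s2 == pytest.approx(s1, abs=1e-12)


def test_end_to_end_competition_recovery():
    """Full pipeline (gates -> f -> ratios -> regression) recovers s = 0.05
    within 2 SE over 7 replicate competitions."""
    ests = []
    for rep in range(7):
        sim = simulate_flow_experiment(FlowSimConfig(s_true=0.05, seed=300 + rep))
        series = analyze_competition(sim["mix_by_day"], sim["ref_by_day"], 14.0,
                                     concentrations=sim["concentrations"])
        ests.append(series.s())
    ests = np.array(ests)
    se = ests.std(ddof=1) / np.sqrt(len(ests))
    assert abs(ests.mean() - 0.05) < 2 * se


def test_uncorrected_pipeline_biased_with_dim_reference():
    """Ignoring f inflates every daily ratio by ~(R + f)/(R (1 - f)); the
    fitted slope is left nearly unchanged only when f is constant, so the
    corrected and uncorrected ratios must differ while truth is recovered."""
    sim = simulate_flow_experiment(FlowSimConfig(s_true=0.0, f_true=0.1,
                                                 r0=1.0, seed=13))
    series = analyze_competition(sim["mix_by_day"], sim["ref_by_day"], 14.0,
                                 concentrations=sim["concentrations"])
    corrected = series.ratios()
    naive = np.array([strain_ratio(t, p, 0.0)
                      for t, p in zip(series.total, series.positive)])
    assert corrected == pytest.approx(np.ones_like(corrected), rel=0.08)
    assert np.all(naive > corrected)
    assert naive.mean() == pytest.approx((1.0 + 0.1) / 0.9, rel=0.08)
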