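"""The GWAS simulation engine and the Monte-Carlo study driver."""

import numpy as np
import pandas as pd
import pytest

from conftest import per_snp_ols_oracle

from pluralmr import (
    GwasEngine,
    SimulationScenario,
    aggregate,
    conditional_f,
    marginal_f,
    run_study,
    scenario_grid,
    simulate_replicate,
)
from pluralmr.metrics import parse_ci


def test_scenario_validation_and_labels():
    sc = SimulationScenario(causal=False, p_pleio=80, pleio_mean=-0.03)
    assert sc.label == "null_d40" and sc.effects == (0.0, 0.0)
    assert SimulationScenario(causal=True).label == "causal_none"
    with pytest.raises(ValueError):
        SimulationScenario(p_pleio=300)
    with pytest.raises(ValueError):
        SimulationScenario(maf=0.7)


def test_scenario_grid_covers_study():
    grid = scenario_grid()
    assert len(grid) == 14
    assert len({s.label for s in grid}) == 14


def test_genotype_frequencies_match_maf():
    engine = GwasEngine(50_000, 20, maf=0.4)
    rng = np.random.default_rng(0)
    engine.gwas(rng, np.zeros(20), 1.0, keep_sample=True)
    G, _ = engine.last_sample_
    freq = G.mean() / 2
    assert freq == pytest.approx(0.4, abs=0.005)
    counts = np.bincount(G.ravel(), minlength=3) / G.size
    np.testing.assert_allclose(counts, [0.36, 0.48, 0.16], atol=0.01)


def test_per_snp_ols_matches_regression_oracle():
    """Engine betas/SEs equal an independent per-SNP least-squares fit on
    the raw miniature sample."""
    engine = GwasEngine(500, 5, maf=0.4)
    rng = np.random.default_rng(1)
    effects = np.array([0.3, -0.2, 0.0, 0.5, 0.1])
    beta, se = engine.gwas(rng, effects, 1.0, keep_sample=True)
    G, y = engine.last_sample_
    ob, os_ = per_snp_ols_oracle(G.astype(float), y)
    np.testing.assert_allclose(beta, ob, rtol=1e-4, atol=1e-7)
    np.testing.assert_allclose(se, os_, rtol=1e-4)


def test_noiseless_propagation_of_causal_and_pleiotropic_effects():
    """With no confounding and no trait noise the outcome GWAS recovers
    0.3*b1 + 0.4*b2 + p up to genotype sampling correlation."""
    sc = SimulationScenario(causal=True, p_pleio=5, pleio_mean=-0.03,
                            conf_e1=0.0, conf_e2=0.0, conf_out=0.0,
                            noise_sd=0.0, n_snps=20, n_per_gwas=20_000)
    rng = np.random.default_rng(2)
    p = sc.n_snps
    b1 = rng.normal(sc.b_mean, sc.b_sd, p)
    b2 = rng.normal(sc.b_mean, sc.b_sd, p)
    pl = np.zeros(p)
    pl[:5] = rng.normal(sc.pleio_mean, sc.pleio_sd, 5)
    ds = simulate_replicate(sc, rng=np.random.default_rng(2))
    truth = 0.3 * b1 + 0.4 * b2 + pl
    assert np.all(np.abs(ds.beta_outcome - truth) < 6 * ds.se_outcome)
    assert np.all(np.abs(ds.beta_exposures[:, 0] - b1) < 6 * ds.se_exposures[:, 0])


def test_replicate_reproducibility_bit_identical():
    sc = SimulationScenario(n_snps=50, n_per_gwas=5000)
    a = simulate_replicate(sc, rng=np.random.default_rng(9))
    b = simulate_replicate(sc, rng=np.random.default_rng(9))
    np.testing.assert_array_equal(a.beta_outcome, b.beta_outcome)
    np.testing.assert_array_equal(a.beta_exposures, b.beta_exposures)
    np.testing.assert_array_equal(a.se_outcome, b.se_outcome)


def test_se_scaling_with_sample_size():
    """Doubling the GWAS sample size shrinks the median per-SNP SE by
    about 1/sqrt(2)."""
    sc1 = SimulationScenario(n_snps=50, n_per_gwas=20_000)
    sc2 = SimulationScenario(n_snps=50, n_per_gwas=40_000)
    d1 = simulate_replicate(sc1, rng=np.random.default_rng(5))
    d2 = simulate_replicate(sc2, rng=np.random.default_rng(6))
    ratio = np.median(d2.se_outcome) / np.median(d1.se_outcome)
    assert ratio == pytest.approx(1 / np.sqrt(2), rel=0.05)


def test_conditional_f_collinear_exposures_is_zero():
    rng = np.random.default_rng(3)
    from pluralmr import MVMRDataset

    bx1 = rng.normal(0.05, 0.02, 30)
    ds = MVMRDataset(
        [f"v{i}" for i in range(30)],
        np.column_stack([bx1, 3 * bx1]),
        np.full((30, 2), 0.004),
        0.3 * bx1, np.full(30, 0.004), ["a", "b"],
    )
    assert conditional_f(ds, 0) == pytest.approx(0.0, abs=1e-12)


def test_conditional_f_univariable_reduction_matches_mean_f_oracle():
    from pluralmr import MVMRDataset

    rng = np.random.default_rng(4)
    bx = rng.normal(0.05, 0.02, 40)
    se = np.abs(rng.normal(0.004, 0.001, 40)) + 1e-4
    ds = MVMRDataset([f"v{i}" for i in range(40)], bx[:, None], se[:, None],
                     0.3 * bx, np.full(40, 0.004), ["a"])
    oracle = np.mean((bx / se) ** 2) * 40 / 39
    assert conditional_f(ds, 0) == pytest.approx(oracle, rel=1e-12)
    assert marginal_f(ds, 0) == pytest.approx(np.mean((bx / se) ** 2))


def test_run_study_shape_failures_and_persistence(tmp_path):
    scenarios = scenario_grid(causal=True, pleio=["none", "d40"],
                              n_snps=40, n_per_gwas=3000)
    res = run_study(scenarios, n_reps=2, methods=("ivw", "cm"), seed=7,
                    compute_f=True, out_dir=tmp_path)
    # shape: scenario x rep x method x exposure
    assert len(res.replicates) == 2 * 2 * 2 * 2
    assert res.n_failures == 0
    assert set(res.replicates.scenario) == {"causal_none", "causal_d40"}
    # persisted replicate-level results re-aggregate to the same table
    back = pd.read_csv(tmp_path / "replicates.csv")
    truth = {s.label: dict(zip(["E1", "E2"], s.effects)) for s in scenarios}
    again = aggregate(back, truth)
    merged = res.performance.frame.merge(
        again.frame, on=["scenario", "method", "exposure"], suffixes=("", "_r")
    )
    np.testing.assert_allclose(merged["bias"], merged["bias_r"], atol=1e-12)
    np.testing.assert_allclose(merged["ci_width"], merged["ci_width_r"], atol=1e-12)
    assert {"f_conditional_E1", "f_marginal_E1"} <= set(res.fstats.columns)


def test_run_study_reproducible_and_order_invariant():
    sc_a = scenario_grid(causal=True, pleio=["none", "b10"], n_snps=30, n_per_gwas=2000)
    res1 = run_study(sc_a, n_reps=2, methods=("ivw",), seed=11)
    res2 = run_study(sc_a[::-1], n_reps=2, methods=("ivw",), seed=11)
    a = res1.replicates.sort_values(["scenario", "rep", "exposure"]).reset_index(drop=True)
    b = res2.replicates.sort_values(["scenario", "rep", "exposure"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_directional_pleiotropy_monotonically_biases_ivw():
    """|IVW bias| grows with the share of directionally pleiotropic SNPs."""
    scenarios = scenario_grid(causal=True, pleio=["d10", "d20", "d40"],
                              n_snps=50, n_per_gwas=20_000)
    res = run_study(scenarios, n_reps=60, methods=("ivw",), seed=13)
    bias = {
        code: abs(res.performance.get(f"causal_{code}", "ivw", "E1", "bias"))
        for code in ("d10", "d20", "d40")
    }
    slack = 0.03  # two Monte-Carlo SEs at this replicate count
    assert bias["d20"] > bias["d10"] - slack
    assert bias["d40"] > bias["d20"] - slack
    assert bias["d40"] > bias["d10"]


def test_ci_serialization_roundtrip():
    from pluralmr.metrics import serialize_ci

    ci = [(-1.234567890123, -0.5), (0.25, 0.75)]
    assert parse_ci(serialize_ci(ci)) == ci
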