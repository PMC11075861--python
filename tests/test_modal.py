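"""Univariable mode-based and contamination-mixture estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import cm_exhaustive_oracle, dense_grid_mode_oracle

from pluralmr import RatioSet, contamination_mixture, mbe, wald_ratios
from pluralmr.modal import EstimateResult, silverman_bandwidth
from pluralmr.residualize import ResidualizedData


def _ratio_set(theta, se):
    return RatioSet(np.asarray(theta, float), np.asarray(se, float))


def test_wald_ratios_from_residuals():
    resid = ResidualizedData(
        beta_y_resid=[0.3, -0.3, 0.6],
        beta_x_resid=[1.0, -1.0, 2.0],
        se_resid=[0.1, 0.1, 0.05],
        target_exposure=0, n_variants=3, kept=np.arange(3), dropped_variants=[],
    )
    rs = wald_ratios(resid)
    np.testing.assert_allclose(rs.theta_hat, [0.3, 0.3, 0.3])
    np.testing.assert_allclose(rs.se, [0.1, 0.1, 0.05])


def test_mbe_degenerate_identical_ratios():
    res = mbe(_ratio_set([0.3, 0.3, 0.3, 0.3], [0.1, 0.2, 0.1, 0.3]),
              n_boot=50, rng=0)
    assert res.theta == pytest.approx(0.30, abs=1e-12)
    assert np.isfinite(res.se) and res.se > 0


def test_mbe_matches_dense_grid_oracle():
    theta = [0.1, 0.1, 0.1, 0.9]
    se = [0.05] * 4
    res = mbe(_ratio_set(theta, se), phi=1.0, n_boot=0)
    oracle = dense_grid_mode_oracle(theta, se, phi=1.0, step=1e-4)
    h = silverman_bandwidth(np.asarray(theta))
    assert res.theta == pytest.approx(oracle, abs=max(2e-3 * h, 2e-4))


def test_mbe_unweighted_matches_its_oracle():
    rng = np.random.default_rng(2)
    theta = np.concatenate([rng.normal(0.3, 0.02, 12), rng.normal(1.5, 0.3, 5)])
    se = np.abs(rng.normal(0.05, 0.01, 17)) + 0.01
    res = mbe(_ratio_set(theta, se), n_boot=0, weighted=False)
    oracle = dense_grid_mode_oracle(theta, se, step=1e-4, weighted=False)
    h = silverman_bandwidth(theta)
    assert res.theta == pytest.approx(oracle, abs=max(2e-3 * h, 2e-4))


def test_mbe_requires_three_variants():
    with pytest.raises(ValueError):
        mbe(_ratio_set([0.1, 0.2], [0.1, 0.1]))


@settings(deadline=None, derandomize=True, max_examples=25)
@given(c=st.floats(0.1, 10.0), seed=st.integers(0, 50))
def test_mbe_scale_equivariance(c, seed):
    """Scaling ratios and SEs by c > 0 scales the mode by c (the Silverman
    bandwidth is scale-aware)."""
    rng = np.random.default_rng(seed)
    theta = np.concatenate([rng.normal(0.4, 0.05, 9), rng.normal(-1.0, 0.5, 4)])
    se = np.abs(rng.normal(0.08, 0.02, 13)) + 0.01
    base = mbe(_ratio_set(theta, se), n_boot=0).theta
    scaled = mbe(_ratio_set(c * theta, c * se), n_boot=0).theta
    assert scaled == pytest.approx(c * base, rel=1e-6, abs=1e-9 + 2e-3 * c)


def test_cm_all_valid_cluster():
    res = contamination_mixture(_ratio_set([0.5, 0.5, 0.5], [0.01] * 3), psi=1.0)
    assert res.theta == pytest.approx(0.5, abs=0.01)
    assert len(res.ci) == 1
    assert res.contains(0.5)


def test_cm_matches_exhaustive_assignment_oracle():
    """Estimate and confidence set agree with brute-force enumeration of all
    2^5 valid/invalid assignments."""
    theta = np.array([0.3, 0.3, 0.3, 2.0, -2.0])
    se = np.full(5, 0.05)
    psi = 1.0
    res = contamination_mixture(_ratio_set(theta, se), psi=psi,
                                grid_range=(-3.0, 3.0), grid_step=0.005)
    grid = -3.0 + 0.005 * np.arange(1201)
    o_theta, _, _, mask = cm_exhaustive_oracle(theta, se, psi, grid)
    assert res.theta == pytest.approx(o_theta, abs=0.005)
    runs = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    oracle_intervals = [(grid[a], grid[b - 1]) for a, b in zip(runs[::2], runs[1::2])]
    assert len(res.ci) == len(oracle_intervals)
    for (lo, hi), (olo, ohi) in zip(res.ci, oracle_intervals):
        assert lo == pytest.approx(olo, abs=0.011)
        assert hi == pytest.approx(ohi, abs=0.011)


def test_cm_bimodal_union_of_intervals():
    """Two equally sized tight clusters give a disjoint confidence set; the
    argmax tie resolves to the smaller theta."""
    theta = np.array([-0.5, -0.5, -0.5, -0.5, 0.5, 0.5, 0.5, 0.5])
    se = np.full(8, 0.01)
    res = contamination_mixture(_ratio_set(theta, se), psi=2.0,
                                grid_range=(-2.0, 2.0))
    assert len(res.ci) >= 2
    assert res.theta == pytest.approx(-0.5, abs=0.011)
    assert res.contains(-0.5) and res.contains(0.5) and not res.contains(0.0)


def test_cm_psi_sensitivity_sweep_reported():
    rng = np.random.default_rng(6)
    theta = np.concatenate([np.full(10, 0.3) + rng.normal(0, 0.01, 10),
                            rng.uniform(-2, 2, 5)])
    se = np.full(15, 0.05)
    res = contamination_mixture(_ratio_set(theta, se), psi=1.0,
                                psi_sensitivity=True)
    sweep = res.diagnostics["psi_sensitivity"]
    assert set(sweep) == {0.5, 1.0, 2.0}
    assert sweep[1.0] == pytest.approx(res.theta)
    for v in sweep.values():
        assert v == pytest.approx(0.3, abs=0.05)


def test_cm_boundary_argmax_on_explicit_grid_errors():
    with pytest.raises(ValueError, match="widen"):
        contamination_mixture(_ratio_set([5.0, 5.0, 5.0], [0.01] * 3),
                              psi=1.0, grid_range=(-1.0, 1.0))


def test_cm_needs_two_variants_and_positive_psi():
    with pytest.raises(ValueError):
        contamination_mixture(_ratio_set([0.3], [0.1]))
    with pytest.raises(ValueError):
        contamination_mixture(_ratio_set([0.3, 0.4], [0.1, 0.1]), psi=0.0)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(seed=st.integers(0, 100))
def test_modal_estimators_consistent_in_noiseless_limit(seed):
    """With a strict plurality of ratios exactly at theta0 and tiny SEs,
    both estimators return theta0 to grid/bandwidth resolution."""
    rng = np.random.default_rng(seed)
    theta0 = float(rng.uniform(-0.8, 0.8))
    n_valid, n_invalid = 7, 4
    theta = np.concatenate([
        np.full(n_valid, theta0) + rng.normal(0, 1e-6, n_valid),
        theta0 + rng.choice([-1, 1], n_invalid) * rng.uniform(0.7, 3.0, n_invalid),
    ])
    se = np.full(theta.size, 1e-3)
    cm = contamination_mixture(_ratio_set(theta, se), psi=1.0, grid_step=0.002)
    assert cm.theta == pytest.approx(theta0, abs=0.004)
    mb = mbe(_ratio_set(theta, se), n_boot=0)
    # the mode of the smoothed density sits within a fraction of a bandwidth
    # of the plurality cluster
    h = silverman_bandwidth(theta)
    assert mb.theta == pytest.approx(theta0, abs=max(0.01, 0.2 * h))


def test_estimate_result_invariants_enforced():
    with pytest.raises(ValueError):
        EstimateResult(theta=0.5, se=0.1, ci=[(0.6, 0.9)], method="x",
                       n_variants_used=3)
    with pytest.raises(ValueError):
        EstimateResult(theta=0.5, se=0.1, ci=[(0.4, 0.8), (0.7, 1.0)],
                       method="x", n_variants_used=3)
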