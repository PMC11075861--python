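"""Shared fixtures and independent oracles for the test suite.

The oracle implementations here are deliberately naive (normal equations,
exhaustive enumeration, dense-grid scans) and independent of the package's
code paths; tests compare the package against them.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pluralmr import MVMRDataset


# ---------------------------------------------------------------------------
# independent oracles


def wls_oracle(X, y, w, intercept=False):
    """Closed-form weighted least squares via the normal equations."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if intercept:
        X = np.column_stack([np.ones(len(X)), X])
    W = np.diag(np.asarray(w, float))
    return np.linalg.solve(X.T @ W @ X, X.T @ W @ np.asarray(y, float))


def weighted_median_oracle(values, weights):
    """Sort-and-accumulate weighted median (interpolated at the crossing)."""
    order = np.argsort(values)
    v = np.asarray(values, float)[order]
    w = np.asarray(weights, float)[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(0.5, cum, v))


def dense_grid_mode_oracle(theta, se, phi=1.0, step=1e-4, weighted=True):
    """Weighted-KDE mode by brute-force dense grid evaluation."""
    theta = np.asarray(theta, float)
    n = theta.size
    s = np.std(theta, ddof=1)
    q1, q3 = np.percentile(theta, [25, 75])
    h = phi * 0.9 * min(s, (q3 - q1) / 1.349) * n ** (-0.2)
    w = 1.0 / np.asarray(se, float) ** 2 if weighted else np.ones(n)
    w = w / w.sum()
    grid = np.arange(theta.min() - 3 * h, theta.max() + 3 * h, step)
    dens = np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2) @ w
    return float(grid[np.argmax(dens)])


def cm_exhaustive_oracle(theta, se, psi, grid):
    """Contamination-mixture profile by enumerating all 2^n valid/invalid
    assignments; returns (theta_hat, boolean CI mask over the grid)."""
    theta = np.asarray(theta, float)
    se = np.asarray(se, float)
    n = theta.size
    inv = -np.log(np.sqrt(se**2 + psi**2)) - 0.5 * np.log(2 * np.pi) - 0.5 * theta**2 / (
        se**2 + psi**2
    )
    best_overall = -np.inf
    best_theta = None
    profile = np.full(grid.shape, -np.inf)
    for assignment in itertools.product([False, True], repeat=n):
        valid = np.array(assignment)
        base = inv[~valid].sum()
        if valid.any():
            wv = 1.0 / se[valid] ** 2
            # per-assignment likelihood is maximised at the precision-
            # weighted mean of the valid ratios
            theta_opt = float(np.sum(wv * theta[valid]) / wv.sum())
            const = (-np.log(se[valid]) - 0.5 * np.log(2 * np.pi)).sum()

            def ll(t, c=const, b=base, v=valid):
                return b + c - 0.5 * np.sum(((theta[v] - t) / se[v]) ** 2)

            cand = ll(theta_opt)
            if cand > best_overall:
                best_overall, best_theta = cand, theta_opt
            profile = np.maximum(profile, np.array([ll(t) for t in grid]))
        else:
            profile = np.maximum(profile, base)
            if base > best_overall:
                best_overall, best_theta = base, None
    mask = 2 * (best_overall - profile) <= 3.841458820694124
    return best_theta, best_overall, profile, mask


def per_snp_ols_oracle(G, y):
    """Per-SNP simple linear regression (with intercept) via lstsq."""
    betas, ses = [], []
    n = len(y)
    for j in range(G.shape[1]):
        X = np.column_stack([np.ones(n), G[:, j]])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        sigma2 = resid @ resid / (n - 2)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        betas.append(coef[1])
        ses.append(np.sqrt(cov[1, 1]))
    return np.array(betas), np.array(ses)


# ---------------------------------------------------------------------------
# dataset builders


def random_summary_dataset(rng, n=50, k=2, heterogeneity=0.0):
    """A synthetic summary dataset with known effects (0.3, 0.4, -0.2, ...)."""
    effects = np.array([0.3, 0.4, -0.2, 0.1][:k])
    X = rng.normal(0.05, 0.02, (n, k))
    se_y = np.abs(rng.normal(0.005, 0.001, n)) + 1e-4
    y = X @ effects + rng.normal(0, se_y) + rng.normal(0, heterogeneity, n)
    return MVMRDataset(
        variant_ids=[f"rs{i}" for i in range(n)],
        beta_exposures=X,
        se_exposures=np.full((n, k), 0.004),
        beta_outcome=y,
        se_outcome=se_y,
        exposure_names=[f"x{j+1}" for j in range(k)],
    ), effects


def noiseless_dataset(n=40, k=2, seed=7):
    rng = np.random.default_rng(seed)
    effects = np.array([0.3, 0.4, -0.2][:k])
    X = rng.normal(0.05, 0.02, (n, k))
    y = X @ effects
    return MVMRDataset(
        variant_ids=[f"rs{i}" for i in range(n)],
        beta_exposures=X,
        se_exposures=np.full((n, k), 0.004),
        beta_outcome=y,
        se_outcome=np.full(n, 0.01),
        exposure_names=[f"x{j+1}" for j in range(k)],
    ), effects


@pytest.fixture
def small_dataset():
    ds, _ = random_summary_dataset(np.random.default_rng(11), n=30, k=2)
    return ds
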