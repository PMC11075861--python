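"""End-to-end multivariable MR estimators.

Five estimators of the direct causal effects theta_1..theta_K of K exposures
on an outcome from per-variant GWAS summary statistics:

* :class:`MVMRIVW` — intercept-free multiple WLS of the variant-outcome
  associations on the variant-exposure associations, weights 1/se_out^2;
* :class:`MVMREgger` — the same regression with an intercept, after
  orienting every variant to a positive association with exposure 1;
* :class:`MVMRMedian` — intercept-free weighted L1 (median) regression with
  a parametric-bootstrap standard error;
* :class:`MVMRMBE` — the residual framework: IVW residualisation per
  exposure, Wald ratios, then the univariable mode-based estimator;
* :class:`MVMRCM` — IVW residualisation feeding the contamination mixture.

All follow the scikit-learn estimator protocol: hyper-parameters in
``__init__``, data in ``fit(X, y, se_y=..., se_X=...)`` where ``X`` is the
(n_variants, K) matrix of variant-exposure associations and ``y`` the
variant-outcome associations, and fitted attributes with trailing
underscores (``estimate_``, ``se_``, ``conf_int_``, ``results_``).
``predict(X)`` returns fitted variant-outcome associations ``X @ estimate_``
(Egger adds its intercept), so the classes compose with sklearn tooling.

The module-level functions (:func:`mvmr_ivw`, ...) are thin wrappers taking
an :class:`~pluralmr.io.MVMRDataset` and returning an :class:`MVMRResult`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .modal import EstimateResult, RatioSet, Z_975, contamination_mixture, mbe
from .residualize import DEFAULT_FLOOR, residualize_arrays

logger = logging.getLogger(__name__)

__all__ = [
    "MVMRResult",
    "MVMRIVW",
    "MVMREgger",
    "MVMRMedian",
    "MVMRMBE",
    "MVMRCM",
    "mvmr_ivw",
    "mvmr_egger",
    "mvmr_median",
    "mvmr_mbe",
    "mvmr_cm",
    "METHODS",
]


@dataclass
class MVMRResult:
    """Per-exposure estimates from one multivariable method."""

    results: list  # K EstimateResult objects, in exposure order
    method: str
    exposure_names: list = field(default_factory=list)

    def __post_init__(self):
        if not self.exposure_names:
            self.exposure_names = [f"x{k + 1}" for k in range(len(self.results))]
        if len(self.exposure_names) != len(self.results):
            raise ValueError("one result per exposure required")

    @property
    def K(self) -> int:
        return len(self.results)

    @property
    def estimates(self) -> np.ndarray:
        return np.array([r.theta for r in self.results])

    def __getitem__(self, k) -> EstimateResult:
        if isinstance(k, str):
            k = self.exposure_names.index(k)
        return self.results[k]


def _validate_summary(X, y, se_y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] == 1 and y.size > 1:
        X = X.T
    if se_y is None:
        raise ValueError("se_y (outcome standard errors) is required")
    se_y = np.asarray(se_y, dtype=float).ravel()
    n, k = X.shape
    if y.shape[0] != n or se_y.shape[0] != n:
        raise ValueError("X, y and se_y must agree on the number of variants")
    if n <= k:
        raise ValueError(f"need more variants ({n}) than exposures ({k})")
    if np.any(se_y <= 0) or not np.all(np.isfinite(se_y)):
        raise ValueError("se_y must be finite and strictly positive")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("associations must be finite")
    return X, y, se_y


def _check_rank(design: np.ndarray, names) -> None:
    u, s, vt = np.linalg.svd(design, full_matrices=False)
    if s[-1] <= s[0] * np.finfo(float).eps * max(design.shape):
        null = np.abs(vt[-1]) > 1e-8
        involved = [str(names[j]) for j in np.flatnonzero(null) if j < len(names)]
        raise np.linalg.LinAlgError(
            f"rank-deficient design: exposures {involved} are collinear"
        )


def _wls_result(X, y, weights, names, add_intercept=False):
    """Floored multiplicative-overdispersion WLS.

    The residual-variance factor (statsmodels ``scale``) multiplies the
    coefficient covariance but is floored at 1: random-effects standard
    errors under heterogeneity, fixed-effect otherwise.
    """
    design = sm.add_constant(X) if add_intercept else X
    _check_rank(np.sqrt(weights)[:, None] * design, (["const"] if add_intercept else []) + list(names))
    fit = sm.WLS(y, design, weights=weights).fit()
    scale = float(fit.scale)
    infl = np.sqrt(max(scale, 1.0) / scale)
    params = np.asarray(fit.params, dtype=float)
    bse = np.asarray(fit.bse, dtype=float) * infl
    return params, bse, scale, fit


class _SummaryMVMR(BaseEstimator):
    """Shared fit plumbing for summary-data MVMR estimators."""

    _method = ""

    def fit(self, X, y, se_y=None, se_X=None, exposure_names=None):
        X, y, se_y = _validate_summary(X, y, se_y)
        if se_X is not None:
            se_X = np.atleast_2d(np.asarray(se_X, dtype=float))
            if se_X.shape[0] == 1 and X.shape[0] > 1:
                se_X = se_X.T
            if se_X.shape != X.shape:
                raise ValueError("se_X must match the shape of X")
        names = list(exposure_names) if exposure_names else [f"x{k+1}" for k in range(X.shape[1])]
        self.exposure_names_ = names
        self.n_features_in_ = X.shape[1]
        self.results_ = self._fit_summary(X, y, se_y, se_X, names)
        self.estimate_ = np.array([r.theta for r in self.results_])
        self.se_ = np.array([r.se for r in self.results_])
        self.conf_int_ = [r.ci for r in self.results_]
        self.n_variants_used_ = np.array([r.n_variants_used for r in self.results_])
        return self

    def fit_dataset(self, dataset):
        return self.fit(
            dataset.beta_exposures,
            dataset.beta_outcome,
            se_y=dataset.se_outcome,
            se_X=dataset.se_exposures,
            exposure_names=dataset.exposure_names,
        )

    def predict(self, X):
        check_is_fitted(self, "estimate_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.estimate_ + getattr(self, "intercept_", 0.0)

    def result(self) -> MVMRResult:
        check_is_fitted(self, "results_")
        return MVMRResult(list(self.results_), self._method, list(self.exposure_names_))

    def _fit_summary(self, X, y, se_y, se_X, names):  # pragma: no cover - abstract
        raise NotImplementedError


class MVMRIVW(_SummaryMVMR):
    """Multivariable inverse-variance-weighted estimator (Eq. of the model
    beta_y_i = sum_k theta_k beta_xk_i + eps_i, eps_i ~ N(0, se_y_i^2))."""

    _method = "ivw"

    def _fit_summary(self, X, y, se_y, se_X, names):
        w = 1.0 / se_y**2
        params, bse, scale, _ = _wls_result(X, y, w, names)
        self.scale_ = scale
        return [
            EstimateResult(
                theta=float(b), se=float(s),
                ci=[(b - Z_975 * s, b + Z_975 * s)],
                method=self._method, n_variants_used=X.shape[0],
                diagnostics={"overdispersion": scale},
            )
            for b, s in zip(params, bse)
        ]


class MVMREgger(_SummaryMVMR):
    """Multivariable MR-Egger: WLS with an intercept (average directional
    pleiotropy) after orienting every variant so its association with
    exposure 1 is positive."""

    _method = "egger"

    def _fit_summary(self, X, y, se_y, se_X, names):
        flip = np.where(X[:, 0] < 0, -1.0, 1.0)
        Xo = X * flip[:, None]
        yo = y * flip
        w = 1.0 / se_y**2
        params, bse, scale, _ = _wls_result(Xo, yo, w, names, add_intercept=True)
        self.intercept_ = float(params[0])
        self.intercept_se_ = float(bse[0])
        self.scale_ = scale
        diag = {"overdispersion": scale, "intercept": self.intercept_,
                "intercept_se": self.intercept_se_}
        return [
            EstimateResult(
                theta=float(b), se=float(s),
                ci=[(b - Z_975 * s, b + Z_975 * s)],
                method=self._method, n_variants_used=X.shape[0],
                diagnostics=dict(diag),
            )
            for b, s in zip(params[1:], bse[1:])
        ]


class MVMRMedian(_SummaryMVMR):
    """Multivariable weighted median: intercept-free quantile regression
    (tau = 0.5) of the outcome associations on the exposure associations,
    weighted by 1/se_out^2, with a parametric-bootstrap standard error.

    The weighted L1 objective sum_i w_i |y_i - x_i beta| is fitted by
    scaling each row by w_i (the check function is positively homogeneous),
    so ``QuantReg`` on the scaled data solves exactly the weighted problem.
    """

    _method = "median"

    def __init__(self, n_boot: int = 1000, random_state=None, max_iter: int = 2000):
        self.n_boot = n_boot
        self.random_state = random_state
        self.max_iter = max_iter

    def _solve(self, X, y, w):
        scaled = w[:, None] * X
        model = sm.QuantReg(w * y, scaled)
        fit = model.fit(q=0.5, max_iter=self.max_iter)
        if getattr(fit, "iterations", 0) >= self.max_iter:
            raise RuntimeError(
                f"weighted median regression did not converge in {self.max_iter} iterations"
            )
        return np.asarray(fit.params, dtype=float)

    def _fit_summary(self, X, y, se_y, se_X, names):
        w = 1.0 / se_y**2
        _check_rank(np.sqrt(w)[:, None] * X, names)
        params = self._solve(X, y, w)
        k = X.shape[1]
        ses = np.full(k, np.nan)
        if self.n_boot > 0:
            if se_X is None:
                raise ValueError("se_X is required for the parametric-bootstrap SE")
            rng = np.random.default_rng(self.random_state)
            boots = np.empty((self.n_boot, k))
            for b in range(self.n_boot):
                Xb = rng.normal(X, se_X)
                yb = rng.normal(y, se_y)
                boots[b] = self._solve(Xb, yb, w)
            ses = boots.std(axis=0, ddof=1)
        return [
            EstimateResult(
                theta=float(t), se=float(s),
                ci=[(t - Z_975 * s, t + Z_975 * s)] if np.isfinite(s) else [(t, t)],
                method=self._method, n_variants_used=X.shape[0],
                diagnostics={"n_boot": self.n_boot},
            )
            for t, s in zip(params, ses)
        ]


class _ResidualModal(_SummaryMVMR):
    """Residual-framework pipeline shared by the two plurality-valid
    estimators: per target exposure, IVW residualisation, Wald ratios, then
    a univariable modal estimator."""

    def __init__(self, floor: float = DEFAULT_FLOOR):
        self.floor = floor

    def _modal(self, ratios, k):  # pragma: no cover - abstract
        raise NotImplementedError

    def _fit_summary(self, X, y, se_y, se_X, names):
        from .modal import wald_ratios

        out = []
        for k in range(X.shape[1]):
            resid = residualize_arrays(X, y, se_y, target=k, floor=self.floor)
            res = self._modal(wald_ratios(resid), k)
            res.method = self._method
            out.append(res)
        return out


class MVMRMBE(_ResidualModal):
    """Multivariable mode-based estimator (residual framework + weighted
    kernel mode)."""

    _method = "mbe"

    def __init__(
        self,
        phi: float = 1.0,
        n_boot: int = 1000,
        weighted: bool = True,
        floor: float = DEFAULT_FLOOR,
        random_state=None,
    ):
        super().__init__(floor=floor)
        self.phi = phi
        self.n_boot = n_boot
        self.weighted = weighted
        self.random_state = random_state

    def _modal(self, ratios: RatioSet, k: int) -> EstimateResult:
        seed = self.random_state
        rng = np.random.default_rng(None if seed is None else [int(seed) % 2**31, k])
        return mbe(
            ratios,
            phi=self.phi,
            n_boot=self.n_boot,
            rng=rng,
            weighted=self.weighted,
        )


class MVMRCM(_ResidualModal):
    """Multivariable contamination mixture (residual framework + profile
    likelihood over valid/invalid variant classes)."""

    _method = "cm"

    def __init__(
        self,
        psi: float | None = None,
        grid_step: float = 0.01,
        grid_range: tuple | None = None,
        psi_sensitivity: bool = False,
        floor: float = DEFAULT_FLOOR,
    ):
        super().__init__(floor=floor)
        self.psi = psi
        self.grid_step = grid_step
        self.grid_range = grid_range
        self.psi_sensitivity = psi_sensitivity

    def _modal(self, ratios: RatioSet, k: int) -> EstimateResult:
        return contamination_mixture(
            ratios,
            psi=self.psi,
            grid_step=self.grid_step,
            grid_range=self.grid_range,
            psi_sensitivity=self.psi_sensitivity,
        )


def _wrap(cls):
    def run(dataset, **kwargs) -> MVMRResult:
        return cls(**kwargs).fit_dataset(dataset).result()

    run.__name__ = f"mvmr_{cls._method}"
    run.__doc__ = f"Run :class:`{cls.__name__}` on an MVMRDataset and return an MVMRResult."
    return run


mvmr_ivw = _wrap(MVMRIVW)
mvmr_egger = _wrap(MVMREgger)
mvmr_median = _wrap(MVMRMedian)
mvmr_mbe = _wrap(MVMRMBE)
mvmr_cm = _wrap(MVMRCM)

METHODS = {
    "ivw": MVMRIVW,
    "egger": MVMREgger,
    "median": MVMRMedian,
    "mbe": MVMRMBE,
    "cm": MVMRCM,
}
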