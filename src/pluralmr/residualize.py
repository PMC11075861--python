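"""Residual construction for the residual framework of multivariable MR.

For a target exposure, the variant-outcome associations and the
variant-target-exposure associations are each regressed (without an
intercept) on the associations with the remaining exposures, using weighted
least squares with weights 1/se_out^2.  The residual pair (beta_y_resid,
beta_x_resid) then plays the role of a univariable instrument set: its
per-variant Wald ratios can be fed to any univariable estimator.

Both regressions use the *same* outcome-variance weights.  That choice makes
the residual path exactly reproduce direct multivariable IVW for the target
coefficient (Frisch-Waugh-Lovell), which is the structural identity the
residual framework's validity argument rests on.

The residual Wald-ratio standard error is the first-order approximation
se_out_i / |beta_x_resid_i|: the exposure associations are treated as
measured precisely enough to contribute no error, so residualisation leaves
the outcome standard error untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ResidualizedData", "ivw_residualize", "residual_se"]

#: variants whose residual exposure association is below this absolute value
#: are dropped (their Wald ratio is undefined)
DEFAULT_FLOOR = 1e-10


@dataclass
class ResidualizedData:
    """Residualised associations for one target exposure."""

    beta_y_resid: np.ndarray
    beta_x_resid: np.ndarray
    se_resid: np.ndarray
    target_exposure: int
    n_variants: int
    kept: np.ndarray  # indices into the source dataset rows
    dropped_variants: list

    def __post_init__(self):
        for name in ("beta_y_resid", "beta_x_resid", "se_resid"):
            arr = np.asarray(getattr(self, name), dtype=float).ravel()
            setattr(self, name, arr)
            if arr.shape[0] != self.n_variants:
                raise ValueError(f"{name} length {arr.shape[0]} != n_variants {self.n_variants}")


def _wls_no_intercept(design: np.ndarray, targets: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Intercept-free WLS coefficients for one or more target vectors.

    ``targets`` has one column per regression; all share ``design`` and
    ``weights``.  Raises on rank deficiency (e.g. an all-zero regressor).
    """
    sw = np.sqrt(weights)[:, None]
    a = design * sw
    b = targets * sw
    coef, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            "singular design in residualising regression (collinear or zero "
            "exposure associations)"
        )
    return coef


def residual_se(se_outcome: np.ndarray, beta_x_resid: np.ndarray) -> np.ndarray:
    """Element-wise first-order Wald-ratio SE: se_outcome / |beta_x_resid|."""
    se_outcome = np.asarray(se_outcome, dtype=float)
    beta_x_resid = np.asarray(beta_x_resid, dtype=float)
    denom = np.abs(beta_x_resid)
    if np.any(denom == 0):
        raise ZeroDivisionError(
            "zero residual exposure association: the Wald ratio standard "
            "error is undefined (such variants should have been dropped)"
        )
    return se_outcome / denom


def residualize_arrays(
    beta_exposures: np.ndarray,
    beta_outcome: np.ndarray,
    se_outcome: np.ndarray,
    target: int,
    floor: float = DEFAULT_FLOOR,
    variant_ids=None,
) -> ResidualizedData:
    """Array-level residualisation; see :func:`ivw_residualize`."""
    bx = np.atleast_2d(np.asarray(beta_exposures, dtype=float))
    if bx.shape[0] == 1 and np.asarray(beta_outcome).size > 1:
        bx = bx.T
    by = np.asarray(beta_outcome, dtype=float).ravel()
    se = np.asarray(se_outcome, dtype=float).ravel()
    n, k = bx.shape
    if not 0 <= target < k:
        raise IndexError(f"target exposure {target} out of range for K={k}")
    if variant_ids is None:
        variant_ids = [str(i) for i in range(n)]

    others = [j for j in range(k) if j != target]
    if others:
        w = 1.0 / se**2
        design = bx[:, others]
        coef = _wls_no_intercept(design, np.column_stack([by, bx[:, target]]), w)
        by_res = by - design @ coef[:, 0]
        bx_res = bx[:, target] - design @ coef[:, 1]
    else:
        # K = 1: nothing to regress out, the residual path is the identity
        by_res = by.copy()
        bx_res = bx[:, target].copy()

    keep = np.abs(bx_res) >= floor
    dropped = [variant_ids[i] for i in np.flatnonzero(~keep)]
    if dropped:
        logger.warning(
            "residualize: dropped %d variant(s) with |residual exposure association| < %g: %s",
            len(dropped), floor, ", ".join(map(str, dropped[:10])),
        )
    if not np.any(keep):
        raise ValueError("all variants dropped: residual exposure associations are ~0")

    kept = np.flatnonzero(keep)
    return ResidualizedData(
        beta_y_resid=by_res[keep],
        beta_x_resid=bx_res[keep],
        se_resid=residual_se(se[keep], bx_res[keep]),
        target_exposure=int(target),
        n_variants=int(keep.sum()),
        kept=kept,
        dropped_variants=dropped,
    )


def ivw_residualize(dataset, target: int, floor: float = DEFAULT_FLOOR) -> ResidualizedData:
    """Residualise a dataset's outcome and target-exposure associations.

    Regresses the variant-outcome associations, and the variant-target-
    exposure associations, on the remaining K-1 exposures' associations in a
    single joint intercept-free WLS with weights 1/se_out^2, and returns the
    residual pair with first-order standard errors.

    Requires K >= 2 (with a single exposure there is nothing to residualise;
    use the univariable estimators directly).  Variants whose residual
    exposure association falls below ``floor`` in absolute value are dropped
    with a warning.
    """
    if dataset.n_exposures < 2:
        raise ValueError(
            "residualisation needs at least two exposures; for K=1 use a "
            "univariable estimator on the raw associations"
        )
    return residualize_arrays(
        dataset.beta_exposures,
        dataset.beta_outcome,
        dataset.se_outcome,
        target,
        floor=floor,
        variant_ids=dataset.variant_ids,
    )
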