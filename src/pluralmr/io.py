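"""Reading, validating and writing multivariable MR summary datasets.

The on-disk format is delimited text with one row per genetic variant and
columns

    snp, beta_<exposure>, se_<exposure> (one pair per exposure),
    beta_out, se_out

holding effect-allele-aligned per-variant association estimates and their
standard errors for K exposures and one outcome.  Inputs are assumed to be
pre-harmonised (allele alignment, strand flips and proxy lookup are out of
scope); rows with any missing cell are dropped with a logged count because
every estimator in this package needs complete rows.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["MVMRDataset", "read_dataset", "write_dataset"]


class DatasetValidationError(ValueError):
    """Raised when a summary dataset violates its invariants."""


@dataclass
class MVMRDataset:
    """Per-variant association estimates for K exposures and one outcome.

    Attributes
    ----------
    variant_ids : list of str
        Identifiers (typically rsids) of the n variants.
    beta_exposures : ndarray, shape (n, K)
        Per-allele variant-exposure association estimates.
    se_exposures : ndarray, shape (n, K)
        Standard errors of ``beta_exposures``; strictly positive.
    beta_outcome : ndarray, shape (n,)
        Variant-outcome association estimates.
    se_outcome : ndarray, shape (n,)
        Standard errors of ``beta_outcome``; strictly positive.
    exposure_names : list of str
        Names of the K exposures, in column order.
    """

    variant_ids: list
    beta_exposures: np.ndarray
    se_exposures: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    exposure_names: list = field(default_factory=list)

    def __post_init__(self):
        self.beta_exposures = np.atleast_2d(np.asarray(self.beta_exposures, dtype=float))
        self.se_exposures = np.atleast_2d(np.asarray(self.se_exposures, dtype=float))
        if self.beta_exposures.shape[0] == 1 and len(self.variant_ids) > 1:
            # a 1-D vector for a single exposure came in as a row
            self.beta_exposures = self.beta_exposures.T
            self.se_exposures = self.se_exposures.T
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float).ravel()
        self.se_outcome = np.asarray(self.se_outcome, dtype=float).ravel()
        self.variant_ids = [str(v) for v in self.variant_ids]
        if not self.exposure_names:
            self.exposure_names = [f"x{k + 1}" for k in range(self.beta_exposures.shape[1])]
        self.exposure_names = [str(e) for e in self.exposure_names]
        self.validate()

    @property
    def n_variants(self) -> int:
        return self.beta_exposures.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.beta_exposures.shape[1]

    def validate(self) -> None:
        n, k = self.beta_exposures.shape
        if n < 1:
            raise DatasetValidationError("dataset must contain at least one variant")
        if k < 1:
            raise DatasetValidationError("dataset must contain at least one exposure")
        if self.se_exposures.shape != (n, k):
            raise DatasetValidationError(
                f"se_exposures shape {self.se_exposures.shape} does not match beta_exposures {(n, k)}"
            )
        for name, arr in (("beta_outcome", self.beta_outcome), ("se_outcome", self.se_outcome)):
            if arr.shape != (n,):
                raise DatasetValidationError(f"{name} has length {arr.shape[0]}, expected {n}")
        if len(self.variant_ids) != n:
            raise DatasetValidationError("variant_ids length does not match the matrices")
        if len(self.exposure_names) != k:
            raise DatasetValidationError("exposure_names length does not match beta_exposures")
        for name, arr in (
            ("beta_exposures", self.beta_exposures),
            ("se_exposures", self.se_exposures),
            ("beta_outcome", self.beta_outcome),
            ("se_outcome", self.se_outcome),
        ):
            if not np.all(np.isfinite(arr)):
                bad = np.argwhere(~np.isfinite(arr))[0]
                raise DatasetValidationError(
                    f"non-finite value in {name} at variant {self.variant_ids[int(bad[0])]}"
                )
        for name, arr in (("se_exposures", self.se_exposures), ("se_outcome", self.se_outcome)):
            bad = np.argwhere(~(arr > 0))
            if bad.size:
                raise DatasetValidationError(
                    f"non-positive standard error in {name} for variant "
                    f"{self.variant_ids[int(bad[0][0])]}"
                )

    def subset(self, index) -> "MVMRDataset":
        """Return the dataset restricted to the given row index."""
        index = np.asarray(index)
        return MVMRDataset(
            variant_ids=[self.variant_ids[i] for i in np.arange(self.n_variants)[index]],
            beta_exposures=self.beta_exposures[index],
            se_exposures=self.se_exposures[index],
            beta_outcome=self.beta_outcome[index],
            se_outcome=self.se_outcome[index],
            exposure_names=list(self.exposure_names),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"snp": self.variant_ids}
        for k, name in enumerate(self.exposure_names):
            data[f"beta_{name}"] = self.beta_exposures[:, k]
            data[f"se_{name}"] = self.se_exposures[:, k]
        data["beta_out"] = self.beta_outcome
        data["se_out"] = self.se_outcome
        return pd.DataFrame(data)


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if os.path.splitext(str(path))[1].lower() in {".tsv", ".tab", ".txt"} else ","


def read_dataset(path, column_map: dict | None = None, delimiter: str | None = None) -> MVMRDataset:
    """Read a delimited summary-statistics file into an :class:`MVMRDataset`.

    Parameters
    ----------
    path : path-like
        Delimited text file with a header row.  The delimiter is taken from
        the extension (``.tsv``/``.tab``/``.txt`` tab, otherwise comma)
        unless ``delimiter`` is given.
    column_map : dict, optional
        Overrides column names.  Keys: ``id`` (variant-id column),
        ``exposures`` (mapping exposure name -> (beta column, se column)),
        ``outcome`` ((beta column, se column)).  By default columns follow
        the ``snp, beta_<name>, se_<name>, beta_out, se_out`` convention and
        exposure names are discovered from the header.
    """
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), float_precision="round_trip")
    column_map = column_map or {}
    id_col = column_map.get("id", "snp")
    if id_col not in df.columns:
        raise KeyError(f"required variant-id column {id_col!r} missing from {path}")

    if "exposures" in column_map:
        exposures = dict(column_map["exposures"])
    else:
        exposures = {}
        for col in df.columns:
            if col.startswith("beta_") and col != "beta_out":
                name = col[len("beta_"):]
                se_col = f"se_{name}"
                if se_col not in df.columns:
                    raise KeyError(f"exposure column {col!r} has no matching {se_col!r}")
                exposures[name] = (col, se_col)
    if not exposures:
        raise KeyError(f"no exposure beta/se column pairs found in {path}")
    out_beta, out_se = column_map.get("outcome", ("beta_out", "se_out"))

    needed = [id_col, out_beta, out_se]
    for b, s in exposures.values():
        needed.extend([b, s])
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise KeyError(f"required columns missing from {path}: {missing}")

    numeric = [c for c in needed if c != id_col]
    df[numeric] = df[numeric].apply(pd.to_numeric, errors="coerce")
    complete = df[numeric].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("read_dataset: dropped %d row(s) with missing cells from %s", n_dropped, path)
    df = df[complete]
    if df.empty:
        raise DatasetValidationError(f"no complete rows in {path}")

    names = list(exposures)
    return MVMRDataset(
        variant_ids=df[id_col].astype(str).tolist(),
        beta_exposures=df[[exposures[e][0] for e in names]].to_numpy(float),
        se_exposures=df[[exposures[e][1] for e in names]].to_numpy(float),
        beta_outcome=df[out_beta].to_numpy(float),
        se_outcome=df[out_se].to_numpy(float),
        exposure_names=names,
    )


def write_dataset(dataset: MVMRDataset, path, delimiter: str | None = None):
    """Write a dataset so that :func:`read_dataset` round-trips it exactly.

    Floats are printed with 17 significant digits, which is lossless for
    IEEE doubles.
    """
    dataset.validate()
    dataset.to_frame().to_csv(
        path, sep=_delimiter_for(path, delimiter), index=False, float_format="%.17g"
    )
    return path
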