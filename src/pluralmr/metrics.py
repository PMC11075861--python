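"""Performance measures and comparison tables for the simulation study.

Replicate-level estimates are aggregated per (scenario, method, exposure)
cell into:

* bias — mean(estimate) minus the true effect;
* sd — sample standard deviation of the estimates (n-1 denominator);
* ci_width — mean 95% CI width; for disjoint confidence sets the width is
  the sum of the interval widths (the hull width is kept as a diagnostic);
* pct_ci_includes_zero — percentage of replicates whose confidence set
  contains 0 (any interval of the union counts);
* coverage — percentage containing the true effect.

In null scenarios coverage and pct_ci_includes_zero coincide by definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PerformanceTable",
    "aggregate",
    "render_table",
    "serialize_ci",
    "parse_ci",
]

METRIC_BLOCKS = ["Bias", "95% CI width", "% CI includes 0"]
COLUMN_ORDER = ["none", "b10", "b20", "b40", "d10", "d20", "d40"]
COLUMN_TITLES = {
    "none": "No bias",
    "b10": "10% balanced pleiotropy",
    "b20": "20% balanced pleiotropy",
    "b40": "40% balanced pleiotropy",
    "d10": "10% directional pleiotropy",
    "d20": "20% directional pleiotropy",
    "d40": "40% directional pleiotropy",
}


def serialize_ci(ci) -> str:
    """Render a union of intervals as ``lo:hi|lo:hi`` (17 digits, lossless)."""
    return "|".join(f"{lo:.17g}:{hi:.17g}" for lo, hi in ci)


def parse_ci(text: str) -> list:
    if not isinstance(text, str) or not text:
        return []
    out = []
    for part in text.split("|"):
        lo, hi = part.split(":")
        out.append((float(lo), float(hi)))
    return out


def _ci_stats(ci_text: str, truth: float):
    ci = parse_ci(ci_text)
    finite = [iv for iv in ci if np.isfinite(iv[0]) and np.isfinite(iv[1])]
    if not finite:
        return np.nan, np.nan, np.nan, np.nan
    width = sum(hi - lo for lo, hi in finite)
    hull = finite[-1][1] - finite[0][0]
    inc0 = any(lo <= 0.0 <= hi for lo, hi in finite)
    inct = any(lo <= truth <= hi for lo, hi in finite)
    return width, hull, float(inc0), float(inct)


@dataclass
class PerformanceTable:
    """Aggregated performance measures, one row per
    (scenario, method, exposure)."""

    frame: pd.DataFrame

    def get(self, scenario: str, method: str, exposure: str, metric: str):
        f = self.frame
        row = f[
            (f.scenario == scenario) & (f.method == method) & (f.exposure == exposure)
        ]
        if row.empty:
            raise KeyError(f"no cell ({scenario}, {method}, {exposure})")
        return float(row.iloc[0][metric])

    def __len__(self):
        return len(self.frame)


def aggregate(replicates: pd.DataFrame, truth: dict, expected=None) -> PerformanceTable:
    """Aggregate replicate-level results into the performance measures.

    Parameters
    ----------
    replicates : DataFrame
        Columns scenario, rep, method, exposure, estimate, ci (serialized).
    truth : dict
        ``truth[scenario][exposure]`` -> true causal effect.
    expected : iterable of (scenario, method, exposure), optional
        Cells that must appear; empty ones are emitted flagged with
        ``n_effective_reps = 0`` rather than silently dropped.
    """
    rows = []
    seen = set()
    if not replicates.empty:
        for (scenario, method, exposure), grp in replicates.groupby(
            ["scenario", "method", "exposure"], sort=True
        ):
            t = float(truth[scenario][exposure])
            est = grp["estimate"].to_numpy(float)
            stats = np.array([_ci_stats(c, t) for c in grp["ci"]])
            ok = np.isfinite(stats[:, 0])
            rows.append(
                {
                    "scenario": scenario,
                    "method": method,
                    "exposure": exposure,
                    "truth": t,
                    "bias": float(np.mean(est) - t),
                    "sd": float(np.std(est, ddof=1)) if est.size > 1 else np.nan,
                    "ci_width": float(np.mean(stats[ok, 0])) if ok.any() else np.nan,
                    "ci_width_hull": float(np.mean(stats[ok, 1])) if ok.any() else np.nan,
                    "pct_ci_includes_zero": float(100 * np.mean(stats[ok, 2])) if ok.any() else np.nan,
                    "coverage": float(100 * np.mean(stats[ok, 3])) if ok.any() else np.nan,
                    "n_effective_reps": int(est.size),
                    "flagged": False,
                }
            )
            seen.add((scenario, method, exposure))
    for cell in expected or []:
        if tuple(cell) not in seen:
            rows.append(
                {
                    "scenario": cell[0], "method": cell[1], "exposure": cell[2],
                    "truth": np.nan, "bias": np.nan, "sd": np.nan,
                    "ci_width": np.nan, "ci_width_hull": np.nan,
                    "pct_ci_includes_zero": np.nan, "coverage": np.nan,
                    "n_effective_reps": 0, "flagged": True,
                }
            )
    return PerformanceTable(pd.DataFrame(rows))


_METRIC_COLUMNS = {
    "Bias": "bias",
    "95% CI width": "ci_width",
    "% CI includes 0": "pct_ci_includes_zero",
}


def render_table(table: PerformanceTable, layout: str, path=None):
    """Render the primary-results comparison table for one effect setting.

    ``layout`` is ``"table1"`` (both exposures causal) or ``"table2"``
    (neither causal).  Rows are metric blocks x method x exposure; columns
    are the pleiotropy settings in study order.  Missing cells are rendered
    as the explicit gap marker ``"--"``.
    """
    prefix = {"table1": "causal", "table2": "null"}[layout]
    f = table.frame
    f = f[f.scenario.str.startswith(prefix + "_")]
    methods = list(dict.fromkeys(f["method"]))
    exposures = sorted(set(f["exposure"]))
    rows = []
    for metric in METRIC_BLOCKS:
        col = _METRIC_COLUMNS[metric]
        for method in methods:
            for exposure in exposures:
                row = {"metric": metric, "method": method, "exposure": exposure}
                for code in COLUMN_ORDER:
                    cell = f[
                        (f.scenario == f"{prefix}_{code}")
                        & (f.method == method)
                        & (f.exposure == exposure)
                    ]
                    row[COLUMN_TITLES[code]] = (
                        float(cell.iloc[0][col]) if len(cell) else "--"
                    )
                rows.append(row)
    out = pd.DataFrame(rows)
    if path is not None:
        out.to_csv(path, index=False)
        return path
    return out
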