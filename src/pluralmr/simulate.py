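"""Monte-Carlo simulation of two-exposure multivariable MR studies.

The data-generating mechanism simulates, per replicate:

* ``n_snps`` independent bi-allelic variants, genotype ~
  Binomial(1, maf) + Binomial(1, maf);
* per-SNP effects on each exposure drawn independently per exposure,
  b ~ N(b_mean, b_sd^2);
* pleiotropic direct effects p ~ N(pleio_mean, pleio_sd^2) on the first
  ``p_pleio`` SNPs;
* a standard-normal confounder C and unit-variance noise on every trait;
* exposure 1 = conf_e1*C + G b1 + eps, exposure 2 = conf_e2*C + G b2 + eps,
  outcome = conf_out*C + theta1*E1 + theta2*EPl + G p + eps with causal
  effects (theta1, theta2) = (0.3, 0.4) or (0, 0).

Genetic associations with each trait are estimated by per-SNP ordinary
least squares (with intercept) in three mutually disjoint samples of
``n_per_gwas`` individuals — one sample per GWAS, no sample overlap — and
assembled into an :class:`~pluralmr.io.MVMRDataset`.

Implementation notes: within a sample only one trait is ever regressed, so
the confounder and noise contributions are drawn as a single normal with
the combined standard deviation (distributionally identical and cheaper),
and genotypes are generated by thresholding 16-bit uniform integers
(category probabilities exact to 2^-16, a deviation below 2e-5 that is
orders of magnitude under the sampling noise of the allele frequency).
Per-sample individual-level data live only in reused buffers; memory does
not grow with the number of replicates.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import METHODS
from .io import MVMRDataset
from .metrics import PerformanceTable, aggregate, serialize_ci

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationScenario",
    "GwasEngine",
    "simulate_replicate",
    "conditional_f",
    "marginal_f",
    "run_study",
    "StudyResult",
    "scenario_grid",
    "PLEIO_CODES",
]

#: pleiotropy settings of the study: code -> (fraction of SNPs affected,
#: mean pleiotropic effect).  b = balanced (zero mean), d = directional
#: (mean -0.03); with the default 200 SNPs the fractions give 0/20/40/80
#: pleiotropic variants.
PLEIO_CODES = {
    "none": (0.0, 0.0),
    "b10": (0.1, 0.0),
    "b20": (0.2, 0.0),
    "b40": (0.4, 0.0),
    "d10": (0.1, -0.03),
    "d20": (0.2, -0.03),
    "d40": (0.4, -0.03),
}

TRUE_EFFECTS = (0.3, 0.4)


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulation design."""

    causal: bool = True
    p_pleio: int = 0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.1
    n_snps: int = 200
    maf: float = 0.4
    b_mean: float = 0.05
    b_sd: float = 0.02
    conf_e1: float = 0.3
    conf_e2: float = 0.4
    conf_out: float = 1.0
    noise_sd: float = 1.0
    n_per_gwas: int = 200_000
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.p_pleio <= self.n_snps:
            raise ValueError("p_pleio must lie in [0, n_snps]")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        for name in ("pleio_sd", "b_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_per_gwas < 10:
            raise ValueError("n_per_gwas unrealistically small")

    @property
    def effects(self) -> tuple:
        return TRUE_EFFECTS if self.causal else (0.0, 0.0)

    @property
    def pleio_code(self) -> str:
        if self.p_pleio == 0:
            return "none"
        pct = round(100 * self.p_pleio / self.n_snps)
        return f"{'d' if self.pleio_mean != 0 else 'b'}{pct}"

    @property
    def label(self) -> str:
        return f"{'causal' if self.causal else 'null'}_{self.pleio_code}"


def scenario_grid(causal=None, pleio=None, **overrides) -> list:
    """Scenarios of the full study: 2 effect settings x 7 pleiotropy settings.

    ``causal`` (bool) and ``pleio`` (code or list of codes) restrict the
    grid; keyword overrides (e.g. ``n_per_gwas``) apply to every scenario.
    """
    causal_opts = [True, False] if causal is None else [bool(causal)]
    if pleio is None:
        codes = list(PLEIO_CODES)
    else:
        codes = [pleio] if isinstance(pleio, str) else list(pleio)
    n_snps = overrides.get("n_snps", SimulationScenario.n_snps)
    out = []
    for c in causal_opts:
        for code in codes:
            frac, mean = PLEIO_CODES[code]
            out.append(
                SimulationScenario(
                    causal=c, p_pleio=round(frac * n_snps), pleio_mean=mean, **overrides
                )
            )
    return out


class GwasEngine:
    """Reusable-buffer generator of per-SNP OLS GWAS summary statistics."""

    def __init__(self, n_individuals: int, n_snps: int, maf: float):
        self.n = int(n_individuals)
        self.p = int(n_snps)
        self.maf = float(maf)
        p2 = maf * maf
        p12 = 1.0 - (1.0 - maf) ** 2
        self._t2 = np.uint16(round(p2 * 65536))
        self._t12 = np.uint16(round(p12 * 65536))
        self._G = np.empty((self.n, self.p), dtype=np.float32)
        self._mask = np.empty((self.n, self.p), dtype=np.bool_)

    def gwas(
        self,
        rng: np.random.Generator,
        snp_effects: np.ndarray,
        nongenetic_sd: float,
        keep_sample: bool = False,
    ):
        """Simulate one sample and regress the trait on each SNP.

        Returns per-SNP OLS slope estimates and standard errors (intercept
        included in each regression).  ``keep_sample`` stores the genotype
        matrix and (centred) trait on ``last_sample_`` for verification
        against an independent regression on the raw data.
        """
        n, p = self.n, self.p
        v = rng.integers(0, 1 << 16, size=(n, p), dtype=np.uint16)
        np.less(v, self._t2, out=self._mask)  # homozygous effect-allele
        n2 = self._mask.sum(axis=0, dtype=np.int64)
        np.copyto(self._G, self._mask)
        np.less(v, self._t12, out=self._mask)
        np.add(self._G, self._mask, out=self._G, casting="unsafe")
        del v

        s1 = self._G.sum(axis=0, dtype=np.float64)
        y = self._G @ snp_effects.astype(np.float32)
        y += rng.normal(0.0, nongenetic_sd, n).astype(np.float32)
        y -= np.float32(y.mean(dtype=np.float64))
        gy = (self._G.T @ y).astype(np.float64)
        syy = float(y @ y)

        if keep_sample:
            self.last_sample_ = (self._G.astype(np.uint8), np.asarray(y, dtype=np.float64).copy())

        sxx = (s1 + 2.0 * n2) - s1 * s1 / n
        sxy = gy - s1 * (float(y.sum(dtype=np.float64)) / n)
        beta = sxy / sxx
        rss = np.maximum(syy - beta * sxy, 0.0)
        se = np.sqrt(rss / (n - 2) / sxx)
        return beta, se


_engine_cache: dict = {}


def _get_engine(n: int, p: int, maf: float) -> GwasEngine:
    key = (n, p, maf)
    if key not in _engine_cache:
        _engine_cache.clear()  # hold at most one buffer set
        _engine_cache[key] = GwasEngine(n, p, maf)
    return _engine_cache[key]


def simulate_replicate(
    scenario: SimulationScenario, rng=None, engine: GwasEngine | None = None
) -> MVMRDataset:
    """Generate one replicate's MVMRDataset (three disjoint GWAS samples)."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if engine is None:
        engine = _get_engine(scenario.n_per_gwas, scenario.n_snps, scenario.maf)

    p = scenario.n_snps
    th1, th2 = scenario.effects
    b1 = rng.normal(scenario.b_mean, scenario.b_sd, p)
    b2 = rng.normal(scenario.b_mean, scenario.b_sd, p)
    pleio = np.zeros(p)
    if scenario.p_pleio:
        pleio[: scenario.p_pleio] = rng.normal(
            scenario.pleio_mean, scenario.pleio_sd, scenario.p_pleio
        )

    eps = scenario.noise_sd
    sd_e1 = float(np.hypot(scenario.conf_e1, eps))
    sd_e2 = float(np.hypot(scenario.conf_e2, eps))
    conf_coef_out = scenario.conf_out + th1 * scenario.conf_e1 + th2 * scenario.conf_e2
    sd_out = float(np.sqrt(conf_coef_out**2 + (th1**2 + th2**2 + 1.0) * eps**2))

    bx1, sx1 = engine.gwas(rng, b1, sd_e1)
    bx2, sx2 = engine.gwas(rng, b2, sd_e2)
    by, sy = engine.gwas(rng, th1 * b1 + th2 * b2 + pleio, sd_out)

    return MVMRDataset(
        variant_ids=[f"snp{j + 1}" for j in range(p)],
        beta_exposures=np.column_stack([bx1, bx2]),
        se_exposures=np.column_stack([sx1, sx2]),
        beta_outcome=by,
        se_outcome=sy,
        exposure_names=["E1", "E2"],
    )


def conditional_f(dataset: MVMRDataset, exposure: int = 0) -> float:
    """Summary-data conditional F statistic of one exposure given the rest.

    Regresses the target exposure's associations on the other exposures'
    associations (intercept-free WLS, weights w_i = 1/se_x_target_i^2) and
    returns F = sum(w_i d_i^2) / (n_variants - K), d being the residuals.
    With K = 1 this reduces to the mean-F-style marginal strength
    sum(w_i beta_i^2)/(n - 1).
    """
    bx = dataset.beta_exposures
    n, k = bx.shape
    if n <= k:
        raise ValueError("conditional F needs more variants than exposures")
    target = bx[:, exposure]
    w = 1.0 / dataset.se_exposures[:, exposure] ** 2
    others = np.delete(bx, exposure, axis=1)
    if others.shape[1]:
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(others * sw[:, None], target * sw, rcond=None)
        delta = target - others @ coef
    else:
        delta = target
    return float(np.sum(w * delta**2) / (n - k))


def marginal_f(dataset: MVMRDataset, exposure: int = 0) -> float:
    """Mean per-variant (marginal) F statistic, mean((beta/se)^2), for one
    exposure — the univariable instrument-strength summary conventionally
    reported alongside GWAS instruments."""
    z = dataset.beta_exposures[:, exposure] / dataset.se_exposures[:, exposure]
    return float(np.mean(z**2))


@dataclass
class StudyResult:
    """Replicate-level and aggregated results of a simulation study."""

    replicates: pd.DataFrame
    performance: PerformanceTable
    fstats: pd.DataFrame
    n_failures: int = 0
    failures: list = field(default_factory=list)


def _make_estimator(method: str, options: dict, seed: int):
    opts = dict(options.get(method, {}))
    cls = METHODS[method]
    if method in ("mbe", "median"):
        opts.setdefault("random_state", seed)
    return cls(**opts)


def run_study(
    scenarios,
    n_reps: int,
    methods=("ivw", "egger", "median", "mbe", "cm"),
    seed: int = 0,
    method_options: dict | None = None,
    compute_f: bool = False,
    out_dir=None,
    progress: bool = False,
) -> StudyResult:
    """Run the Monte-Carlo study: scenarios x replicates x methods.

    Per replicate a fresh :class:`MVMRDataset` is simulated and every
    requested method fitted; per-replicate estimates are retained (and
    written to ``out_dir`` when given) and aggregated into the performance
    measures (bias, SD, CI width, % CI includes zero, coverage).  Estimator
    failures are logged, counted and excluded cell-wise.

    Seeding is hierarchical (scenario, then replicate) so results are
    reproducible and independent of the order scenarios are listed in.
    """
    if isinstance(scenarios, SimulationScenario):
        scenarios = [scenarios]
    method_options = method_options or {}
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise KeyError(f"unknown methods: {sorted(unknown)}")

    rows, frows, failures = [], [], []
    root = np.random.SeedSequence(seed)
    for scenario in scenarios:
        scen_seq = np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(zlib.crc32(scenario.label.encode()),)
        )
        engine = _get_engine(scenario.n_per_gwas, scenario.n_snps, scenario.maf)
        for rep, rep_seq in enumerate(scen_seq.spawn(n_reps)):
            rng = np.random.Generator(np.random.SFC64(rep_seq))
            dataset = simulate_replicate(scenario, rng, engine)
            est_seed = int(rng.integers(2**31))
            if compute_f:
                frows.append(
                    {
                        "scenario": scenario.label,
                        "rep": rep,
                        **{
                            f"f_conditional_{name}": conditional_f(dataset, k)
                            for k, name in enumerate(dataset.exposure_names)
                        },
                        **{
                            f"f_marginal_{name}": marginal_f(dataset, k)
                            for k, name in enumerate(dataset.exposure_names)
                        },
                    }
                )
            for method in methods:
                try:
                    est = _make_estimator(method, method_options, est_seed)
                    result = est.fit_dataset(dataset).result()
                except Exception as exc:  # noqa: BLE001 - failures are data
                    logger.warning(
                        "%s failed on %s rep %d: %s", method, scenario.label, rep, exc
                    )
                    failures.append((scenario.label, rep, method, str(exc)))
                    continue
                for k, er in enumerate(result.results):
                    rows.append(
                        {
                            "scenario": scenario.label,
                            "rep": rep,
                            "method": method,
                            "exposure": dataset.exposure_names[k],
                            "estimate": er.theta,
                            "se": er.se,
                            "ci": serialize_ci(er.ci),
                            "n_variants": er.n_variants_used,
                        }
                    )
            if progress and (rep + 1) % 25 == 0:
                logger.info("%s: %d/%d replicates", scenario.label, rep + 1, n_reps)

    replicates = pd.DataFrame(rows)
    truth = {
        s.label: dict(zip(["E1", "E2"], s.effects)) for s in scenarios
    }
    performance = aggregate(replicates, truth)
    fstats = pd.DataFrame(frows)
    result = StudyResult(
        replicates=replicates,
        performance=performance,
        fstats=fstats,
        n_failures=len(failures),
        failures=failures,
    )
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        replicates.to_csv(os.path.join(out_dir, "replicates.csv"), index=False)
        performance.frame.to_csv(os.path.join(out_dir, "performance.csv"), index=False)
        if not fstats.empty:
            fstats.to_csv(os.path.join(out_dir, "fstats.csv"), index=False)
    return result
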