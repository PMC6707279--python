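"""Latent-factor survival-cohort simulator.

Emulates the statistical structure the downstream analysis assumes on a
bulk tumor cohort: two anti-correlated latent factors, each read out by a
seed gene and a module of genes loading on it with signed loadings; a
designated subset of module genes carries proportional-hazards log-hazard
coefficients of consistent sign per module; survival times come from an
exponential baseline hazard via the inverse-transform, with independent
exponential censoring and an administrative cutoff. Optional hazard-free
"decoy" modules provide negative-control seeds for signature ranking.

The defaults mirror a TCGA-style lung adenocarcinoma cohort: 521 tumors,
seed-seed correlation -0.42, follow-up administratively truncated at 200
months, and roughly 35-40% observed deaths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coexsurv.io import ExpressionMatrix, IHCTable, SurvivalTable

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


def _default_signs(size: int, frac_negative: float = 1 / 3) -> np.ndarray:
    # both arms of a co-expression signature exist: last third anti-correlated
    signs = np.ones(size)
    signs[size - int(round(size * frac_negative)):] = -1.0
    return signs


@dataclass
class SimConfig:
    """Parameters of one simulated cohort.

    Loadings are per-module-gene correlations to the latent factor
    (population Pearson r of gene g to its seed equals ``sign * loading``).
    Hazard coefficients are log-hazards per SD of expression attached to
    the first ``n_hazard_*`` genes of each module, with the module-wide
    sign convention ``hazard_beta_* * sign(g)`` so the module's hazard acts
    coherently through its factor.
    """

    n_samples: int = 521
    n_genes: int = 1000
    seed_a: str = "SEEDA"
    seed_b: str = "SEEDB"
    module_size_a: int = 150
    module_size_b: int = 150
    loadings_a: np.ndarray | float = 0.6
    loadings_b: np.ndarray | float = 0.6
    signs_a: np.ndarray | None = None
    signs_b: np.ndarray | None = None
    seed_anticorrelation: float = -0.42
    hazard_beta_a: float = 0.01
    hazard_beta_b: float = -0.01
    n_hazard_a: int | None = None  # default: all module-A genes
    n_hazard_b: int | None = None
    seed_noise_sd: float = 0.05
    baseline_rate: float = 0.014  # events per month (median ~50 months)
    censor_rate: float = 0.015
    admin_cutoff: float = 200.0
    n_decoy_modules: int = 0
    decoy_module_size: int = 0
    decoy_loading: float = 0.6
    rng_seed: int = 0

    def __post_init__(self):
        self.loadings_a = self._expand(self.loadings_a, self.module_size_a, "loadings_a")
        self.loadings_b = self._expand(self.loadings_b, self.module_size_b, "loadings_b")
        if self.signs_a is None:
            self.signs_a = _default_signs(self.module_size_a)
        if self.signs_b is None:
            self.signs_b = _default_signs(self.module_size_b)
        self.signs_a = np.asarray(self.signs_a, dtype=float)
        self.signs_b = np.asarray(self.signs_b, dtype=float)
        if self.n_hazard_a is None:
            self.n_hazard_a = self.module_size_a
        if self.n_hazard_b is None:
            self.n_hazard_b = self.module_size_b
        if not (-1.0 <= self.seed_anticorrelation <= 0.0):
            raise ConfigError("seed_anticorrelation must lie in [-1, 0]")
        if self.baseline_rate <= 0:
            raise ConfigError("baseline_rate must be > 0")
        if self.admin_cutoff <= 0:
            raise ConfigError("admin_cutoff must be > 0")
        n_planted = 2 + self.module_size_a + self.module_size_b + self.n_decoy_modules * (1 + self.decoy_module_size)
        if n_planted > self.n_genes:
            raise ConfigError(
                f"module sizes require {n_planted} genes but n_genes={self.n_genes}"
            )
        for name, lam in (("loadings_a", self.loadings_a), ("loadings_b", self.loadings_b)):
            if np.any(lam <= 0) or np.any(lam > 1):
                raise ConfigError(f"{name} must lie in (0, 1]")

    @staticmethod
    def _expand(lam, size, name) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        if lam.ndim == 0:
            lam = np.full(size, float(lam))
        if lam.shape != (size,):
            raise ConfigError(f"{name} must be scalar or length {size}")
        return lam


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a simulated cohort, for recovery testing."""

    genes: pd.DataFrame      # gene, module, loading, sign, beta
    samples: pd.DataFrame    # sample, f_a, f_b, eta

    def module_genes(self, module: str) -> list[str]:
        return self.genes.loc[self.genes["module"] == module, "gene"].tolist()

    def hazard_genes(self) -> list[str]:
        return self.genes.loc[self.genes["beta"] != 0, "gene"].tolist()


def simulate_survival(
    eta: np.ndarray,
    baseline_rate: float,
    censor_rate: float,
    admin_cutoff: float,
    rng_seed: int | np.random.Generator = 0,
    sample_ids=None,
) -> SurvivalTable:
    """Exponential proportional-hazards survival via inverse transform.

    Event time ``T_i = -ln(U_i) / (rate * exp(eta_i))``; censoring time is
    the minimum of an Exp(censor_rate) draw and the administrative cutoff;
    the recorded time is ``min(T, C)`` with ``event = [T <= C]``.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    n = eta.size
    u = rng.uniform(size=n)
    t_event = -np.log(u) / (baseline_rate * np.exp(eta))
    if censor_rate > 0:
        c = np.minimum(rng.exponential(1.0 / censor_rate, size=n), admin_cutoff)
    else:
        c = np.full(n, admin_cutoff)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    # guard against a zero recorded time from floating underflow
    time = np.maximum(time, np.finfo(float).tiny)
    if event.sum() == 0:
        logger.warning("all %d samples censored; downstream scoring requires >= 2 events", n)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    frame = pd.DataFrame({"sample": list(sample_ids), "time": time, "event": event})
    return SurvivalTable(frame=frame)


def generate_cohort(config: SimConfig) -> tuple[ExpressionMatrix, SurvivalTable, GroundTruth]:
    """Draw one cohort: expression, survival and the planted ground truth.

    Factors ``f_A, f_B`` are jointly standard Gaussian with the configured
    correlation. A seed-gene row equals its factor plus small noise; module
    gene g is ``sign_g * loading_g * f + sqrt(1 - loading_g^2) * eps`` so its
    population correlation to the seed equals ``sign_g * loading_g``. The
    remaining genes are independent noise. The per-sample linear predictor
    is ``eta_i = sum_g beta_g x_gi`` over hazard genes (on the pre-shift
    standardized scale) and feeds :func:`simulate_survival`. Finally the
    whole matrix is mapped affinely to non-negative log2-like values.
    """
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_samples

    rho = cfg.seed_anticorrelation
    z = rng.standard_normal((2, n))
    f_a = z[0]
    f_b = rho * z[0] + np.sqrt(1.0 - rho**2) * z[1]

    gene_names: list[str] = []
    rows: list[np.ndarray] = []
    truth_rows: list[dict] = []

    def add_gene(name, values, module, loading, sign, beta):
        gene_names.append(name)
        rows.append(values)
        truth_rows.append({"gene": name, "module": module, "loading": loading, "sign": sign, "beta": beta})

    noise_sd = cfg.seed_noise_sd
    add_gene(cfg.seed_a, f_a + noise_sd * rng.standard_normal(n), "seed_a", 1.0, 1.0, 0.0)
    add_gene(cfg.seed_b, f_b + noise_sd * rng.standard_normal(n), "seed_b", 1.0, 1.0, 0.0)

    def add_module(prefix, module, factor, loadings, signs, beta0, n_hazard):
        for j, (lam, s) in enumerate(zip(loadings, signs)):
            eps = rng.standard_normal(n)
            x = s * lam * factor + np.sqrt(1.0 - lam**2) * eps
            beta = beta0 * s if j < n_hazard else 0.0
            add_gene(f"{prefix}{j + 1:04d}", x, module, float(lam), float(s), float(beta))

    add_module("MA", "module_a", f_a, cfg.loadings_a, cfg.signs_a, cfg.hazard_beta_a, cfg.n_hazard_a)
    add_module("MB", "module_b", f_b, cfg.loadings_b, cfg.signs_b, cfg.hazard_beta_b, cfg.n_hazard_b)

    for d in range(cfg.n_decoy_modules):
        f_d = rng.standard_normal(n)
        name = f"SEED{chr(ord('C') + d)}" if d < 24 else f"SEEDD{d}"
        add_gene(name, f_d + noise_sd * rng.standard_normal(n), f"decoy_seed_{d}", 1.0, 1.0, 0.0)
        lam = cfg.decoy_loading
        signs = _default_signs(cfg.decoy_module_size)
        for j in range(cfg.decoy_module_size):
            eps = rng.standard_normal(n)
            x = signs[j] * lam * f_d + np.sqrt(1.0 - lam**2) * eps
            add_gene(f"MD{d}_{j + 1:04d}", x, f"decoy_module_{d}", lam, float(signs[j]), 0.0)

    n_noise = cfg.n_genes - len(gene_names)
    for j in range(n_noise):
        add_gene(f"NG{j + 1:05d}", rng.standard_normal(n), "noise", 0.0, 0.0, 0.0)

    raw = np.vstack(rows)
    truth_genes = pd.DataFrame(truth_rows)

    betas = truth_genes["beta"].to_numpy()
    hazard_idx = np.nonzero(betas)[0]
    eta = betas[hazard_idx] @ raw[hazard_idx] if hazard_idx.size else np.zeros(n)

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    survival = simulate_survival(
        eta, cfg.baseline_rate, cfg.censor_rate, cfg.admin_cutoff, rng, sample_ids=sample_ids
    )

    # affine map onto a non-negative log2(x+1)-like scale; correlations are
    # unaffected, the clip at zero touches only a ~5e-7 tail
    values = np.clip(7.0 + 1.5 * raw, 0.0, None)
    matrix = ExpressionMatrix(gene_ids=tuple(gene_names), sample_ids=tuple(sample_ids), values=values)

    truth = GroundTruth(
        genes=truth_genes,
        samples=pd.DataFrame({"sample": sample_ids, "f_a": f_a, "f_b": f_b, "eta": eta}),
    )
    return matrix, survival, truth


def generate_ihc_fixture(counts: dict[str, dict[int, int]]) -> IHCTable:
    """Deterministic IHC table with exact per-(marker, score) cell counts.

    Markers with equal totals share the same patient ids (assigned in
    score order), so a two-marker fixture behaves like one cohort scored
    for both markers. Ids are stable across runs.
    """
    rows = []
    for marker in sorted(counts):
        per_score = counts[marker]
        i = 0
        for score in sorted(per_score):
            c = int(per_score[score])
            if c < 0:
                raise ValueError("counts must be non-negative")
            if not (0 <= int(score) <= 3):
                raise ValueError(f"score {score} outside 0..3")
            for _ in range(c):
                i += 1
                rows.append({"sample": f"P{i:04d}", "marker": marker, "score": int(score)})
    frame = pd.DataFrame(rows, columns=["sample", "marker", "score"])
    if len(frame) == 0:
        frame = frame.astype({"score": int})
    return IHCTable(frame=frame)


def luad_ihc_counts() -> dict[str, dict[int, int]]:
    """Score-category counts of the motivating 140-patient IHC cohort.

    Only the dichotomized margins are established (AK1: 58 low / 82 high;
    AK4: 66 low / 74 high); each margin is split evenly across its two
    scores, odd remainder to the lower score. Synthetic in that respect.
    """
    return {
        "AK1": {0: 29, 1: 29, 2: 41, 3: 41},
        "AK4": {0: 33, 1: 33, 2: 37, 3: 37},
    }
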