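"""Per-gene survival z-scores and signature-level prognostic scoring.

The survival z-score of a gene is the Wald z of a univariate Cox
proportional-hazards fit of outcome on the gene's standardized (mean 0,
SD 1) expression, with Efron handling of tied event times. A gene is
prognostic when |z| strictly exceeds 2: positive z is adverse (higher
expression, higher hazard), negative z protective. A signature's score is
the percentage of its members that are prognostic.

The Cox solver is a Newton iteration on the Efron partial likelihood,
vectorized across genes so a whole-transcriptome scan is a handful of
matrix operations per iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coexsurv.coexpression import CoexpressionSignature
from coexsurv.io import ExpressionMatrix, SurvivalTable

logger = logging.getLogger(__name__)

Z_CLAMP = 37.0  # reported |z| under monotone likelihood (perfect separation)


class CoxError(RuntimeError):
    pass


@dataclass(frozen=True)
class GeneSurvivalStat:
    """Univariate Cox summary for one gene: beta per SD of expression."""

    gene: str
    beta: float
    se: float
    z: float
    hr: float
    n_samples: int
    n_events: int
    separated: bool = False

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError("standard error must be positive")


@dataclass(frozen=True)
class SignatureProfile:
    """Prognostic content of one signature: counts, percentage, quadrants.

    Quadrant keys are (sign of r to the seed, sign of z) over the
    prognostic members only, mirroring the r-vs-z scatter of a signature.
    """

    seed_gene: str
    n_total: int
    n_prognostic: int
    percent: float
    quadrants: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.percent <= 100.0):
            raise ValueError("percent must lie in [0, 100]")
        if sum(self.quadrants.values()) != self.n_prognostic:
            raise ValueError("quadrant counts must sum to n_prognostic")


# ---------------------------------------------------------------------------
# Efron partial-likelihood machinery


def _prepare(time: np.ndarray, event: np.ndarray):
    """Sort by time ascending and group ties; precompute event-group layout."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = event[order]
    # group boundaries of tied times
    starts = np.r_[0, 1 + np.nonzero(np.diff(t))[0]]
    group_of = np.cumsum(np.r_[0, np.diff(t) != 0])
    k = len(starts)
    d_per_group = np.bincount(group_of, weights=d, minlength=k).astype(int)
    eg = np.nonzero(d_per_group)[0]             # groups containing >= 1 event
    d_eg = d_per_group[eg]
    gi = np.repeat(np.arange(len(eg)), d_eg)    # event slot -> index into eg
    frac = np.concatenate([np.arange(m) / m for m in d_eg]) if len(eg) else np.array([])
    return order, d.astype(float), starts, eg, gi, frac


def _efron_terms(W, XW, X2W, starts, ev_mask, eg, gi, frac):
    """Risk-set and tied-event sums entering the Efron likelihood."""
    def revcum(a):
        return np.cumsum(a[:, ::-1], axis=1)[:, ::-1]

    s0r = revcum(np.add.reduceat(W, starts, axis=1))
    s1r = revcum(np.add.reduceat(XW, starts, axis=1))
    s2r = revcum(np.add.reduceat(X2W, starts, axis=1))
    s0d = np.add.reduceat(W * ev_mask, starts, axis=1)[:, eg]
    s1d = np.add.reduceat(XW * ev_mask, starts, axis=1)[:, eg]
    s2d = np.add.reduceat(X2W * ev_mask, starts, axis=1)[:, eg]
    a0 = s0r[:, eg][:, gi] - frac * s0d[:, gi]
    a1 = s1r[:, eg][:, gi] - frac * s1d[:, gi]
    a2 = s2r[:, eg][:, gi] - frac * s2d[:, gi]
    return a0, a1, a2


def _cox_newton(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                max_iter: int = 60, tol: float = 1e-10):
    """Vectorized univariate Newton solver, one Cox fit per row of X.

    Returns (beta, se, separated) arrays. X rows should be standardized.
    """
    n_genes, n = X.shape
    order, d, starts, eg, gi, frac = _prepare(time, event)
    Xs = X[:, order]
    ev_mask = d[None, :]
    sum_x_events = (Xs * ev_mask).sum(axis=1)

    beta = np.zeros(n_genes)
    active = np.ones(n_genes, dtype=bool)
    info = np.full(n_genes, np.nan)
    separated = np.zeros(n_genes, dtype=bool)

    for _ in range(max_iter):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        Xa = Xs[idx]
        Ba = beta[idx][:, None]
        E = np.clip(Ba * Xa, -500, 500)
        W = np.exp(E)
        XW = Xa * W
        X2W = Xa * XW
        a0, a1, a2 = _efron_terms(W, XW, X2W, starts, ev_mask, eg, gi, frac)
        m1 = a1 / a0
        grad = sum_x_events[idx] - m1.sum(axis=1)
        fisher = (a2 / a0 - m1**2).sum(axis=1)
        fisher = np.maximum(fisher, 1e-12)
        step = np.clip(grad / fisher, -1.0, 1.0)
        beta[idx] += step
        info[idx] = fisher
        done = (np.abs(grad) < tol) | (np.abs(step) < 1e-13)
        diverged = np.abs(beta[idx]) > 20.0
        separated[idx[diverged]] = True
        active[idx] = ~(done | diverged)

    if active.any():
        # ran out of iterations without a monotone-likelihood flag
        separated |= active
    se = 1.0 / np.sqrt(info)
    return beta, se, separated


def efron_loglik(beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Scalar Efron partial log-likelihood (reference form, plain loops)."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        at_risk = time >= t
        wd = np.exp(beta * x[dead])
        wr = np.exp(beta * x[at_risk])
        m = int(dead.sum())
        ll += beta * x[dead].sum()
        for l in range(m):
            ll -= np.log(wr.sum() - (l / m) * wd.sum())
    return float(ll)


# ---------------------------------------------------------------------------
# public operations


def _align(expr_values: np.ndarray, expr_samples, surv: SurvivalTable):
    surv_idx = surv.frame.set_index("sample")
    keep = [i for i, s in enumerate(expr_samples) if s in surv_idx.index]
    n_dropped = len(expr_samples) - len(keep)
    if n_dropped:
        logger.info("dropped %d samples without survival annotation", n_dropped)
    samples = [expr_samples[i] for i in keep]
    sub = surv_idx.loc[samples]
    return expr_values[..., keep], sub["time"].to_numpy(float), sub["event"].to_numpy(int)


def cox_z_scan(
    matrix: ExpressionMatrix,
    surv: SurvivalTable,
    genes=None,
) -> pd.DataFrame:
    """Univariate Cox z for every requested gene (default: all genes).

    Returns a DataFrame (gene, beta, se, z, hr, n_samples, n_events,
    separated) in the input gene order; zero-variance genes are dropped
    with a logged count.
    """
    if genes is None:
        genes = list(matrix.gene_ids)
    missing = [g for g in genes if g not in matrix.gene_ids]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    sel = [gene_pos[g] for g in genes]
    X, time, event = _align(matrix.values[sel], list(matrix.sample_ids), surv)
    if event.sum() < 2:
        raise CoxError("need at least 2 events for survival scoring")

    sd = X.std(axis=1, ddof=0)
    keep = sd > 0
    n_zero = int((~keep).sum())
    if n_zero:
        logger.warning("dropped %d zero-variance genes from Cox scan", n_zero)
    genes_kept = [g for g, k in zip(genes, keep) if k]
    Xk = X[keep]
    Xk = (Xk - Xk.mean(axis=1, keepdims=True)) / sd[keep][:, None]

    beta, se, separated = _cox_newton(Xk, time, event)
    z = beta / se
    bad = np.abs(z) > Z_CLAMP
    if (separated | bad).any():
        logger.warning("%d genes hit monotone likelihood; z clamped to +/-%g",
                       int((separated | bad).sum()), Z_CLAMP)
    z = np.where(separated | bad, np.sign(beta) * Z_CLAMP, z)

    return pd.DataFrame({
        "gene": genes_kept,
        "beta": beta,
        "se": se,
        "z": z,
        "hr": np.exp(beta),
        "n_samples": len(time),
        "n_events": int(event.sum()),
        "separated": separated | bad,
    })


def cox_z(expr_g, surv: SurvivalTable, gene: str = "") -> GeneSurvivalStat:
    """Univariate Cox fit for a single gene's expression vector.

    ``expr_g`` may be a pandas Series indexed by sample id (aligned to the
    survival table by id) or a plain vector already aligned with it.
    """
    if isinstance(expr_g, pd.Series):
        name = gene or str(expr_g.name or "")
        values = expr_g.to_numpy(float)[None, :]
        samples = [str(s) for s in expr_g.index]
    else:
        name = gene
        values = np.asarray(expr_g, float)[None, :]
        samples = list(surv.frame["sample"])
        if values.shape[1] != len(samples):
            raise ValueError("unlabelled expression vector must align with the survival table")
    X, time, event = _align(values, samples, surv)
    if event.sum() < 2:
        raise CoxError(f"gene {name!r}: need at least 2 events")
    sd = X.std(axis=1, ddof=0)
    if sd[0] == 0:
        raise CoxError(f"gene {name!r}: zero-variance expression")
    Xk = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    beta, se, separated = _cox_newton(Xk, time, event)
    z = float(beta[0] / se[0])
    sep = bool(separated[0]) or abs(z) > Z_CLAMP
    if sep:
        logger.warning("gene %s: monotone likelihood, z clamped to +/-%g", name, Z_CLAMP)
        z = float(np.sign(beta[0]) * Z_CLAMP)
    return GeneSurvivalStat(
        gene=name, beta=float(beta[0]), se=float(se[0]), z=z,
        hr=float(np.exp(beta[0])), n_samples=len(time), n_events=int(event.sum()),
        separated=sep,
    )


def flag_prognostic(stats, threshold: float = 2.0) -> pd.DataFrame:
    """Mark genes prognostic when |z| strictly exceeds the threshold.

    Accepts a DataFrame from :func:`cox_z_scan` or an iterable of
    :class:`GeneSurvivalStat`. Direction is "adverse" for z > 0,
    "protective" for z < 0.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not isinstance(stats, pd.DataFrame):
        stats = pd.DataFrame([{"gene": s.gene, "z": s.z} for s in stats])
    out = stats[["gene", "z"]].copy()
    out["prognostic"] = np.abs(out["z"]) > threshold
    out["direction"] = np.where(out["z"] > 0, "adverse", "protective")
    return out


def prognostic_fraction(signature: CoexpressionSignature, flags: pd.DataFrame) -> SignatureProfile:
    """Score a signature by the percentage of prognostic members.

    Members without a flag entry are dropped with a logged count. The
    quadrant counts cross the sign of each prognostic member's r to the
    seed with the sign of its survival z.
    """
    fl = flags.set_index("gene")
    known = [(g, r) for g, r in signature.members if g in fl.index]
    n_dropped = len(signature) - len(known)
    if n_dropped:
        logger.warning("signature %s: %d members lack survival flags and were dropped",
                       signature.seed_gene, n_dropped)
    if not known:
        logger.warning("signature %s is empty after flag matching; percent reported as 0",
                       signature.seed_gene)
        return SignatureProfile(seed_gene=signature.seed_gene, n_total=0, n_prognostic=0,
                                percent=0.0, quadrants={})
    quadrants: dict[tuple[str, str], int] = {}
    n_prog = 0
    for g, r in known:
        if bool(fl.loc[g, "prognostic"]):
            n_prog += 1
            key = ("+" if r > 0 else "-", "+" if fl.loc[g, "z"] > 0 else "-")
            quadrants[key] = quadrants.get(key, 0) + 1
    n_total = len(known)
    return SignatureProfile(
        seed_gene=signature.seed_gene,
        n_total=n_total,
        n_prognostic=n_prog,
        percent=100.0 * n_prog / n_total,
        quadrants=quadrants,
    )


def rank_signatures(profiles) -> list[SignatureProfile]:
    """Order signature profiles by percent prognostic, descending.

    Ties break by seed symbol ascending; the sort is stable.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    return sorted(profiles, key=lambda p: (-p.percent, p.seed_gene))
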