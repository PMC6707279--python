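"""Gene-set enrichment of a ranked signature and upstream-regulator calls.

Three tools:

* pre-ranked weighted Kolmogorov-Smirnov enrichment (running-sum ES with
  a gene-label permutation null, signed one-sided permutation p, NES and
  Benjamini-Hochberg FDR across sets);
* hypergeometric over-representation of an unranked query set against a
  collection (a transparent stand-in for proprietary pathway scoring);
* upstream-regulator activation z over a signed regulator->target
  network: z = (N_consistent - N_inconsistent) / sqrt(N), with |z| >= 2
  declaring an activated or inhibited state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    fdr: float
    n_hits: int
    leading_edge: tuple[str, ...]

    def __post_init__(self):
        if not (-1.0 <= self.es <= 1.0):
            raise ValueError("ES must lie in [-1, 1]")
        if self.n_hits < 1:
            raise ValueError("a reported set must have at least one hit")


@dataclass(frozen=True)
class RegulatorCall:
    regulator: str
    n_targets_observed: int
    z_activation: float
    state: str  # activated | inhibited | not-significant
    low_evidence: bool = False

    def __post_init__(self):
        expected = "activated" if self.z_activation >= 2 else (
            "inhibited" if self.z_activation <= -2 else "not-significant")
        if self.state != expected:
            raise ValueError("state inconsistent with z threshold")


# ---------------------------------------------------------------------------
# weighted-KS enrichment score


def _es_from_hits(abs_w: np.ndarray, hit_pos: np.ndarray, n: int):
    """ES and extremum index from sorted 0-based hit positions.

    The running sum changes only at hits; between consecutive hits it
    decays linearly by the miss penalty, so the signed maximum deviation
    is attained either at a hit (upward extreme) or immediately before
    one / at the end (downward extreme).
    """
    nh = hit_pos.size
    if nh == n:  # no misses: the sum climbs monotonically to 1
        return 1.0, n - 1
    miss_pen = 1.0 / (n - nh)
    w = abs_w[hit_pos]
    tot = w.sum()
    if tot == 0:
        # all hit scores exactly zero: hits contribute nothing
        cum_hit = np.zeros(nh)
    else:
        cum_hit = np.cumsum(w) / tot
    j = np.arange(1, nh + 1)
    up = cum_hit - (hit_pos + 1 - j) * miss_pen          # right after each hit
    down = np.r_[0.0, cum_hit[:-1]] - (hit_pos - (j - 1)) * miss_pen  # right before
    i_up = int(np.argmax(up))
    i_dn = int(np.argmin(down))
    if up[i_up] >= -down[i_dn]:
        return float(up[i_up]), int(hit_pos[i_up])
    return float(down[i_dn]), int(hit_pos[i_dn]) - 1


def es_running_sum(ranked, gene_set, weight_p: float = 1.0):
    """Enrichment score of one gene set against a ranked (gene, score) list.

    Hits increment by |score|^p normalized over the hits; misses decrement
    by 1/(N - N_hits). Returns (es, running_sum_profile, leading_edge).
    The leading edge contains the members at or before the extremum for a
    positive ES, and at or after it for a negative ES.
    """
    genes = [g for g, _ in ranked]
    scores = np.array([s for _, s in ranked], dtype=float)
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    n = len(genes)
    members = set(gene_set.members) if hasattr(gene_set, "members") else set(gene_set)
    hit_mask = np.array([g in members for g in genes])
    nh = int(hit_mask.sum())
    if nh == 0:
        raise ValueError("no gene-set member present in the ranked list")
    abs_w = np.abs(scores) ** weight_p
    # O(N) running sum (returned for plotting / inspection)
    if nh == n:
        inc = abs_w / abs_w.sum() if abs_w.sum() > 0 else np.full(n, 1.0 / n)
        running = np.cumsum(inc)
        es, extremum = 1.0, n - 1
    else:
        tot_hit = abs_w[hit_mask].sum()
        inc = np.where(hit_mask, abs_w / tot_hit if tot_hit > 0 else 0.0, -1.0 / (n - nh))
        running = np.cumsum(inc)
        es, extremum = _es_from_hits(abs_w, np.nonzero(hit_mask)[0], n)
    if es >= 0:
        leading = tuple(g for i, g in enumerate(genes) if hit_mask[i] and i <= extremum)
    else:
        leading = tuple(g for i, g in enumerate(genes) if hit_mask[i] and i > extremum)
    return float(np.clip(es, -1.0, 1.0)), running, leading


def _null_es(abs_w: np.ndarray, n_hits: int, n_perm: int, rng) -> np.ndarray:
    """Gene-label permutation null: ES of random same-size sets."""
    n = abs_w.size
    null = np.empty(n_perm)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n, size=n_hits, replace=False))
        null[i], _ = _es_from_hits(abs_w, pos, n)
    return null


def preranked_gsea(
    ranked,
    collection,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> list[EnrichmentResult]:
    """Pre-ranked enrichment of every set in a collection.

    The null draws ``n_perm`` random same-size gene sets from the ranked
    universe. The permutation p-value is the one-sided tail among
    same-sign null ES with add-one continuity; NES divides the observed
    ES by the mean |null ES| of the same sign; FDR is Benjamini-Hochberg
    across the reported sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(rng_seed)
    genes = [g for g, _ in ranked]
    scores = np.array([s for _, s in ranked], dtype=float)
    n = len(genes)
    abs_w = np.abs(scores) ** weight_p
    universe = set(genes)

    rows = []
    for gs in collection:
        present = [m for m in gs.members if m in universe]
        if not present:
            logger.warning("set %s: no member in the ranked universe; skipped", gs.name)
            continue
        if len(gs.members) > n:
            logger.warning("set %s is larger than the universe; skipped", gs.name)
            continue
        es, _, leading = es_running_sum(ranked, present, weight_p)
        null = _null_es(abs_w, len(present), n_perm, rng)
        same = null[null >= 0] if es >= 0 else null[null < 0]
        n_extreme = int((np.abs(same) >= abs(es)).sum())
        p = (1 + n_extreme) / (1 + same.size)
        denom = np.abs(same).mean() if same.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        rows.append({"set": gs.name, "es": es, "nes": nes, "p": p,
                     "n_hits": len(present), "leading": leading})
    if not rows:
        return []
    pvals = np.array([r["p"] for r in rows])
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return [
        EnrichmentResult(
            set_name=r["set"], es=r["es"], nes=float(r["nes"]), p_perm=float(r["p"]),
            fdr=float(q), n_hits=r["n_hits"], leading_edge=r["leading"],
        )
        for r, q in zip(rows, fdr)
    ]


# ---------------------------------------------------------------------------
# over-representation


def overrepresentation(query, collection, universe) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a query gene set.

    Returns one row per set: overlap k, set size K in the universe,
    raw p (P[X >= k]), BH-adjusted p, and -log10(p).
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("universe is empty")
    uni = set(universe)
    query = set(query)
    dropped = query - uni
    if dropped:
        logger.warning("dropped %d query genes outside the universe", len(dropped))
    query &= uni
    if not query:
        raise ValueError("query has no genes in the universe")
    n_uni, n_query = len(uni), len(query)

    rows = []
    for gs in collection:
        in_uni = set(gs.members) & uni
        if not in_uni:
            continue
        k = len(query & in_uni)
        # P[X >= k] for X ~ Hypergeom(N=n_uni, K=|set|, n=|query|)
        p = float(stats.hypergeom.sf(k - 1, n_uni, len(in_uni), n_query))
        rows.append({"set": gs.name, "k_overlap": k, "set_size": len(in_uni),
                     "query_size": n_query, "universe_size": n_uni, "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["set", "k_overlap", "set_size", "query_size", "universe_size", "p"])
    if len(df):
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df["neg_log10_p"] = -np.log10(np.maximum(df["p"].to_numpy(), 1e-300))
        df = df.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# upstream-regulator activation


def upstream_activation_z(network, observed) -> list[RegulatorCall]:
    """Activation z per regulator over its observed targets.

    ``network`` holds signed (regulator, target, sign in {+1,-1}) edges
    (iterable of triples or a DataFrame with those columns); ``observed``
    maps gene -> direction in {+1,-1} (e.g. adverse +1 / protective -1
    from the consensus signature). A target is consistent when
    ``edge_sign * observed_direction == +1``; then
    ``z = (N_consistent - N_inconsistent) / sqrt(N)``. Regulators with
    fewer than 3 observed targets are reported but flagged low-evidence.
    """
    if isinstance(network, pd.DataFrame):
        edges = list(network[["regulator", "target", "sign"]].itertuples(index=False, name=None))
    else:
        edges = list(network)
    obs = dict(observed)
    per_reg: dict[str, list[int]] = {}
    for reg, target, sign in edges:
        if sign not in (1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
        if target in obs:
            per_reg.setdefault(reg, []).append(int(sign) * int(obs[target]))
    calls = []
    for reg in sorted(per_reg):
        agreement = per_reg[reg]
        n = len(agreement)
        n_consistent = sum(1 for a in agreement if a == 1)
        z = (2 * n_consistent - n) / np.sqrt(n)
        state = "activated" if z >= 2 else ("inhibited" if z <= -2 else "not-significant")
        calls.append(RegulatorCall(
            regulator=reg, n_targets_observed=n, z_activation=float(z),
            state=state, low_evidence=n < 3,
        ))
    return calls
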