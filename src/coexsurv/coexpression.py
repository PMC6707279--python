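"""Seed-gene co-expression signatures.

A signature is the set of genes whose Pearson correlation with a chosen
seed gene across the cohort clears a magnitude cutoff (default 0.3),
split into a positively and a negatively correlated arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from coexsurv.io import ExpressionMatrix

logger = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """Correlation is undefined for a constant vector."""


@dataclass(frozen=True)
class CoexpressionSignature:
    """A seed gene with its correlated members, sorted by descending r.

    Members all satisfy ``|r| >= cutoff`` (or ``>`` under the strict rule);
    ties in r break by gene symbol ascending; the seed itself is excluded.
    """

    seed_gene: str
    members: tuple[tuple[str, float], ...]
    cutoff: float

    def __post_init__(self):
        genes = [g for g, _ in self.members]
        if self.seed_gene in genes:
            raise ValueError("seed gene cannot be a member of its own signature")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate members in signature")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def member_genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.members)

    @property
    def positive_arm(self) -> tuple[tuple[str, float], ...]:
        return tuple((g, r) for g, r in self.members if r > 0)

    @property
    def negative_arm(self) -> tuple[tuple[str, float], ...]:
        return tuple((g, r) for g, r in self.members if r < 0)

    def r_of(self, gene: str) -> float:
        for g, r in self.members:
            if g == gene:
                return r
        raise KeyError(gene)


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        raise ZeroVarianceError("correlation undefined: zero-variance input")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def _sorted_by_r(pairs):
    # descending r; exact ties by symbol ascending
    return sorted(pairs, key=lambda gr: (-gr[1], gr[0]))


def correlate_seed(matrix: ExpressionMatrix, seed_gene: str) -> list[tuple[str, float]]:
    """Correlate the seed with every other gene, ranked by descending r.

    Zero-variance genes have no defined correlation and are excluded with
    a logged count; a zero-variance seed is an error.
    """
    if seed_gene not in matrix.gene_ids:
        raise KeyError(f"seed gene {seed_gene!r} not present in the expression matrix")
    values = matrix.values
    seed = matrix.row(seed_gene)
    sc = seed - seed.mean()
    s_norm = np.sqrt(sc @ sc)
    if s_norm == 0:
        raise ZeroVarianceError(f"seed gene {seed_gene!r} has zero variance")
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", centered, centered))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ sc) / (norms * s_norm)
    r = np.clip(r, -1.0, 1.0)

    pairs = []
    n_dropped = 0
    for gene, norm, ri in zip(matrix.gene_ids, norms, r):
        if gene == seed_gene:
            continue
        if norm == 0:
            n_dropped += 1
            continue
        pairs.append((gene, float(ri)))
    if n_dropped:
        logger.warning("dropped %d zero-variance genes from correlation against %s", n_dropped, seed_gene)
    return _sorted_by_r(pairs)


def extract_signature(
    ranked: list[tuple[str, float]],
    cutoff: float = 0.3,
    *,
    seed_gene: str = "",
    strict: bool = False,
) -> CoexpressionSignature:
    """Apply the magnitude cutoff to a ranked correlation list.

    By default a coefficient exactly equal to the cutoff is included;
    ``strict=True`` switches to the strict inequality.
    """
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must lie in (0, 1]")
    if strict:
        members = tuple((g, r) for g, r in _sorted_by_r(ranked) if abs(r) > cutoff)
    else:
        members = tuple((g, r) for g, r in _sorted_by_r(ranked) if abs(r) >= cutoff)
    return CoexpressionSignature(seed_gene=seed_gene, members=members, cutoff=cutoff)


def seed_signature(
    matrix: ExpressionMatrix, seed_gene: str, cutoff: float = 0.3, strict: bool = False
) -> CoexpressionSignature:
    """Convenience composition: correlate a seed and cut at the threshold."""
    ranked = correlate_seed(matrix, seed_gene)
    return extract_signature(ranked, cutoff, seed_gene=seed_gene, strict=strict)
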