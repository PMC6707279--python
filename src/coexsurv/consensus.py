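"""Signed two-seed consensus signature.

The consensus of two seed signatures is the symbol intersection of their
prognostic members; each consensus gene carries its correlation to both
seeds, one survival z (the inputs must come from the same scoring run),
a direction label from the z sign, and a (sign r_a, sign r_b) pattern.
Intersection is by symbol only — no sign-consistency constraint — and the
pattern summary exposes the sign structure so callers can filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from coexsurv.coexpression import CoexpressionSignature


@dataclass(frozen=True)
class PrognosticSet:
    """One seed's prognostic signature members with their (r, z) values."""

    seed_gene: str
    entries: dict  # gene -> (r, z)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ConsensusGene:
    gene: str
    r_to_a: float
    r_to_b: float
    z: float
    direction: str = ""  # adverse | protective
    pattern: tuple = ()  # (sign r_a, sign r_b)


@dataclass(frozen=True)
class ConsensusSignature:
    seed_a: str
    seed_b: str
    genes: tuple[ConsensusGene, ...]
    provenance: dict = field(default_factory=dict)  # n_a, n_b, n_common

    def __post_init__(self):
        prov = self.provenance
        if prov:
            union = prov["n_a"] + prov["n_b"] - prov["n_common"]
            if prov["n_common"] != len(self.genes) or union < max(prov["n_a"], prov["n_b"]):
                raise ValueError("inconsistent provenance counts")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_symbols(self) -> tuple[str, ...]:
        return tuple(g.gene for g in self.genes)

    def pattern_summary(self) -> dict:
        counts: dict[tuple, int] = {}
        for g in self.genes:
            if g.pattern:
                counts[g.pattern] = counts.get(g.pattern, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": g.gene, "r_a": g.r_to_a, "r_b": g.r_to_b, "z": g.z,
                    "direction": g.direction, "pattern": "".join(g.pattern),
                }
                for g in self.genes
            ],
            columns=["gene", "r_a", "r_b", "z", "direction", "pattern"],
        )


def build_prognostic_set(
    signature: CoexpressionSignature, flags: pd.DataFrame
) -> PrognosticSet:
    """Restrict a co-expression signature to its prognostic members.

    ``flags`` is the output of :func:`coexsurv.prognosis.flag_prognostic`
    and supplies the z values.
    """
    fl = flags.set_index("gene")
    entries = {}
    for gene, r in signature.members:
        if gene in fl.index and bool(fl.loc[gene, "prognostic"]):
            entries[gene] = (float(r), float(fl.loc[gene, "z"]))
    return PrognosticSet(seed_gene=signature.seed_gene, entries=entries)


def intersect_signatures(prognostic_a: PrognosticSet, prognostic_b: PrognosticSet) -> ConsensusSignature:
    """Symbol intersection of two prognostic sets with Venn provenance.

    Shared genes must carry identical z values in both inputs — differing
    z means the sets came from different survival-scoring runs.
    """
    if len(prognostic_a) == 0 or len(prognostic_b) == 0:
        raise ValueError("both prognostic sets must be nonempty")
    common = sorted(set(prognostic_a.entries) & set(prognostic_b.entries))
    genes = []
    for g in common:
        r_a, z_a = prognostic_a.entries[g]
        r_b, z_b = prognostic_b.entries[g]
        if abs(z_a - z_b) > 1e-9:
            raise ValueError(
                f"gene {g}: z differs between inputs ({z_a} vs {z_b}); "
                "both sets must come from the same survival-scoring run"
            )
        genes.append(ConsensusGene(gene=g, r_to_a=r_a, r_to_b=r_b, z=z_a))
    provenance = {
        "n_a": len(prognostic_a),
        "n_b": len(prognostic_b),
        "n_common": len(common),
    }
    return ConsensusSignature(
        seed_a=prognostic_a.seed_gene, seed_b=prognostic_b.seed_gene,
        genes=tuple(genes), provenance=provenance,
    )


def annotate_direction(consensus: ConsensusSignature) -> ConsensusSignature:
    """Attach adverse/protective labels and (sign r_a, sign r_b) patterns."""
    if len(consensus) == 0:
        raise ValueError("consensus is empty")

    def sign(v: float) -> str:
        return "+" if v > 0 else "-"

    genes = tuple(
        replace(
            g,
            direction="adverse" if g.z > 0 else "protective",
            pattern=(sign(g.r_to_a), sign(g.r_to_b)),
        )
        for g in consensus.genes
    )
    return replace(consensus, genes=genes)


def order_for_heatmap(consensus: ConsensusSignature, reference_seed: str = "a") -> list[str]:
    """Gene order for display: descending r to the chosen seed, ties by symbol."""
    if reference_seed in ("a", consensus.seed_a):
        key = lambda g: (-g.r_to_a, g.gene)
    elif reference_seed in ("b", consensus.seed_b):
        key = lambda g: (-g.r_to_b, g.gene)
    else:
        raise ValueError(f"reference seed must be one of {consensus.seed_a!r}/{consensus.seed_b!r} (or 'a'/'b')")
    return [g.gene for g in sorted(consensus.genes, key=key)]
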