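"""Readers, writers and validated in-memory containers for every external format.

Expression matrices travel as gene-by-sample TSV (symbols in the first
column, sample ids in the header), gene sets as MSigDB-dialect GMT,
survival / IHC / drug-response tables as delimited text with named header
columns (tab or comma, auto-detected). Loading validates and never
silently reorders; every writer is the exact inverse of its reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file could not be parsed into the expected representation."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant."""


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples expression on the log2(x+1) scale.

    Gene identifiers are uppercased HGNC-style symbols; all values must be
    finite (missing entries are rejected at load time, not imputed).
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_samples), float64

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ValidationError(f"duplicate gene ids: {sorted(dupes)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample ids: {sorted(dupes)}")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if not np.all(np.isfinite(values)):
            n_bad = int(np.size(values) - np.isfinite(values).sum())
            raise ValidationError(f"{n_bad} non-finite expression values; missing data is not imputed")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene: str) -> np.ndarray:
        """Expression vector of one gene across samples."""
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None
        return self.values[i]

    def gene_series(self, gene: str) -> pd.Series:
        return pd.Series(self.row(gene), index=list(self.sample_ids), name=gene)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=tuple(str(g).upper() for g in df.index),
            sample_ids=tuple(str(s) for s in df.columns),
            values=df.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class SurvivalTable:
    """Per-sample follow-up: time in months (> 0) and event (1 death, 0 censored)."""

    frame: pd.DataFrame  # columns: sample, time, event

    def __post_init__(self):
        df = self.frame
        missing = {"sample", "time", "event"} - set(df.columns)
        if missing:
            raise ValidationError(f"survival table missing columns: {sorted(missing)}")
        if df["sample"].duplicated().any():
            dupes = df.loc[df["sample"].duplicated(), "sample"].tolist()
            raise ValidationError(f"duplicate sample ids in survival table: {dupes}")
        if (df["time"] <= 0).any() or not np.all(np.isfinite(df["time"])):
            raise ValidationError("survival times must be finite and strictly positive")
        if not df["event"].isin([0, 1]).all():
            bad = sorted(set(df["event"]) - {0, 1})
            raise ValidationError(f"event indicator must be 0 or 1, found {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def n_events(self) -> int:
        return int(self.frame["event"].sum())

    def aligned(self, sample_ids) -> pd.DataFrame:
        """Subset to the intersection with `sample_ids`, preserving their order."""
        idx = self.frame.set_index("sample")
        keep = [s for s in sample_ids if s in idx.index]
        return idx.loc[keep].reset_index()


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self):
        if len(self.members) < 1:
            raise ValidationError(f"gene set {self.name!r} has no members")


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered collection of named gene sets (GMT payload)."""

    sets: tuple[GeneSet, ...] = field(default_factory=tuple)

    def __post_init__(self):
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate gene-set names: {sorted(_duplicates(names))}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class IHCTable:
    """Immunohistochemistry staining scores: 0 none, 1 weak, 2 moderate, 3 strong."""

    frame: pd.DataFrame  # columns: sample, marker, score

    def __post_init__(self):
        df = self.frame
        missing = {"sample", "marker", "score"} - set(df.columns)
        if missing:
            raise ValidationError(f"IHC table missing columns: {sorted(missing)}")
        if len(df) and not df["score"].isin([0, 1, 2, 3]).all():
            bad = sorted(set(df["score"]) - {0, 1, 2, 3})
            raise ValidationError(f"IHC scores must be integers in 0..3, found {bad}")
        if df.duplicated(subset=["sample", "marker"]).any():
            raise ValidationError("duplicate (sample, marker) pairs in IHC table")

    def marker_scores(self, marker: str) -> pd.Series:
        sub = self.frame[self.frame["marker"] == marker]
        return pd.Series(sub["score"].to_numpy(), index=sub["sample"].to_numpy(), name=marker)


# ---------------------------------------------------------------------------
# readers


def read_expression(path) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column symbols, header row sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = body.isna() & ~df.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if body.isna().any().any():
        r, c = np.argwhere(body.isna().to_numpy())[0]
        raise ValidationError(f"{path}: missing value at gene {df.index[r]!r}, sample {df.columns[c]!r}")
    body.index = [str(g).upper() for g in body.index]
    if pd.Index(body.index).duplicated().any():
        dupes = sorted(_duplicates(list(body.index)))
        raise ValidationError(f"{path}: duplicate gene rows: {dupes}")
    return ExpressionMatrix.from_frame(body)


def read_gmt(path) -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file (name, description, members; tab-separated)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description and >=1 member")
            name, desc, *members = fields
            members = tuple(m.strip().upper() for m in members if m.strip())
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append(GeneSet(name=name, description=desc, members=members))
    return GeneSetCollection(sets=tuple(sets))


def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", comment="#")


def read_survival(path) -> SurvivalTable:
    """Read a survival table (columns sample / time / event; tab or comma)."""
    df = _read_delimited(path)
    df.columns = [c.strip().lower() for c in df.columns]
    rename = {"sample_id": "sample", "patient": "sample", "os_months": "time", "os_status": "event"}
    df = df.rename(columns=rename)
    missing = {"sample", "time", "event"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing survival columns {sorted(missing)}")
    df = df[["sample", "time", "event"]].copy()
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    df["event"] = pd.to_numeric(df["event"], errors="coerce")
    n0 = len(df)
    df = df.dropna(subset=["time", "event"])
    df = df[df["time"] > 0]
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.warning("%s: dropped %d records with missing or non-positive time/event", path, n_dropped)
    if len(df) == 0:
        raise ValidationError(f"{path}: no usable survival records")
    if not df["event"].isin([0, 1]).all():
        bad = sorted(set(df["event"]) - {0, 1})
        raise ValidationError(f"{path}: event indicator must be 0/1, found {bad}")
    df["sample"] = df["sample"].astype(str)
    df["event"] = df["event"].astype(int)
    return SurvivalTable(frame=df.reset_index(drop=True))


def read_ihc(path) -> IHCTable:
    df = _read_delimited(path)
    df.columns = [c.strip().lower() for c in df.columns]
    df = df.rename(columns={"sample_id": "sample"})
    missing = {"sample", "marker", "score"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing IHC columns {sorted(missing)}")
    df = df[["sample", "marker", "score"]].copy()
    score = pd.to_numeric(df["score"], errors="coerce")
    if score.isna().any() or not np.allclose(score, score.round()):
        raise FormatError(f"{path}: IHC scores must be integers")
    df["score"] = score.astype(int)
    df["sample"] = df["sample"].astype(str)
    df["marker"] = df["marker"].astype(str).str.upper()
    return IHCTable(frame=df.reset_index(drop=True))


def read_drug_response(path) -> pd.DataFrame:
    """Read a per-cell-line drug response table (cell_line, drug, auc)."""
    df = _read_delimited(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"cell_line", "drug", "auc"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing drug-response columns {sorted(missing)}")
    df = df[["cell_line", "drug", "auc"]].copy()
    df["auc"] = pd.to_numeric(df["auc"], errors="coerce")
    if df["auc"].isna().any() or (df["auc"] < 0).any():
        raise ValidationError(f"{path}: AUC values must be finite and non-negative")
    if df.duplicated(subset=["cell_line", "drug"]).any():
        raise ValidationError(f"{path}: duplicate (cell_line, drug) pairs")
    df["cell_line"] = df["cell_line"].astype(str)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# writers (exact inverses of the readers above)


def _meta_line(meta: dict | None) -> str:
    from coexsurv import __version__

    parts = [f"coexsurv={__version__}"]
    for k, v in (meta or {}).items():
        parts.append(f"{k}={v}")
    return "# " + " ".join(parts) + "\n"


def write_expression(matrix: ExpressionMatrix, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_line(meta))
        matrix.to_frame().to_csv(fh, sep="\t", index_label="gene")


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def write_survival(table: SurvivalTable, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_line(meta))
        table.frame.to_csv(fh, sep="\t", index=False)


def write_ihc(table: IHCTable, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_line(meta))
        table.frame.to_csv(fh, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Generic result writer: TSV with a commented provenance line."""
    with open(path, "w") as fh:
        fh.write(_meta_line(meta))
        df.to_csv(fh, sep="\t", index=False)


def _duplicates(items) -> set:
    seen, dupes = set(), set()
    for x in items:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes
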