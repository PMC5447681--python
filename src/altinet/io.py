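"""Shared file I/O: TSV tables, design tables, GMT gene-set collections.

All intermediate formats are plain tab-separated text with a header row so
that every stage of the pipeline can be inspected and diffed. Readers are
gzip-transparent (a ``.gz`` suffix is handled automatically).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import pandas as pd

GROUPS = ("AMS", "non-AMS")
TIMEPOINTS = ("pre", "post")

#: float formatting used for every TSV we write, so that identical inputs
#: produce byte-identical outputs across runs
FLOAT_FORMAT = "%.10g"


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a text file, transparently decompressing ``.gz``."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene x sample integer read counts with per-gene feature lengths.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer counts, genes in rows (index = gene ids),
        samples in columns.
    lengths : Series
        Feature length in base pairs per gene, aligned to ``counts.index``.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()][:3].tolist()
            raise ValueError(f"genes missing a length: {missing}")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        """Per-sample totals (column sums), used when no external mapped-read
        totals are supplied."""
        return self.counts.sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "length_bp", self.lengths)
        out.index.name = "gene_id"
        write_tsv(out, path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = read_tsv(path)
        if "length_bp" not in df.columns:
            raise ValueError(f"{path}: expected a 'length_bp' column")
        lengths = df["length_bp"]
        counts = df.drop(columns="length_bp")
        return cls(counts=counts, lengths=lengths)


# ---------------------------------------------------------------------------
# Design table
# ---------------------------------------------------------------------------


def validate_design(design: pd.DataFrame) -> list[str]:
    """Check a sample design table for the paired two-group layout.

    Expected columns: ``subject_id``, ``group`` in {AMS, non-AMS},
    ``timepoint`` in {pre, post}; index = sample ids. Each subject must have
    exactly one pre and one post sample. Returns a list of problems (empty
    when valid).
    """
    issues: list[str] = []
    for col in ("subject_id", "group", "timepoint"):
        if col not in design.columns:
            issues.append(f"design table missing column '{col}'")
    if issues:
        return issues
    bad_grp = set(design["group"]) - set(GROUPS)
    if bad_grp:
        issues.append(f"unknown group labels: {sorted(bad_grp)}")
    bad_tp = set(design["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        issues.append(f"unknown timepoints: {sorted(bad_tp)}")
    for subj, sub in design.groupby("subject_id"):
        tps = sorted(sub["timepoint"])
        if tps != ["post", "pre"]:
            issues.append(f"subject {subj} lacks exactly one pre and one post sample")
        if sub["group"].nunique() > 1:
            issues.append(f"subject {subj} assigned to more than one group")
    return issues


def read_design(path: str | Path) -> pd.DataFrame:
    design = read_tsv(path)
    issues = validate_design(design)
    if issues:
        raise ValueError(f"{path}: " + "; ".join(issues))
    return design


def design_samples(design: pd.DataFrame, group: str, timepoint: str | None = None) -> list[str]:
    """Sample ids of one group (optionally one timepoint), sorted by subject
    so pre/post columns align pairwise."""
    sub = design[design["group"] == group]
    if timepoint is not None:
        sub = sub[sub["timepoint"] == timepoint]
    sub = sub.sort_values(["subject_id", "timepoint"])
    return list(sub.index)


# ---------------------------------------------------------------------------
# Gene-set collections (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """User-supplied annotation terms (e.g. GO biological processes).

    ``terms`` maps term id -> (description, member gene ids); ``universe``
    is the background gene universe enrichment is computed against.
    """

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            members: set[str] = set()
            for _, genes in self.terms.values():
                members |= genes
            self.universe = frozenset(members)

    def restricted(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every term with a new background universe."""
        uni = frozenset(universe)
        terms = {
            tid: (name, genes & uni)
            for tid, (name, genes) in self.terms.items()
        }
        return GeneSetCollection(terms=terms, universe=uni)

    def members(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (term_id <tab> description <tab> gene1 <tab> ...)."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            tid, name = parts[0], parts[1]
            if tid in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term id {tid!r}")
            terms[tid] = (name, frozenset(g for g in parts[2:] if g))
    return GeneSetCollection(terms=terms)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, (name, genes) in collection.terms.items():
            fh.write("\t".join([tid, name, *sorted(genes)]) + "\n")
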