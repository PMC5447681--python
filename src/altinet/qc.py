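"""Raw-read quality filters.

Three whole-read removal rules, applied in a fixed order so each removed
read is counted under exactly one rule:

1. adapter contamination — an exact substring match of any configured
   adapter prefix of length >= ``min_adaptor_overlap`` anywhere in the read;
2. unknown bases — strictly more than ``max_unknown_frac`` of the bases
   are N (default: more than 10%);
3. low quality — strictly more than ``max_lowqual_frac`` of the bases have
   Phred quality <= ``lowqual_base_max_q`` (default: more than 50% at Q<=5).

Reads are never trimmed or modified, only kept or dropped; boundary cases
(exactly 10% N, exactly 50% low-quality bases) are kept because the rules
use strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .io import open_text, write_tsv
from .simulate import DEFAULT_ADAPTOR


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality scores"
            )
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.read_id!r}: negative quality score")


@dataclass
class QCConfig:
    adaptor_sequences: tuple[str, ...] = (DEFAULT_ADAPTOR,)
    min_adaptor_overlap: int = 10
    phred_offset: int = 33
    max_unknown_frac: float = 0.10
    lowqual_base_max_q: int = 5
    max_lowqual_frac: float = 0.50

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_unknown_frac <= 1.0:
            raise ValueError("max_unknown_frac must lie in [0, 1]")
        if not 0.0 <= self.max_lowqual_frac <= 1.0:
            raise ValueError("max_lowqual_frac must lie in [0, 1]")
        if self.lowqual_base_max_q < 0:
            raise ValueError("lowqual_base_max_q must be >= 0")
        if self.min_adaptor_overlap < 1:
            raise ValueError("min_adaptor_overlap must be >= 1")

    def adaptor_patterns(self) -> list[str]:
        # a longer prefix occurring implies its min-length prefix occurs at
        # the same position, so searching the min-length prefix suffices
        return [a[: self.min_adaptor_overlap] for a in self.adaptor_sequences if a]


@dataclass
class QCReport:
    n_input: int = 0
    n_kept: int = 0
    n_removed_adaptor: int = 0
    n_removed_unknown: int = 0
    n_removed_lowqual: int = 0

    @property
    def n_removed(self) -> int:
        return self.n_removed_adaptor + self.n_removed_unknown + self.n_removed_lowqual

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": [
                    self.n_input,
                    self.n_kept,
                    self.n_removed_adaptor,
                    self.n_removed_unknown,
                    self.n_removed_lowqual,
                ]
            },
            index=pd.Index(
                ["input", "kept", "removed_adaptor", "removed_unknown", "removed_lowqual"],
                name="category",
            ),
        )

    def __str__(self) -> str:
        return (
            f"reads in: {self.n_input}; kept: {self.n_kept}; "
            f"removed: {self.n_removed_adaptor} adapter, "
            f"{self.n_removed_unknown} high-N, {self.n_removed_lowqual} low-quality"
        )


def classify_read(read: ReadRecord, config: QCConfig) -> str | None:
    """Return the removal rule for a read, or None if it is kept."""
    n = len(read.bases)
    if n == 0:
        return None
    for pattern in config.adaptor_patterns():
        if pattern in read.bases:
            return "adaptor"
    if read.bases.count("N") / n > config.max_unknown_frac:
        return "unknown"
    if sum(q <= config.lowqual_base_max_q for q in read.qualities) / n > config.max_lowqual_frac:
        return "lowqual"
    return None


def filter_reads(
    reads: Iterable[ReadRecord], config: QCConfig | None = None
) -> tuple[list[ReadRecord], QCReport]:
    """Apply the three filters to a read stream.

    Returns the kept reads (input order preserved, unmodified) and a report
    with per-rule removal counts.
    """
    config = config or QCConfig()
    report = QCReport()
    kept: list[ReadRecord] = []
    for read in reads:
        report.n_input += 1
        rule = classify_read(read, config)
        if rule is None:
            report.n_kept += 1
            kept.append(read)
        elif rule == "adaptor":
            report.n_removed_adaptor += 1
        elif rule == "unknown":
            report.n_removed_unknown += 1
        else:
            report.n_removed_lowqual += 1
    return kept, report


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a FASTQ file (gzip-transparent) as ReadRecords."""
    with open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield ReadRecord(
                read_id=rec.id,
                bases=str(rec.seq),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
            )


def qc_fastq(
    fastq_in: str | Path,
    fastq_out: str | Path | None = None,
    config: QCConfig | None = None,
    report_path: str | Path | None = None,
) -> QCReport:
    """Filter a FASTQ file, optionally writing kept reads and a TSV report."""
    kept, report = filter_reads(read_fastq(fastq_in), config)
    if fastq_out is not None:
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = []
        for r in kept:
            rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(r.qualities)
            records.append(rec)
        with open(fastq_out, "w") as fh:
            SeqIO.write(records, fh, "fastq")
    if report_path is not None:
        write_tsv(report.to_frame(), report_path)
    return report
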