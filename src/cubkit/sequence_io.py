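"""CDS FASTA reading, quality control and per-gene codon counting.

A coding sequence enters the analysis only if it looks like a complete,
unambiguous CDS: length a multiple of three and strictly longer than the
minimum (300 nt by default), ATG start, a stop codon of the chosen genetic
code at the end, no internal stop and no ambiguous base.  Exact duplicate
sequences are optionally collapsed.  Failures are reported, never raised:
the :class:`QcReport` accounts for every input record with its first failing
rule, so corpus attrition is auditable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from .genetic_code import ALL_CODONS, GeneticCode

__all__ = [
    "CdsRecord",
    "CodonCounts",
    "QcReport",
    "EmptyInputError",
    "read_cds_fasta",
    "qc_filter",
    "count_codons",
    "DEFAULT_MIN_LEN",
]

DEFAULT_MIN_LEN = 300  # QC keeps sequences strictly longer than this

_VALID_BASES = frozenset("ACGT")


class EmptyInputError(ValueError):
    """Raised when a FASTA file contains no records."""


@dataclass(frozen=True)
class CdsRecord:
    """A coding sequence as read (pre- or post-QC)."""

    gene_id: str
    sequence: str

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    def codons(self) -> list[str]:
        s = self.sequence
        return [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]


@dataclass(frozen=True)
class CodonCounts:
    """Frame-0 codon counts of one QC-passed gene.

    ``counts`` covers every codon that occurs (terminal stop included);
    ``n_codons_analyzed`` counts only the analyzed (multi-codon-family)
    codons that feed the usage statistics.
    """

    gene_id: str
    counts: dict[str, int]
    n_codons_analyzed: int

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())


@dataclass
class QcReport:
    """Per-gene QC outcome plus corpus totals per failing rule."""

    statuses: list[tuple[str, str, str]] = field(default_factory=list)
    # (gene_id, "pass"/"fail", failed_rule or "")

    def add(self, gene_id: str, failed_rule: str | None) -> None:
        if failed_rule is None:
            self.statuses.append((gene_id, "pass", ""))
        else:
            self.statuses.append((gene_id, "fail", failed_rule))

    @property
    def n_input(self) -> int:
        return len(self.statuses)

    @property
    def n_passed(self) -> int:
        return sum(1 for _, s, _ in self.statuses if s == "pass")

    @property
    def n_failed(self) -> int:
        return self.n_input - self.n_passed

    def rule_totals(self) -> dict[str, int]:
        totals = Counter(rule for _, s, rule in self.statuses if s == "fail")
        return dict(totals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.statuses, columns=["gene_id", "status", "failed_rule"]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_cds_fasta(path) -> list[CdsRecord]:
    """Read a nucleotide FASTA of coding sequences.

    Sequences are upper-cased and RNA ``U`` is mapped to ``T``; records keep
    file order.  Raises :class:`EmptyInputError` on a record-less file.
    """
    records = [
        CdsRecord(rec.id, str(rec.seq).upper().replace("U", "T"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise EmptyInputError(f"no FASTA records found in {path}")
    return records


def _first_failure(
    rec: CdsRecord, code: GeneticCode, min_len: int
) -> str | None:
    seq = rec.sequence
    if not set(seq) <= _VALID_BASES:
        return "ambiguous_bases"
    if len(seq) % 3 != 0:
        return "not_multiple_of_3"
    if len(seq) <= min_len:
        return "too_short"
    if seq[:3] != "ATG":
        return "no_start_codon"
    codons = rec.codons()
    if codons[-1] not in code.stop_codons:
        return "no_stop_codon"
    if any(c in code.stop_codons for c in codons[:-1]):
        return "internal_stop"
    return None


def qc_filter(
    records: list[CdsRecord],
    code: GeneticCode,
    dedupe: bool = True,
    min_len: int = DEFAULT_MIN_LEN,
) -> tuple[list[CdsRecord], QcReport]:
    """Apply CDS quality filters; return passing records and a full report.

    Rules, in the order tested per record: ambiguous bases, frame
    (multiple of 3), minimum length (strictly > ``min_len``), ATG start,
    terminal stop codon, internal stop.  With ``dedupe`` (default), an exact
    full-sequence duplicate of an earlier passing record fails with rule
    ``duplicate_sequence``.  Idempotent: filtering the passed set again
    changes nothing.
    """
    passed: list[CdsRecord] = []
    report = QcReport()
    seen: set[str] = set()
    for rec in records:
        rule = _first_failure(rec, code, min_len)
        if rule is None and dedupe and rec.sequence in seen:
            rule = "duplicate_sequence"
        report.add(rec.gene_id, rule)
        if rule is None:
            passed.append(rec)
            seen.add(rec.sequence)
    return passed, report


def count_codons(record: CdsRecord, code: GeneticCode) -> CodonCounts:
    """Count frame-0 codons of a QC-passed gene.

    The terminal stop is kept in the raw counts but excluded (with the
    Met/Trp codons) from ``n_codons_analyzed``, mirroring the exclusion set
    used by every downstream index.
    """
    if record.length_nt % 3 != 0:
        raise ValueError(
            f"{record.gene_id}: length {record.length_nt} is not a multiple "
            "of 3; count_codons requires a QC-passed record"
        )
    counts = dict(Counter(record.codons()))
    unknown = set(counts) - set(ALL_CODONS)
    if unknown:
        raise ValueError(
            f"{record.gene_id}: non-ACGT codons {sorted(unknown)}"
        )
    excluded = code.excluded_codons
    n_analyzed = sum(n for c, n in counts.items() if c not in excluded)
    return CodonCounts(record.gene_id, counts, n_analyzed)
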