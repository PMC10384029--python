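"""Nucleotide-composition statistics per gene and per genome.

Two codon sets matter here and they are deliberately distinct:

* GC, GC1, GC2, GC3 and GC12 are computed over **all sense codons** of the
  gene (start and Trp codons included, stop codons excluded) — the
  conventional whole-CDS composition.
* GC3s and the third-position base fractions A3/T3/C3/G3 are computed over
  the **synonymously variable** codons only (families of degeneracy ≥ 2,
  i.e. the 59 analyzed codons under the standard code), because those are
  the positions where composition can reflect codon choice rather than
  amino-acid content.

Genome-level values are codon-count-weighted pools — equivalent to
concatenating every gene's analyzed codons — not unweighted means of
per-gene fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

from .genetic_code import GeneticCode
from .sequence_io import CodonCounts

__all__ = ["CompositionProfile", "DegenerateInputError", "composition_profile", "pool_composition"]


class DegenerateInputError(ValueError):
    """Raised when a statistic is requested on an empty codon set."""


@dataclass(frozen=True)
class CompositionProfile:
    """All per-gene (or pooled) composition fractions, each in [0, 1]."""

    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: float
    a3: float
    t3: float
    c3: float
    g3: float

    def as_dict(self) -> dict[str, float]:
        return {
            "gc": self.gc,
            "gc1": self.gc1,
            "gc2": self.gc2,
            "gc3": self.gc3,
            "gc12": self.gc12,
            "gc3s": self.gc3s,
            "a3": self.a3,
            "t3": self.t3,
            "c3": self.c3,
            "g3": self.g3,
        }


def _position_tallies(
    counts: dict[str, int], codon_set: frozenset[str] | set[str] | None
) -> tuple[list[dict[str, int]], int]:
    """Per-position base tallies over codons in ``codon_set`` (None = all)."""
    tallies: list[dict[str, int]] = [dict.fromkeys("ACGT", 0) for _ in range(3)]
    total = 0
    for codon, n in counts.items():
        if codon_set is not None and codon not in codon_set:
            continue
        total += n
        for pos, base in enumerate(codon):
            tallies[pos][base] += n
    return tallies, total


def composition_profile(
    counts: CodonCounts, code: GeneticCode
) -> CompositionProfile:
    """Compute the composition profile of one gene from its codon counts.

    Exact rational arithmetic is used before the final float conversion so
    that a3 + t3 + c3 + g3 == 1 holds exactly.
    """
    sense = frozenset(c for c in counts.counts if c not in code.stop_codons)
    analyzed = frozenset(code.analyzed_codons)
    tal_all, n_all = _position_tallies(counts.counts, sense)
    tal_syn, n_syn = _position_tallies(counts.counts, analyzed)
    if n_all == 0 or n_syn == 0:
        raise DegenerateInputError(
            f"{counts.gene_id}: no analyzed codons; composition undefined"
        )

    def gc_frac(tally: dict[str, int], total: int) -> Fraction:
        return Fraction(tally["G"] + tally["C"], total)

    gc1 = gc_frac(tal_all[0], n_all)
    gc2 = gc_frac(tal_all[1], n_all)
    gc3 = gc_frac(tal_all[2], n_all)
    gc = (gc1 + gc2 + gc3) / 3
    gc12 = (gc1 + gc2) / 2
    gc3s = gc_frac(tal_syn[2], n_syn)
    third = tal_syn[2]
    return CompositionProfile(
        gc=float(gc),
        gc1=float(gc1),
        gc2=float(gc2),
        gc3=float(gc3),
        gc12=float(gc12),
        gc3s=float(gc3s),
        a3=float(Fraction(third["A"], n_syn)),
        t3=float(Fraction(third["T"], n_syn)),
        c3=float(Fraction(third["C"], n_syn)),
        g3=float(Fraction(third["G"], n_syn)),
    )


def pool_composition(
    gene_counts: Iterable[CodonCounts], code: GeneticCode
) -> CompositionProfile:
    """Codon-weighted genome-level composition.

    Pools raw codon counts across genes and recomputes the profile, which is
    identical to concatenating all coding sequences; order-invariant by
    construction.
    """
    pooled: dict[str, int] = {}
    gene_ids = []
    for cc in gene_counts:
        gene_ids.append(cc.gene_id)
        for codon, n in cc.counts.items():
            pooled[codon] = pooled.get(codon, 0) + n
    if not gene_ids:
        raise DegenerateInputError("pool_composition requires at least one gene")
    n_analyzed = sum(
        n for c, n in pooled.items() if c not in code.excluded_codons
    )
    return composition_profile(
        CodonCounts("pooled", pooled, n_analyzed), code
    )
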