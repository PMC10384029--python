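"""Genetic-code tables, synonymous codon families and degeneracy classes.

Every codon-usage statistic in this package consults a :class:`GeneticCode`:
the codon→amino-acid map, the partition of sense codons into synonymous
families (degeneracy 1–6), and the set of codons excluded from bias
statistics (single-codon families plus stop codons).  Under the standard
nuclear code that exclusion leaves the 59 "analyzed" codons on which RSCU,
CAI, GC3s, ENc and the multivariate analyses operate.

Tables are taken from NCBI translation tables via Biopython and the family
partition is always recomputed from the codon→amino-acid map, so alternative
nuclear codes (e.g. the ciliate code, where TAA/TAG encode glutamine) flow
through the whole pipeline without special-casing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable

__all__ = [
    "ALL_CODONS",
    "CodonFamily",
    "GeneticCode",
    "UnsupportedTableError",
    "load_code",
    "degeneracy_class_counts",
    "STANDARD_TABLE",
    "CILIATE_NUCLEAR_TABLE",
]

#: Lexicographically ordered 64 codons over {A,C,G,T}.
ALL_CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=3)
)

STANDARD_TABLE = 1
#: NCBI table 6 — ciliate/dasycladacean/hexamita nuclear: TAA/TAG → Gln, stop = {TGA}.
CILIATE_NUCLEAR_TABLE = 6

_SUPPORTED_TABLES = (STANDARD_TABLE, CILIATE_NUCLEAR_TABLE)


class UnsupportedTableError(ValueError):
    """Raised for a translation-table id this package does not support."""


@dataclass(frozen=True)
class CodonFamily:
    """One synonymous codon family: amino acid, member codons, degeneracy."""

    amino_acid: str
    codons: tuple[str, ...]

    @property
    def degeneracy(self) -> int:
        return len(self.codons)


@dataclass(frozen=True)
class GeneticCode:
    """A translation table with its synonymous-family partition.

    Attributes
    ----------
    table_id:
        NCBI translation-table identifier.
    codon_to_aa:
        Map of all 64 codons to a one-letter amino acid or ``"*"`` for stop.
    stop_codons:
        The table's stop codons.
    families:
        Synonymous families of sense codons, one per amino acid, ordered by
        amino-acid letter.  Degeneracies are whatever the table implies
        (1, 2, 3, 4 or 6 for the standard code).
    excluded_codons:
        Codons excluded from codon-usage statistics: members of single-codon
        families plus stops.  The complement over sense codons is
        :attr:`analyzed_codons`.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str]
    families: tuple[CodonFamily, ...]
    excluded_codons: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        singles = {
            f.codons[0] for f in self.families if f.degeneracy == 1
        }
        object.__setattr__(
            self, "excluded_codons", frozenset(singles | set(self.stop_codons))
        )

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if c not in self.stop_codons)

    @property
    def analyzed_codons(self) -> tuple[str, ...]:
        """Sense codons that belong to multi-codon families, lexicographic."""
        return tuple(c for c in ALL_CODONS if c not in self.excluded_codons)

    @property
    def cub_families(self) -> tuple[CodonFamily, ...]:
        """Families with degeneracy ≥ 2 (the ones that can show usage bias)."""
        return tuple(f for f in self.families if f.degeneracy >= 2)

    @property
    def n_singleton_families(self) -> int:
        return sum(1 for f in self.families if f.degeneracy == 1)

    def family_of(self, codon: str) -> CodonFamily | None:
        return self._codon_family().get(codon)

    def _codon_family(self) -> dict[str, CodonFamily]:
        # cached lazily on the instance; frozen dataclass, so go via __dict__
        cache = self.__dict__.get("_family_index")
        if cache is None:
            cache = {c: f for f in self.families for c in f.codons}
            self.__dict__["_family_index"] = cache
        return cache

    def translate_codon(self, codon: str) -> str:
        return self.codon_to_aa[codon]


def load_code(table_id: int = STANDARD_TABLE) -> GeneticCode:
    """Load a genetic code and recompute its synonymous-family partition.

    Parameters
    ----------
    table_id:
        NCBI translation table number.  Supported: 1 (standard) and
        6 (ciliate nuclear, TAA/TAG → Gln).

    Raises
    ------
    UnsupportedTableError
        For any other table id.
    """
    if table_id not in _SUPPORTED_TABLES:
        raise UnsupportedTableError(
            f"translation table {table_id!r} is not supported; "
            f"choose one of {_SUPPORTED_TABLES}"
        )
    table = CodonTable.unambiguous_dna_by_id[table_id]
    codon_to_aa = {c: "*" for c in table.stop_codons}
    codon_to_aa.update(table.forward_table)
    # family partition derived from the map, never hard-coded
    by_aa: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = codon_to_aa[codon]
        if aa != "*":
            by_aa.setdefault(aa, []).append(codon)
    families = tuple(
        CodonFamily(aa, tuple(sorted(codons)))
        for aa, codons in sorted(by_aa.items())
    )
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=dict(codon_to_aa),
        stop_codons=frozenset(table.stop_codons),
        families=families,
    )


def degeneracy_class_counts(code: GeneticCode) -> dict[int, int]:
    """Number of synonymous families per degeneracy class.

    For the standard table this is ``{1: 2, 2: 9, 3: 1, 4: 5, 6: 3}``
    (Met and Trp are the singletons), accounting for all 61 sense codons.
    """
    counts: dict[int, int] = {}
    for fam in code.families:
        counts[fam.degeneracy] = counts.get(fam.degeneracy, 0) + 1
    return dict(sorted(counts.items()))
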