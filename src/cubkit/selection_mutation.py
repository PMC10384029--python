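"""Mutation-vs-selection diagnostics: PR2 plot, P2 index, neutrality fit.

Parity rule 2 (PR2): absent selection and strand-asymmetric mutation, A ≈ T
and G ≈ C at synonymous third positions, so genes scatter around
(G3/(G3+C3), A3/(A3+T3)) = (0.5, 0.5).  Third positions are tallied over the
two-, four- and six-fold degenerate families only (the three-fold Ile family
and singletons are excluded by default).

P2 is the translational-selection index: the fraction of pyrimidine-ending
codons that choose the translationally favoured pyrimidine among codons
beginning with the doublets AA, AT, TA, TT (W = A/T, "WW") or CC, CG, GC, GG
(S = C/G, "SS"):

    P2 = (WWC + SST) / (WWY + SSY),   Y = C or T.

The neutrality plot regresses GC12 on GC3 across genes (ordinary least
squares); a slope near ±1 reads as mutation pressure alone shaping codon
usage, near 0 as selection alone, and ±1/2 as an even balance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genetic_code import GeneticCode
from .sequence_io import CodonCounts

__all__ = [
    "Pr2Point",
    "P2Result",
    "P2Summary",
    "NeutralityFit",
    "pr2_point",
    "p2_index",
    "p2_summary",
    "neutrality_fit",
    "PR2_DEGENERACIES",
    "WW_DOUBLETS",
    "SS_DOUBLETS",
]

PR2_DEGENERACIES = frozenset({2, 4, 6})
WW_DOUBLETS = frozenset({"AA", "AT", "TA", "TT"})
SS_DOUBLETS = frozenset({"CC", "CG", "GC", "GG"})


@dataclass(frozen=True)
class Pr2Point:
    """One gene's PR2 coordinates; a component is None when its denominator is 0."""

    x: float | None  # G3/(G3+C3)
    y: float | None  # A3/(A3+T3)

    @property
    def defined(self) -> bool:
        return self.x is not None and self.y is not None


@dataclass(frozen=True)
class P2Result:
    wwc: int
    wwt: int
    sst: int
    ssc: int

    @property
    def wwy(self) -> int:
        return self.wwc + self.wwt

    @property
    def ssy(self) -> int:
        return self.ssc + self.sst

    @property
    def p2(self) -> float | None:
        denom = self.wwy + self.ssy
        if denom == 0:
            return None
        return (self.wwc + self.sst) / denom


@dataclass(frozen=True)
class P2Summary:
    """Both aggregation conventions for a genome's P2.

    ``mean_of_genes`` averages defined per-gene P2 values; ``pooled`` applies
    the formula to summed counts.  They differ whenever genes contribute
    unequal numbers of qualifying codons, so both are reported.
    """

    mean_of_genes: float
    pooled: float
    totals: P2Result
    n_genes: int


@dataclass(frozen=True)
class NeutralityFit:
    slope: float
    intercept: float
    r: float
    p_value: float
    n_genes: int

    @property
    def interpretation(self) -> str:
        s = abs(self.slope)
        if s >= 0.75:
            return "mutation-dominated"
        if s <= 0.25:
            return "selection-dominated"
        return "mixed"


def pr2_point(counts: CodonCounts, code: GeneticCode) -> Pr2Point:
    """PR2 coordinates from third-position tallies of 2/4/6-fold families."""
    qualifying = {
        c
        for fam in code.cub_families
        if fam.degeneracy in PR2_DEGENERACIES
        for c in fam.codons
    }
    tally = dict.fromkeys("ACGT", 0)
    for codon, n in counts.counts.items():
        if codon in qualifying:
            tally[codon[2]] += n
    at = tally["A"] + tally["T"]
    gc = tally["G"] + tally["C"]
    x = tally["G"] / gc if gc > 0 else None
    y = tally["A"] / at if at > 0 else None
    return Pr2Point(x, y)


def p2_index(counts: CodonCounts) -> P2Result:
    """Classify codons by starting doublet and pyrimidine third base."""
    wwc = wwt = sst = ssc = 0
    for codon, n in counts.counts.items():
        doublet, third = codon[:2], codon[2]
        if third not in ("C", "T"):
            continue
        if doublet in WW_DOUBLETS:
            if third == "C":
                wwc += n
            else:
                wwt += n
        elif doublet in SS_DOUBLETS:
            if third == "T":
                sst += n
            else:
                ssc += n
    return P2Result(wwc, wwt, sst, ssc)


def p2_summary(genes: Iterable[P2Result]) -> P2Summary:
    """Genome-level P2 under both per-gene-mean and pooled-count conventions."""
    per_gene = []
    wwc = wwt = sst = ssc = 0
    for g in genes:
        if g.p2 is not None:
            per_gene.append(g.p2)
        wwc += g.wwc
        wwt += g.wwt
        sst += g.sst
        ssc += g.ssc
    if not per_gene:
        raise ValueError("no gene has a defined P2")
    totals = P2Result(wwc, wwt, sst, ssc)
    return P2Summary(
        mean_of_genes=float(np.mean(per_gene)),
        pooled=totals.p2,
        totals=totals,
        n_genes=len(per_gene),
    )


def neutrality_fit(
    gc12: Sequence[float], gc3: Sequence[float]
) -> NeutralityFit:
    """OLS regression of GC12 on GC3 across genes."""
    x = np.asarray(gc3, dtype=float)
    y = np.asarray(gc12, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("gc12 and gc3 must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("neutrality fit needs at least 3 genes")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("gc12/gc3 contain non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in GC3; slope undefined")
    fit = stats.linregress(x, y)
    return NeutralityFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n_genes=len(x),
    )
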