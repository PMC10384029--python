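"""Codon-usage-bias indices: ENc, RSCU, CAI, optimal codons, Gravy, Aroma.

ENc (effective number of codons) uses the codon-family formulation with +1
pseudocounts: for a family of degeneracy ``m`` with per-codon counts ``n_i``
and family total ``n``,

    F = sum_i ((n_i + 1) / (n + m))^2

so a family is "worth" 1/F effective codons.  The gene-level value
aggregates families Wright-style by degeneracy class:

    ENc = (#singleton families) + sum_k  (#families of degeneracy k) / F̄_k

where F̄_k is the mean F over the degeneracy-k families.  Under the standard
code this is the familiar 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6, ranging from 20
(one codon per family, in the large-count limit) to exactly 61 (uniform
usage — the pseudocounts make F = 1/m exact there).  ENc < 35 is the
customary threshold for calling a gene's bias strong.

The expected-ENc curve under pure GC mutation pressure is
``2 + s + 29/(s² + (1−s)²)`` with ``s`` = GC3s, and the ENc ratio
``(ENc_exp − ENc_obs)/ENc_exp`` measures the departure from it.

CAI is the geometric mean of Sharp–Li relative-adaptiveness weights ω
(reference-set codon frequency over the most frequent synonym's frequency);
RSCU is the observed codon count over its family-equal-usage expectation,
with the usual 1.6 / 0.6 over/under-representation thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import CodonFamily, GeneticCode
from .sequence_io import CodonCounts

__all__ = [
    "FamilyF",
    "EncResult",
    "RscuTable",
    "OptimalCodon",
    "ProteinProps",
    "UnresolvableWeightError",
    "family_f",
    "enc",
    "enc_expected",
    "enc_ratio",
    "enc_result",
    "rscu",
    "cai_weights",
    "cai",
    "optimal_codons",
    "gravy",
    "aroma",
    "protein_props",
    "KYTE_DOOLITTLE",
    "AROMATIC_RESIDUES",
    "ENC_SIGNIFICANT_BIAS",
]

#: Conventional threshold: a gene with ENc below this shows strong bias.
ENC_SIGNIFICANT_BIAS = 35.0

#: Kyte–Doolittle per-residue hydropathy indices (range −4.5 … +4.5).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AROMATIC_RESIDUES = frozenset("FYW")


class UnresolvableWeightError(ValueError):
    """A synonymous family is entirely absent from the CAI reference set."""


@dataclass(frozen=True)
class FamilyF:
    """Pseudocount homozygosity F of one synonymous family in one gene."""

    amino_acid: str
    degeneracy: int
    n: int
    f: float


@dataclass(frozen=True)
class EncResult:
    enc_obs: float
    enc_exp: float
    enc_ratio: float
    gc3s: float


@dataclass(frozen=True)
class RscuTable:
    """RSCU per analyzed codon plus representation classes.

    ``values`` maps every analyzed codon of an *observed* family to its RSCU
    (0 for an unused codon of an observed family).  Families with zero total
    count are listed in ``undefined_families`` and omitted from ``values``
    rather than propagated as NaN.
    """

    values: dict[str, float]
    classes: dict[str, str]
    undefined_families: frozenset[str]

    def __getitem__(self, codon: str) -> float:
        return self.values[codon]


@dataclass(frozen=True)
class OptimalCodon:
    amino_acid: str
    codon: str | None
    r: float
    p_value: float
    note: str = ""


@dataclass(frozen=True)
class ProteinProps:
    gravy: float
    aroma: float


def family_f(counts: Sequence[int] | Mapping[str, int], m: int | None = None) -> float:
    """Pseudocount family homozygosity F = Σ ((n_i + 1)/(n + m))².

    ``counts`` are the per-codon counts of one synonymous family; ``m``
    defaults to ``len(counts)`` and must be ≥ 2 (singleton families are not
    codon-usage families).  Defined for all-zero counts, where F = 1/m.
    """
    values = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    if m is None:
        m = len(values)
    if m < 2:
        raise ValueError(f"degeneracy m={m} is not a codon-usage family")
    if len(values) != m:
        raise ValueError(f"expected {m} codon counts, got {len(values)}")
    if any(v < 0 for v in values):
        raise ValueError("codon counts must be non-negative")
    n = sum(values)
    return math.fsum(((ni + 1) / (n + m)) ** 2 for ni in values)


def _family_fs(counts: CodonCounts, code: GeneticCode) -> list[FamilyF]:
    out = []
    for fam in code.cub_families:
        fam_counts = [counts.counts.get(c, 0) for c in fam.codons]
        out.append(
            FamilyF(fam.amino_acid, fam.degeneracy, sum(fam_counts),
                    family_f(fam_counts, fam.degeneracy))
        )
    return out


def enc(
    counts: CodonCounts,
    code: GeneticCode,
    drop_unobserved_families: bool = False,
) -> float:
    """Effective number of codons of one gene (codon-family formulation).

    With the default ``drop_unobserved_families=False`` every family
    participates (its F is defined even at zero counts thanks to the
    pseudocounts); setting it drops zero-count families from the class means
    for sensitivity analysis.
    """
    if counts.n_codons_analyzed == 0:
        raise ValueError(f"{counts.gene_id}: no analyzed codons; ENc undefined")
    fams = _family_fs(counts, code)
    if drop_unobserved_families:
        fams = [f for f in fams if f.n > 0]
    by_k: dict[int, list[float]] = {}
    for f in fams:
        by_k.setdefault(f.degeneracy, []).append(f.f)
    total = float(code.n_singleton_families)
    for k, fs in by_k.items():
        n_fam_k = sum(1 for fam in code.cub_families if fam.degeneracy == k)
        f_bar = math.fsum(fs) / len(fs)
        total += n_fam_k / f_bar
    return total


def enc_expected(gc3s: float) -> float:
    """Expected ENc under GC mutation pressure alone: 2 + s + 29/(s²+(1−s)²)."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"gc3s={gc3s} outside [0, 1]")
    return 2.0 + gc3s + 29.0 / (gc3s**2 + (1.0 - gc3s) ** 2)


def enc_ratio(enc_exp: float, enc_obs: float) -> float:
    """(ENc_exp − ENc_obs) / ENc_exp."""
    if enc_exp <= 0:
        raise ValueError(f"enc_exp={enc_exp} must be positive")
    return (enc_exp - enc_obs) / enc_exp


def enc_result(counts: CodonCounts, code: GeneticCode, gc3s: float) -> EncResult:
    """Bundle observed/expected ENc and their ratio for one gene."""
    obs = enc(counts, code)
    exp = enc_expected(gc3s)
    return EncResult(obs, exp, enc_ratio(exp, obs), gc3s)


def _classify_rscu(value: float, tol: float = 1e-9) -> str:
    if value > 1.6:
        return "over"
    if value < 0.6:
        return "under"
    if abs(value - 1.0) <= tol:
        return "unbiased"
    return "average"


def rscu(counts: CodonCounts | Mapping[str, int], code: GeneticCode) -> RscuTable:
    """Relative synonymous codon usage for every analyzed codon.

    RSCU(c) = O_c / ((1/k) Σ_family O), so family sums equal the degeneracy
    whenever the family is observed at all.
    """
    raw = counts.counts if isinstance(counts, CodonCounts) else counts
    values: dict[str, float] = {}
    classes: dict[str, str] = {}
    undefined: set[str] = set()
    for fam in code.cub_families:
        fam_counts = {c: raw.get(c, 0) for c in fam.codons}
        total = sum(fam_counts.values())
        if total == 0:
            undefined.add(fam.amino_acid)
            continue
        expected = total / fam.degeneracy
        for c, o in fam_counts.items():
            v = o / expected
            values[c] = v
            classes[c] = _classify_rscu(v)
    return RscuTable(values, classes, frozenset(undefined))


def cai_weights(
    reference_counts: CodonCounts | Mapping[str, int],
    code: GeneticCode,
    zero_pseudo: float = 0.5,
) -> dict[str, float]:
    """Sharp–Li relative-adaptiveness weights ω from a reference codon pool.

    Within each multi-codon family, ω = count / max synonym count, so the
    most frequent synonym gets ω = 1.  Codons unobserved in the reference
    (within an observed family) receive a pseudo-frequency ``zero_pseudo``
    before the ratio, keeping ln ω finite.  A family absent from the
    reference altogether raises :class:`UnresolvableWeightError`.
    """
    raw = (
        reference_counts.counts
        if isinstance(reference_counts, CodonCounts)
        else reference_counts
    )
    weights: dict[str, float] = {}
    missing: list[str] = []
    for fam in code.cub_families:
        fam_counts = {c: float(raw.get(c, 0)) for c in fam.codons}
        if sum(fam_counts.values()) == 0:
            missing.append(fam.amino_acid)
            continue
        adjusted = {
            c: (v if v > 0 else zero_pseudo) for c, v in fam_counts.items()
        }
        top = max(adjusted.values())
        for c, v in adjusted.items():
            weights[c] = v / top
    if missing:
        raise UnresolvableWeightError(
            "families absent from the CAI reference set: "
            + ", ".join(sorted(missing))
        )
    return weights


def cai(counts: CodonCounts, weights: Mapping[str, float]) -> float:
    """Codon adaptation index: exp of the mean log ω over analyzed codons."""
    log_sum = 0.0
    length = 0
    for codon, n in counts.counts.items():
        w = weights.get(codon)
        if w is None:
            continue  # excluded codon (Met/Trp/stop) or family not in weights
        if w <= 0:
            raise ValueError(f"non-positive weight for {codon}")
        log_sum += n * math.log(w)
        length += n
    if length == 0:
        raise ValueError(f"{counts.gene_id}: no weighted codons; CAI undefined")
    return math.exp(log_sum / length)


def optimal_codons(
    rscu_matrix: pd.DataFrame,
    enc_per_gene: Sequence[float] | pd.Series,
    code: GeneticCode,
    method: str = "spearman",
    alpha: float = 0.05,
    min_genes: int = 10,
) -> list[OptimalCodon]:
    """Putative optimal codon per family: strongest negative RSCU–ENc link.

    For each synonymous family, the per-gene RSCU of each member codon is
    correlated with per-gene ENc across the corpus; the codon with the most
    negative coefficient, significant two-sided at ``alpha``, is the
    family's putative optimal codon.  Ties break by larger mean RSCU, then
    lexicographic order.  Zero-variance columns are skipped with a note.
    """
    enc_vec = np.asarray(enc_per_gene, dtype=float)
    if len(rscu_matrix) != len(enc_vec):
        raise ValueError("rscu_matrix and enc_per_gene have different lengths")
    if len(enc_vec) < min_genes:
        raise ValueError(
            f"need at least {min_genes} genes to estimate correlations, "
            f"got {len(enc_vec)}"
        )
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    results: list[OptimalCodon] = []
    for fam in code.cub_families:
        candidates: list[tuple[float, float, float, str]] = []
        skipped: list[str] = []
        for codon in fam.codons:
            if codon not in rscu_matrix.columns:
                continue
            col = rscu_matrix[codon].to_numpy(dtype=float)
            if np.ptp(col) == 0 or np.ptp(enc_vec) == 0:
                skipped.append(codon)
                continue
            r, p = corr(col, enc_vec)
            candidates.append((float(r), float(p), -float(np.mean(col)), codon))
        note = f"zero-variance: {','.join(skipped)}" if skipped else ""
        significant = [c for c in candidates if c[0] < 0 and c[1] < alpha]
        if significant:
            r, p, _, codon = min(significant)  # most negative r; tie-break baked in
            results.append(OptimalCodon(fam.amino_acid, codon, r, p, note))
        else:
            results.append(
                OptimalCodon(fam.amino_acid, None, float("nan"), float("nan"), note)
            )
    return results


def _residue_counts(
    counts: CodonCounts, code: GeneticCode, include_met_trp: bool
) -> dict[str, int]:
    res: dict[str, int] = {}
    for codon, n in counts.counts.items():
        aa = code.translate_codon(codon)
        if aa == "*":
            continue
        if not include_met_trp and codon in code.excluded_codons:
            continue
        res[aa] = res.get(aa, 0) + n
    return res


def gravy(counts: CodonCounts, code: GeneticCode) -> float:
    """Mean Kyte–Doolittle hydropathy of the translated analyzed codons.

    Positive = hydrophobic product.  Met/Trp residues are excluded, matching
    the codon exclusion set used by the usage indices.
    """
    res = _residue_counts(counts, code, include_met_trp=False)
    total = sum(res.values())
    if total == 0:
        raise ValueError(f"{counts.gene_id}: empty translation; Gravy undefined")
    return math.fsum(KYTE_DOOLITTLE[aa] * n for aa, n in res.items()) / total


def aroma(counts: CodonCounts, code: GeneticCode) -> float:
    """Fraction of aromatic residues (F, Y, W) in the full translated product.

    Unlike the usage indices, the denominator covers *all* translated
    residues including Met and Trp — aromaticity is a property of the
    protein, and Trp is itself aromatic.
    """
    res = _residue_counts(counts, code, include_met_trp=True)
    total = sum(res.values())
    if total == 0:
        raise ValueError(f"{counts.gene_id}: empty translation; Aroma undefined")
    return sum(n for aa, n in res.items() if aa in AROMATIC_RESIDUES) / total


def protein_props(counts: CodonCounts, code: GeneticCode) -> ProteinProps:
    return ProteinProps(gravy(counts, code), aroma(counts, code))
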