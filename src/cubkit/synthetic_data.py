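"""Synthetic CDS corpora with known mutational bias and codon preference.

The generator separates the two forces the downstream diagnostics try to
disentangle:

* **Mutation knob** — ``gc3_target`` tilts the third-position base
  distribution toward G/C (G and C equally likely, likewise A and T), the
  way genome-wide compositional pressure would.  Real ciliate genomes span
  roughly GC3 13–62%; the default 0.35 sits in the AT-rich regime typical
  of them.
* **Selection knob** — ``preference_strength`` multiplies one planted codon
  per family by ``exp(strength)`` before renormalising, concentrating usage
  the way translational selection would.  At strength 0 and ``gc3_target``
  0.5 every family is uniform and mean ENc sits at the no-bias limit; at
  large strength usage collapses to one codon per family and ENc approaches
  its lower limit.  A configurable fraction of genes ("highly expressed")
  gets the strength amplified, producing the CAI/ENc gradient seen in real
  corpora.

Both knobs act multiplicatively per family and are renormalised, so they
can be moved independently.  Amino-acid composition is i.i.d. from
``aa_frequencies`` over the 18 multi-codon families (uniform by default),
gene lengths are uniform over a codon range satisfying the QC minimum, and
every gene gets an ATG start and a stop of the chosen code.  All sampling
is driven by one :class:`numpy.random.Generator` seed, so corpora are
byte-reproducible.

A separate constructor builds neutrality-plot corpora: each gene's GC12 and
GC3 are realised *exactly* (integer codon-count mixing of four archetype
codons) at targets ``gc12 = β·gc3 + (1−β)·0.5 + noise``, so the fitted
GC12-on-GC3 slope recovers the mutation share β as a property of OLS rather
than of sampling luck.

``worked_micro_corpus`` ships five tiny hand-auditable genes with a frozen
expected index table for end-to-end pipeline verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import GeneticCode, load_code
from .sequence_io import CdsRecord

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_corpus",
    "generate_neutrality_corpus",
    "worked_micro_corpus",
    "write_fasta",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generative CDS model."""

    n_genes: int = 100
    length_range: tuple[int, int] = (150, 400)  # internal codons per gene
    gc3_target: float = 0.35
    preference_strength: float = 0.0
    preferred_codons: Mapping[str, str] | None = None
    expression_gradient: float = 0.5  # fraction of genes highly expressed
    expression_amplification: float = 3.0
    aa_frequencies: Mapping[str, float] | None = None
    genetic_code_table: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc3_target <= 1.0:
            raise ValueError("gc3_target must lie in [0, 1]")
        if not 0.0 <= self.expression_gradient <= 1.0:
            raise ValueError("expression_gradient must lie in [0, 1]")
        if self.preference_strength < 0:
            raise ValueError("preference_strength must be non-negative")
        lo, hi = self.length_range
        if lo < 99 or hi < lo:
            raise ValueError(
                "length_range must satisfy 99 <= lo <= hi so generated genes "
                "pass the >300 nt QC rule"
            )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth serialized alongside the FASTA."""

    preferred_codons: dict[str, str]
    genes: pd.DataFrame  # gene_id, length_codons, high_expression, strength
    beta: float | None = None
    seed: int = 0

    def write_tsv(self, path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)


def _third_base_probs(gc3_target: float) -> dict[str, float]:
    g = gc3_target
    return {"A": (1 - g) / 2, "T": (1 - g) / 2, "C": g / 2, "G": g / 2}


def _codon_distribution(
    code: GeneticCode,
    spec: SyntheticSpec,
    preferred: Mapping[str, str],
    strength: float,
) -> tuple[list[str], np.ndarray]:
    """Single distribution over analyzed codons: p(aa) × p(codon | family)."""
    fams = code.cub_families
    if spec.aa_frequencies is None:
        aa_probs = {f.amino_acid: 1.0 / len(fams) for f in fams}
    else:
        total = sum(spec.aa_frequencies.values())
        aa_probs = {
            f.amino_acid: spec.aa_frequencies.get(f.amino_acid, 0.0) / total
            for f in fams
        }
    p3 = _third_base_probs(spec.gc3_target)
    codons: list[str] = []
    probs: list[float] = []
    for fam in fams:
        weights = np.array([p3[c[2]] for c in fam.codons], dtype=float)
        if strength > 0 and fam.amino_acid in preferred:
            idx = fam.codons.index(preferred[fam.amino_acid])
            weights[idx] *= math.exp(strength)
        if weights.sum() == 0:
            raise ValueError(
                f"infeasible spec: family {fam.amino_acid} has zero total "
                f"weight at gc3_target={spec.gc3_target}"
            )
        weights /= weights.sum()
        for c, w in zip(fam.codons, weights):
            codons.append(c)
            probs.append(aa_probs[fam.amino_acid] * w)
    return codons, np.asarray(probs)


def _pick_stop(code: GeneticCode) -> str:
    return "TAA" if "TAA" in code.stop_codons else sorted(code.stop_codons)[0]


def generate_corpus(
    spec: SyntheticSpec,
) -> tuple[list[CdsRecord], SyntheticTruth]:
    """Sample a CDS corpus under the spec; deterministic under its seed."""
    rng = np.random.default_rng(spec.seed)
    code = load_code(spec.genetic_code_table)
    fams = code.cub_families

    preferred = dict(spec.preferred_codons or {})
    if spec.preference_strength > 0 and not preferred:
        # plant one preferred codon per family, chosen reproducibly
        for fam in fams:
            preferred[fam.amino_acid] = fam.codons[
                int(rng.integers(fam.degeneracy))
            ]
    for aa, codon in preferred.items():
        fam = next((f for f in fams if f.amino_acid == aa), None)
        if fam is None or codon not in fam.codons:
            raise ValueError(f"preferred codon {codon} is not in family {aa}")

    n_high = int(round(spec.expression_gradient * spec.n_genes))
    stop = _pick_stop(code)
    lo, hi = spec.length_range

    dists = {}
    for high in (False, True):
        strength = spec.preference_strength * (
            spec.expression_amplification if high else 1.0
        )
        dists[high] = _codon_distribution(code, spec, preferred, strength)

    records: list[CdsRecord] = []
    rows = []
    for i in range(spec.n_genes):
        high = i < n_high
        length = int(rng.integers(lo, hi + 1))
        codon_pool, probs = dists[high]
        body = rng.choice(codon_pool, size=length, p=probs)
        seq = "ATG" + "".join(body) + stop
        gene_id = f"syn{i + 1:04d}"
        records.append(CdsRecord(gene_id, seq))
        rows.append(
            {
                "gene_id": gene_id,
                "length_codons": length,
                "high_expression": high,
                "strength": spec.preference_strength
                * (spec.expression_amplification if high else 1.0),
            }
        )
    truth = SyntheticTruth(
        preferred_codons=preferred,
        genes=pd.DataFrame(rows),
        seed=spec.seed,
    )
    return records, truth


def generate_neutrality_corpus(
    beta: float,
    n_genes: int = 500,
    seed: int = 0,
    n_codons: int = 300,
    noise_sd: float = 0.01,
    baseline: float = 0.5,
    gc3_range: tuple[float, float] = (0.15, 0.85),
) -> tuple[list[CdsRecord], SyntheticTruth]:
    """Corpus whose GC12-on-GC3 OLS slope has expectation β.

    Each gene draws a latent mutational GC level g, sets GC3 = g exactly and
    GC12 = β·g + (1−β)·baseline + ε exactly (up to integer codon rounding),
    by mixing four archetype codons — GGG/GGT (GC at positions 1–2) and
    AAG/AAT (AT at positions 1–2) — whose counts are matched to the target
    margins.  ε ~ N(0, noise_sd²).  At β = 1 and noise 0 each gene's GC12
    equals its GC3 and the fitted slope is exactly 1.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    if n_genes < 10:
        raise ValueError("need at least 10 genes for a neutrality corpus")
    rng = np.random.default_rng(seed)
    records = []
    rows = []
    for i in range(n_genes):
        g = float(rng.uniform(*gc3_range))
        gc12_target = beta * g + (1 - beta) * baseline
        if noise_sd > 0:
            gc12_target += float(rng.normal(0.0, noise_sd))
        gc12_target = min(max(gc12_target, 0.0), 1.0)
        n3 = int(round(g * n_codons))
        n12 = int(round(gc12_target * n_codons))
        # 2x2 table with margins (n12, n3); near-independent fill
        a_lo = max(0, n12 + n3 - n_codons)
        a_hi = min(n12, n3)
        a = min(max(int(round(n12 * n3 / n_codons)), a_lo), a_hi)
        codons = (
            ["GGG"] * a
            + ["GGT"] * (n12 - a)
            + ["AAG"] * (n3 - a)
            + ["AAT"] * (n_codons - n12 - n3 + a)
        )
        rng.shuffle(codons)
        gene_id = f"neu{i + 1:04d}"
        records.append(CdsRecord(gene_id, "ATG" + "".join(codons) + "TAA"))
        rows.append(
            {
                "gene_id": gene_id,
                "gc3_latent": g,
                "gc12_target": gc12_target,
                "n3": n3,
                "n12": n12,
            }
        )
    truth = SyntheticTruth(
        preferred_codons={},
        genes=pd.DataFrame(rows),
        beta=beta,
        seed=seed,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Worked micro corpus: 5 tiny hand-auditable genes with a frozen index table.
# ---------------------------------------------------------------------------

def _micro_genes() -> list[CdsRecord]:
    analyzed = load_code(1).analyzed_codons
    return [
        # 100 GCT codons: one four-fold family, maximally biased
        CdsRecord("micro1", "ATG" + "GCT" * 100 + "TAA"),
        # the classic P2 worked example, repeated to pass QC length
        CdsRecord("micro2", "ATG" + "AACAATCCTCCC" * 25 + "TAA"),
        # every analyzed codon exactly twice: perfectly uniform usage
        CdsRecord("micro3", "ATG" + "".join(analyzed) * 2 + "TAA"),
        # half Ile (hydropathy +4.5), half Asn (−3.5)
        CdsRecord("micro4", "ATG" + "ATT" * 50 + "AAT" * 50 + "TAA"),
        # Phe/Tyr/Gly repeats: aromatic-rich
        CdsRecord("micro5", "ATG" + "TTTTATGGT" * 34 + "TAA"),
    ]


#: Expected per-gene indices of the micro corpus, hand-computed from the
#: defining formulas (CAI under the corpus's own pooled reference weights),
#: rounded to 4 decimals.  None marks an undefined value (flagged, not NaN).
_MICRO_EXPECTED: list[dict[str, object]] = [
    # micro1: one four-fold family (Ala) fully collapsed onto GCT.
    # F(Ala) = (101/104)² + 3·(1/104)²; RSCU(GCT) = 4; GC3s = 0.
    {"gene_id": "micro1", "length_nt": 306, "gc": 0.6634, "gc3": 0.0099,
     "gc3s": 0.0, "enc": 53.8639, "enc_exp": 31.0, "enc_ratio": -0.7375,
     "cai": 1.0, "gravy": 1.8, "aroma": 0.0,
     "pr2_x": None, "pr2_y": 0.0, "p2": 1.0},
    # micro2: AAC/AAT/CCT/CCC in equal numbers → WWC=WWT=SST=SSC → P2 = 1/2.
    {"gene_id": "micro2", "length_nt": 306, "gc": 0.4983, "gc3": 0.505,
     "gc3s": 0.5, "enc": 58.0726, "enc_exp": 60.5, "enc_ratio": 0.0401,
     "cai": 0.7695, "gravy": -2.55, "aroma": 0.0,
     "pr2_x": 0.0, "pr2_y": 0.0, "p2": 0.5},
    # micro3: every analyzed codon twice → ENc = 61 exactly; PR2 reflects the
    # A/T-asymmetric codon inventory (13 A vs 15 T third bases), not 0.5.
    {"gene_id": "micro3", "length_nt": 360, "gc": 0.5126, "gc3": 0.4958,
     "gc3s": 0.4915, "enc": 61.0, "enc_exp": 60.4749, "enc_ratio": -0.0087,
     "cai": 0.5162, "gravy": -0.2797, "aroma": 0.0672,
     "pr2_x": 0.4643, "pr2_y": 0.4643, "p2": 0.5},
    # micro4: 50 Ile (+4.5) + 50 Asn (−3.5) → Gravy = 0.5 exactly.
    {"gene_id": "micro4", "length_nt": 306, "gc": 0.0033, "gc3": 0.0099,
     "gc3s": 0.0, "enc": 57.4023, "enc_exp": 31.0, "enc_ratio": -0.8517,
     "cai": 1.0, "gravy": 0.5, "aroma": 0.0,
     "pr2_x": None, "pr2_y": 0.0, "p2": 0.0},
    # micro5: F/Y/G repeats → Aroma = 68/103; Gravy = (2.8−1.3−0.4)/3.
    {"gene_id": "micro5", "length_nt": 312, "gc": 0.2233, "gc3": 0.0097,
     "gc3s": 0.0, "enc": 51.5328, "enc_exp": 31.0, "enc_ratio": -0.6623,
     "cai": 1.0, "gravy": 0.3667, "aroma": 0.6602,
     "pr2_x": None, "pr2_y": 0.0, "p2": 0.3333},
]


def worked_micro_corpus() -> tuple[list[CdsRecord], pd.DataFrame]:
    """Five tiny genes plus their fully pre-computed expected index table."""
    expected = pd.DataFrame(_MICRO_EXPECTED).set_index("gene_id")
    return _micro_genes(), expected


def write_fasta(records: Sequence[CdsRecord], path, width: int = 70) -> None:
    """Write records as plain wrapped FASTA (byte-deterministic)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
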