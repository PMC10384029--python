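"""Independent brute-force oracles used to check the package's statistics.

Everything here is written straight from the defining formulas, operating on
plain strings and dicts, sharing no code path with :mod:`cubkit` beyond the
genetic-code *table* (codon→amino-acid assignments are facts, not
algorithms).  Deliberately slow and literal.
"""

from __future__ import annotations

import itertools
import math

ALL_CODONS = ["".join(p) for p in itertools.product("ACGT", repeat=3)]

# NCBI standard code written out as data, TCAG nesting order.
_BASES = "TCAG"
_STANDARD_BY_TCAG = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
STANDARD_CODE: dict[str, str] = {}
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_BASES, repeat=3)):
    STANDARD_CODE[_b1 + _b2 + _b3] = _STANDARD_BY_TCAG[_i]

STOPS = {c for c, a in STANDARD_CODE.items() if a == "*"}


def families() -> dict[str, list[str]]:
    fams: dict[str, list[str]] = {}
    for codon in sorted(STANDARD_CODE):
        aa = STANDARD_CODE[codon]
        if aa != "*":
            fams.setdefault(aa, []).append(codon)
    return fams


ANALYZED = sorted(
    c
    for aa, cods in families().items()
    for c in cods
    if len(cods) >= 2
)


def triplets(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def codon_counts(seq: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for t in triplets(seq):
        out[t] = out.get(t, 0) + 1
    return out


def family_f_literal(counts: list[int]) -> float:
    m = len(counts)
    n = sum(counts)
    return sum(((ni + 1) / (n + m)) ** 2 for ni in counts)


def enc_literal(counts: dict[str, int]) -> float:
    by_k: dict[int, list[float]] = {}
    n_single = 0
    for aa, cods in families().items():
        if len(cods) == 1:
            n_single += 1
            continue
        f = family_f_literal([counts.get(c, 0) for c in cods])
        by_k.setdefault(len(cods), []).append(f)
    total = float(n_single)
    for k, fs in by_k.items():
        total += len(fs) / (sum(fs) / len(fs))
    return total


def enc_expected_literal(s: float) -> float:
    return 2 + s + 29 / (s**2 + (1 - s) ** 2)


def rscu_literal(counts: dict[str, int]) -> dict[str, float]:
    out: dict[str, float] = {}
    for aa, cods in families().items():
        if len(cods) < 2:
            continue
        total = sum(counts.get(c, 0) for c in cods)
        if total == 0:
            continue
        for c in cods:
            out[c] = counts.get(c, 0) / (total / len(cods))
    return out


def cai_weights_literal(ref: dict[str, int], pseudo: float = 0.5) -> dict[str, float]:
    w: dict[str, float] = {}
    for aa, cods in families().items():
        if len(cods) < 2:
            continue
        vals = {c: float(ref.get(c, 0)) for c in cods}
        if sum(vals.values()) == 0:
            continue
        vals = {c: (v if v > 0 else pseudo) for c, v in vals.items()}
        top = max(vals.values())
        for c, v in vals.items():
            w[c] = v / top
    return w


def cai_literal(counts: dict[str, int], weights: dict[str, float]) -> float:
    logs = []
    for codon, n in counts.items():
        if codon in weights:
            logs.extend([math.log(weights[codon])] * n)
    return math.exp(sum(logs) / len(logs))


def composition_literal(seq: str) -> dict[str, float]:
    """Character-tally composition of a CDS string (with start + stop)."""
    sense = [t for t in triplets(seq) if t not in STOPS]
    syn = [t for t in sense if t in ANALYZED]

    def frac(codons: list[str], pos: int, bases: str) -> float:
        return sum(1 for c in codons if c[pos] in bases) / len(codons)

    gc1 = frac(sense, 0, "GC")
    gc2 = frac(sense, 1, "GC")
    gc3 = frac(sense, 2, "GC")
    return {
        "gc": (gc1 + gc2 + gc3) / 3,
        "gc1": gc1,
        "gc2": gc2,
        "gc3": gc3,
        "gc12": (gc1 + gc2) / 2,
        "gc3s": frac(syn, 2, "GC"),
        "a3": frac(syn, 2, "A"),
        "t3": frac(syn, 2, "T"),
        "c3": frac(syn, 2, "C"),
        "g3": frac(syn, 2, "G"),
    }


def pr2_literal(counts: dict[str, int]) -> tuple[float | None, float | None]:
    fams = families()
    qualifying = {
        c for aa, cods in fams.items() if len(cods) in (2, 4, 6) for c in cods
    }
    tally = {b: 0 for b in "ACGT"}
    for codon, n in counts.items():
        if codon in qualifying:
            tally[codon[2]] += n
    gc = tally["G"] + tally["C"]
    at = tally["A"] + tally["T"]
    x = tally["G"] / gc if gc else None
    y = tally["A"] / at if at else None
    return x, y


def p2_literal(counts: dict[str, int]) -> dict[str, float]:
    ww = {"AA", "AT", "TA", "TT"}
    ss = {"CC", "CG", "GC", "GG"}
    tall = {"WWC": 0, "WWT": 0, "SST": 0, "SSC": 0}
    for codon, n in counts.items():
        d, t = codon[:2], codon[2]
        if t in "CT":
            if d in ww:
                tall["WWC" if t == "C" else "WWT"] += n
            elif d in ss:
                tall["SST" if t == "T" else "SSC"] += n
    denom = sum(tall.values())
    tall["P2"] = (tall["WWC"] + tall["SST"]) / denom if denom else float("nan")
    return tall


KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def gravy_literal(counts: dict[str, int]) -> float:
    vals = []
    for codon, n in counts.items():
        aa = STANDARD_CODE[codon]
        if aa == "*" or codon in ("ATG", "TGG"):
            continue
        vals.extend([KD[aa]] * n)
    return sum(vals) / len(vals)


def aroma_literal(counts: dict[str, int]) -> float:
    total = 0
    arom = 0
    for codon, n in counts.items():
        aa = STANDARD_CODE[codon]
        if aa == "*":
            continue
        total += n
        if aa in "FYW":
            arom += n
    return arom / total


def two_point_slope(x: list[float], y: list[float]) -> float:
    return (y[1] - y[0]) / (x[1] - x[0])


def ca_eigen_oracle(x, n_axes: int):
    """Row principal coordinates via eigendecomposition of S·Sᵀ (not SVD)."""
    import numpy as np

    x = np.asarray(x, dtype=float)
    total = x.sum()
    p = x / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    # eigen-decompose the row cross-product matrix
    m = s @ s.T
    evals, evecs = np.linalg.eigh(m)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes]) / np.sqrt(r)[:, None]
    fractions = evals / evals.sum()
    return coords, fractions
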