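"""Gene×RSCU matrix, correspondence analysis and the correlation panels.

Each QC-passed gene becomes a 59-dimensional RSCU vector (one dimension per
analyzed codon, fixed lexicographic order), which removes most of the
amino-acid-composition signal before ordination.  Classical correspondence
analysis (CA) is then applied: the matrix is scaled to a correspondence
table, centred by row and column masses, and the standardized residuals are
decomposed by SVD; squared singular values are the per-axis inertias.  Genes
separate along axis 1 by their dominant codon-usage trend (typically GC3
content), and the per-axis inertia fractions quantify how concentrated that
trend is.

Correlation analyses (ENc–GC3s, axis1–composition, CAI–ENc, Gravy/Aroma/
length panels) default to Spearman's rank coefficient, with Pearson
selectable; panel p-values are reported raw and Benjamini–Hochberg adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cub_indices import rscu
from .genetic_code import GeneticCode
from .sequence_io import CodonCounts

__all__ = [
    "RscuMatrix",
    "CaResult",
    "CorrelationResult",
    "DegenerateInertiaError",
    "build_rscu_matrix",
    "correspondence_analysis",
    "correlation",
    "correlation_panels",
    "DEFAULT_PANEL_PAIRS",
]

#: Variable pairs examined across the corpus, in reporting order.
DEFAULT_PANEL_PAIRS: tuple[tuple[str, str], ...] = (
    ("enc", "gc3s"),
    ("axis1", "gc"),
    ("axis1", "gc3"),
    ("axis1", "cai"),
    ("axis1", "enc"),
    ("cai", "enc"),
    ("cai", "gc3"),
    ("gravy", "gc"),
    ("gravy", "enc"),
    ("aroma", "gc"),
    ("aroma", "enc"),
    ("length_nt", "gc"),
    ("length_nt", "enc"),
)


class DegenerateInertiaError(ValueError):
    """CA input has (numerically) zero total inertia or zero mass."""


@dataclass(frozen=True)
class RscuMatrix:
    """Genes × analyzed-codons RSCU values.

    ``zero_imputed`` records (gene_id, amino_acid) pairs whose family was
    unobserved in that gene; their codons' entries are 0 by imputation.
    """

    values: pd.DataFrame
    zero_imputed: tuple[tuple[str, str], ...]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def codons(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class CaResult:
    row_coords: pd.DataFrame  # genes × axes (principal coordinates)
    col_coords: pd.DataFrame  # codons × axes
    inertia_fractions: np.ndarray  # over all axes, sums to 1

    @property
    def n_axes(self) -> int:
        return self.row_coords.shape[1]


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p_value: float
    n: int
    flag: str = ""

    @property
    def defined(self) -> bool:
        return self.flag == ""


def build_rscu_matrix(
    genes: Sequence[CodonCounts], code: GeneticCode
) -> RscuMatrix:
    """One RSCU row per gene over the fixed lexicographic codon columns."""
    if len(genes) < 2:
        raise ValueError("an RSCU matrix needs at least 2 genes")
    columns = list(code.analyzed_codons)
    rows = []
    imputed: list[tuple[str, str]] = []
    for cc in genes:
        table = rscu(cc, code)
        rows.append([table.values.get(c, 0.0) for c in columns])
        imputed.extend((cc.gene_id, aa) for aa in sorted(table.undefined_families))
    frame = pd.DataFrame(
        rows, index=[cc.gene_id for cc in genes], columns=columns, dtype=float
    )
    return RscuMatrix(frame, tuple(imputed))


def correspondence_analysis(
    matrix: RscuMatrix | pd.DataFrame, n_axes: int = 4
) -> CaResult:
    """Classical CA of a non-negative matrix.

    Returns principal row/column coordinates on up to ``n_axes`` axes and
    the inertia fraction of *every* axis (non-increasing, summing to 1).
    Axis signs are fixed so that the first codon (column) with a nonzero
    loading has a positive loading, making output deterministic.
    """
    frame = matrix.values if isinstance(matrix, RscuMatrix) else matrix
    x = frame.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("CA requires a non-negative matrix")
    total = x.sum()
    if total <= 0:
        raise DegenerateInertiaError("matrix grand total is zero")
    max_rank = min(x.shape) - 1
    if n_axes > max_rank:
        raise ValueError(f"n_axes={n_axes} exceeds max rank {max_rank}")
    p = x / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    keep_rows = r > 0
    keep_cols = c > 0
    p = p[np.ix_(keep_rows, keep_cols)]
    r = r[keep_rows]
    c = c[keep_cols]
    expected = np.outer(r, c)
    s = (p - expected) / np.sqrt(expected)
    u, sv, vt = np.linalg.svd(s, full_matrices=False)
    inertias = sv**2
    total_inertia = inertias.sum()
    if total_inertia <= 1e-12:
        raise DegenerateInertiaError(
            "zero total inertia: all rows share one profile"
        )
    # trailing numerically-zero axes are noise; rank cap
    inertias = inertias[:max_rank]
    u, sv, vt = u[:, :max_rank], sv[:max_rank], vt[:max_rank]
    fractions = inertias / inertias.sum()
    row_coords = (u * sv) / np.sqrt(r)[:, None]
    col_coords = (vt.T * sv) / np.sqrt(c)[:, None]
    # deterministic sign: first nonzero codon loading per axis is positive
    for j in range(col_coords.shape[1]):
        col = col_coords[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            col_coords[:, j] *= -1
            row_coords[:, j] *= -1
    axes = [f"axis{i + 1}" for i in range(n_axes)]
    return CaResult(
        row_coords=pd.DataFrame(
            row_coords[:, :n_axes],
            index=frame.index[keep_rows],
            columns=axes,
        ),
        col_coords=pd.DataFrame(
            col_coords[:, :n_axes],
            index=frame.columns[keep_cols],
            columns=axes,
        ),
        inertia_fractions=fractions,
    )


def correlation(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "spearman",
) -> CorrelationResult:
    """Spearman or Pearson correlation with complete-case filtering."""
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[mask], yv[mask]
    n = len(xv)
    if n < 3:
        return CorrelationResult(float("nan"), float("nan"), n, "too-few-cases")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, "zero-variance")
    if method == "spearman":
        rho, p = stats.spearmanr(xv, yv)
    else:
        rho, p = stats.pearsonr(xv, yv)
    return CorrelationResult(float(rho), float(p), n)


def correlation_panels(
    index_table: pd.DataFrame,
    pairs: Iterable[tuple[str, str]] = DEFAULT_PANEL_PAIRS,
    method: str = "spearman",
) -> pd.DataFrame:
    """Run the fixed correlation panel over a per-gene index table.

    Returns one row per variable pair with the coefficient, raw two-sided
    p-value, Benjamini–Hochberg adjusted p-value and complete-case n.
    """
    pairs = list(pairs)
    missing = {v for pair in pairs for v in pair} - set(index_table.columns)
    if missing:
        raise KeyError(f"index table lacks columns: {sorted(missing)}")
    rows = []
    for a, b in pairs:
        res = correlation(index_table[a], index_table[b], method=method)
        rows.append(
            {
                "var_x": a,
                "var_y": b,
                "method": method,
                "coefficient": res.coefficient,
                "p_value": res.p_value,
                "n": res.n,
                "flag": res.flag,
            }
        )
    panel = pd.DataFrame(rows)
    defined = panel["flag"] == ""
    adjusted = np.full(len(panel), np.nan)
    if defined.any():
        adjusted[defined.to_numpy()] = multipletests(
            panel.loc[defined, "p_value"], method="fdr_bh"
        )[1]
    panel["p_adjusted"] = adjusted
    return panel
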