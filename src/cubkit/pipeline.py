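"""End-to-end orchestration: QC → per-gene indices → summaries → diagnostics.

``run_pipeline`` takes one or more CDS FASTA files (one "genome" each),
applies quality control, computes every per-gene index (composition, ENc
and its expected value, CAI, Gravy, Aroma, PR2 coordinates, P2), runs the
RSCU correspondence analysis and the optimal-codon and correlation panels,
and writes everything as TSV coordinate/table files plus a JSON config
snapshot — deterministic given config and inputs.  Percentages are printed
to 2 decimals and indices to 4, with a full-precision sidecar for machine
consumption.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import composition as comp
from . import cub_indices as cub
from . import multivariate as mv
from . import selection_mutation as sel
from .genetic_code import GeneticCode, load_code
from .sequence_io import (
    CdsRecord,
    CodonCounts,
    DEFAULT_MIN_LEN,
    count_codons,
    qc_filter,
    read_cds_fasta,
)

__all__ = ["RunConfig", "run_pipeline", "analyze_genome", "gene_index_table", "compare_genomes"]

log = logging.getLogger("cubkit")

_PERCENT_COLS = ("gc", "gc1", "gc2", "gc3", "gc12", "gc3s", "a3", "t3", "c3", "g3")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on; serialized for provenance."""

    fasta_paths: tuple[str, ...]
    out_dir: str
    genetic_code_table: int = 1
    min_len: int = DEFAULT_MIN_LEN
    dedupe: bool = True
    cai_reference: str | None = None  # FASTA of highly expressed genes
    correlation_method: str = "spearman"
    ca_axes: int = 4
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def gene_index_table(
    gene_counts: Sequence[CodonCounts],
    code: GeneticCode,
    cai_ref_weights: Mapping[str, float],
) -> pd.DataFrame:
    """All per-gene statistics, one row per QC-passed gene.

    Undefined values (e.g. a PR2 component with a zero denominator) appear
    as NaN alongside an explicit ``flags`` column naming what is undefined.
    """
    rows = []
    for cc in gene_counts:
        profile = comp.composition_profile(cc, code)
        res = cub.enc_result(cc, code, profile.gc3s)
        pr2 = sel.pr2_point(cc, code)
        p2 = sel.p2_index(cc)
        flags = []
        if pr2.x is None:
            flags.append("pr2_x-undefined")
        if pr2.y is None:
            flags.append("pr2_y-undefined")
        if p2.p2 is None:
            flags.append("p2-undefined")
        row = {
            "gene_id": cc.gene_id,
            "length_nt": 3 * cc.total_codons,
            **profile.as_dict(),
            "enc": res.enc_obs,
            "enc_exp": res.enc_exp,
            "enc_ratio": res.enc_ratio,
            "cai": cub.cai(cc, cai_ref_weights),
            "gravy": cub.gravy(cc, code),
            "aroma": cub.aroma(cc, code),
            "pr2_x": np.nan if pr2.x is None else pr2.x,
            "pr2_y": np.nan if pr2.y is None else pr2.y,
            "p2": np.nan if p2.p2 is None else p2.p2,
            "flags": ";".join(flags),
        }
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def _pooled_counts(gene_counts: Sequence[CodonCounts], code: GeneticCode) -> CodonCounts:
    pooled: dict[str, int] = {}
    for cc in gene_counts:
        for codon, n in cc.counts.items():
            pooled[codon] = pooled.get(codon, 0) + n
    n_analyzed = sum(n for c, n in pooled.items() if c not in code.excluded_codons)
    return CodonCounts("pooled", pooled, n_analyzed)


def summarize_genome(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/min/max per index over the per-gene table."""
    numeric = table.select_dtypes(include=[np.number])
    return pd.DataFrame(
        {
            "mean": numeric.mean(),
            "sd": numeric.std(ddof=1),
            "min": numeric.min(),
            "max": numeric.max(),
        }
    )


def analyze_genome(
    records: Sequence[CdsRecord],
    code: GeneticCode,
    *,
    label: str = "genome",
    dedupe: bool = True,
    min_len: int = DEFAULT_MIN_LEN,
    cai_reference: Sequence[CdsRecord] | None = None,
    correlation_method: str = "spearman",
    ca_axes: int = 4,
) -> dict[str, object]:
    """Run the full analysis on one genome's records; return all artifacts."""
    passed, qc_report = qc_filter(records, code, dedupe=dedupe, min_len=min_len)
    log.info(
        "%s: %d/%d CDS passed QC (%s)",
        label, qc_report.n_passed, qc_report.n_input,
        qc_report.rule_totals() or "no failures",
    )
    if len(passed) < 2:
        raise ValueError(f"{label}: fewer than 2 QC-passing genes")
    gene_counts = [count_codons(r, code) for r in passed]

    if cai_reference is not None:
        ref_passed, _ = qc_filter(cai_reference, code, dedupe=dedupe, min_len=min_len)
        ref_counts = [count_codons(r, code) for r in ref_passed]
    else:
        ref_counts = gene_counts  # self-referenced default
    weights = cub.cai_weights(_pooled_counts(ref_counts, code), code)

    table = gene_index_table(gene_counts, code, weights)

    rscu_matrix = mv.build_rscu_matrix(gene_counts, code)
    ca = mv.correspondence_analysis(rscu_matrix, n_axes=ca_axes)
    table = table.join(ca.row_coords)

    pooled = _pooled_counts(gene_counts, code)
    pooled_rscu = cub.rscu(pooled, code)

    n_genes = len(gene_counts)
    optimal = cub.optimal_codons(
        rscu_matrix.values, table["enc"], code,
        method=correlation_method, min_genes=min(10, n_genes),
    )
    panel = mv.correlation_panels(table, method=correlation_method)
    neutrality = sel.neutrality_fit(table["gc12"], table["gc3"])
    p2s = sel.p2_summary(sel.p2_index(cc) for cc in gene_counts)
    pooled_profile = comp.pool_composition(gene_counts, code)

    return {
        "label": label,
        "qc_report": qc_report,
        "gene_counts": gene_counts,
        "gene_table": table,
        "summary": summarize_genome(table),
        "pooled_composition": pooled_profile,
        "pooled_rscu": pooled_rscu,
        "rscu_matrix": rscu_matrix,
        "ca": ca,
        "optimal_codons": optimal,
        "correlation_panel": panel,
        "neutrality": neutrality,
        "p2_summary": p2s,
    }


def _fmt(table: pd.DataFrame) -> pd.DataFrame:
    """Table-style rounding: composition as % to 2 dp, indices to 4 dp."""
    out = table.copy()
    for col in out.columns:
        if col in _PERCENT_COLS:
            out[col] = (out[col] * 100).round(2)
        elif pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(4)
    return out


def _write_genome_outputs(result: dict[str, object], out: Path, code: GeneticCode) -> None:
    out.mkdir(parents=True, exist_ok=True)
    table: pd.DataFrame = result["gene_table"]
    result["qc_report"].write_tsv(out / "qc_report.tsv")
    _fmt(table).to_csv(out / "gene_indices.tsv", sep="\t")
    table.to_csv(out / "gene_indices_full.tsv", sep="\t")
    _fmt(result["summary"].T).T.to_csv(out / "summary.tsv", sep="\t")

    # figure-backing coordinate files, all reconstructible from gene_indices
    table[["gc3s", "enc", "enc_exp", "enc_ratio"]].to_csv(
        out / "enc_plot.tsv", sep="\t"
    )
    grid = np.linspace(0.0, 1.0, 101)
    pd.DataFrame(
        {"gc3s": grid, "enc_expected": [cub.enc_expected(s) for s in grid]}
    ).to_csv(out / "enc_expected_curve.tsv", sep="\t", index=False)
    table[["pr2_x", "pr2_y"]].to_csv(out / "pr2_plot.tsv", sep="\t")
    table[["gc3", "gc12"]].to_csv(out / "neutrality_plot.tsv", sep="\t")

    neutrality = result["neutrality"]
    pd.DataFrame(
        [{
            "slope": neutrality.slope, "intercept": neutrality.intercept,
            "r": neutrality.r, "p_value": neutrality.p_value,
            "n_genes": neutrality.n_genes,
            "interpretation": neutrality.interpretation,
        }]
    ).to_csv(out / "neutrality_fit.tsv", sep="\t", index=False)

    pooled_rscu = result["pooled_rscu"]
    pd.DataFrame(
        [
            {
                "codon": c,
                "amino_acid": code.translate_codon(c),
                "rscu": round(v, 4),
                "class": pooled_rscu.classes[c],
            }
            for c, v in sorted(pooled_rscu.values.items())
        ]
    ).to_csv(out / "rscu_pooled.tsv", sep="\t", index=False)
    rscu_long = (
        result["rscu_matrix"].values.stack().rename("rscu").reset_index()
    )
    rscu_long.columns = ["gene_id", "codon", "rscu"]
    rscu_long.to_csv(out / "rscu_long.tsv", sep="\t", index=False)

    ca = result["ca"]
    ca.row_coords.round(6).to_csv(out / "ca_gene_coords.tsv", sep="\t")
    ca.col_coords.round(6).to_csv(out / "ca_codon_coords.tsv", sep="\t")
    fr = ca.inertia_fractions
    pd.DataFrame(
        {
            "axis": [f"axis{i + 1}" for i in range(len(fr))],
            "inertia_fraction": np.round(fr, 6),
            "cumulative": np.round(np.cumsum(fr), 6),
        }
    ).to_csv(out / "ca_inertia.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "amino_acid": oc.amino_acid,
                "codon": oc.codon if oc.codon else "none",
                "r": round(oc.r, 4) if oc.r == oc.r else "",
                "p_value": oc.p_value if oc.p_value == oc.p_value else "",
                "note": oc.note,
            }
            for oc in result["optimal_codons"]
        ]
    ).to_csv(out / "optimal_codons.tsv", sep="\t", index=False)

    result["correlation_panel"].to_csv(
        out / "correlation_panel.tsv", sep="\t", index=False
    )

    p2s = result["p2_summary"]
    pd.DataFrame(
        [{
            "WWC": p2s.totals.wwc, "WWT": p2s.totals.wwt, "WWY": p2s.totals.wwy,
            "SST": p2s.totals.sst, "SSC": p2s.totals.ssc, "SSY": p2s.totals.ssy,
            "P2_pooled": round(p2s.pooled, 4),
            "P2_mean_of_genes": round(p2s.mean_of_genes, 4),
            "n_genes": p2s.n_genes,
        }]
    ).to_csv(out / "p2_summary.tsv", sep="\t", index=False)


def genome_summary_row(result: dict[str, object]) -> dict[str, object]:
    """One cross-genome comparison row from a genome's analysis artifacts."""
    pooled = result["pooled_composition"]
    table = result["gene_table"]
    p2s = result["p2_summary"]
    neutrality = result["neutrality"]
    ca = result["ca"]
    return {
        "genome": result["label"],
        "n_genes": len(table),
        **{f"{k}_pct": 100 * v for k, v in pooled.as_dict().items()},
        "mean_enc": table["enc"].mean(),
        "sd_enc": table["enc"].std(ddof=1),
        "mean_cai": table["cai"].mean(),
        "sd_cai": table["cai"].std(ddof=1),
        "mean_gravy": table["gravy"].mean(),
        "mean_aroma": table["aroma"].mean(),
        "p2_pooled": p2s.pooled,
        "p2_mean_of_genes": p2s.mean_of_genes,
        "neutrality_slope": neutrality.slope,
        "axis1_fraction": float(ca.inertia_fractions[0]),
        "axis1_4_fraction": float(ca.inertia_fractions[:4].sum()),
    }


def compare_genomes(rows: Iterable[Mapping[str, object]]) -> pd.DataFrame:
    """Stack per-genome summary rows into one sortable comparison table."""
    frame = pd.DataFrame(list(rows))
    if frame.empty:
        raise ValueError("no genome summaries to compare")
    dup = frame["genome"][frame["genome"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate genome labels: {sorted(set(dup))}")
    return frame.set_index("genome")


def run_pipeline(config: RunConfig) -> Path:
    """Run the whole analysis for every input FASTA; return the output dir."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    (out_root / "config.json").write_text(config.to_json() + "\n")
    code = load_code(config.genetic_code_table)
    cai_ref = (
        read_cds_fasta(config.cai_reference) if config.cai_reference else None
    )
    summary_rows = []
    for path in config.fasta_paths:
        label = Path(path).stem
        records = read_cds_fasta(path)
        result = analyze_genome(
            records,
            code,
            label=label,
            dedupe=config.dedupe,
            min_len=config.min_len,
            cai_reference=cai_ref,
            correlation_method=config.correlation_method,
            ca_axes=config.ca_axes,
        )
        _write_genome_outputs(result, out_root / label, code)
        summary_rows.append(genome_summary_row(result))
    compare = compare_genomes(summary_rows)
    _fmt(compare).to_csv(out_root / "genome_comparison.tsv", sep="\t")
    log.info("pipeline finished: %d genome(s) → %s", len(summary_rows), out_root)
    return out_root
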