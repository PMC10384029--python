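# Methods

## Scope and model

`cubkit` quantifies codon usage bias (CUB) in sets of protein-coding
sequences and attributes it to its two classical drivers: directional
mutation pressure (visible as compositional trends, chiefly GC content at
synonymous third positions) and natural/translational selection (visible as
codon concentration beyond what composition explains). All statistics
operate on per-gene codon counts derived from quality-filtered CDSs; nothing
requires alignments, annotations, or expression data.

## Genetic code and codon sets

Translation tables come from the NCBI definitions (standard table 1 and the
ciliate nuclear table 6, where TAA/TAG encode glutamine and TGA is the sole
stop). The synonymous-family partition — the grouping of sense codons by
amino acid, with degeneracy 1–6 — is always recomputed from the codon→amino
acid map, so every downstream statistic adapts automatically to a reassigned
code. Three codon sets matter:

* **sense codons** (61 under the standard code),
* **analyzed codons**: sense codons in multi-codon families (59 under the
  standard code; Met and Trp are excluded because a one-codon family cannot
  show synonymous bias),
* **PR2-qualifying codons**: members of 2-, 4- and 6-fold families (the
  3-fold Ile family is additionally excluded there).

## Quality control

A CDS is kept iff it contains only A/C/G/T, its length is a multiple of 3
and strictly greater than `min_len` (default 300 nt), it starts with ATG,
ends with a stop codon of the chosen table, and contains no internal stop.
Records containing any ambiguous base are rejected whole — trimming would
break the reading frame and there is no principled repair rule. Exact
full-sequence duplicates are collapsed (no near-duplicate clustering; no
threshold would be defensible without an explicit identity model). Failures
are reported with the first failing rule, never raised, and the report
accounts for every input record; filtering is idempotent.

## Composition

GC, GC1, GC2, GC3 and GC12 = (GC1+GC2)/2 are computed over all sense codons
of a gene (start and Trp codons included, stops excluded) — the whole-CDS
convention. GC3s and the third-position base fractions A3/T3/C3/G3 are
computed over analyzed codons only, where third-position composition can
reflect codon *choice*. Keeping GC3 and GC3s distinct matters: the expected
ENc curve and ENc plot are functions of GC3s, while the neutrality
regression uses GC3. Position tallies use exact rational arithmetic before
float conversion, so A3+T3+C3+G3 = 1 holds exactly. Genome-level values are
codon-count-weighted pools (equivalent to concatenating all CDSs), which is
order-invariant and not an unweighted mean of per-gene fractions.

## ENc — codon-family formulation

For a family of degeneracy m with codon counts n_i (total n),

    F = Σ_{i=1..m} ((n_i + 1) / (n + m))²

and the family is worth 1/F effective codons. The +1 pseudocounts make F
defined even at n = 0 (where F = 1/m exactly), so no family is ever dropped
by default (`drop_unobserved_families` exists for sensitivity analysis).
Gene-level aggregation is Wright-style by degeneracy class:

    ENc = (#singleton families) + Σ_k (#families of degeneracy k) / F̄_k

i.e. 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ under the standard code. Six-fold
families are treated as single 6-codon families, not 2+4 splits, because m
in the formula is the family size. The pseudocount algebra makes uniform
usage give exactly 61; a gene using one codon per family approaches 20 from
above as counts grow (20.008 at 10,000 copies per family). ENc < 35 is the
conventional threshold for strong bias.

The expected ENc under GC mutation pressure alone is

    ENc_exp(s) = 2 + s + 29 / (s² + (1 − s)²),   s = GC3s,

and the ENc ratio (ENc_exp − ENc_obs)/ENc_exp measures the departure.
A numerical caveat documented here because it is easy to mis-assert: the
curve's value at s = 0.5 is exactly 60.5, but because of the linear term its
true maximum sits slightly above, at s ≈ 0.502 (value ≈ 60.501).

## RSCU and optimal codons

RSCU(c) = O_c / ((1/k)·Σ_family O), so family sums equal the degeneracy
whenever the family is observed; a zero-total family is flagged as
undefined rather than propagated as NaN (and imputed as 0-with-flag in the
gene×codon matrix). Codons are classed over-represented above 1.6 and
under-represented below 0.6, with exactly 1 labelled unbiased.

A family's putative optimal codon is the member whose per-gene RSCU has the
strongest *negative* correlation with per-gene ENc (usage rising as bias
strengthens), requiring two-sided p < 0.05. Spearman correlation is the
default (index distributions are heavy-tailed); Pearson is selectable. Ties
break by larger mean RSCU, then lexicographic codon order — deterministic by
construction. Zero-variance codon columns are skipped with a note. At least
10 genes (configurable) are required for estimable correlations.

## CAI

CAI = exp((1/L)·Σ ln ω_ck) over a gene's analyzed codons. The relative
adaptiveness ω is the Sharp–Li ratio-to-family-max computed on a reference
codon pool. The reference defaults to the entire filtered gene set
(self-referenced, the common workflow default when no highly-expressed set
is curated); `--cai-reference` accepts a FASTA of highly expressed genes.
Codons absent from the reference within an observed family receive a
pseudo-frequency of 0.5 before the ratio, keeping ln ω finite; a family
absent from the reference altogether is an error naming the family.

## Gravy and Aroma

Gravy is the mean Kyte–Doolittle hydropathy (per-residue scale −4.5…+4.5)
of the translated analyzed codons; Met/Trp are excluded, consistent with the
codon exclusions of the usage indices. Typical whole-protein values land
around −2…+2. Aroma is the fraction of F/Y/W residues over *all* translated
residues including Met and Trp — deliberately a property of the protein, not
of the codon-usage exclusion set, since Trp is itself aromatic.

## PR2, P2 and the neutrality regression

PR2 coordinates are x = G3/(G3+C3), y = A3/(A3+T3) over third positions of
2/4/6-fold families; a zero denominator flags the component undefined and
excludes the gene from plot aggregates. Note that "no bias" does not put a
random-usage gene exactly at (0.5, 0.5): after removing stops, Met/Trp and
the Ile family, the qualifying codon inventory itself is A/T- and
G/C-asymmetric, so even a perfectly neutral corpus centers near (0.42, 0.42)
at GC3 = 0.5. The (0.5, 0.5) reference point is the parity expectation, not
the neutral-generator expectation; tests verify both statements separately.

P2 = (WWC + SST)/(WWY + SSY), tallied over codons starting with AA/AT/TA/TT
(W = A/T) or CC/CG/GC/GG (S = C/G) and ending in a pyrimidine. Genome-level
P2 is reported under *both* aggregation conventions — the mean of per-gene
values and the value recomputed from pooled counts — because they genuinely
differ when genes contribute unequal numbers of qualifying codons and
published tables are often ambiguous about which was used.

The neutrality fit is unweighted OLS of GC12 on GC3 across genes (slope,
intercept, r, two-sided p). |slope| near 1 reads as mutation pressure alone,
near 0 as selection alone, near 1/2 as balanced; these labels are attached
as interpretation only (thresholds 0.75/0.25), never used in computation.

## Correspondence analysis

Classical CA of the gene×RSCU matrix (59 columns, fixed lexicographic
order): scale to a correspondence table, center by row/column masses,
SVD of the standardized residuals; squared singular values are axis
inertias, row/column principal coordinates are reported for the first
`n_axes` (default 4) axes, and inertia fractions over all axes sum to 1.
Zero-mass rows/columns are dropped; a matrix with a single distinct row
profile raises a degenerate-inertia error. Axis signs are fixed so the first
codon with a nonzero loading loads positively, making output byte-stable
across platforms. Whether to feed CA raw or row-normalized RSCU is an open
choice in the literature; classical CA's internal mass normalization is
adopted here.

## Correlation panels

A fixed panel — (ENc, GC3s), (axis1 vs GC/GC3/CAI/ENc), (CAI vs ENc/GC3),
(Gravy/Aroma/length vs GC/ENc) — is computed with complete-case filtering,
Spearman by default, reporting raw and Benjamini–Hochberg adjusted p-values.

## Synthetic data generator

The generator's role is to give every pipeline stage a ground truth:

* **Mutation knob** `gc3_target`: third-position base probabilities with
  P(G) = P(C) = g/2, P(A) = P(T) = (1−g)/2, applied within each family and
  renormalized. Default 0.35 (AT-rich, the regime typical of ciliate
  macronuclear genomes, whose GC3s spans roughly 13–62%).
* **Selection knob** `preference_strength` s: one planted codon per family
  is boosted by e^s before renormalization. A fraction
  `expression_gradient` (default 0.5) of genes is "highly expressed" with
  the strength amplified ×3, creating the CAI/ENc gradient used by the
  optimal-codon machinery.

Amino acids are i.i.d. over the 18 multi-codon families (uniform default),
lengths uniform over 150–400 internal codons (satisfying the >300 nt QC
rule), ATG/stop appended; one seed drives everything, and identical specs
produce byte-identical FASTA. What the generator does **not** emulate:
amino-acid composition of real proteomes, length/expression correlations,
phylogenetic correlation between genes, dinucleotide effects, and
position-dependent codon usage — so passing tests validate the statistics'
algebra and recovery behavior, not claims about any real genome.

Finite-length caveat: per-gene ENc is biased below 61 at neutrality by
multinomial sampling noise of order m/n per family (≈58 at 200-codon genes,
≈60.5 at 6000), so neutral-limit tests check monotone approach, not
equality.

The neutrality-corpus constructor realizes targets exactly instead of
sampling them: each gene draws a latent GC level g ~ U(0.15, 0.85), sets
GC3 = g and GC12 = β·g + (1−β)·0.5 + ε (ε ~ N(0, 0.01²)) by mixing integer
counts of four archetype codons (GGG/GGT/AAG/AAT) matched to the target
margins. The OLS slope of GC12 on GC3 then has expectation β by
construction, and recovery (±0.05 at n = 500, exact to ±0.01 at β = 1) is a
property of the regression rather than of rejection-sampling luck.

Optimal-codon recovery is exercised at `preference_strength = 2.0`
(≈7.4-fold boost, ×3 amplified in the highly expressed half) on 60-gene,
150–250-codon corpora: strong enough that every family's planted codon is
recovered in ≥95 of 100 seeded replicates, but below the saturation regime
where both expression classes pin RSCU at its ceiling and the RSCU–ENc
correlation that defines optimality flattens out.

The worked micro corpus is five hand-auditable genes (a collapsed Ala gene,
the classic 4-codon P2 = 0.5 example, a perfectly uniform gene, an Ile/Asn
Gravy = 0.5 gene, and an aromatic-rich gene) with a frozen expected table
computed from the defining formulas; the pipeline must reproduce it to 4
printed decimals, bit for bit.

## Numerical and formatting choices

Indices are printed to 4 decimals and composition percentages to 2, with a
full-precision machine-readable sidecar. Family F values use compensated
summation; composition uses rational arithmetic; RSCU classification treats
1 as unbiased within 1e−9. All pipeline outputs are reconstructible from the
per-gene table (coordinate files carry no hidden state), and reruns on the
same config and inputs are byte-identical.

## Problem sizes used in the shipped checks

The shipped verification suite runs at desk scale by design: 1000-gene
random batches for the RSCU/CAI algebra checks, 500-gene corpora for
neutrality recovery, 100 replicates × 60 genes for optimal-codon recovery,
and 20×59 matrices for the CA oracle comparisons. These sizes put every
sampling-based assertion comfortably inside its stated tolerance band while
keeping the whole suite in the seconds-to-minutes range.

## Known limitations

* Only NCBI tables 1 and 6 are wired up; other nuclear or organellar codes
  would need their table ids added (the partition logic already generalizes).
* The self-referenced CAI default measures conformity to the genome-wide
  codon profile, not expression-calibrated adaptation; supply a curated
  highly-expressed reference for the latter.
* ENc's pseudocount formulation is length-biased downward for short genes;
  comparisons across corpora with very different length distributions should
  use the ENc ratio or restrict to comparable lengths.
* The P2 "correct pyrimidine" convention (C after W-starting doublets, T
  after S-starting ones) is taken as the fixed published rule; no attempt is
  made to infer tRNA pools.
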