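# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the `germsoma` pipeline.

## Expression classification

**Normalization.** Size factor of a sample = (column sum after removing
the `ceil(0.003 · n_genes)` largest counts in that sample) / 10⁷. Trimming
is per-sample and uses a stable sort, so ties at the trim boundary resolve
deterministically. The divisor makes factors ≈ 1 for libraries of ten
million trimmed reads; only ratios between factors matter downstream.

**Expressed-gene filter.** Genes with zero counts in *all* samples are
removed first; then genes whose mean normalized expression lies at or
below the 10th percentile (linear-interpolation quantile) of the remaining
genes' means. Whether the original study computed its decile on per-gene
means or another summary is not stated in its text; the mean was chosen
and is exposed (`low_quantile`, default 0.10). The ≤ comparison removes
ties at the threshold.

**RPKM.** `(count + 0.1) · 10⁹ / (length_bp · total_mapped)`. The 0.1
pseudocount guarantees positivity so fold ratios are always defined; RPKM
ratios are reported alongside the size-factor-normalized ratios used for
classification, and the two correlate at r² > 0.95 on synthetic data (the
property suite asserts this).

**Differential expression.** The pipeline is built around classification
thresholds, not a particular test. The built-in test models a gene's
normalized counts as negative binomial with variance μ + αμ², estimating a
single pooled dispersion α by method of moments across both cell types
(solve Σ(x−m)² = Σ(m/s + αm²) on the normalized scale); α ≤ 0 degenerates
to Poisson. The Wald statistic is the natural-log fold change of group
means over its delta-method standard error, `Var(log m_g) = Σ_j (1/(μ s_j)
+ α) / n_g²`; with unit size factors and α = 0 this reduces to the Poisson
limit z = Δlog / √(1/S_A + 1/S_B) on the group sums. A gene with zero
counts in both groups reports a missing p (NaN); a gene with zero counts
in exactly one group gets a half-count shift of both group means so the
statistic stays finite (the call is extreme regardless). Real DESeq2-style
output can replace the built-in test via an external per-gene p-value
column (`classify --pvals`); BH adjustment is always applied in-pipeline
across the expressed genes.

**Class boundaries.** Ratio exactly 2 → biased (the threshold is "at
least twofold"); ratio exactly 5 → biased ("two- to fivefold"); specific
requires strictly more than fivefold. Significance is strict: q < α. A
gene with missing p/FDR can only be constitutive or low-confidence.

## Fisher testing and FDR

The two-sided p-value follows the probability-mass definition: the sum of
hypergeometric probabilities of all tables with the observed margins that
do not exceed the observed table's probability, with relative slack
1 + 1e−7 for float comparison. It is computed directly from log-gamma
binomial coefficients (vectorized over the support), which agrees with
`scipy.stats.fisher_exact` to ≤ 1e−13 and with exact rational enumeration
to ≤ 1e−9 over all 635,375 tables of total ≤ 60. The odds ratio is the
unconditional cross-product ratio a·d/(b·c) (+∞ when b·c = 0 and a·d > 0,
NaN when both products vanish); it is used only for direction, so the
conditional MLE adds nothing here. FDR control is Benjamini–Hochberg, with
one FDR family per `enrichment_table` call (all category × class pairs
tested together). The study named only "FDR < 0.05", not the procedure; BH
is the ecosystem default and the assumption is recorded here.

Note one edge: at α = 1 the strict q < α rule leaves rows with q exactly 1
unflagged; BH yields q = 1 routinely, so "flag everything" saturation only
applies to rows with q < 1.

## Orthology

Internal alignment mode uses Biopython's `PairwiseAligner`
(Smith–Waterman, affine gaps open 11 / extend 1, BLOSUM80 by default;
BLOSUM45 for phylostratigraphy, designed for distant homologs). Query
coverage is aligned-query-span / query-length. Unknown residues score as
X. Because Karlin–Altschul E-value calibration for arbitrary toy matrices
is out of scope, internal mode filters on raw score (default 200) plus
coverage; at the generator's default settings unrelated sequence pairs
score ≤ 142 and true homologs ≥ 394, so the threshold sits in a wide dead
zone. BLAST outfmt-6 ingestion applies the E-value cutoffs instead
(1e−10 for orthology, strict < 1e−20 for phylostratigraphy).

Best hits break ties lexicographically by gene id (deterministic); a
strict mode treats a top-score tie as disqualifying. True reciprocal MBH
is the default; the one-directional variant described in some orthology
protocols ("a is the best focal hit for b") is available behind a flag
(`--one-directional`) because prose definitions of "mutual best hit" vary.

Co-ortholog rule: for ortholog pair (A, P), an unpaired focal gene B
attaches to P iff P is B's best cross-species hit and
score(B, A) > score(A, P). Candidates lacking a within-species score are
skipped with a logged warning rather than failing the run.

## Phylostratigraphy

The ladder is an ordered, strictly nested list of strata, rank 1 (focal
species) to rank R (most inclusive); every subject proteome maps to
exactly one rank. A gene's stratum is the maximum rank among its
filtered hits' subjects; self-hits count only toward rank 1, and genes
absent from the hit set are rank 1 (focal-species-specific) by definition.
Assignment is monotone under database growth: adding hits can only raise
a rank. Whether the original analysis excluded each gene's own record
from its proteome's search is unstated; the self-hit-to-rank-1 convention
makes the two readings equivalent.

## Orthogroup propagation and overlap

Gene classes merge three ways (gonidial, somatic, not-cell-type-regulated
= constitutive + low-confidence) before unanimity propagation. Unexpressed
members carry no vote; groups of only unexpressed members are dropped, as
are mixed groups. The overlap universe is the set of groups that survived
propagation — classified groups, not all groups. Expected overlap is
reported unrounded.

## Cooption analysis

Only one-to-one ortholog pairs enter (co-ortholog cluster membership is
ambiguous); unexpressed and low-confidence focal genes are removed, and
classes merge to {gonidial, somatic, constitutive}. The per-cluster test's
background is the class margin of the analysis table itself; the
reciprocal supercluster test accepts a broader background table (all
orthologs of expressed genes) because the two background definitions
genuinely differ in the design being reproduced. The unclustered group
"uc" participates as a 19th category. Supercluster bins: light c1–c8,
transition c9–c11, dark c12–c18.

## Synthetic data generator

The generator emulates a two-cell-type, two-replicate bulk RNA-seq design
with comparative context; all randomness flows from one seed through named
substreams (`stage_rng`), so adding a stage never perturbs another's
output, and a fixed seed yields byte-identical files.

* **Counts**: NB(mean, α) with variance μ + αμ², α = 0.05 by default
  (typical for bulk RNA-seq replicates; α = 0 gives Poisson). Cell-type
  means are baseline · fold^{±1/2} · library factor, baselines log-uniform
  on [10, 1000] counts, library factors uniform on [0.8, 1.25], transcript
  lengths uniform on [500, 5000] bp. Class proportions default to the
  rough shape of a germ–soma transcriptome (≈ 25% germ-specific, 15%
  soma-specific, 5%/3% biased, 26% constitutive, 25% unsupported); fold
  distributions are log-uniform per class (specific (5, 50], biased
  [2, 5], "low-confidence" genes get folds in (2, 3) with 20× inflated
  dispersion so they genuinely lack statistical support). Class counts are
  allocated by largest remainder, then shuffled.
* **Proteomes**: random uniform sequences of 90–150 residues over the 20
  amino acids; each gene draws a birth stratum uniformly on the ladder
  (default 7 nested strata) and accumulates exactly `round(0.05·L)`
  substitutions per branch step at random interior positions. A 5-residue
  terminal margin is never mutated, so optimal local alignments of
  homologs span the full sequence and scores are exactly self-score minus
  the substitution penalties. Duplications (probability 0.1) copy the
  focal gene with strictly fewer, conservative (I/L/V) substitutions at
  positions disjoint from the speciation branch, which makes the
  co-ortholog score inequality hold by construction whenever the branch
  rate is positive.
* **Cluster labels**: per class, the 19-cluster distribution (uniform
  base, planted (class, supercluster) odds-ratio multipliers) is allocated
  exactly by largest remainder and shuffled within the class, so the
  realized contingency carries the configured odds ratios up to integer
  rounding rather than in noisy expectation. Multiplying a supercluster's
  weight by w for one class makes that supercluster-vs-rest odds ratio
  exactly w against the unweighted base.

What the generator does **not** emulate: GC/length biases, batch effects,
gene–gene correlation, realistic codon or indel evolution, paralog
families with complex topologies, and unequal diurnal-cluster sizes.
Passing recovery tests therefore demonstrates correctness of the inference
rules under the stated statistical model, not robustness to those real-data
complications.

## Problem sizes and determinism

Default analysis-scale runs use 2,000 genes × 4 samples; proteome-level
stages use 30-protein toy proteomes over 7 strata, where all-vs-all
Smith–Waterman is exact and fast. Benchmark conditions for recovery
checks: specific fold fixed at 8, baseline mean 500, dispersion 0.05, two
replicates per type (≈ 92% of truly specific genes recovered into the
correct class; under a global null, directional calls stay under 2·α·n).
The cooption benchmark plants a dark↔somatic odds ratio of 3 over 2,000
ortholog rows. Stage outputs are pure functions of (inputs, config, seed);
re-runs are byte-identical, and each output TSV carries a JSON sidecar
with input hashes, thresholds and the package version.

## Known limitations

* The built-in Wald test is anti-conservative at two replicates compared
  with shrinkage-based tools; with real data, supply the external p-value
  column instead.
* Internal alignment mode has no E-values; its score threshold is
  calibrated for the generator's sequence model, not for real proteomes —
  use BLAST ingestion for real data.
* Group-level (paralog) classes carry no confidence statistics by design;
  they are ratio-only summaries.
* Enrichment tests treat genes as exchangeable units; gene length, family
  structure and expression level are not covariates.
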