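"""Cell-type expression classification from replicate read counts.

The input is a gene x sample matrix of raw read counts from the two cell
types of Volvox carteri (gonidia, the germ cells, and somatic cells), with
at least one replicate per type.  The stages mirror the study design:

1. per-sample size factors from the upper-trimmed column sums divided by 1e7;
2. removal of genes with zero counts everywhere, then of the bottom decile of
   mean normalized expression, leaving the "expressed" transcriptome;
3. RPKM with a 0.1 read-count pseudocount (so ratios are always finite);
4. a per-gene differential-expression test (negative-binomial Wald with
   pooled method-of-moments dispersion and Poisson fallback, or an externally
   supplied p-value column, e.g. from DESeq2);
5. assignment of one of six classes from the fold ratio and FDR:
   cell-type-specific (> 5-fold, FDR < alpha), cell-type-biased (2-5-fold,
   FDR < alpha), constitutive (< 2-fold otherwise) or low-confidence
   (>= 2-fold without statistical support).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust

__all__ = [
    "CountMatrix",
    "CLASSES",
    "trimmed_size_factors",
    "normalize",
    "filter_expressed",
    "rpkm",
    "de_test",
    "classify_gene",
    "ratio_only_class",
    "classify_expression",
]

GONIDIAL = "gonidial"
SOMATIC = "somatic"
CELL_TYPES = (GONIDIAL, SOMATIC)

CLASSES = (
    "gonidial-specific",
    "gonidial-biased",
    "somatic-specific",
    "somatic-biased",
    "constitutive",
    "low-confidence",
)


@dataclass
class CountMatrix:
    """Raw counts with sample metadata.

    ``counts`` is a genes x samples DataFrame of non-negative integers;
    ``cell_type`` maps each sample id to "gonidial" or "somatic";
    ``total_mapped`` gives per-sample mapped-read totals for RPKM and
    defaults to the column sums.
    """

    counts: pd.DataFrame
    cell_type: Mapping[str, str]
    replicate: Mapping[str, int] | None = None
    total_mapped: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        missing = [s for s in self.counts.columns if s not in self.cell_type]
        if missing:
            raise ValueError(f"samples without cell_type metadata: {missing}")
        types = {self.cell_type[s] for s in self.counts.columns}
        bad = types - set(CELL_TYPES)
        if bad:
            raise ValueError(f"unknown cell types: {sorted(bad)}")
        if types != set(CELL_TYPES):
            raise ValueError("need at least one sample per cell type")
        if self.total_mapped is None:
            self.total_mapped = self.counts.sum(axis=0).to_dict()

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def samples_of(self, cell_type: str) -> list[str]:
        return [s for s in self.samples if self.cell_type[s] == cell_type]


def trimmed_size_factors(
    counts: CountMatrix | pd.DataFrame,
    trim_fraction: float = 0.003,
    denominator: float = 1e7,
) -> pd.Series:
    """Per-sample size factors from upper-trimmed column sums.

    In each sample the ceil(trim_fraction * n_genes) largest counts are
    excluded before summing, and the trimmed sum is divided by
    ``denominator`` (10 million by default).  Trimming the extreme upper
    tail keeps a handful of massively expressed genes from dominating the
    library-size estimate.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if not (0.0 <= trim_fraction < 0.5):
        raise ValueError("trim_fraction must be in [0, 0.5)")
    n_trim = int(np.ceil(trim_fraction * df.shape[0]))
    factors = {}
    for sample in df.columns:
        col = df[sample].to_numpy()
        if n_trim:
            order = np.argsort(col, kind="stable")
            kept = col[order[: len(col) - n_trim]]
        else:
            kept = col
        total = float(kept.sum())
        if total <= 0:
            raise ValueError(f"empty sample after trimming: {sample}")
        factors[sample] = total / denominator
    return pd.Series(factors, name="size_factor")


def normalize(
    counts: CountMatrix | pd.DataFrame, factors: pd.Series
) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return df.div(factors[df.columns], axis=1)


def filter_expressed(
    normalized: pd.DataFrame, low_quantile: float = 0.10
) -> list[str]:
    """Expressed-gene filter: drop all-zero genes, then the bottom decile.

    Genes with zero normalized expression in every sample are removed first;
    of the remainder, genes whose mean normalized expression is at or below
    the ``low_quantile`` quantile (linear interpolation) of those means are
    removed.  Returns the surviving gene ids in input order.
    """
    if not (0.0 <= low_quantile < 1.0):
        raise ValueError("low_quantile must be in [0, 1)")
    nonzero = normalized.loc[(normalized != 0).any(axis=1)]
    if nonzero.empty:
        raise ValueError("all genes have zero counts in every sample")
    means = nonzero.mean(axis=1)
    if low_quantile > 0:
        cut = float(means.quantile(low_quantile, interpolation="linear"))
        survivors = means.index[means > cut]
    else:
        survivors = means.index
    if len(survivors) == 0:
        raise ValueError("expression filter removed every gene")
    return list(survivors)


def rpkm(
    counts: CountMatrix,
    lengths: Mapping[str, float],
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, with pseudocount.

    value = (count + pseudocount) * 1e9 / (length_bp * total_mapped_reads).
    The pseudocount (0.1 by default) keeps every value positive so that
    expression ratios never divide by zero.
    """
    missing = [g for g in counts.genes if g not in lengths]
    if missing:
        head = ", ".join(map(str, missing[:5]))
        raise KeyError(
            f"{len(missing)} genes missing transcript lengths (e.g. {head})"
        )
    lens = pd.Series({g: float(lengths[g]) for g in counts.genes})
    if (lens <= 0).any():
        raise ValueError("transcript lengths must be positive")
    totals = pd.Series(
        {s: float(counts.total_mapped[s]) for s in counts.samples}
    )
    out = (counts.counts + pseudocount).div(lens, axis=0)
    return out.div(totals, axis=1) * 1e9


def _group_sums(counts: CountMatrix, gene: str) -> tuple[np.ndarray, np.ndarray]:
    g = counts.counts.loc[gene, counts.samples_of(GONIDIAL)].to_numpy(float)
    s = counts.counts.loc[gene, counts.samples_of(SOMATIC)].to_numpy(float)
    return g, s


def de_test(
    counts: CountMatrix, factors: pd.Series, gene: str
) -> tuple[float, float]:
    """Wald test for differential expression of one gene between cell types.

    The gene's normalized counts are modelled as negative binomial with a
    single pooled dispersion estimated by method of moments on the
    normalized scale; when the moment estimate is non-positive the model
    degenerates to Poisson.  The test statistic is the log fold change of
    the group means divided by its delta-method standard error.

    Returns ``(log2_fold_change, p)``; ``p`` is NaN when the gene has zero
    counts in both groups.
    """
    raw_g, raw_s = _group_sums(counts, gene)
    if raw_g.sum() == 0 and raw_s.sum() == 0:
        return 0.0, float("nan")
    sg = factors[counts.samples_of(GONIDIAL)].to_numpy(float)
    ss = factors[counts.samples_of(SOMATIC)].to_numpy(float)
    xg, xs = raw_g / sg, raw_s / ss
    mg, ms = xg.mean(), xs.mean()
    # pooled MoM dispersion: solve sum (x - m)^2 = sum (m/s + alpha m^2)
    resid = np.concatenate([(xg - mg) ** 2, (xs - ms) ** 2])
    pois = np.concatenate([mg / sg, ms / ss])
    msq = np.concatenate([np.full_like(sg, mg**2), np.full_like(ss, ms**2)])
    denom = msq.sum()
    alpha = (resid.sum() - pois.sum()) / denom if denom > 0 else 0.0
    alpha = max(alpha, 0.0)
    # one group entirely zero: shift means by half a normalized count so the
    # log ratio and its variance stay finite (the call will be extreme anyway)
    eps = 0.0
    if mg == 0 or ms == 0:
        eps = 0.5 / len(xg) if mg == 0 else 0.5 / len(xs)
    mg_, ms_ = mg + eps, ms + eps
    var_g = (1.0 / (mg_ * sg) + alpha).sum() / len(sg) ** 2
    var_s = (1.0 / (ms_ * ss) + alpha).sum() / len(ss) ** 2
    z = (np.log(mg_) - np.log(ms_)) / np.sqrt(var_g + var_s)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(np.log2(mg_ / ms_)), float(min(p, 1.0))


def ratio_only_class(
    mean_g: float,
    mean_s: float,
    ratio_lo: float = 2.0,
    ratio_hi: float = 5.0,
    no_preference: str = "constitutive",
) -> tuple[float, str, str]:
    """Ratio, direction and class ignoring any statistical gate."""
    if mean_g <= 0 or mean_s <= 0:
        raise ValueError("means must be positive")
    ratio = max(mean_g, mean_s) / min(mean_g, mean_s)
    direction = GONIDIAL if mean_g > mean_s else SOMATIC if mean_s > mean_g else "none"
    if ratio < ratio_lo:
        return ratio, direction, no_preference
    label = f"{direction}-specific" if ratio > ratio_hi else f"{direction}-biased"
    return ratio, direction, label


def classify_gene(
    mean_g: float,
    mean_s: float,
    fdr: float,
    ratio_lo: float = 2.0,
    ratio_hi: float = 5.0,
    alpha: float = 0.05,
) -> str:
    """Six-way expression class from per-cell-type means and FDR.

    With FDR < alpha and ratio >= ratio_lo the gene is cell-type-regulated:
    "-specific" above ratio_hi, "-biased" otherwise (both boundary ratios
    fall in the biased band).  Without statistical support the gene is
    "constitutive" below ratio_lo and "low-confidence" at or above it.
    """
    if mean_g <= 0 or mean_s <= 0:
        raise ValueError("means must be positive")
    ratio = max(mean_g, mean_s) / min(mean_g, mean_s)
    significant = fdr == fdr and fdr < alpha  # NaN-safe
    if significant and ratio >= ratio_lo:
        direction = GONIDIAL if mean_g > mean_s else SOMATIC
        return (
            f"{direction}-specific" if ratio > ratio_hi else f"{direction}-biased"
        )
    return "constitutive" if ratio < ratio_lo else "low-confidence"


def classify_expression(
    counts: CountMatrix,
    lengths: Mapping[str, float],
    trim_fraction: float = 0.003,
    denominator: float = 1e7,
    low_quantile: float = 0.10,
    pseudocount: float = 0.1,
    ratio_lo: float = 2.0,
    ratio_hi: float = 5.0,
    alpha: float = 0.05,
    external_pvalues: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Run the full classification and return one record per expressed gene.

    ``external_pvalues`` substitutes per-gene p-values from an external
    differential-expression tool (e.g. DESeq2 output) for the built-in test;
    FDR adjustment is always applied here, across the expressed genes.

    Returns a DataFrame indexed by gene with columns mean_G, mean_S, rpkm_G,
    rpkm_S, ratio, direction, log2fc, p, fdr, class.
    """
    factors = trimmed_size_factors(counts, trim_fraction, denominator)
    normed = normalize(counts, factors)
    expressed = filter_expressed(normed, low_quantile)
    rp = rpkm(counts, lengths, pseudocount)

    gsamps = counts.samples_of(GONIDIAL)
    ssamps = counts.samples_of(SOMATIC)
    # pseudocount before normalization keeps classification means positive
    pn = normalize(counts.counts + pseudocount, factors)
    mean_g = pn.loc[expressed, gsamps].mean(axis=1)
    mean_s = pn.loc[expressed, ssamps].mean(axis=1)

    if external_pvalues is not None:
        pvals = pd.Series(
            {g: float(external_pvalues.get(g, np.nan)) for g in expressed}
        )
        log2fc = np.log2(mean_g / mean_s)
    else:
        res = {g: de_test(counts, factors, g) for g in expressed}
        log2fc = pd.Series({g: r[0] for g, r in res.items()})
        pvals = pd.Series({g: r[1] for g, r in res.items()})

    finite = pvals.dropna()
    qmap = dict(zip(finite.index, bh_adjust(finite.tolist())))
    fdr = pd.Series({g: qmap.get(g, np.nan) for g in expressed})

    records = pd.DataFrame(
        {
            "mean_G": mean_g,
            "mean_S": mean_s,
            "rpkm_G": rp.loc[expressed, gsamps].mean(axis=1),
            "rpkm_S": rp.loc[expressed, ssamps].mean(axis=1),
            "log2fc": log2fc,
            "p": pvals,
            "fdr": fdr,
        }
    )
    records["ratio"] = records[["mean_G", "mean_S"]].max(axis=1) / records[
        ["mean_G", "mean_S"]
    ].min(axis=1)
    records["direction"] = np.where(
        records.mean_G > records.mean_S,
        GONIDIAL,
        np.where(records.mean_S > records.mean_G, SOMATIC, "none"),
    )
    records["class"] = [
        classify_gene(r.mean_G, r.mean_S, r.fdr, ratio_lo, ratio_hi, alpha)
        for r in records.itertuples()
    ]
    records.index.name = "gene"
    return records[
        [
            "mean_G",
            "mean_S",
            "rpkm_G",
            "rpkm_S",
            "ratio",
            "direction",
            "log2fc",
            "p",
            "fdr",
            "class",
        ]
    ]
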