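"""Temporal-to-spatial regulon cooption test.

The hypothesis: diurnal (light/dark-cycle) co-expression regulons of the
unicellular relative were coopted into cell-type programs of the
multicellular descendant.  Focal-species genes are mapped to the relative's
diurnal clusters (c1..c18 plus an unclustered group "uc") through one-to-one
orthologs only — co-orthologs are excluded because their cluster membership
is ambiguous — and genes that are unexpressed or low-confidence are dropped.
The remaining (cluster, class) contingency is Fisher-tested per cluster
against the within-analysis class background; a reciprocal test merges
clusters into four superclusters (light c1-c8, transition c9-c11, dark
c12-c18, unclustered) and tests class x supercluster against the broader
background of all orthologs of expressed genes.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping

import pandas as pd

from .enrichment import EnrichmentRow, enrichment_table
from .orthology import OrthologyMap

__all__ = [
    "CLUSTERS",
    "SUPERCLUSTERS",
    "supercluster_of",
    "build_cooption_table",
    "cluster_class_enrichment",
    "reciprocal_supercluster_enrichment",
    "exclude_and_retest",
    "class_fraction_table",
]

CLUSTERS = tuple(f"c{i}" for i in range(1, 19)) + ("uc",)
SUPERCLUSTERS = ("light", "transition", "dark", "unclustered")

MERGED_CLASSES = {
    "gonidial-specific": "gonidial",
    "gonidial-biased": "gonidial",
    "somatic-specific": "somatic",
    "somatic-biased": "somatic",
    "constitutive": "constitutive",
}


def supercluster_of(cluster: str) -> str:
    """Merge a diurnal cluster label into its phase supercluster."""
    if cluster == "uc":
        return "unclustered"
    m = re.fullmatch(r"c(\d+)", cluster)
    if not m:
        raise ValueError(f"unknown diurnal cluster label {cluster!r}")
    i = int(m.group(1))
    if 1 <= i <= 8:
        return "light"
    if 9 <= i <= 11:
        return "transition"
    if 12 <= i <= 18:
        return "dark"
    raise ValueError(f"unknown diurnal cluster label {cluster!r}")


def build_cooption_table(
    orthologs: OrthologyMap | Mapping[str, str],
    diurnal: Mapping[str, str],
    classes: Mapping[str, str],
    exclude_classes: Iterable[str] = ("low-confidence",),
) -> pd.DataFrame:
    """One row per usable ortholog pair: (focal gene, cluster, class).

    Only one-to-one ortholog pairs enter (co-ortholog attachments are
    dropped); focal genes lacking an expression class (unexpressed) or in an
    excluded class are removed; surviving classes are merged to
    {gonidial, somatic, constitutive}.
    """
    pairs = (
        orthologs.orthologs if isinstance(orthologs, OrthologyMap) else dict(orthologs)
    )
    excl = set(exclude_classes)
    rows = []
    for focal, partner in pairs.items():
        if partner not in diurnal:
            continue
        cls = classes.get(focal)
        if cls is None or cls in excl:
            continue
        merged = MERGED_CLASSES.get(cls, cls)
        cluster = diurnal[partner]
        rows.append(
            (focal, partner, cluster, supercluster_of(cluster), merged)
        )
    return pd.DataFrame(
        rows, columns=["gene", "partner", "cluster", "supercluster", "class"]
    )


def _table_enrichment(
    table: pd.DataFrame, category_col: str, alpha: float
) -> list[EnrichmentRow]:
    if table.empty:
        raise ValueError("empty cooption table")
    universe = set(table["gene"])
    cats = {
        name: set(sub["gene"]) for name, sub in table.groupby(category_col)
    }
    clss = {name: set(sub["gene"]) for name, sub in table.groupby("class")}
    return enrichment_table(cats, clss, universe, alpha)


def cluster_class_enrichment(
    table: pd.DataFrame, alpha: float = 0.05
) -> list[EnrichmentRow]:
    """Per-cluster Fisher tests of class composition.

    Background is the class distribution over all genes in the table (the
    genes surviving every exclusion), per the within-analysis convention.
    """
    return _table_enrichment(table, "cluster", alpha)


def reciprocal_supercluster_enrichment(
    table: pd.DataFrame,
    alpha: float = 0.05,
    background: pd.DataFrame | None = None,
) -> list[EnrichmentRow]:
    """Class x supercluster tests against the broader ortholog background.

    ``background`` is the table of all orthologs of expressed focal genes
    (before the low-confidence exclusion); it defaults to ``table`` when the
    two coincide.  Supercluster membership comes from the background; class
    sets come from ``table``.
    """
    if background is None:
        return _table_enrichment(table, "supercluster", alpha)
    if table.empty or background.empty:
        raise ValueError("empty cooption table")
    universe = set(background["gene"])
    cats = {
        name: set(sub["gene"])
        for name, sub in background.groupby("supercluster")
    }
    clss = {
        name: set(sub["gene"]) & universe
        for name, sub in table.groupby("class")
    }
    return enrichment_table(cats, clss, universe, alpha)


def exclude_and_retest(
    table: pd.DataFrame, gene_set: Iterable[str], alpha: float = 0.05
) -> tuple[list[EnrichmentRow], list[EnrichmentRow]]:
    """Drop a focal gene set (e.g. flagellar genes) and redo both analyses."""
    excl = set(gene_set)
    reduced = table.loc[~table["gene"].isin(excl)]
    if reduced.empty:
        raise ValueError("exclusion removed every gene from the analysis")
    return (
        cluster_class_enrichment(reduced, alpha),
        reciprocal_supercluster_enrichment(reduced, alpha),
    )


def class_fraction_table(table: pd.DataFrame) -> pd.DataFrame:
    """Fraction of each expression class within each cluster (stacked-bar layout)."""
    counts = table.pivot_table(
        index="cluster", columns="class", values="gene", aggfunc="count", fill_value=0
    )
    order = [c for c in CLUSTERS if c in counts.index]
    counts = counts.loc[order]
    return counts.div(counts.sum(axis=1), axis=0)
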