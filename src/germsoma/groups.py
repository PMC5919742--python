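"""Orthogroup class propagation and overlap enrichment.

Expression classes are lifted from genes to orthology groups by unanimity:
after merging the six per-gene classes into three (gonidial, somatic,
not-cell-type-regulated), a group whose focal-species members all agree
gets that class; mixed groups, and groups containing only unexpressed or
filtered-out genes, are dropped.  Classified groups then form the
background universe for overlap enrichment between arbitrary group sets
(e.g. stem-cell orthogroup collections from other lineages).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .enrichment import ContingencyTable, EnrichmentRow, bh_adjust, fisher_two_sided

__all__ = ["DEFAULT_MERGE", "propagate_classes", "overlap_enrichment", "venn_counts"]

DEFAULT_MERGE = {
    "gonidial-specific": "gonidial",
    "gonidial-biased": "gonidial",
    "somatic-specific": "somatic",
    "somatic-biased": "somatic",
    "constitutive": "not-cell-type-regulated",
    "low-confidence": "not-cell-type-regulated",
}


def propagate_classes(
    groups: Mapping[str, Iterable[str]],
    gene_classes: Mapping[str, str],
    merge_map: Mapping[str, str] | None = None,
    unexpressed: Iterable[str] = (),
) -> dict[str, str]:
    """Unanimity propagation of (merged) gene classes to orthogroups.

    ``groups`` maps group id -> focal-species member gene ids.  Members in
    ``unexpressed`` carry no class and never veto unanimity, but groups made
    only of them are dropped.  A gene neither classified nor declared
    unexpressed is an error.  Returns group id -> merged class for the
    groups that survive.
    """
    merge = dict(DEFAULT_MERGE if merge_map is None else merge_map)
    unexpr = set(unexpressed)
    out: dict[str, str] = {}
    for gid, members in groups.items():
        merged: set[str] = set()
        for g in members:
            if g in gene_classes:
                cls = gene_classes[g]
                merged.add(merge.get(cls, cls))
            elif g not in unexpr:
                raise KeyError(
                    f"gene {g} in group {gid} has no class and is not flagged unexpressed"
                )
        if len(merged) == 1:
            out[gid] = merged.pop()
        # len 0: only unexpressed members -> dropped; len > 1: mixed -> dropped
    return out


def overlap_enrichment(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    alpha: float = 0.05,
    label: str = "A|B",
) -> EnrichmentRow:
    """Fisher test of the overlap of two group sets against a universe.

    observed = |A ∩ B|; expected = |A||B|/|U|; enrichment and deenrichment
    flagged from the odds ratio at ``alpha`` (single test: q = p).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    a_set, b_set = set(set_a), set(set_b)
    if not a_set <= uni or not b_set <= uni:
        raise ValueError("sets must be subsets of the universe")
    inter = len(a_set & b_set)
    t = ContingencyTable(
        inter,
        len(a_set) - inter,
        len(b_set) - inter,
        len(uni) - len(a_set | b_set),
    )
    orr, p = fisher_two_sided(t)
    q = bh_adjust([p])[0]
    flag = "ns"
    if q < alpha and orr > 1:
        flag = "enriched"
    elif q < alpha and orr < 1:
        flag = "deenriched"
    return EnrichmentRow(
        label=label,
        table=t,
        observed=inter,
        expected=len(a_set) * len(b_set) / len(uni),
        odds_ratio=orr,
        p=p,
        q=q,
        flag=flag,
    )


def venn_counts(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> dict[str, float]:
    """Two-set Venn summary with the hypergeometric expected overlap."""
    uni = set(universe)
    a_set, b_set = set(set_a) & uni, set(set_b) & uni
    return {
        "A_only": len(a_set - b_set),
        "intersection": len(a_set & b_set),
        "B_only": len(b_set - a_set),
        "expected": len(a_set) * len(b_set) / len(uni) if uni else float("nan"),
    }
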