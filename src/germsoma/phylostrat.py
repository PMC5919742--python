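"""Phylostratigraphic gene-age assignment and stratum enrichment.

A phylostratum ladder is an ordered, strictly nested series of taxonomic
levels from the focal species (rank 1, youngest) out to the most inclusive
level (rank R, e.g. cellular organisms).  Each focal gene is assigned the
most distant stratum in which it has a homolog surviving the similarity
cutoffs; genes with no non-self hits are focal-species-specific (rank 1).
Each expression class is then tested for enrichment of every stratum with
the expressed transcriptome as background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .enrichment import EnrichmentRow, enrichment_table
from .orthology import HomologyHit

__all__ = ["PhylostratumLadder", "assign_stratum", "assign_strata", "stratum_enrichment"]


@dataclass(frozen=True)
class PhylostratumLadder:
    """Ordered stratum names (rank 1 = focal species) and the proteome->rank map."""

    strata: tuple[str, ...]
    proteome_rank: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("ladder needs at least one stratum")
        ranks = set(self.proteome_rank.values())
        bad = ranks - set(range(1, len(self.strata) + 1))
        if bad:
            raise ValueError(f"proteome ranks outside ladder: {sorted(bad)}")
        if 1 not in ranks:
            raise ValueError("rank 1 must contain the focal proteome")

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    def name_of(self, rank: int) -> str:
        return self.strata[rank - 1]


def assign_stratum(
    gene: str,
    hits: Iterable[HomologyHit],
    ladder: PhylostratumLadder,
    subject_proteome: Mapping[str, str],
) -> tuple[int, str]:
    """Stratum of one gene: the max rank among its surviving hits' subjects.

    ``hits`` must already be filtered at the phylostratigraphy cutoffs and
    restricted to this gene's queries; ``subject_proteome`` maps subject ids
    to proteome labels.  Self-hits count only toward rank 1, so a gene with
    no hits outside the focal proteome is focal-species-specific.
    """
    rank = 1
    for h in hits:
        if h.query != gene or h.subject == gene:
            continue
        prot = subject_proteome.get(h.subject)
        if prot is None or prot not in ladder.proteome_rank:
            raise KeyError(
                f"subject {h.subject} maps to unknown proteome {prot!r}"
            )
        rank = max(rank, ladder.proteome_rank[prot])
    return rank, ladder.name_of(rank)


def assign_strata(
    genes: Iterable[str],
    hits: Iterable[HomologyHit],
    ladder: PhylostratumLadder,
    subject_proteome: Mapping[str, str],
) -> dict[str, tuple[int, str]]:
    """Stratum assignment for every gene (all genes get >= rank 1)."""
    by_gene: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_gene.setdefault(h.query, []).append(h)
    return {
        g: assign_stratum(g, by_gene.get(g, []), ladder, subject_proteome)
        for g in genes
    }


def stratum_enrichment(
    assignments: Mapping[str, tuple[int, str]] | Mapping[str, str],
    classes: Mapping[str, str],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """Fisher enrichment of every (stratum, expression class) pair.

    Background is the expressed transcriptome (``universe``); q-values are
    BH-adjusted across all pairs.
    """
    uni = set(universe)
    missing = [g for g in uni if g not in assignments]
    if missing:
        raise KeyError(f"{len(missing)} universe genes lack stratum assignments")
    strat_sets: dict[str, set[str]] = {}
    for g in uni:
        val = assignments[g]
        name = val[1] if isinstance(val, tuple) else val
        strat_sets.setdefault(name, set()).add(g)
    class_sets: dict[str, set[str]] = {}
    for g in uni:
        if g in classes:
            class_sets.setdefault(classes[g], set()).add(g)
    return enrichment_table(strat_sets, class_sets, uni, alpha)
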