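"""Protein homology scoring and mutual-best-hit ortholog inference.

Orthologs between the focal species (e.g. V. carteri) and a relative
(e.g. C. reinhardtii) are called by the classic reciprocal best-hit rule on
Smith-Waterman alignment scores.  Additional focal-species genes are
attached to an ortholog pair as co-orthologs (in-paralogs) when their best
cross-species hit is the same partner and they are closer to their
within-species ortholog than that ortholog is to the partner — the
signature of a duplication postdating the speciation.

Two scoring modes are supported: a built-in affine-gap local aligner for
toy-scale proteomes (BLOSUM matrices via Biopython), and ingestion of
precomputed BLAST tabular (outfmt 6) hits where E-values are available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceRecord",
    "HomologyHit",
    "OrthologyMap",
    "local_align",
    "align_proteomes",
    "filter_hits",
    "mutual_best_hits",
    "assign_coorthologs",
    "read_blast6",
]

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
_MATRICES = ("BLOSUM80", "BLOSUM62", "BLOSUM45")


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str
    taxon: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for {self.id}")


@dataclass(frozen=True)
class HomologyHit:
    """One scored query-subject pair."""

    query: str
    subject: str
    raw_score: float
    evalue: float | None = None
    query_coverage: float = 0.0


@dataclass
class OrthologyMap:
    """MBH ortholog pairs plus co-ortholog attachments with their evidence.

    ``orthologs`` maps focal gene -> partner gene, one-to-one.
    ``coorthologs`` maps extra focal gene -> (partner gene, within-species
    score, partner-ortholog cross score).
    """

    orthologs: dict[str, str] = field(default_factory=dict)
    coorthologs: dict[str, tuple[str, float, float]] = field(default_factory=dict)

    def partner_of(self, focal_gene: str) -> str | None:
        if focal_gene in self.orthologs:
            return self.orthologs[focal_gene]
        if focal_gene in self.coorthologs:
            return self.coorthologs[focal_gene][0]
        return None


def _get_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    if matrix not in _MATRICES:
        raise ValueError(f"unknown substitution matrix {matrix!r}; choose from {_MATRICES}")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.mode = "local"
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def _sanitize(residues: str) -> str:
    # unknown residues score as X (the matrix minimum-information symbol)
    return "".join(r if r in AMINO_ALPHABET else "X" for r in residues.upper())


def local_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[float, float]:
    """Optimal Smith-Waterman score and query coverage of ``a`` against ``b``.

    Coverage is the aligned span on the query divided by query length (the
    BLAST convention).  Sequences with no positive-scoring residue pair
    align empty: score 0, coverage 0.
    """
    qa = _sanitize(a.residues if isinstance(a, SequenceRecord) else a)
    qb = _sanitize(b.residues if isinstance(b, SequenceRecord) else b)
    aligner = _get_aligner(matrix, gap_open, gap_extend)
    score = float(aligner.score(qa, qb))
    if score <= 0:
        return 0.0, 0.0
    aln = aligner.align(qa, qb)[0]
    qspans = aln.aligned[0]
    span = int(qspans[-1][1] - qspans[0][0])
    return score, span / len(qa)


def align_proteomes(
    queries: Iterable[SequenceRecord],
    subjects: Iterable[SequenceRecord],
    matrix: str = "BLOSUM80",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    allow_self: bool = False,
) -> list[HomologyHit]:
    """All-vs-all local alignment of two sequence collections (toy scale)."""
    subjects = list(subjects)
    hits = []
    for q in queries:
        for s in subjects:
            if not allow_self and q.id == s.id:
                continue
            score, cov = local_align(q, s, matrix, gap_open, gap_extend)
            if score > 0:
                hits.append(
                    HomologyHit(q.id, s.id, raw_score=score, query_coverage=cov)
                )
    return hits


def filter_hits(
    hits: Iterable[HomologyHit],
    max_evalue: float | None = 1e-10,
    min_coverage: float = 0.5,
    min_score: float | None = None,
) -> list[HomologyHit]:
    """Apply the homology-assignment cutoffs.

    Hits carrying an E-value must satisfy ``evalue <= max_evalue``; hits
    without one (internal alignment mode) must satisfy
    ``raw_score >= min_score`` when a score threshold is given.  Coverage is
    strict: ``query_coverage > min_coverage``.
    """
    kept = []
    for h in hits:
        if not (h.query_coverage > min_coverage):
            continue
        if h.evalue is not None:
            if max_evalue is not None and not (h.evalue <= max_evalue):
                continue
        elif min_score is not None and not (h.raw_score >= min_score):
            continue
        kept.append(h)
    return kept


def _score_table(hits: Iterable[HomologyHit]) -> dict[tuple[str, str], float]:
    table: dict[tuple[str, str], float] = {}
    for h in hits:
        key = (h.query, h.subject)
        if key not in table or h.raw_score > table[key]:
            table[key] = h.raw_score
    return table


def _best_partner(
    scores: Mapping[tuple[str, str], float], fixed: str, axis: int, strict: bool
) -> str | None:
    """Best partner of ``fixed`` along the other axis; lexicographic tie-break
    unless ``strict``, where a top tie disqualifies."""
    cands = [
        (key[1 - axis], s) for key, s in scores.items() if key[axis] == fixed
    ]
    if not cands:
        return None
    best = max(s for _, s in cands)
    top = sorted(g for g, s in cands if s == best)
    if strict and len(top) > 1:
        return None
    return top[0]


def mutual_best_hits(
    scores: Mapping[tuple[str, str], float] | Iterable[HomologyHit],
    strict_ties: bool = False,
    reciprocal: bool = True,
) -> list[tuple[str, str, float]]:
    """Ortholog pairs by the mutual-best-hit criterion.

    ``scores`` maps (focal gene, partner gene) -> raw score.  A pair (a, b)
    is emitted iff a is the best focal-species scorer against b AND b is the
    best partner-species scorer against a.  Ties are broken
    lexicographically by gene id; with ``strict_ties`` a tie at the top
    disqualifies uniqueness.  ``reciprocal=False`` relaxes to the
    one-directional variant (a need only be b's best focal hit).
    """
    if not isinstance(scores, Mapping):
        scores = _score_table(scores)
    focal_genes = sorted({q for q, _ in scores})
    pairs = []
    for a in focal_genes:
        b = _best_partner(scores, a, 0, strict_ties)
        if b is None:
            continue
        back = _best_partner(scores, b, 1, strict_ties)
        if back != a:
            continue
        pairs.append((a, b, scores[(a, b)]))
    if not reciprocal:
        # one-directional: a is b's best focal hit, regardless of a's own best
        partner_genes = sorted({s for _, s in scores})
        pairs = []
        claimed: set[str] = set()
        for b in partner_genes:
            a = _best_partner(scores, b, 1, strict_ties)
            if a is None or a in claimed:
                continue
            claimed.add(a)
            pairs.append((a, b, scores[(a, b)]))
        pairs.sort()
    return pairs


def assign_coorthologs(
    cross_scores: Mapping[tuple[str, str], float] | Iterable[HomologyHit],
    within_scores: Mapping[tuple[str, str], float] | Iterable[HomologyHit],
    orthologs: Sequence[tuple[str, str, float]] | Sequence[tuple[str, str]],
    strict_ties: bool = False,
) -> dict[str, tuple[str, float, float]]:
    """Attach unpaired focal genes to ortholog pairs as co-orthologs.

    For an ortholog pair (A, P): an unpaired focal gene B is a co-ortholog
    of P iff P is B's best cross-species hit AND score(B, A) within the
    focal species exceeds score(A, P).  Candidates lacking a within-species
    score are skipped with a warning.
    """
    if not isinstance(cross_scores, Mapping):
        cross_scores = _score_table(cross_scores)
    if not isinstance(within_scores, Mapping):
        within_scores = _score_table(within_scores)
    sym_within: dict[tuple[str, str], float] = {}
    for (x, y), s in within_scores.items():
        for key in ((x, y), (y, x)):
            if key not in sym_within or s > sym_within[key]:
                sym_within[key] = s
    anchor_of = {b: a for a, b, *_ in orthologs}
    paired = set(anchor_of.values())
    cross_of_anchor = {
        a: cross_scores.get((a, b), math.nan) for a, b, *_ in orthologs
    }
    out: dict[str, tuple[str, float, float]] = {}
    for gene_b in sorted({q for q, _ in cross_scores}):
        if gene_b in paired:
            continue
        best = _best_partner(cross_scores, gene_b, 0, strict_ties)
        if best is None or best not in anchor_of:
            continue
        gene_a = anchor_of[best]
        within = sym_within.get((gene_b, gene_a))
        if within is None:
            logger.warning(
                "no within-species score for co-ortholog candidate %s-%s; skipped",
                gene_b,
                gene_a,
            )
            continue
        cross = cross_of_anchor[gene_a]
        if within > cross:
            out[gene_b] = (best, within, cross)
    return out


def read_blast6(
    path, query_lengths: Mapping[str, float]
) -> list[HomologyHit]:
    """Read BLAST tabular (outfmt 6) hits, computing query coverage.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Coverage = (qend - qstart + 1) / query
    length, from the supplied length table.
    """
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    hits = []
    for r in df.itertuples():
        if r.qseqid not in query_lengths:
            raise KeyError(f"no length for query {r.qseqid}")
        cov = (abs(r.qend - r.qstart) + 1) / float(query_lengths[r.qseqid])
        hits.append(
            HomologyHit(
                str(r.qseqid),
                str(r.sseqid),
                raw_score=float(r.bitscore),
                evalue=float(r.evalue),
                query_coverage=cov,
            )
        )
    return hits
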