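"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of a two-cell-type bulk
RNA-seq study of a multicellular alga plus its comparative context:

* a gene x sample count matrix, negative-binomially dispersed around
  cell-type means separated by a per-gene fold change (variance
  mu + alpha*mu^2; alpha = 0 degenerates to Poisson);
* toy proteomes along a nested phylostratum ladder, with genes "born" at a
  planted stratum and focal-species duplications planting co-orthologs;
* orthogroup memberships over the simulated genes;
* diurnal cluster labels for the relative species with configurable
  (class, supercluster) odds ratios.

Default proportions of the six expression classes follow the rough shape of
a germ-soma transcriptome: a quarter each of germ-cell-specific,
constitutive and statistically unsupported genes, with smaller biased and
somatic fractions.  All randomness flows from a single seed through named
substreams, so adding a stage never perturbs the output of another.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import CLASSES, CountMatrix
from .orthology import SequenceRecord
from .phylostrat import PhylostratumLadder
from .cooption import CLUSTERS, supercluster_of

__all__ = [
    "SimConfig",
    "stage_rng",
    "simulate_counts",
    "simulate_proteomes",
    "simulate_cluster_labels",
    "simulate_orthologs",
    "simulate_orthogroups",
    "ladder_from_config",
    "write_bundle",
]

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

DEFAULT_LADDER = (
    "focal-species",
    "family",
    "order",
    "phylum",
    "kingdom",
    "eukaryotes",
    "cellular-organisms",
)

# gonidial-specific, gonidial-biased, somatic-specific, somatic-biased,
# constitutive, low-confidence
DEFAULT_PROPORTIONS = (0.255, 0.052, 0.154, 0.028, 0.257, 0.254)


@dataclass
class SimConfig:
    """All knobs of the generator; defaults define the study conditions."""

    seed: int = 1
    # count matrix
    n_genes: int = 2000
    replicates: int = 2
    class_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    specific_fold: tuple[float, float] = (5.0, 50.0)
    biased_fold: tuple[float, float] = (2.0, 5.0)
    lowconf_fold: tuple[float, float] = (2.0, 3.0)
    dispersion: float = 0.05
    lowconf_dispersion_mult: float = 20.0
    baseline_mean: tuple[float, float] = (10.0, 1000.0)
    library_factor: tuple[float, float] = (0.8, 1.25)
    gene_length: tuple[int, int] = (500, 5000)
    # proteomes / ladder
    n_proteins: int = 30
    protein_length: tuple[int, int] = (90, 150)
    ladder: tuple[str, ...] = DEFAULT_LADDER
    branch_rate: float = 0.05
    duplication_prob: float = 0.1
    duplication_rate: float = 0.02
    # orthologs & diurnal clusters
    ortholog_fraction: float = 0.8
    cluster_associations: Mapping[tuple[str, str], float] = field(
        default_factory=dict
    )
    # orthogroups
    group_size_geom_p: float = 0.6

    def __post_init__(self) -> None:
        if len(self.class_proportions) != len(CLASSES):
            raise ValueError(
                f"class_proportions needs {len(CLASSES)} entries (order {CLASSES})"
            )
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if any(p < 0 for p in self.class_proportions):
            raise ValueError("class_proportions must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for cls, sc in self.cluster_associations:
            if sc not in {supercluster_of(c) for c in CLUSTERS}:
                raise ValueError(f"unknown supercluster {sc!r}")
        if any(v < 0 for v in self.cluster_associations.values()):
            raise ValueError("planted odds ratios must be >= 0")

    def rng(self, stage: str) -> np.random.Generator:
        return stage_rng(self.seed, stage)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named substream: independent generator per (seed, stage name)."""
    return np.random.default_rng([int(seed), zlib.crc32(stage.encode())])


def _allocate_classes(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder integer allocation of n genes to the classes."""
    raw = np.asarray(proportions, float) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    out: list[int] = []
    for idx, k in enumerate(base):
        out.extend([idx] * k)
    return out


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """NB(mean, dispersion alpha) with variance mu + alpha*mu^2."""
    out = np.empty(mean.shape, dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        n = 1.0 / alpha[~pois]
        p = n / (n + mean[~pois])
        out[~pois] = rng.negative_binomial(n, p)
    return out


def simulate_counts(
    cfg: SimConfig,
) -> tuple[CountMatrix, dict[str, int], pd.DataFrame]:
    """Simulate the count matrix; returns (counts, lengths, truth).

    Truth columns: class (one of the six), fold (true cell-type ratio >= 1),
    direction, baseline.  Cell-type means are baseline * fold^{+-1/2} times
    the sample's library factor.
    """
    rng = cfg.rng("counts")
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    class_idx = np.array(_allocate_classes(cfg.n_genes, cfg.class_proportions))
    rng.shuffle(class_idx)
    cls = np.array(CLASSES)[class_idx]

    def log_uniform(lo: float, hi: float, size: int) -> np.ndarray:
        if hi <= lo:
            return np.full(size, float(lo))
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size))

    fold = np.ones(cfg.n_genes)
    for name, rng_pair in (
        ("gonidial-specific", cfg.specific_fold),
        ("somatic-specific", cfg.specific_fold),
        ("gonidial-biased", cfg.biased_fold),
        ("somatic-biased", cfg.biased_fold),
        ("low-confidence", cfg.lowconf_fold),
    ):
        mask = cls == name
        fold[mask] = log_uniform(rng_pair[0], rng_pair[1], mask.sum())

    direction = np.where(
        np.char.startswith(cls, "gonidial"),
        "gonidial",
        np.where(np.char.startswith(cls, "somatic"), "somatic", "none"),
    )
    lowconf = cls == "low-confidence"
    direction[lowconf] = rng.choice(["gonidial", "somatic"], lowconf.sum())

    baseline = log_uniform(*cfg.baseline_mean, cfg.n_genes)
    alpha = np.full(cfg.n_genes, cfg.dispersion)
    alpha[lowconf] *= cfg.lowconf_dispersion_mult

    samples = [
        f"{ct}_{r + 1}"
        for ct in ("gonidial", "somatic")
        for r in range(cfg.replicates)
    ]
    cell_type = {s: s.split("_")[0] for s in samples}
    replicate = {s: int(s.split("_")[1]) for s in samples}
    lib = rng.uniform(*cfg.library_factor, len(samples))

    sqrtf = np.sqrt(fold)
    mean_g = np.where(direction == "somatic", baseline / sqrtf, baseline * sqrtf)
    mean_g = np.where(direction == "none", baseline, mean_g)
    mean_s = np.where(direction == "somatic", baseline * sqrtf, baseline / sqrtf)
    mean_s = np.where(direction == "none", baseline, mean_s)

    cols = {}
    for j, s in enumerate(samples):
        mu = (mean_g if cell_type[s] == "gonidial" else mean_s) * lib[j]
        cols[s] = _nb_draw(rng, mu, alpha)
    counts = pd.DataFrame(cols, index=genes)
    lengths = {
        g: int(L)
        for g, L in zip(
            genes, rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1, cfg.n_genes)
        )
    }
    truth = pd.DataFrame(
        {"class": cls, "fold": fold, "direction": direction, "baseline": baseline},
        index=pd.Index(genes, name="gene"),
    )
    cm = CountMatrix(counts=counts, cell_type=cell_type, replicate=replicate)
    return cm, lengths, truth


# mutations keep out of the terminal EDGE residues so optimal local
# alignments of homologs always span the full sequence and alignment scores
# equal self-score minus the exact substitution penalties
_EDGE = 5
_CONSERVATIVE = set("ILV")  # minimum-penalty residues under BLOSUM80


def _mutation_count(rate: float, length: int) -> int:
    if rate <= 0:
        return 0
    return max(1, round(rate * length))


def _best_substitutions() -> dict[str, str]:
    """Most conservative non-self replacement per residue (BLOSUM80)."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM80")
    out = {}
    for r in AA20:
        best = max((s for s in AA20 if s != r), key=lambda s: mat[r][s])
        out[str(r)] = str(best)
    return out


def simulate_proteomes(
    cfg: SimConfig,
) -> tuple[dict[str, list[SequenceRecord]], pd.DataFrame]:
    """Toy proteomes along the ladder, with planted birth strata and duplications.

    Returns ``(proteomes, truth)``: one proteome per stratum (rank 1 is the
    focal species), and a truth table with each focal gene's birth rank plus
    duplicate relations.  A gene born at rank k has homologs in every
    stratum proteome of rank 2..k, accumulating ``round(branch_rate * L)``
    substitutions per branch step at random interior positions.

    With probability ``duplication_prob`` a focal gene with a rank-2 homolog
    gains a recent duplicate — the planted co-ortholog.  Duplicate
    substitutions are conservative (I/L/V to their closest exchange
    partner), disjoint from the speciation-branch positions, and strictly
    fewer than the speciation-branch count, so under BLOSUM80 scoring the
    co-ortholog inequality score(dup, parent) > score(parent, relative)
    holds by construction whenever ``branch_rate > 0``.
    """
    rng = cfg.rng("proteomes")
    best_sub = _best_substitutions()
    R = len(cfg.ladder)
    proteomes: dict[str, list[SequenceRecord]] = {name: [] for name in cfg.ladder}
    rows = []
    for i in range(cfg.n_proteins):
        gid = f"p{i:04d}"
        L = int(rng.integers(cfg.protein_length[0], cfg.protein_length[1] + 1))
        seq = rng.choice(AA20, L)
        interior = np.arange(_EDGE, L - _EDGE)
        birth = int(rng.integers(1, R + 1))
        proteomes[cfg.ladder[0]].append(
            SequenceRecord(gid, "".join(seq), taxon=cfg.ladder[0])
        )
        current = seq.copy()
        branch_positions: np.ndarray | None = None  # rank-2 branch mutations
        for rank in range(2, birth + 1):
            m = _mutation_count(cfg.branch_rate, L)
            pos = rng.choice(interior, size=min(m, len(interior)), replace=False)
            for p in pos:
                current[p] = rng.choice(AA20[AA20 != current[p]])
            if rank == 2:
                branch_positions = pos
            hid = f"{gid}|{cfg.ladder[rank - 1]}"
            proteomes[cfg.ladder[rank - 1]].append(
                SequenceRecord(hid, "".join(current), taxon=cfg.ladder[rank - 1])
            )
        dup_id = ""
        if birth >= 2 and rng.random() < cfg.duplication_prob:
            dup_id = f"{gid}_dup"
            m_rel = _mutation_count(cfg.branch_rate, L)
            m_dup = min(_mutation_count(cfg.duplication_rate, L), max(m_rel - 1, 1))
            used = set(branch_positions.tolist()) if branch_positions is not None else set()
            cands = [
                p for p in interior
                if p not in used and str(seq[p]) in _CONSERVATIVE
            ]
            if len(cands) < m_dup:  # pragma: no cover - vanishing for random seqs
                cands += [p for p in interior if p not in used and p not in cands]
            pos = rng.choice(np.array(cands), size=m_dup, replace=False)
            dup = seq.copy()
            for p in pos:
                dup[p] = best_sub[str(seq[p])]
            proteomes[cfg.ladder[0]].append(
                SequenceRecord(dup_id, "".join(dup), taxon=cfg.ladder[0])
            )
        rows.append(
            {
                "gene": gid,
                "birth_rank": birth,
                "birth_stratum": cfg.ladder[birth - 1],
                "duplicate": dup_id,
                "relative_homolog": f"{gid}|{cfg.ladder[1]}" if birth >= 2 else "",
            }
        )
    truth = pd.DataFrame(rows).set_index("gene")
    return proteomes, truth


def ladder_from_config(cfg: SimConfig) -> PhylostratumLadder:
    return PhylostratumLadder(
        strata=tuple(cfg.ladder),
        proteome_rank={name: i + 1 for i, name in enumerate(cfg.ladder)},
    )


def simulate_cluster_labels(
    cfg: SimConfig,
    gene_classes: Mapping[str, str],
    stage: str = "clusters",
) -> dict[str, str]:
    """Draw diurnal cluster labels with the configured planted associations.

    ``gene_classes`` maps the gene ids to be labeled to their (merged)
    expression class.  For a planted odds ratio w of (class, supercluster),
    the clusters of that supercluster are up-weighted by w for genes of that
    class, which makes the supercluster-vs-class odds ratio w against the
    unweighted base distribution.  Labels are planted by exact allocation:
    each class's genes receive the largest-remainder integer allocation of
    its cluster distribution, shuffled within the class, so the realized
    contingency carries the configured odds ratios up to rounding rather
    than in noisy expectation.
    """
    if not CLUSTERS:
        raise ValueError("no clusters configured")
    rng = cfg.rng(stage)
    supers = np.array([supercluster_of(c) for c in CLUSTERS])
    base = np.ones(len(CLUSTERS))
    by_class: dict[str, list[str]] = {}
    for gene in sorted(gene_classes):
        by_class.setdefault(gene_classes[gene], []).append(gene)
    out: dict[str, str] = {}
    for cls in sorted(by_class):
        genes = by_class[cls]
        w = base.copy()
        for (acls, asc), orr in cfg.cluster_associations.items():
            if cls == acls:
                w[supers == asc] *= orr
        w = w / w.sum()
        idx = _allocate_classes(len(genes), w)
        rng.shuffle(idx)
        for gene, k in zip(genes, idx):
            out[gene] = CLUSTERS[k]
    return out


def simulate_orthologs(
    cfg: SimConfig, genes: Sequence[str]
) -> dict[str, str]:
    """Full-scale one-to-one ortholog truth: focal gene -> relative gene id."""
    rng = cfg.rng("orthologs")
    keep = rng.random(len(genes)) < cfg.ortholog_fraction
    return {g: f"Cre_{g}" for g, k in zip(genes, keep) if k}


def simulate_orthogroups(
    cfg: SimConfig, genes: Sequence[str]
) -> dict[str, list[str]]:
    """Partition genes into orthogroups with geometric size distribution."""
    rng = cfg.rng("orthogroups")
    order = list(genes)
    rng.shuffle(order)
    groups: dict[str, list[str]] = {}
    i = gidx = 0
    while i < len(order):
        size = int(rng.geometric(cfg.group_size_geom_p))
        groups[f"OG{gidx:05d}"] = order[i : i + size]
        i += size
        gidx += 1
    return groups


def _write_fasta(records: Sequence[SequenceRecord], path: Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.residues}\n")


def write_bundle(cfg: SimConfig, outdir: str | Path) -> Path:
    """Write the full synthetic input bundle for the pipeline.

    Emits counts.tsv, samples.tsv, lengths.tsv, proteomes/<stratum>.fasta,
    ladder.yaml, groups.tsv, set_a.txt/set_b.txt, orthologs.tsv,
    clusters.tsv, paralog_groups.tsv and truth.json.  Deterministic per
    seed: the same config yields byte-identical files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cm, lengths, truth = simulate_counts(cfg)
    cm.counts.rename_axis("gene").to_csv(out / "counts.tsv", sep="\t")
    pd.DataFrame(
        {
            "sample": cm.samples,
            "cell_type": [cm.cell_type[s] for s in cm.samples],
            "replicate": [cm.replicate[s] for s in cm.samples],
        }
    ).to_csv(out / "samples.tsv", sep="\t", index=False)
    pd.Series(lengths, name="length_bp").rename_axis("gene").to_csv(
        out / "lengths.tsv", sep="\t"
    )

    proteomes, prot_truth = simulate_proteomes(cfg)
    pdir = out / "proteomes"
    pdir.mkdir(exist_ok=True)
    for stratum, records in proteomes.items():
        _write_fasta(records, pdir / f"{stratum}.fasta")
    with open(out / "ladder.yaml", "w") as fh:
        fh.write("strata:\n")
        for name in cfg.ladder:
            fh.write(f"  - name: {name}\n    fasta: proteomes/{name}.fasta\n")

    genes = cm.genes
    groups = simulate_orthogroups(cfg, genes)
    pd.DataFrame(
        [(gid, g, "focal") for gid, members in groups.items() for g in members],
        columns=["group_id", "gene_id", "species"],
    ).to_csv(out / "groups.tsv", sep="\t", index=False)

    rng_sets = cfg.rng("group_sets")
    gids = sorted(groups)
    set_a = sorted(rng_sets.choice(gids, size=max(2, len(gids) // 10), replace=False))
    set_b = sorted(rng_sets.choice(gids, size=max(2, len(gids) // 10), replace=False))
    (out / "set_a.txt").write_text("\n".join(set_a) + "\n")
    (out / "set_b.txt").write_text("\n".join(set_b) + "\n")

    ortho = simulate_orthologs(cfg, genes)
    pd.DataFrame(
        [(g, p, 500.0) for g, p in ortho.items()],
        columns=["gene_a", "gene_b", "score"],
    ).to_csv(out / "orthologs.tsv", sep="\t", index=False)

    merged = {
        "gonidial-specific": "gonidial",
        "gonidial-biased": "gonidial",
        "somatic-specific": "somatic",
        "somatic-biased": "somatic",
        "constitutive": "constitutive",
        "low-confidence": "low-confidence",
    }
    partner_class = {
        ortho[g]: merged[truth.loc[g, "class"]] for g in ortho
    }
    labels = simulate_cluster_labels(cfg, partner_class)
    pd.DataFrame(
        sorted(labels.items()), columns=["gene_id", "cluster"]
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)

    rng_par = cfg.rng("paralog_groups")
    par_rows = []
    pool = list(genes)
    rng_par.shuffle(pool)
    for k in range(20):
        size = int(rng_par.integers(1, 5))
        name = f"PG{k:03d}"
        for g in pool[:size]:
            par_rows.append((name, g))
        pool = pool[size:]
    pd.DataFrame(par_rows, columns=["group", "gene_id"]).to_csv(
        out / "paralog_groups.tsv", sep="\t", index=False
    )

    truth_payload = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
            if k != "cluster_associations"
        },
        "cluster_associations": {
            f"{cls}|{sc}": orr
            for (cls, sc), orr in cfg.cluster_associations.items()
        },
        "gene_truth": truth.reset_index().to_dict(orient="list"),
        "proteome_truth": prot_truth.reset_index().to_dict(orient="list"),
        "orthologs": ortho,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_payload, fh, indent=1, sort_keys=True)
    return out
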