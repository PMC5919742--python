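"""End-to-end orchestration of the analysis stages with provenance capture.

``run_all`` executes the stages in dependency order on a directory of
inputs (typically a synthetic bundle from :mod:`germsoma.simulate`):
expression classification, sequence orthology on the ladder proteomes,
phylostratigraphy, orthogroup propagation and overlap, the diurnal-regulon
cooption test, and paralog-group classification.  Every stage output TSV
gets a JSON sidecar recording input hashes, thresholds and the package
version, so re-runs are audited and idempotent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .enrichment import rows_to_frame
from .expression import classify_expression
from .orthology import (
    align_proteomes,
    assign_coorthologs,
    filter_hits,
    mutual_best_hits,
)
from .phylostrat import assign_strata, stratum_enrichment
from .groups import propagate_classes, overlap_enrichment, venn_counts
from .cooption import (
    build_cooption_table,
    class_fraction_table,
    cluster_class_enrichment,
    reciprocal_supercluster_enrichment,
)
from .paralogs import classify_groups
from . import io as gio

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run."""

    indir: str
    outdir: str
    # expression thresholds
    trim_fraction: float = 0.003
    denominator: float = 1e7
    low_quantile: float = 0.10
    pseudocount: float = 0.1
    ratio_lo: float = 2.0
    ratio_hi: float = 5.0
    alpha: float = 0.05
    # homology cutoffs: (orthology, phylostratigraphy)
    ortho_max_evalue: float = 1e-10
    ortho_min_coverage: float = 0.5
    ortho_min_score: float = 200.0
    phylo_max_evalue: float = 1e-20
    phylo_min_coverage: float = 0.5
    phylo_min_score: float = 200.0
    ortho_matrix: str = "BLOSUM80"
    phylo_matrix: str = "BLOSUM45"
    strict_ties: bool = False
    reciprocal: bool = True
    external_pvalues: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.trim_fraction < 0.5):
            raise ValueError("trim_fraction out of range")
        if not (0 <= self.low_quantile < 1):
            raise ValueError("low_quantile out of range")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha out of range")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sidecar(out_path: Path, inputs: list[Path], params: dict) -> None:
    meta = {
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
        "params": params,
        "version": __version__,
    }
    out_path.with_suffix(out_path.suffix + ".json").write_text(
        json.dumps(meta, indent=1, sort_keys=True) + "\n"
    )


def run_all(cfg: RunConfig) -> Path:
    """Run every stage; returns the output directory.

    Raises with the stage name on the first failing stage.
    """
    ind, outd = Path(cfg.indir), Path(cfg.outdir)
    outd.mkdir(parents=True, exist_ok=True)
    # thresholds only: paths are machine-specific and inputs are hashed anyway
    params = {
        k: v for k, v in asdict(cfg).items()
        if k not in ("indir", "outdir", "external_pvalues")
    }

    # --- stage: expression classification -------------------------------
    stage = "classify"
    try:
        counts = gio.read_counts(ind / "counts.tsv", ind / "samples.tsv")
        lengths = gio.read_lengths(ind / "lengths.tsv")
        external = (
            gio.read_external_pvalues(cfg.external_pvalues)
            if cfg.external_pvalues
            else None
        )
        records = classify_expression(
            counts,
            lengths,
            trim_fraction=cfg.trim_fraction,
            denominator=cfg.denominator,
            low_quantile=cfg.low_quantile,
            pseudocount=cfg.pseudocount,
            ratio_lo=cfg.ratio_lo,
            ratio_hi=cfg.ratio_hi,
            alpha=cfg.alpha,
            external_pvalues=external,
        )
        gio.write_tsv(records, outd / "expression.tsv")
        _sidecar(
            outd / "expression.tsv",
            [ind / "counts.tsv", ind / "samples.tsv", ind / "lengths.tsv"],
            params,
        )
        logger.info(
            "classify: %d genes in, %d expressed", counts.counts.shape[0], len(records)
        )
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    gene_classes = records["class"].to_dict()
    expressed = set(records.index)

    # --- stage: orthology on the ladder proteomes ------------------------
    stage = "orthology"
    try:
        ladder, fastas = gio.read_ladder_yaml(ind / "ladder.yaml")
        focal = gio.read_fasta(fastas[ladder.strata[0]], taxon=ladder.strata[0])
        relative = gio.read_fasta(fastas[ladder.strata[1]], taxon=ladder.strata[1])
        cross = align_proteomes(focal, relative, matrix=cfg.ortho_matrix)
        within = align_proteomes(focal, focal, matrix=cfg.ortho_matrix)
        cross_f = filter_hits(
            cross, None, cfg.ortho_min_coverage, min_score=cfg.ortho_min_score
        )
        pairs = mutual_best_hits(
            cross_f, strict_ties=cfg.strict_ties, reciprocal=cfg.reciprocal
        )
        coorth = assign_coorthologs(cross_f, within, pairs, cfg.strict_ties)
        pd.DataFrame(pairs, columns=["gene_a", "gene_b", "score"]).to_csv(
            outd / "orthologs_seq.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [(g, *v) for g, v in sorted(coorth.items())],
            columns=["gene", "attached_to", "within_score", "cross_score"],
        ).to_csv(outd / "coorthologs_seq.tsv", sep="\t", index=False)
        _sidecar(outd / "orthologs_seq.tsv", list(filter(None, fastas.values())), params)
        logger.info("orthology: %d pairs, %d coorthologs", len(pairs), len(coorth))
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    # --- stage: phylostratigraphy ----------------------------------------
    stage = "phylostrat"
    try:
        subject_proteome: dict[str, str] = {}
        hits = []
        for stratum in ladder.strata[1:]:
            recs = gio.read_fasta(fastas[stratum], taxon=stratum)
            for r in recs:
                subject_proteome[r.id] = stratum
            hits.extend(
                filter_hits(
                    align_proteomes(focal, recs, matrix=cfg.phylo_matrix),
                    None,
                    cfg.phylo_min_coverage,
                    min_score=cfg.phylo_min_score,
                )
            )
        focal_ids = [r.id for r in focal]
        strata = assign_strata(focal_ids, hits, ladder, subject_proteome)
        strat_df = pd.DataFrame(
            [(g, r, n) for g, (r, n) in strata.items()],
            columns=["gene", "stratum_rank", "stratum_name"],
        )
        strat_df.to_csv(outd / "phylostrata.tsv", sep="\t", index=False)
        strat_universe = set(focal_ids) & expressed
        if strat_universe:
            rows = stratum_enrichment(
                strata,
                {g: gene_classes[g] for g in strat_universe},
                strat_universe,
                cfg.alpha,
            )
            gio.write_tsv(rows_to_frame(rows), outd / "phylostrat_enrichment.tsv", index=False)
        _sidecar(outd / "phylostrata.tsv", list(filter(None, fastas.values())), params)
        logger.info("phylostrat: %d genes assigned", len(strata))
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    # --- stage: orthogroup propagation and overlap ------------------------
    stage = "groups"
    try:
        groups = gio.read_group_table(ind / "groups.tsv")
        unexpressed = {
            g for members in groups.values() for g in members if g not in expressed
        }
        group_classes = propagate_classes(groups, gene_classes, unexpressed=unexpressed)
        pd.Series(group_classes, name="class").rename_axis("group_id").to_csv(
            outd / "group_classes.tsv", sep="\t"
        )
        universe = set(group_classes)
        set_a = gio.read_id_set(ind / "set_a.txt") & universe
        set_b = gio.read_id_set(ind / "set_b.txt") & universe
        if set_a and set_b:
            row = overlap_enrichment(set_a, set_b, universe, cfg.alpha, label="setA|setB")
            gio.write_tsv(rows_to_frame([row]), outd / "group_overlap.tsv", index=False)
            venn = venn_counts(set_a, set_b, universe)
            (outd / "group_overlap_venn.json").write_text(
                json.dumps(venn, indent=1) + "\n"
            )
        _sidecar(outd / "group_classes.tsv", [ind / "groups.tsv"], params)
        logger.info(
            "groups: %d/%d groups classified", len(group_classes), len(groups)
        )
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    # --- stage: cooption ---------------------------------------------------
    stage = "cooption"
    try:
        ortho = gio.read_ortholog_table(ind / "orthologs.tsv")
        diurnal = gio.read_cluster_labels(ind / "clusters.tsv")
        table = build_cooption_table(ortho, diurnal, gene_classes)
        table.to_csv(outd / "cooption_table.tsv", sep="\t", index=False)
        if not table.empty:
            fwd = cluster_class_enrichment(table, cfg.alpha)
            gio.write_tsv(rows_to_frame(fwd), outd / "cooption_cluster.tsv", index=False)
            rec = reciprocal_supercluster_enrichment(table, cfg.alpha)
            gio.write_tsv(
                rows_to_frame(rec), outd / "cooption_supercluster.tsv", index=False
            )
            gio.write_tsv(class_fraction_table(table), outd / "cooption_fractions.tsv")
        _sidecar(
            outd / "cooption_table.tsv",
            [ind / "orthologs.tsv", ind / "clusters.tsv"],
            params,
        )
        logger.info("cooption: %d ortholog rows", len(table))
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    # --- stage: paralog groups ---------------------------------------------
    stage = "paralogs"
    try:
        par_path = ind / "paralog_groups.tsv"
        if par_path.exists():
            pgroups_df = pd.read_csv(par_path, sep="\t")
            pgroups = {
                str(name): [str(g) for g in sub["gene_id"]]
                for name, sub in pgroups_df.groupby("group")
            }
            pgroups = {
                name: [g for g in members if g in expressed]
                for name, members in pgroups.items()
            }
            pgroups = {n: m for n, m in pgroups.items() if m}
            out = classify_groups(
                pgroups,
                records["rpkm_G"].to_dict(),
                records["rpkm_S"].to_dict(),
                cfg.ratio_lo,
                cfg.ratio_hi,
            )
            gio.write_tsv(out, outd / "paralog_classes.tsv")
            _sidecar(outd / "paralog_classes.tsv", [par_path], params)
            logger.info("paralogs: %d groups classified", len(out))
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    # --- summary -----------------------------------------------------------
    summary = {
        "n_genes": int(counts.counts.shape[0]),
        "n_expressed": int(len(records)),
        "class_counts": records["class"].value_counts().to_dict(),
        "n_ortholog_pairs_seq": len(pairs),
        "n_coorthologs_seq": len(coorth),
        "n_groups_classified": len(group_classes),
        "n_cooption_rows": int(len(table)),
    }
    (outd / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return outd
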