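"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is TSV with explicit headers, FASTA for sequences, YAML for the
phylostratum ladder, and plain id-per-line files for gene/group sets.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO

from .expression import CountMatrix
from .orthology import SequenceRecord
from .phylostrat import PhylostratumLadder

__all__ = [
    "read_counts",
    "read_lengths",
    "read_fasta",
    "read_ladder_yaml",
    "read_group_table",
    "read_id_set",
    "read_cluster_labels",
    "read_ortholog_table",
    "read_external_pvalues",
    "write_tsv",
]


def read_counts(counts_path, samples_path) -> CountMatrix:
    """Counts TSV (first column gene id) + sample metadata TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(samples_path, sep="\t")
    for col in ("sample", "cell_type"):
        if col not in meta.columns:
            raise ValueError(f"samples file lacks required column {col!r}")
    cell_type = dict(zip(meta["sample"].astype(str), meta["cell_type"]))
    replicate = (
        dict(zip(meta["sample"].astype(str), meta["replicate"]))
        if "replicate" in meta.columns
        else None
    )
    counts.columns = counts.columns.astype(str)
    return CountMatrix(
        counts=counts.astype(int), cell_type=cell_type, replicate=replicate
    )


def read_lengths(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(float).to_dict()


def read_fasta(path, taxon: str = "") -> list[SequenceRecord]:
    return [
        SequenceRecord(id=rec.id, residues=str(rec.seq), taxon=taxon)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_ladder_yaml(path) -> tuple[PhylostratumLadder, dict[str, Path]]:
    """Ladder config: ordered strata with per-stratum proteome FASTA paths.

    Returns the ladder plus stratum -> FASTA path (relative paths resolved
    against the config file's directory).
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    entries = cfg["strata"]
    names = tuple(e["name"] for e in entries)
    ladder = PhylostratumLadder(
        strata=names, proteome_rank={n: i + 1 for i, n in enumerate(names)}
    )
    fastas = {
        e["name"]: (path.parent / e["fasta"]) if "fasta" in e else None
        for e in entries
    }
    return ladder, fastas


def read_group_table(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.group_id), []).append(str(r.gene_id))
    return out


def read_id_set(path) -> set[str]:
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }


def read_cluster_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_ortholog_table(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_external_pvalues(path) -> dict[str, float]:
    """Per-gene p-values from an external DE tool (gene id, p columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    col = "p" if "p" in df.columns else df.columns[0]
    return df[col].astype(float).to_dict()


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
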