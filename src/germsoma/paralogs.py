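"""Aggregate cell-type classification of functionally similar paralog groups.

When several paralogs encode isoforms of the same enzyme, their summed
per-cell-type RPKM is a better proxy for the activity available to each
cell type than any single member.  Group sums are classified with the same
fold-ratio thresholds as single genes but without any statistical gate —
no replicate-level model exists for a sum of genes — so the "no cell-type
preference" label replaces both constitutive and low-confidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .expression import ratio_only_class

__all__ = ["ParalogGroup", "group_class", "classify_groups"]

NO_PREFERENCE = "no-preference"


@dataclass(frozen=True)
class ParalogGroup:
    name: str
    members: tuple[str, ...]
    sum_g: float
    sum_s: float
    ratio: float
    direction: str
    label: str  # ratio-only class; no confidence statistics


def group_class(
    name: str,
    members: Sequence[str],
    rpkm_g: Mapping[str, float],
    rpkm_s: Mapping[str, float],
    ratio_lo: float = 2.0,
    ratio_hi: float = 5.0,
) -> ParalogGroup:
    """Classify one paralog group from summed per-cell-type RPKM means."""
    if not members:
        raise ValueError(f"paralog group {name} has no members")
    missing = [g for g in members if g not in rpkm_g or g not in rpkm_s]
    if missing:
        raise KeyError(f"group {name}: members missing from RPKM table: {missing}")
    sum_g = float(sum(rpkm_g[g] for g in members))
    sum_s = float(sum(rpkm_s[g] for g in members))
    ratio, direction, label = ratio_only_class(
        sum_g, sum_s, ratio_lo, ratio_hi, no_preference=NO_PREFERENCE
    )
    return ParalogGroup(
        name=name,
        members=tuple(members),
        sum_g=sum_g,
        sum_s=sum_s,
        ratio=ratio,
        direction=direction,
        label=label,
    )


def classify_groups(
    groups: Mapping[str, Sequence[str]],
    rpkm_g: Mapping[str, float],
    rpkm_s: Mapping[str, float],
    ratio_lo: float = 2.0,
    ratio_hi: float = 5.0,
) -> pd.DataFrame:
    """Classify every group; returns a TSV-ready DataFrame."""
    recs = [
        group_class(name, list(members), rpkm_g, rpkm_s, ratio_lo, ratio_hi)
        for name, members in groups.items()
    ]
    return pd.DataFrame(
        {
            "group": [r.name for r in recs],
            "members": [",".join(r.members) for r in recs],
            "sum_G": [r.sum_g for r in recs],
            "sum_S": [r.sum_s for r in recs],
            "ratio": [r.ratio for r in recs],
            "direction": [r.direction for r in recs],
            "class": [r.label for r in recs],
        }
    ).set_index("group")
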