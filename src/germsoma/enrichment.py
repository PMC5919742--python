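"""Exact 2x2 enrichment machinery shared by every downstream analysis stage.

Every comparative question in the pipeline — is an expression class
over-represented in a phylostratum, do two orthogroup sets overlap more than
chance, is a diurnal cluster associated with a cell type — reduces to a 2x2
contingency table tested with a two-sided Fisher's exact test, followed by
Benjamini-Hochberg control of the false discovery rate across the family of
tests run together.  Enrichment is an odds ratio > 1 with q < alpha;
deenrichment an odds ratio < 1 with q < alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "EnrichmentRow",
    "fisher_two_sided",
    "bh_adjust",
    "enrichment_table",
    "rows_to_frame",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of a 2x2 contingency table.

    ``a`` counts items both in the category and in the class of interest;
    ``b`` in the category only, ``c`` in the class only, ``d`` in neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.total == 0:
            raise ValueError("degenerate margins: all-zero table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Hypergeometric mean of ``a`` under fixed margins."""
        return (self.a + self.b) * (self.a + self.c) / self.total

    @property
    def odds_ratio(self) -> float:
        """Unconditional cross-product ratio a*d / b*c.

        +inf when b*c == 0 while a*d > 0; NaN when both products vanish.
        """
        ad = self.a * self.d
        bc = self.b * self.c
        if bc == 0:
            return math.inf if ad > 0 else math.nan
        return ad / bc


@dataclass(frozen=True)
class EnrichmentRow:
    """One labeled Fisher-test result: the common currency of all stages."""

    label: str
    table: ContingencyTable
    observed: int
    expected: float
    odds_ratio: float
    p: float
    q: float
    flag: str  # "enriched" | "deenriched" | "ns"


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_two_sided(table: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p)``.  The p-value is the probability-mass
    definition: the sum, over all tables sharing the observed margins, of
    hypergeometric probabilities not exceeding that of the observed table,
    with relative slack 1 + 1e-7 for floating-point comparison.  The odds
    ratio is the cross-product ratio, not the conditional MLE — downstream
    rules use it only for direction.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row, col = a + b, a + c
    lo, hi = max(0, row + col - n), min(row, col)
    ks = np.arange(lo, hi + 1)
    pmf = np.exp(
        _log_comb(row, ks) + _log_comb(n - row, col - ks) - _log_comb(n, col)
    )
    p = float(pmf[pmf <= pmf[a - lo] * (1 + 1e-7)].sum())
    return table.odds_ratio, min(p, 1.0)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, order preserved."""
    ps = list(pvalues)
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {p}")
    if not ps:
        return []
    _, q, _, _ = multipletests(ps, method="fdr_bh")
    return [float(x) for x in q]


def _flag(odds_ratio: float, q: float, alpha: float) -> str:
    if q < alpha and odds_ratio > 1:
        return "enriched"
    if q < alpha and odds_ratio < 1:
        return "deenriched"
    return "ns"


def enrichment_table(
    categories: Mapping[str, Iterable],
    classes: Mapping[str, Iterable],
    universe: Iterable,
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """Fisher-test every (category, class) pair against a shared background.

    Each pair yields the 2x2 table
    ``[[|cat & cls|, |cat - cls|], [|cls - cat|, |rest|]]`` over ``universe``;
    q-values are BH-adjusted across all pairs of this call (one FDR family
    per invocation), and flags set at ``alpha``.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    cats = {k: set(v) & uni for k, v in categories.items()}
    clss = {k: set(v) & uni for k, v in classes.items()}
    for name, members in {**categories, **classes}.items():
        extra = set(members) - uni
        if extra:
            raise ValueError(
                f"set {name!r} has {len(extra)} members outside the universe"
            )
    labels, tables, pvals = [], [], []
    n = len(uni)
    for cname, cset in cats.items():
        for kname, kset in clss.items():
            a = len(cset & kset)
            b = len(cset) - a
            c = len(kset) - a
            t = ContingencyTable(a, b, c, n - a - b - c)
            labels.append(f"{cname}|{kname}")
            tables.append(t)
            pvals.append(fisher_two_sided(t)[1])
    qvals = bh_adjust(pvals)
    rows = []
    for label, t, p, q in zip(labels, tables, pvals, qvals):
        orr = t.odds_ratio
        rows.append(
            EnrichmentRow(
                label=label,
                table=t,
                observed=t.a,
                expected=t.expected,
                odds_ratio=orr,
                p=p,
                q=q,
                flag=_flag(orr, q, alpha),
            )
        )
    return rows


def rows_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Tabulate enrichment rows for TSV output (inf/nan as literals)."""
    return pd.DataFrame(
        {
            "label": [r.label for r in rows],
            "a": [r.table.a for r in rows],
            "b": [r.table.b for r in rows],
            "c": [r.table.c for r in rows],
            "d": [r.table.d for r in rows],
            "observed": [r.observed for r in rows],
            "expected": [r.expected for r in rows],
            "odds_ratio": [r.odds_ratio for r in rows],
            "p": [r.p for r in rows],
            "q": [r.q for r in rows],
            "flag": [r.flag for r in rows],
        }
    )
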