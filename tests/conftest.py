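"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from itertools import combinations

from hypothesis import settings

from germsoma.expression import CountMatrix

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


# ---------------------------------------------------------------------------
# independent oracles (kept free of the package's computational paths)


def enumerate_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by explicit enumeration of all same-margin tables.

    Uses exact rational hypergeometric probabilities via math.comb, so it is
    an exact-arithmetic oracle independent of the package's log-gamma route.
    """
    from math import comb
    from fractions import Fraction

    n, row, col = a + b + c + d, a + b, a + c
    denom = comb(n, col)
    lo, hi = max(0, row + col - n), min(row, col)
    probs = {
        k: Fraction(comb(row, k) * comb(n - row, col - k), denom)
        for k in range(lo, hi + 1)
    }
    obs = probs[a]
    return float(sum(p for p in probs.values() if p <= obs))


def brute_force_local_align(
    a: str, b: str, matrix, gap_open: float, gap_extend: float
) -> float:
    """Optimal local alignment score by exhaustive enumeration.

    Enumerates every pair of equal-length increasing index subsets of the
    two sequences (every trimmed alignment); internal unaligned runs are
    charged affine gap costs open + (L-1)*extend per run.  The empty
    alignment scores 0.
    """
    la, lb = len(a), len(b)
    best = 0.0

    def gap_cost(g: int) -> float:
        return 0.0 if g == 0 else gap_open + (g - 1) * gap_extend

    for k in range(1, min(la, lb) + 1):
        for ia in combinations(range(la), k):
            for ib in combinations(range(lb), k):
                s = 0.0
                for t in range(k):
                    s += matrix[a[ia[t]]][b[ib[t]]]
                    if t:
                        s -= gap_cost(ia[t] - ia[t - 1] - 1)
                        s -= gap_cost(ib[t] - ib[t - 1] - 1)
                best = max(best, s)
    return best


def brute_force_mbh(scores: dict[tuple[str, str], float]) -> set[tuple[str, str]]:
    """Reciprocal-argmax oracle with lexicographic tie-break."""
    a_genes = {q for q, _ in scores}
    b_genes = {s for _, s in scores}
    pairs = set()
    for a in a_genes:
        cands = [(s, key[1]) for key, s in scores.items() if key[0] == a]
        best = max(x[0] for x in cands)
        b = min(g for s, g in cands if s == best)
        back = [(s, key[0]) for key, s in scores.items() if key[1] == b]
        bbest = max(x[0] for x in back)
        if min(g for s, g in back if s == bbest) == a:
            pairs.add((a, b))
    return pairs


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def small_counts() -> CountMatrix:
    """Four genes, two replicates per cell type, hand-set counts."""
    counts = pd.DataFrame(
        {
            "gonidial_1": [100, 0, 40, 5],
            "gonidial_2": [110, 0, 36, 4],
            "somatic_1": [10, 0, 38, 50],
            "somatic_2": [12, 0, 42, 45],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    return CountMatrix(
        counts=counts,
        cell_type={
            "gonidial_1": "gonidial",
            "gonidial_2": "gonidial",
            "somatic_1": "somatic",
            "somatic_2": "somatic",
        },
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
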