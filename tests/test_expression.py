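"""Normalization, expression filtering, RPKM, DE testing and classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from germsoma.expression import (
    CountMatrix,
    classify_expression,
    classify_gene,
    de_test,
    filter_expressed,
    normalize,
    rpkm,
    trimmed_size_factors,
)
from germsoma.simulate import SimConfig, simulate_counts


def _matrix(cols: dict, genes=None) -> CountMatrix:
    df = pd.DataFrame(cols, index=genes or [f"g{i}" for i in range(len(next(iter(cols.values()))))])
    ct = {s: ("gonidial" if s.startswith("g") else "somatic") for s in df.columns}
    return CountMatrix(counts=df, cell_type=ct)


class TestSizeFactors:
    def test_post_trim_sum_divided_by_denominator(self):
        # 1000 genes of 10000 with the 3 largest bumped: at 0.3% trim exactly
        # those 3 are excluded, leaving 997 * 10000 = 9.97e6 -> factor 0.997
        col = [10000] * 1000
        col[0] = col[1] = col[2] = 10010
        cm = _matrix({"g1": col, "s1": col})
        f = trimmed_size_factors(cm, trim_fraction=0.003)
        assert f["g1"] == pytest.approx(0.997)
        assert f["g1"] == pytest.approx(sum(sorted(col)[:-3]) / 1e7)

    def test_relative_factors(self):
        cm = _matrix({"g1": [20_000_000], "s1": [5_000_000]}, genes=["g0"])
        f = trimmed_size_factors(cm, trim_fraction=0.0)
        assert f["g1"] == pytest.approx(2.0)
        assert f["s1"] == pytest.approx(0.5)

    def test_matches_sort_oracle(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 5000, size=(1000, 4)),
            columns=["g1", "g2", "s1", "s2"],
        )
        cm = CountMatrix(
            counts=counts,
            cell_type={"g1": "gonidial", "g2": "gonidial", "s1": "somatic", "s2": "somatic"},
        )
        f = trimmed_size_factors(cm, trim_fraction=0.003)
        for s in counts.columns:
            oracle = np.sort(counts[s].to_numpy())[:-3].sum() / 1e7
            assert f[s] == pytest.approx(oracle)

    def test_empty_sample_rejected(self):
        cm = _matrix({"g1": [0, 0], "s1": [1, 1]})
        with pytest.raises(ValueError, match="empty sample"):
            trimmed_size_factors(cm, trim_fraction=0.0)


class TestNormalize:
    def test_division_and_roundtrip(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 100, size=(50, 2)), columns=["g1", "s1"]
        )
        factors = pd.Series({"g1": 2.0, "s1": 0.5})
        normed = normalize(counts, factors)
        assert normed.iloc[0, 0] == counts.iloc[0, 0] / 2.0
        back = normed.mul(factors, axis=1)
        assert np.allclose(back.to_numpy(), counts.to_numpy())

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            normalize(pd.DataFrame({"a": [1]}), pd.Series({"a": 0.0}))


class TestFilterExpressed:
    def test_all_zero_gene_removed_and_decile_cut(self):
        # means 1..100 on a linear grid: bottom decile (<= 10.9) removed
        df = pd.DataFrame({"s1": range(1, 101), "s2": range(1, 101)}, dtype=float)
        df.index = [f"g{i}" for i in range(100)]
        survivors = filter_expressed(df, low_quantile=0.10)
        assert len(survivors) == 90
        assert "g9" not in survivors and "g10" in survivors

    def test_zero_quantile_removes_only_all_zero_rows(self):
        df = pd.DataFrame({"s1": [0, 1, 5], "s2": [0, 0, 5]}, index=["z", "a", "b"], dtype=float)
        assert filter_expressed(df, low_quantile=0.0) == ["a", "b"]

    def test_all_zero_matrix_rejected(self):
        df = pd.DataFrame({"s1": [0, 0]}, dtype=float)
        with pytest.raises(ValueError):
            filter_expressed(df)


class TestRpkm:
    @pytest.mark.parametrize(
        "count, length, total, expected",
        [
            (1, 1000, 1e6, 1.1),
            (0, 1000, 1e6, 0.1),
            (9, 2000, 3e6, 9.1e9 / (2000 * 3e6)),
        ],
    )
    def test_formula(self, count, length, total, expected):
        cm = CountMatrix(
            counts=pd.DataFrame({"g1": [count], "s1": [count]}, index=["gene"]),
            cell_type={"g1": "gonidial", "s1": "somatic"},
            total_mapped={"g1": total, "s1": total},
        )
        vals = rpkm(cm, {"gene": length})
        assert vals.loc["gene", "g1"] == pytest.approx(expected)

    def test_missing_length_reported_with_gene_id(self, small_counts):
        with pytest.raises(KeyError, match="gB"):
            rpkm(small_counts, {"gA": 100, "gC": 100, "gD": 100})


class TestDeTest:
    def _factors(self, cm):
        return pd.Series({s: 1.0 for s in cm.samples})

    def test_symmetric_counts_give_p_one(self):
        cm = _matrix({"g1": [100], "g2": [100], "s1": [100], "s2": [100]}, genes=["x"])
        lfc, p = de_test(cm, self._factors(cm), "x")
        assert lfc == 0.0
        assert p == pytest.approx(1.0)

    def test_all_zero_gene_gives_missing_p(self):
        cm = _matrix({"g1": [0], "g2": [0], "s1": [0], "s2": [0]}, genes=["x"])
        _, p = de_test(cm, self._factors(cm), "x")
        assert math.isnan(p)

    def test_poisson_fallback_matches_wald_oracle(self):
        """Equal replicates force MoM dispersion <= 0 -> Poisson Wald."""
        from scipy.stats import norm

        cm = _matrix({"g1": [100], "g2": [100], "s1": [200], "s2": [200]}, genes=["x"])
        lfc, p = de_test(cm, self._factors(cm), "x")
        z = (np.log(100) - np.log(200)) / np.sqrt(1 / 200 + 1 / 400)
        assert p == pytest.approx(2 * norm.sf(abs(z)), rel=1e-9)
        assert lfc == pytest.approx(np.log2(0.5))

    def test_detects_large_fold_change(self):
        cm = _matrix({"g1": [800], "g2": [820], "s1": [100], "s2": [95]}, genes=["x"])
        lfc, p = de_test(cm, self._factors(cm), "x")
        assert lfc > 2.9
        assert p < 1e-6


class TestClassifyGene:
    @pytest.mark.parametrize(
        "mean_g, mean_s, fdr, expected",
        [
            (0.007, 6.594, 0.001, "somatic-specific"),   # germ-soma regulator archetype
            (9.0, 72.0, 0.001, "somatic-specific"),      # 8-fold autophagy-gene archetype
            (5.0, 5.0, 0.001, "constitutive"),
            (1.0, 3.0, 0.20, "low-confidence"),
            (3.0, 1.0, 0.001, "gonidial-biased"),        # ratio 3, significant
            (2.0, 1.0, 0.001, "gonidial-biased"),        # boundary: exactly 2-fold
            (5.0, 1.0, 0.001, "gonidial-biased"),        # boundary: exactly 5-fold
            (5.01, 1.0, 0.001, "gonidial-specific"),
            (1.0, 1.9, 0.20, "constitutive"),
            (1.0, 5.0, float("nan"), "low-confidence"),  # missing FDR, big ratio
        ],
    )
    def test_decision_table(self, mean_g, mean_s, fdr, expected):
        assert classify_gene(mean_g, mean_s, fdr) == expected

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            classify_gene(0.0, 1.0, 0.01)

    @given(
        mg=st.floats(0.01, 1e4),
        ms=st.floats(0.01, 1e4),
        fdr=st.floats(0, 1),
    )
    @settings(max_examples=300, deadline=None)
    def test_cell_type_label_symmetry(self, mg, ms, fdr):
        """Swapping the two cell types exchanges the directional classes."""
        swap = {
            "gonidial-specific": "somatic-specific",
            "gonidial-biased": "somatic-biased",
            "somatic-specific": "gonidial-specific",
            "somatic-biased": "gonidial-biased",
            "constitutive": "constitutive",
            "low-confidence": "low-confidence",
        }
        assert classify_gene(ms, mg, fdr) == swap[classify_gene(mg, ms, fdr)]


class TestClassifyExpression:
    def test_classes_partition_expressed_genes(self):
        cfg = SimConfig(seed=7, n_genes=300)
        cm, lengths, _ = simulate_counts(cfg)
        rec = classify_expression(cm, lengths)
        assert rec["class"].notna().all()
        assert rec["class"].value_counts().sum() == len(rec)
        assert set(rec.index).issubset(set(cm.genes))

    def test_rpkm_and_normalized_ratios_correlate(self):
        """RPKM-derived and size-factor-derived fold ratios track each other."""
        cfg = SimConfig(seed=3, n_genes=800)
        cm, lengths, _ = simulate_counts(cfg)
        rec = classify_expression(cm, lengths)
        log_norm = np.log2(rec["mean_G"] / rec["mean_S"])
        log_rpkm = np.log2(rec["rpkm_G"] / rec["rpkm_S"])
        r = np.corrcoef(log_norm, log_rpkm)[0, 1]
        assert r**2 > 0.95

    def test_external_pvalues_override_builtin_test(self):
        cfg = SimConfig(seed=5, n_genes=200)
        cm, lengths, _ = simulate_counts(cfg)
        forced = {g: 1.0 for g in cm.genes}
        rec = classify_expression(cm, lengths, external_pvalues=forced)
        # nothing can be significant -> only constitutive / low-confidence
        assert set(rec["class"]) <= {"constitutive", "low-confidence"}
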