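"""Diurnal-cluster to cell-type cooption analysis."""

import pandas as pd
import pytest

from germsoma.cooption import (
    CLUSTERS,
    build_cooption_table,
    class_fraction_table,
    cluster_class_enrichment,
    exclude_and_retest,
    reciprocal_supercluster_enrichment,
    supercluster_of,
)
from germsoma.orthology import OrthologyMap


class TestSupercluster:
    @pytest.mark.parametrize(
        "cluster, expected",
        [("c1", "light"), ("c3", "light"), ("c8", "light"),
         ("c9", "transition"), ("c10", "transition"), ("c11", "transition"),
         ("c12", "dark"), ("c18", "dark"), ("uc", "unclustered")],
    )
    def test_phase_bins(self, cluster, expected):
        assert supercluster_of(cluster) == expected

    @pytest.mark.parametrize("bad", ["c0", "c19", "x", "light", ""])
    def test_unknown_label_rejected(self, bad):
        with pytest.raises(ValueError):
            supercluster_of(bad)


class TestBuildTable:
    def _setup(self):
        omap = OrthologyMap(
            orthologs={"v1": "c_a", "v2": "c_b", "v3": "c_c", "v4": "c_d"},
            coorthologs={"v5": ("c_a", 120.0, 100.0)},
        )
        diurnal = {"c_a": "c5", "c_b": "c12", "c_c": "c12", "c_d": "uc"}
        classes = {
            "v1": "constitutive",
            "v2": "somatic-specific",
            "v3": "low-confidence",
            # v4 unexpressed: absent from the class map
            "v5": "gonidial-specific",
        }
        return omap, diurnal, classes

    def test_exclusion_rules(self):
        omap, diurnal, classes = self._setup()
        table = build_cooption_table(omap, diurnal, classes)
        genes = set(table["gene"])
        assert "v5" not in genes  # coortholog
        assert "v3" not in genes  # low-confidence
        assert "v4" not in genes  # unexpressed
        assert genes == {"v1", "v2"}

    def test_classes_merged_and_cluster_carried(self):
        omap, diurnal, classes = self._setup()
        table = build_cooption_table(omap, diurnal, classes)
        row = table.set_index("gene").loc["v1"]
        assert row["cluster"] == "c5"
        assert row["supercluster"] == "light"
        assert row["class"] == "constitutive"
        assert set(table["class"]) <= {"gonidial", "somatic", "constitutive"}


def _planted_table(rng, n=2000, dark_somatic_or=3.0):
    """Synthetic cooption table with a planted dark<->somatic association."""
    from germsoma.simulate import SimConfig, simulate_counts, simulate_orthologs, simulate_cluster_labels

    merge = {
        "gonidial-specific": "gonidial", "gonidial-biased": "gonidial",
        "somatic-specific": "somatic", "somatic-biased": "somatic",
        "constitutive": "constitutive", "low-confidence": "low-confidence",
    }
    cfg = SimConfig(
        seed=int(rng.integers(1, 10000)),
        n_genes=n,
        ortholog_fraction=1.0,
        class_proportions=(0.342, 0.070, 0.206, 0.038, 0.344, 0.0),
        cluster_associations={("somatic", "dark"): dark_somatic_or} if dark_somatic_or != 1 else {},
    )
    _, _, truth = simulate_counts(cfg)
    ortho = simulate_orthologs(cfg, list(truth.index))
    labels = simulate_cluster_labels(
        cfg, {ortho[g]: merge[truth.loc[g, "class"]] for g in ortho}
    )
    return build_cooption_table(ortho, labels, truth["class"].to_dict())


class TestEnrichment:
    def test_background_equals_column_margin(self, rng):
        table = _planted_table(rng, n=500)
        rows = cluster_class_enrichment(table)
        for r in rows:
            cls = r.label.split("|")[1]
            assert r.table.a + r.table.c == (table["class"] == cls).sum()

    def test_independent_classes_mostly_ns(self, rng):
        table = _planted_table(rng, n=1000, dark_somatic_or=1.0)
        rows = cluster_class_enrichment(table)
        assert sum(r.flag != "ns" for r in rows) <= 0.05 * len(rows)

    def test_planted_association_detected_both_directions(self, rng):
        table = _planted_table(rng, n=2000, dark_somatic_or=3.0)
        fwd = cluster_class_enrichment(table)
        dark_hits = [
            r for r in fwd
            if r.flag == "enriched" and r.label.endswith("|somatic")
            and r.label.split("|")[0] != "uc"
            and supercluster_of(r.label.split("|")[0]) == "dark"
        ]
        assert dark_hits
        rec = reciprocal_supercluster_enrichment(table)
        assert any(r.label == "dark|somatic" and r.flag == "enriched" for r in rec)

    def test_supercluster_rows_sum_constituent_clusters(self, rng):
        table = _planted_table(rng, n=800)
        fwd = cluster_class_enrichment(table)
        rec = reciprocal_supercluster_enrichment(table)
        for sc in ("light", "transition", "dark"):
            for cls in ("gonidial", "somatic", "constitutive"):
                cluster_sum = sum(
                    r.observed for r in fwd
                    if r.label.endswith(f"|{cls}")
                    and r.label.split("|")[0] != "uc"
                    and supercluster_of(r.label.split("|")[0]) == sc
                )
                (srow,) = [r for r in rec if r.label == f"{sc}|{cls}"]
                assert srow.observed == cluster_sum

    def test_single_cluster_table_degenerate(self):
        table = pd.DataFrame(
            {"gene": ["a", "b"], "partner": ["x", "y"],
             "cluster": ["c1", "c1"], "supercluster": ["light", "light"],
             "class": ["somatic", "gonidial"]}
        )
        rows = cluster_class_enrichment(table)
        assert all(r.flag == "ns" for r in rows)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cluster_class_enrichment(pd.DataFrame(columns=["gene", "cluster", "class"]))


class TestExcludeAndRetest:
    def test_disjoint_exclusion_is_identity(self, rng):
        table = _planted_table(rng, n=500)
        fwd0 = cluster_class_enrichment(table)
        fwd1, _ = exclude_and_retest(table, {"not-a-gene"})
        assert [(r.label, r.p, r.flag) for r in fwd0] == [
            (r.label, r.p, r.flag) for r in fwd1
        ]

    def test_excluding_a_class_removes_it(self, rng):
        table = _planted_table(rng, n=500)
        somatic_genes = set(table.loc[table["class"] == "somatic", "gene"])
        fwd, rec = exclude_and_retest(table, somatic_genes)
        assert not any(r.label.endswith("|somatic") for r in fwd)
        assert not any(r.label.endswith("|somatic") for r in rec)

    def test_excluding_signal_carriers_removes_flags(self, rng):
        table = _planted_table(rng, n=2000, dark_somatic_or=3.0)
        carriers = set(
            table.loc[(table["class"] == "somatic") & (table["supercluster"] == "dark"), "gene"]
        )
        fwd, rec = exclude_and_retest(table, carriers)
        assert not any(
            r.flag == "enriched" and r.label.endswith("|somatic")
            and r.label.split("|")[0] != "uc"
            and supercluster_of(r.label.split("|")[0]) == "dark"
            for r in fwd
        )

    def test_excluding_everything_rejected(self, rng):
        table = _planted_table(rng, n=100)
        with pytest.raises(ValueError):
            exclude_and_retest(table, set(table["gene"]))


class TestFractions:
    def test_rows_sum_to_one(self, rng):
        table = _planted_table(rng, n=600)
        frac = class_fraction_table(table)
        assert frac.sum(axis=1).round(9).eq(1.0).all()
        assert list(frac.index) == [c for c in CLUSTERS if c in set(table["cluster"])]
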