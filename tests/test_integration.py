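"""Methylome-transcriptome integration: DE partitioning, intragenic DMR
profiles and clusters, GSEA running sums, tiered overlap."""

import numpy as np
import pandas as pd
import pytest

from methnet.annotate import AnnotatedDMR, FeatureClass, annotate_dmrs
from methnet.core import DMR, GeneModel
from methnet.integrate import (
    DeConfig,
    de_gene_sets,
    define_de_genes,
    detect_dmr_clusters,
    enrichment_score,
    expression_methylation_overlap,
    gsea_enrichment,
    profile_gene_dmrs,
    rank_genes_by_dmr_count,
    running_sum,
)


def expr_row(gene, m1, m2, p):
    return {"gene_id": gene, "mean_group1": m1, "mean_group2": m2,
            "log2fc": np.log2(m2 / m1), "pvalue": p}


class TestDefineDeGenes:
    def test_strong_repression(self):
        out = define_de_genes(pd.DataFrame([expr_row("g", 10.0, 2.0, 0.01)]))
        assert out.status.iloc[0] == "repressed"

    def test_fold_exactly_at_threshold_is_unchanged(self):
        out = define_de_genes(pd.DataFrame([expr_row("g", 4.0, 7.0, 0.001)]))
        assert 2 ** out.log2fc.iloc[0] == pytest.approx(1.75)
        assert out.status.iloc[0] == "unchanged"  # strictly "more than"

    def test_low_expression_filtered(self):
        out = define_de_genes(pd.DataFrame([expr_row("g", 0.5, 0.8, 0.001)]))
        assert out.status.iloc[0] == "filtered"

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame([expr_row("g", 2, 2, 0.5), expr_row("g", 3, 3, 0.5)])
        with pytest.raises(ValueError, match="duplicate"):
            define_de_genes(df)

    def test_partition_complete_and_idempotent(self):
        rng = np.random.default_rng(1)
        rows = [expr_row(f"g{i}", float(rng.uniform(0.1, 50)),
                         float(rng.uniform(0.1, 50)), float(rng.random()))
                for i in range(200)]
        out = define_de_genes(pd.DataFrame(rows))
        assert set(out.status) <= {"induced", "repressed", "unchanged", "filtered"}
        assert out.status.notna().all()
        again = define_de_genes(out)
        assert (again.status == out.status).all()


def gene(gid, start, end, chrom="chr1", strand="+"):
    return GeneModel(gid, chrom, strand, start, end, exons=((start, end),))


def annotated_at(mid, direction="hypo", assigned=()):
    d = DMR("chr1", mid - 10, mid + 10, 3,
            -0.2 if direction == "hypo" else 0.2, direction)
    return AnnotatedDMR(d, FeatureClass("intron", 1), None, None, tuple(assigned))


class TestProfiles:
    def test_six_dmrs_make_a_cluster(self):
        g = gene("gA", 1000, 20_000)
        ann = [annotated_at(2000 + 500 * i, "hypo" if i < 4 else "hyper")
               for i in range(6)]
        prof = profile_gene_dmrs(ann, [g]).iloc[0]
        assert (prof.n_intragenic_dmrs, prof.n_hypo, prof.n_hyper) == (6, 4, 2)
        assert prof.is_cluster

    def test_five_dmrs_do_not(self):
        g = gene("gA", 1000, 20_000)
        ann = [annotated_at(2000 + 500 * i) for i in range(5)]
        assert not profile_gene_dmrs(ann, [g]).iloc[0].is_cluster

    def test_midpoint_just_upstream_not_intragenic(self):
        g = gene("gA", 1000, 20_000)
        assert profile_gene_dmrs([annotated_at(999)], [g]).iloc[0].n_intragenic_dmrs == 0
        assert profile_gene_dmrs([annotated_at(1000)], [g]).iloc[0].n_intragenic_dmrs == 1

    def test_cluster_detection_arithmetic(self):
        profiles = pd.DataFrame({
            "gene_id": list("abcde"),
            "n_intragenic_dmrs": [6, 6, 6, 5, 1],
            "n_hypo": [6, 6, 6, 5, 1],
            "n_hyper": [0, 0, 0, 0, 0],
            "is_cluster": [True, True, True, False, False],
        })
        out = detect_dmr_clusters(profiles)
        assert out["cluster_genes"] == {"a", "b", "c"}
        assert out["n_dmrs_captured"] == 18
        assert out["fraction_dmrs_captured"] == pytest.approx(18 / 24)

    def test_all_below_threshold_empty(self):
        profiles = profile_gene_dmrs([], [gene("gA", 0, 10)])
        assert detect_dmr_clusters(profiles)["cluster_genes"] == set()

    def test_planted_cluster_genes_recovered(self, methylome, genes, design):
        """All 10 planted cluster genes are called, with no false
        positives, from the called DMRs at default noise."""
        from methnet.dmr import call_dmcs, call_dmrs

        matrix, truth = methylome
        dmrs = call_dmrs(call_dmcs(matrix, design))
        annotated = annotate_dmrs(dmrs, genes)
        profiles = profile_gene_dmrs(annotated, genes)
        called = detect_dmr_clusters(profiles)["cluster_genes"]
        planted = {t.name for t in truth if t.kind == "cluster_gene"}
        assert called == planted


class TestRanking:
    def test_descending_by_count(self):
        profiles = pd.DataFrame({"gene_id": ["a", "b"], "n_intragenic_dmrs": [3, 7],
                                 "n_hypo": [3, 7], "n_hyper": [0, 0],
                                 "is_cluster": [False, True]})
        assert list(rank_genes_by_dmr_count(profiles).gene_id) == ["b", "a"]

    def test_ties_lexicographic_and_order_invariant(self):
        profiles = pd.DataFrame({"gene_id": ["c", "a"], "n_intragenic_dmrs": [3, 3],
                                 "n_hypo": [3, 3], "n_hyper": [0, 0],
                                 "is_cluster": [False, False]})
        assert list(rank_genes_by_dmr_count(profiles).gene_id) == ["a", "c"]
        assert list(rank_genes_by_dmr_count(profiles.iloc[::-1]).gene_id) == ["a", "c"]


class TestGsea:
    def test_top_gene_set_gives_unit_score(self):
        assert enrichment_score(list("abcde"), {"a"}) == pytest.approx(1.0)

    def test_worked_running_sum(self):
        rs = running_sum(["g1", "g2", "g3", "g4", "g5"], {"g2"})
        assert rs == pytest.approx([-0.25, 0.75, 0.5, 0.25, 0.0])
        assert enrichment_score(["g1", "g2", "g3", "g4", "g5"], {"g2"}) == pytest.approx(0.75)

    def test_full_universe_set_rejected(self):
        with pytest.raises(ValueError, match="whole ranked list"):
            running_sum(list("abc"), set("abc"))

    def test_empty_intersection_rejected(self):
        ranked = pd.DataFrame({"gene_id": list("abc"), "statistic": [3, 2, 1]})
        with pytest.raises(ValueError, match="intersect"):
            gsea_enrichment(ranked, {"z"})

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_enumeration(self, seed):
        """ES equals a direct step-by-step recomputation on random
        (list, set) pairs."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 100))
        ids = [f"g{i}" for i in range(n)]
        k = int(rng.integers(1, n))
        chosen = set(rng.choice(ids, size=k, replace=False))
        nh = len(chosen)
        acc, best = 0.0, 0.0
        for g in ids:
            acc += 1 / nh if g in chosen else -1 / (n - nh)
            if abs(acc) > abs(best):
                best = acc
        assert enrichment_score(ids, chosen) == pytest.approx(best, abs=1e-12)

    def test_planted_top_set_is_significant(self):
        ids = [f"g{i}" for i in range(100)]
        ranked = pd.DataFrame({"gene_id": ids, "statistic": np.arange(100, 0, -1)})
        res = gsea_enrichment(ranked, set(ids[:10]), n_perm=1000, seed=0)
        assert res.es > 0.8 and res.p < 0.05


class TestOverlap:
    def _frames(self):
        genes = [gene(g, 1000 * i + 100, 1000 * i + 900)
                 for i, g in enumerate(["g1", "g2", "g3", "g4", "g5"], start=1)]
        expr = pd.DataFrame([
            expr_row("g1", 4, 16, 0.01), expr_row("g2", 4, 16, 0.01),
            expr_row("g3", 4, 16, 0.01), expr_row("g4", 8, 8, 0.9),
            expr_row("g5", 8, 8, 0.9),
        ])
        records = define_de_genes(expr)
        return genes, records

    def test_hand_counted_overlap(self):
        genes, records = self._frames()
        # 6 hypo DMRs inside each of g2, g3, g4 -> clusters; none elsewhere
        ann = []
        for gid, lo in (("g2", 2100), ("g3", 3100), ("g4", 4100)):
            for i in range(6):
                ann.append(annotated_at(lo + 100 * i, assigned=(gid,)))
        profiles = profile_gene_dmrs(ann, genes)
        out = expression_methylation_overlap(records, profiles, ann)
        tier = {o.tier: o for o in out}
        clustered = tier["clustered_dmr"]
        assert clustered.n_methylated == 3
        assert clustered.n_overlap == 2  # g2, g3 induced; g4 unchanged
        assert clustered.overlap_fraction == pytest.approx(2 / 3)

    def test_disjoint_sets_zero_overlap(self):
        genes, records = self._frames()
        ann = [annotated_at(4100 + 100 * i, assigned=("g4",)) for i in range(6)]
        profiles = profile_gene_dmrs(ann, genes)
        out = expression_methylation_overlap(records, profiles, ann)
        assert all(o.n_overlap == 0 for o in out)

    def test_tier_sets_are_nested(self, methylome, genes, design):
        """any >= intragenic >= clustered methylated-set sizes."""
        from methnet.dmr import call_dmcs, call_dmrs

        matrix, _ = methylome
        cfg = __import__("methnet.sim", fromlist=["SimConfig"]).SimConfig()
        from methnet.sim import simulate_expression

        table, _ = simulate_expression(cfg, genes, methylome[1])
        records = define_de_genes(table)
        dmrs = call_dmrs(call_dmcs(matrix, design))
        annotated = annotate_dmrs(dmrs, genes)
        profiles = profile_gene_dmrs(annotated, genes)
        out = expression_methylation_overlap(records, profiles, annotated)
        sizes = [o.n_methylated for o in out]
        assert sizes == sorted(sizes, reverse=True)
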