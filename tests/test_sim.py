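"""The generator must be deterministic, truth-consistent, and honest
about its planted structure."""

import numpy as np
import pytest

from methnet.methcall import reference_cpg_sites
from methnet.sim import (
    SimConfig,
    simulate_bisulfite_reads,
    simulate_expression,
    simulate_gene_models,
    simulate_interactome,
    simulate_methylome,
    simulate_reference,
)


class TestGeneModels:
    def test_zero_genes_gives_empty_list(self):
        assert simulate_gene_models(SimConfig(n_genes=0)) == []

    def test_deterministic_under_seed(self):
        cfg = SimConfig(rng_seed=7)
        assert simulate_gene_models(cfg) == simulate_gene_models(cfg)

    def test_intron_count_matches_exon_range(self):
        """exons_per_gene=(3,8) genes carry 2-7 introns, recounted
        independently from the exon list."""
        cfg = SimConfig(rng_seed=3, n_genes=100, exons_per_gene=(3, 8))
        for g in simulate_gene_models(cfg):
            gaps = [
                (g.exons[i][1], g.exons[i + 1][0])
                for i in range(len(g.exons) - 1)
                if g.exons[i + 1][0] > g.exons[i][1]
            ]
            assert 2 <= len(gaps) <= 7
            assert sorted(g.introns()) == sorted(gaps)

    def test_genes_do_not_overlap(self, genes):
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="configuration error"):
            simulate_gene_models(SimConfig(n_genes=500, chrom_length_bp=100_000))


class TestMethylome:
    def test_null_config_has_empty_truth(self, null_methylome):
        _, truth = null_methylome
        assert [t for t in truth if t.kind == "dmr"] == []

    def test_cluster_bookkeeping(self, methylome):
        """10 cluster genes x 8 runs -> exactly 80 truth DMRs carry
        cluster-gene ids."""
        _, truth = methylome
        cluster_ids = {t.name for t in truth if t.kind == "cluster_gene"}
        assert len(cluster_ids) == 10
        tagged = [t for t in truth if t.kind == "dmr" and t.name in cluster_ids]
        assert len(tagged) == 80

    def test_planted_counts_match_config(self, methylome, default_config):
        _, truth = methylome
        n_dmr = sum(1 for t in truth if t.kind == "dmr")
        expected = (default_config.n_planted_dmrs
                    + default_config.n_cluster_genes * default_config.dmrs_per_cluster_gene)
        assert n_dmr == expected

    def test_planted_effect_recovered_empirically(self, methylome, default_config):
        """Group-mean difference over a planted hypo run sits near the
        planted -0.3 within a few binomial standard errors."""
        matrix, truth = methylome
        design = default_config.design()
        frac = matrix.fractions()
        i1 = matrix.sample_index(design.group1)
        i2 = matrix.sample_index(design.group2)
        diffs = []
        for t in truth:
            if t.kind != "dmr" or t.direction != "hypo":
                continue
            on = (matrix.chrom == t.chrom) & (matrix.pos >= t.start) & (matrix.pos < t.end)
            with np.errstate(invalid="ignore"):
                d = np.nanmean(frac[on][:, i2]) - np.nanmean(frac[on][:, i1])
            diffs.append(d)
        # per-run SE ~ sqrt(p(1-p)/cov/n_samples/n_sites) ~ 0.03; mean over
        # >100 runs is far tighter
        assert abs(np.mean(diffs) - (-default_config.planted_effect)) < 0.02

    def test_deterministic_under_seed(self, genes, default_config):
        m1, t1 = simulate_methylome(default_config, genes)
        m2, t2 = simulate_methylome(default_config, genes)
        assert np.array_equal(m1.meth, m2.meth)
        assert np.array_equal(m1.unmeth, m2.unmeth)
        assert t1 == t2

    def test_sites_sorted_and_counts_consistent(self, methylome):
        matrix, _ = methylome
        assert np.all(matrix.coverage() >= 0)
        same = matrix.chrom[1:] == matrix.chrom[:-1]
        assert np.all(matrix.pos[1:][same] > matrix.pos[:-1][same])

    def test_too_many_runs_raise(self, genes):
        cfg = SimConfig(n_cpgs=500, n_planted_dmrs=200)
        with pytest.raises(ValueError, match="configuration error"):
            simulate_methylome(cfg, simulate_gene_models(cfg))


class TestExpression:
    def test_full_coupling_no_noise_induces_every_cluster_gene(self, genes, methylome):
        _, truth = methylome
        cfg = SimConfig(expression_coupling=1.0, expression_noise_sd=0.0)
        table, _ = simulate_expression(cfg, genes, truth)
        cluster = {t.name for t in truth if t.kind == "cluster_gene"}
        sub = table[table.gene_id.isin(cluster)]
        assert (sub.log2fc > np.log2(1.75)).all()

    def test_null_coupling_matches_background(self, genes, methylome):
        """coupling == per-direction baseline -> induction rates agree."""
        _, truth = methylome
        cfg = SimConfig(rng_seed=5, expression_coupling=0.3, de_baseline_prob=0.3)
        _, de_truth = simulate_expression(cfg, genes, truth)
        cluster = {t.name for t in truth if t.kind == "cluster_gene"}
        up = {t.name for t in de_truth if t.direction == "up"}
        rate_cluster = len(up & cluster) / len(cluster)
        rate_bg = len(up - cluster) / (len(genes) - len(cluster))
        assert abs(rate_cluster - rate_bg) < 0.35  # 10 cluster genes: coarse

    def test_coupling_gives_positive_odds_ratio_by_direct_count(self, genes, methylome, default_config):
        """2x2 contingency recount: cluster genes are enriched among
        induced calls at coupling 0.8 vs baseline 0.1."""
        _, truth = methylome
        table, _ = simulate_expression(default_config, genes, truth)
        from methnet.integrate import define_de_genes

        records = define_de_genes(table)
        cluster = {t.name for t in truth if t.kind == "cluster_gene"}
        induced = set(records.loc[records.status == "induced", "gene_id"])
        a = len(cluster & induced)
        b = len(cluster - induced)
        c = len(induced - cluster)
        d = len(set(table.gene_id) - cluster - induced)
        assert (a * d) > (b * c)  # OR > 1


class TestInteractome:
    def test_null_module_empty_truth(self):
        cfg = SimConfig(planted_module_size=0)
        _, _, truth = simulate_interactome(cfg)
        assert truth == []

    def test_deterministic_edge_lists(self):
        cfg = SimConfig(rng_seed=9)
        g1, s1, _ = simulate_interactome(cfg)
        g2, s2, _ = simulate_interactome(cfg)
        assert sorted(g1.edges) == sorted(g2.edges)
        assert s1 == s2

    def test_module_denser_than_graph(self, default_config):
        g, _, truth = simulate_interactome(default_config)
        module = [t.name for t in truth]
        sub = g.subgraph(module)
        m = len(module)
        density_mod = sub.number_of_edges() / (m * (m - 1) / 2)
        n = g.number_of_nodes()
        density_all = g.number_of_edges() / (n * (n - 1) / 2)
        assert density_mod > density_all


class TestBisulfiteReads:
    def test_all_methylated_reads_keep_cytosines(self):
        cfg = SimConfig(conversion_failure_rate=0.0, read_sim_meth_prob=1.0)
        ref = simulate_reference(cfg)
        pairs, truth = simulate_bisulfite_reads(cfg, ref)
        assert all(v == 1 for v in truth.values())
        for pair in pairs:
            for read in (pair.read1, pair.read2):
                seq = ref[read.chrom]
                for j in range(len(read)):
                    p = read.ref_start + j
                    if pair.bs_strand == "top" and seq[p : p + 2] == "CG":
                        assert read.seq[j] == "C"
                    if pair.bs_strand == "bottom" and p > 0 and seq[p - 1 : p + 1] == "CG":
                        assert read.seq[j] == "G"

    def test_all_unmethylated_reads_convert_outside_artifacts(self):
        from methnet.methcall import MethylCallConfig, mask_tagmentation_ends

        cfg = SimConfig(conversion_failure_rate=0.0, read_sim_meth_prob=0.0)
        ref = simulate_reference(cfg)
        pairs, truth = simulate_bisulfite_reads(cfg, ref)
        assert all(v == 0 for v in truth.values())
        mcfg = MethylCallConfig()
        for pair in pairs:
            masks = mask_tagmentation_ends(pair, mcfg)
            for read, mask in zip((pair.read1, pair.read2), masks):
                seq = ref[read.chrom]
                for j in range(len(read)):
                    if mask[read.read_index(j)]:
                        continue  # tagmentation artifact zone carries raw bases
                    p = read.ref_start + j
                    if pair.bs_strand == "top" and seq[p : p + 2] == "CG":
                        assert read.seq[j] == "T"
                    if pair.bs_strand == "bottom" and p > 0 and seq[p - 1 : p + 1] == "CG":
                        assert read.seq[j] == "A"

    def test_truth_covers_reference_cpgs(self, default_config):
        ref = simulate_reference(default_config)
        _, truth = simulate_bisulfite_reads(default_config, ref)
        assert set(truth) == set(reference_cpg_sites(ref))

    def test_conversion_failures_near_planted_rate(self):
        """Unconverted CH fraction tracks the planted 2% failure rate
        within 3 binomial SDs (masked/low-quality bases excluded)."""
        from methnet.methcall import estimate_conversion_rate

        cfg = SimConfig(rng_seed=4, conversion_failure_rate=0.02,
                        low_quality_fraction=0.0, n_read_pairs=600)
        ref = simulate_reference(cfg)
        pairs, _ = simulate_bisulfite_reads(cfg, ref)
        est = estimate_conversion_rate(pairs, ref)
        assert est.total >= 5000
        sd = np.sqrt(0.02 * 0.98 / est.total)
        assert abs((1 - est.rate) - 0.02) <= 3 * sd
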