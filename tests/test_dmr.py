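"""The consecutive-CpG DMR model: coverage filter, site tests, maximal
runs, and genome-wide summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methnet.core import CpGCountMatrix, GroupDesign
from methnet.dmr import (
    DmrCallConfig,
    call_dmcs,
    call_dmrs,
    filter_coverage,
    global_cpg_distribution,
    summarize_dmrs,
)
from methnet.dmr import test_site as site_stat  # alias: keep pytest collection away

from conftest import brute_force_dmrs

DESIGN = GroupDesign(("i1", "i2", "i3"), ("a1", "a2", "a3"))


def matrix_from_coverage(cov_rows, meth_fraction=0.5):
    cov = np.array(cov_rows)
    meth = np.round(cov * meth_fraction).astype(int)
    n = len(cov)
    return CpGCountMatrix(
        chrom=np.array(["chr1"] * n, dtype=object),
        pos=np.arange(n) * 100,
        samples=list(DESIGN.samples),
        meth=meth,
        unmeth=cov - meth,
    )


class TestFilterCoverage:
    def test_two_of_three_at_8x_kept(self):
        m = matrix_from_coverage([[8, 9, 3, 12, 8, 8]])
        assert filter_coverage(m, DESIGN).n_sites == 1

    def test_one_of_three_dropped(self):
        m = matrix_from_coverage([[7, 7, 30, 12, 8, 8]])
        assert filter_coverage(m, DESIGN).n_sites == 0

    def test_zero_threshold_is_identity(self):
        m = matrix_from_coverage([[0, 0, 0, 0, 0, 0], [1, 1, 1, 1, 1, 1]])
        out = filter_coverage(m, DESIGN, DmrCallConfig(min_coverage=0))
        assert out.n_sites == 2


class TestSiteTest:
    def test_identical_groups_not_significant(self):
        s = site_stat([5, 5, 5, 5, 5, 5], [5, 5, 5, 5, 5, 5], DESIGN)
        assert s["diff"] == 0 and not s.significant and s.p == 1.0

    def test_welch_example_two_vs_two(self):
        """Fractions (0.2,0.4) vs (0.8,0.6): t=-2.828, Welch df=2,
        p=0.1056 from the closed-form t CDF."""
        d = GroupDesign(("i1", "i2"), ("a1", "a2"))
        s = site_stat([2, 4, 8, 6], [8, 6, 2, 4], d,
                      DmrCallConfig(test_variant="welch"))
        assert s["diff"] == pytest.approx(0.4)
        assert s.t == pytest.approx(-2.8284271, abs=1e-6)
        assert s.p == pytest.approx(2 * stats.t.sf(2.8284271, 2), abs=1e-6)
        assert s.p == pytest.approx(0.105573, abs=1e-5)

    def test_zero_variance_unequal_means_is_significant(self):
        s = site_stat([1, 1, 1, 9, 9, 9], [9, 9, 9, 1, 1, 1], DESIGN)
        assert s.p == 0.0 and s.significant

    def test_pooled_and_welch_agree_on_balanced_variance(self):
        d = GroupDesign(("i1", "i2"), ("a1", "a2"))
        for variant in ("student", "welch"):
            s = site_stat([2, 4, 8, 6], [8, 6, 2, 4], d,
                          DmrCallConfig(test_variant=variant))
            assert s.t == pytest.approx(-2.8284271, abs=1e-6)

    def test_vacuous_thresholds_flag_every_site(self, null_methylome, default_config):
        matrix, _ = null_methylome
        cfg = DmrCallConfig(alpha=0.999999, min_diff=1e-12)
        dmcs = call_dmcs(matrix, default_config.design(), cfg)
        # every filtered site with any group difference is a DMC
        nonzero = np.abs(dmcs["diff"]) >= 1e-12
        assert dmcs.loc[nonzero & (dmcs.p < 0.999999), "is_dmc"].all()


def dmc_frame(diffs, is_dmc=None, chrom=None, pvals=None):
    n = len(diffs)
    return pd.DataFrame({
        "chrom": chrom or ["chr1"] * n,
        "pos": np.arange(n) * 50,
        "diff": diffs,
        "p": pvals or [0.01] * n,
        "is_dmc": [True] * n if is_dmc is None else is_dmc,
    })


class TestCallDmrs:
    def test_three_adjacent_dmcs_form_one_dmr(self):
        dmrs = call_dmrs(dmc_frame([0.12, 0.25, 0.20]))
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.direction == "hyper"
        assert d.mean_diff == pytest.approx(0.19)
        assert d.n_cpgs == 3
        assert (d.start, d.end) == (0, 102)

    def test_two_adjacent_dmcs_are_not_enough(self):
        assert call_dmrs(dmc_frame([0.2, 0.2])) == []

    def test_sign_change_breaks_runs(self):
        """Pattern (+,+,-,+,+,+) yields exactly one DMR over the last
        three sites, matching the brute-force window enumeration."""
        diffs = [0.2, 0.2, -0.2, 0.2, 0.2, 0.2]
        dmrs = call_dmrs(dmc_frame(diffs))
        assert len(dmrs) == 1
        assert dmrs[0].site_index == (3, 4, 5)
        oracle = brute_force_dmrs(["chr1"] * 6, diffs, [True] * 6)
        assert [(d.site_index[0], d.site_index[-1]) for d in dmrs] == [
            (i, j) for i, j, _ in oracle
        ]

    def test_chromosome_change_breaks_runs(self):
        frame = dmc_frame([0.2] * 6, chrom=["chr1"] * 3 + ["chr2"] * 3)
        frame.loc[3:, "pos"] = [0, 50, 100]
        dmrs = call_dmrs(frame)
        assert len(dmrs) == 2 and {d.chrom for d in dmrs} == {"chr1", "chr2"}

    def test_unsorted_input_rejected(self):
        frame = dmc_frame([0.2, 0.2, 0.2])
        frame["pos"] = [100, 50, 0]
        with pytest.raises(ValueError, match="sorted"):
            call_dmrs(frame)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_on_random_sequences(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(5, 60))
        diffs = rng.uniform(-0.4, 0.4, n).round(3)
        is_dmc = rng.random(n) < 0.5
        chrom = list(np.where(np.arange(n) < rng.integers(0, n + 1), "chr1", "chr2"))
        frame = dmc_frame(list(diffs), list(is_dmc), chrom)
        frame["pos"] = np.concatenate([
            np.arange(sum(c == "chr1" for c in chrom)) * 50,
            np.arange(sum(c == "chr2" for c in chrom)) * 50,
        ])
        got = [(d.site_index[0], d.site_index[-1], pytest.approx(d.mean_diff))
               for d in call_dmrs(frame)]
        assert got == [(i, j, pytest.approx(m))
                       for i, j, m in brute_force_dmrs(chrom, diffs, is_dmc)]

    def test_threshold_monotonicity(self):
        """Raising min_diff or min_consecutive never increases the DMR
        count."""
        rng = np.random.default_rng(42)
        diffs = rng.uniform(-0.5, 0.5, 200)
        is_dmc = rng.random(200) < 0.6
        frame = dmc_frame(list(diffs), list(is_dmc))
        counts_by_mindiff = [
            len(call_dmrs(frame, DmrCallConfig(min_diff=t)))
            for t in (0.05, 0.1, 0.2, 0.3)
        ]
        assert counts_by_mindiff == sorted(counts_by_mindiff, reverse=True)
        counts_by_len = [
            len(call_dmrs(frame, DmrCallConfig(min_consecutive=k)))
            for k in (2, 3, 4, 6)
        ]
        assert counts_by_len == sorted(counts_by_len, reverse=True)


class TestSummaries:
    def test_direction_split_at_thresholds(self):
        dmrs = call_dmrs(dmc_frame([0.2, 0.2, 0.2, -0.2, -0.2, -0.2][::1],
                                   chrom=["chr1"] * 3 + ["chr2"] * 3))
        # fix positions per chromosome
        s = summarize_dmrs(dmrs, [0.1, 0.3])
        at10 = s[s.threshold == 0.1].iloc[0]
        assert at10.gain_fraction == 0.5 and at10.loss_fraction == 0.5
        at30 = s[s.threshold == 0.3].iloc[0]
        assert at30.n_total == 0

    def test_loss_fraction_mirrors_planted_hypo_fraction(self, methylome, design):
        """With 80% of planted runs hypomethylated at effect 0.3, the
        loss fraction at the 0.3 threshold recounts near 0.8."""
        matrix, truth = methylome
        dmrs = call_dmrs(call_dmcs(matrix, design))
        s = summarize_dmrs(dmrs, [0.3]).iloc[0]
        planted_loss = np.mean([t.direction == "hypo" for t in truth if t.kind == "dmr"])
        assert planted_loss > 0.8  # clusters are all hypo on top of the 80%
        assert s.loss_fraction == pytest.approx(planted_loss, abs=0.1)

    def test_high_methylation_fraction(self):
        m = CpGCountMatrix(
            chrom=np.array(["chr1"] * 3, dtype=object), pos=np.array([0, 100, 200]),
            samples=list(DESIGN.samples),
            meth=np.array([[9, 9, 9, 9, 9, 9], [5, 5, 5, 5, 5, 5], [17, 17, 17, 17, 17, 17]]),
            unmeth=np.array([[1, 1, 1, 1, 1, 1], [5, 5, 5, 5, 5, 5], [3, 3, 3, 3, 3, 3]]),
        )
        out = global_cpg_distribution(m, DESIGN)
        assert out["group1"]["fraction_high"] == pytest.approx(2 / 3)
        assert out["high_bin_test"]["p"] == 1.0  # identical groups

    def test_group2_shift_raises_high_fraction(self):
        from methnet.sim import SimConfig, simulate_gene_models, simulate_methylome

        cfg = SimConfig(rng_seed=13, n_planted_dmrs=0, n_cluster_genes=0,
                        planted_effect=0.0, group2_high_shift=0.05, n_cpgs=8000)
        m, _ = simulate_methylome(cfg, simulate_gene_models(cfg))
        out = global_cpg_distribution(m, cfg.design())
        assert out["group2"]["fraction_high"] > out["group1"]["fraction_high"]
        assert out["high_bin_test"]["difference"] > 0

    def test_empty_matrix_rejected(self):
        m = matrix_from_coverage(np.empty((0, 6), dtype=int))
        with pytest.raises(ValueError, match="empty"):
            global_cpg_distribution(m, DESIGN)


class TestNullBehaviour:
    def test_type_one_rate_near_nominal(self, null_methylome, design):
        """Null simulation: p<0.05 fraction within [0.03, 0.07] and
        essentially no DMRs."""
        matrix, _ = null_methylome
        dmcs = call_dmcs(matrix, design)
        assert len(dmcs) >= 20000
        assert 0.03 <= dmcs.significant.mean() <= 0.07
        dmrs = call_dmrs(dmcs)
        assert len(dmrs) / len(dmcs) * 10000 <= 5
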