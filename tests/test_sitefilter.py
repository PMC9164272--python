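"""Filter cascade: standard filter, Gini C-cutoff, signal/noise, FDR,
regions, replicate concordance, attrition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m5cpipe.sitefilter import (
    FilterConfig,
    apply_c_cutoff,
    attrition_report,
    bh_fdr,
    gini,
    region_filter,
    replicate_concordance,
    run_filter_cascade,
    select_c_cutoff,
    signal_noise,
    standard_filter,
    transcript_gene_map,
)
from m5cpipe.simdata import SimConfig, simulate


def site_table(rows):
    df = pd.DataFrame(rows, columns=["ref", "pos0", "strand", "i", "j"])
    df["pos1"] = df["pos0"] + 1
    df["level"] = df["i"] / df["j"]
    df["p_value"] = 1.0
    df["q_value"] = np.nan
    return df


class TestStandardFilter:
    @pytest.mark.parametrize(
        "i, j, expect",
        [
            (3, 20, True),   # exact boundary on all three thresholds' scale
            (2, 20, False),  # count below 3
            (3, 40, False),  # level 0.075 below 0.1
            (2, 10, False),  # coverage below 20 (i=2 also fails)
            (5, 20, True),
        ],
    )
    def test_boundaries(self, i, j, expect):
        out = standard_filter(site_table([("TX", 5, "+", i, j)]))
        assert (len(out) == 1) is expect

    def test_level_boundary_inclusive(self):
        out = standard_filter(site_table([("TX", 5, "+", 4, 40)]))  # level exactly 0.1
        assert len(out) == 1


class TestGini:
    def test_perfect_equality(self):
        assert gini([5, 5, 5, 5]) == 0.0

    def test_hand_computed_pair(self):
        # sum |xa-xb| = 4 over ordered pairs; 4 / (2 * 4 * 2) = 0.25
        assert gini([1, 3]) == pytest.approx(0.25, abs=1e-15)

    def test_scale_invariance(self):
        x = [2, 7, 1, 9, 4]
        assert gini([10 * v for v in x]) == pytest.approx(gini(x), abs=1e-12)

    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(ValueError):
            gini([])
        with pytest.raises(ValueError):
            gini([1, 0, 2])

    @given(st.lists(st.integers(1, 50), min_size=1, max_size=20))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_pairwise_oracle(self, values):
        x = np.asarray(values, dtype=float)
        n = len(x)
        brute = np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * x.mean())
        assert gini(values) == pytest.approx(brute, abs=1e-12)


class TestBhFdr:
    def test_single_p(self):
        q, passed = bh_fdr([0.03])
        assert q[0] == pytest.approx(0.03) and passed[0]

    def test_hand_step_up(self):
        q, passed = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert passed.all()

    def test_all_ones(self):
        q, passed = bh_fdr([1.0, 1.0, 1.0])
        assert (q == 1.0).all() and not passed.any()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 11)))
            q, passed = bh_fdr(p)
            ref_passed, ref_q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert np.allclose(q, ref_q, atol=1e-12)
            assert (passed == ref_passed).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestRegionFilter:
    def test_half_open_boundaries(self):
        sites = site_table(
            [("TX", 100, "+", 5, 50), ("TX", 110, "+", 5, 50), ("TX", 89, "+", 5, 50)]
        )
        out = region_filter(sites, {"TX": [(90, 110)]})
        assert sorted(out["pos0"]) == [89, 110]

    def test_empty_regions_identity(self):
        sites = site_table([("TX", 1, "+", 5, 50)])
        assert region_filter(sites, {}).equals(sites.reset_index(drop=True))

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            region_filter(site_table([("TX", 1, "+", 5, 50)]), {"TX": [(10, 10)]})


class TestSignalNoise:
    def test_ratios_and_retention(self):
        before = site_table(
            [("TX", 1, "+", 10, 50), ("TX", 2, "+", 10, 50), ("TX", 3, "+", 4, 50)]
        )
        after = site_table([("TX", 1, "+", 10, 48), ("TX", 2, "+", 5, 40)])
        out = signal_noise(before, after, sn_min=0.9)
        by_pos = out.set_index("pos0")
        assert by_pos.loc[1, "sn_ratio"] == 1.0 and by_pos.loc[1, "sn_pass"]
        assert by_pos.loc[2, "sn_ratio"] == 0.5 and not by_pos.loc[2, "sn_pass"]
        # site supported only by removed reads: absent after cutoff, ratio 0
        assert by_pos.loc[3, "sn_ratio"] == 0.0 and not by_pos.loc[3, "sn_pass"]
        assert (out["sn_ratio"] <= 1.0).all()


class TestReplicateConcordance:
    def make_tables(self, rep2_i, rep2_j):
        passing = {
            "rep1": site_table([("TX", 5, "+", 10, 50)]),
            "rep2": site_table([]),
        }
        post = {
            "rep1": site_table([("TX", 5, "+", 10, 50)]),
            "rep2": site_table([("TX", 5, "+", rep2_i, rep2_j)]) if rep2_j else site_table([]),
        }
        return passing, post

    def test_minimal_support_retains(self):
        passing, post = self.make_tables(1, 10)
        out = replicate_concordance(passing, post)
        assert len(out) == 1 and out.iloc[0]["supported_in"] == "rep2"

    def test_zero_count_support_drops(self):
        passing, post = self.make_tables(0, 50)
        assert len(replicate_concordance(passing, post)) == 0

    def test_pass_in_both_retained_once(self):
        t = site_table([("TX", 5, "+", 10, 50)])
        out = replicate_concordance({"rep1": t, "rep2": t}, {"rep1": t, "rep2": t})
        assert len(out) == 1

    def test_requires_two_replicates(self):
        t = site_table([("TX", 5, "+", 10, 50)])
        with pytest.raises(ValueError, match="two replicates"):
            replicate_concordance({"rep1": t}, {"rep1": t})


class TestAttrition:
    def test_no_filtering(self):
        out = attrition_report({"a": 7, "b": 7})
        assert (out["pct_remaining"] == 100.0).all()

    def test_percentages(self):
        out = attrition_report({"s0": 200, "s1": 100, "s2": 10, "s3": 10})
        assert list(out["pct_remaining"]) == [100.0, 50.0, 5.0, 5.0]


@pytest.fixture(scope="module")
def resistant_sim():
    cfg = SimConfig(
        n_transcripts=6, n_control_transcripts=2, length_range=(1500, 1700),
        n_true_sites=12, mean_coverage=60, seed=53,
    )
    return simulate(cfg)


class TestCutoffScan:
    def test_threshold_one_selects_max_of_range(self, resistant_sim):
        ref = resistant_sim.reference.sequences
        cfg = FilterConfig(gini_threshold=1.0, c_cutoff_range=(1, 5))
        scan = select_c_cutoff(
            resistant_sim.reads, ref, transcript_gene_map(list(ref)), cfg
        )
        assert scan.chosen_k == 5

    def test_gini_drops_when_resistant_reads_removed(self, resistant_sim):
        ref = resistant_sim.reference.sequences
        cfg = FilterConfig(c_cutoff_range=(3, 30))
        scan = select_c_cutoff(
            resistant_sim.reads, ref, transcript_gene_map(list(ref)), cfg
        )
        table = scan.table.set_index("cutoff")
        assert table.loc[30, "gini"] > table.loc[3, "gini"]
        assert table.loc[30, "gini"] > cfg.gini_threshold

    def test_read_retention_nested_in_cutoff(self, resistant_sim):
        ref = resistant_sim.reference.sequences
        k3 = {id(r) for r in apply_c_cutoff(resistant_sim.reads, ref, 3)}
        k10 = {id(r) for r in apply_c_cutoff(resistant_sim.reads, ref, 10)}
        assert k3 <= k10

    def test_scan_read_counts_monotone(self, resistant_sim):
        ref = resistant_sim.reference.sequences
        scan = select_c_cutoff(
            resistant_sim.reads, ref, transcript_gene_map(list(ref)), FilterConfig()
        )
        n = scan.table["n_reads"].to_numpy()
        assert (np.diff(n) >= 0).all()


class TestCascade:
    def test_stagewise_set_reduction(self, resistant_sim):
        ref = resistant_sim.reference.sequences
        res = run_filter_cascade(
            resistant_sim.reads, ref, transcript_gene_map(list(ref)), error_rate=1e-3
        )
        def keys(df):
            return set(zip(df["ref"], df["pos0"], df["strand"]))

        assert keys(res.sites_standard) <= keys(res.sites_start)
        assert keys(res.sites_sn) <= keys(res.sites_standard)
        assert keys(res.sites_region) <= keys(res.sites_sn)
        assert keys(res.sites_final) <= keys(res.sites_region)
        pct = res.attrition["pct_remaining"].to_numpy()
        assert pct[0] == 100.0 and (np.diff(pct) <= 1e-9).all()

    def test_control_sites_fail_standard_plus_cutoff(self, resistant_sim):
        # unmethylated spike-ins: artifact sites never survive the first
        # two filters of the cascade
        ref = resistant_sim.reference.sequences
        res = run_filter_cascade(
            resistant_sim.reads, ref, transcript_gene_map(list(ref)), error_rate=1e-3
        )
        controls = set(resistant_sim.reference.control_ids)
        assert not (set(res.sites_sn["ref"]) & controls)
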