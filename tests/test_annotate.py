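"""Annotation, metagene, motif, CPM and cross-library statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import make_read
from m5cpipe.annotate import (
    GeneModel,
    annotate_sites,
    compare_libraries,
    cpm_with_without_dedup,
    gene_cpm,
    metagene,
    motif_matrix,
    parse_gtf,
)


def site_df(rows):
    df = pd.DataFrame(rows, columns=["ref", "pos0", "strand", "i", "j"])
    df["pos1"] = df["pos0"] + 1
    df["level"] = df["i"] / df["j"]
    return df


@pytest.fixture
def mrna_model():
    # 1000 nt transcript: 5'UTR [0,150), CDS [150,750), 3'UTR [750,1000)
    return GeneModel(
        gene_id="G1",
        transcript_id="G1.1",
        ref="TX0001",
        strand="+",
        exons=[(0, 1000)],
        cds=[(150, 750)],
        utr5=[(0, 150)],
        utr3=[(750, 1000)],
    )


def write_gtf(path, with_utrs=True):
    attrs = 'gene_id "G1"; transcript_id "G1.1";'
    lines = [
        f"TX0001\tsrc\texon\t1\t1000\t.\t+\t.\t{attrs}",
        f"TX0001\tsrc\tCDS\t151\t750\t.\t+\t.\t{attrs}",
    ]
    if with_utrs:
        lines += [
            f"TX0001\tsrc\tfive_prime_utr\t1\t150\t.\t+\t.\t{attrs}",
            f"TX0001\tsrc\tthree_prime_utr\t751\t1000\t.\t+\t.\t{attrs}",
        ]
    path.write_text("\n".join(lines) + "\n")


class TestGtfParsing:
    def test_explicit_utrs(self, tmp_path):
        p = tmp_path / "a.gtf"
        write_gtf(p)
        (m,) = parse_gtf(p)
        assert m.exons == [(0, 1000)] and m.cds == [(150, 750)]
        assert m.utr5 == [(0, 150)] and m.utr3 == [(750, 1000)]

    def test_utrs_derived_from_exon_minus_cds(self, tmp_path):
        p = tmp_path / "b.gtf"
        write_gtf(p, with_utrs=False)
        (m,) = parse_gtf(p)
        assert m.utr5 == [(0, 150)] and m.utr3 == [(750, 1000)]

    def test_no_exons_rejected(self, tmp_path):
        p = tmp_path / "c.gtf"
        p.write_text('TX0001\tsrc\tCDS\t1\t10\t.\t+\t.\tgene_id "G"; transcript_id "T";\n')
        with pytest.raises(ValueError, match="exon"):
            parse_gtf(p)


class TestAnnotateSites:
    def test_feature_classes(self, mrna_model):
        sites = site_df(
            [
                ("TX0001", 100, "+", 5, 50),
                ("TX0001", 400, "+", 5, 50),
                ("TX0001", 800, "+", 5, 50),
                ("TX0002", 5, "+", 5, 50),
            ]
        )
        out = annotate_sites(sites, [mrna_model])
        assert list(out["feature"]) == ["5UTR", "CDS", "3UTR", "intergenic"]
        assert out.loc[0, "gene"] == "G1"

    def test_multi_overlap_resolved_by_longest_cds(self, mrna_model):
        short = GeneModel(
            "G2", "G2.1", "TX0001", "+", exons=[(0, 1000)], cds=[(300, 450)],
            utr5=[(0, 300)], utr3=[(450, 1000)],
        )
        out = annotate_sites(site_df([("TX0001", 400, "+", 5, 50)]), [mrna_model, short])
        assert out.loc[0, "gene"] == "G1"  # 600 nt CDS beats 150 nt
        assert out.loc[0, "all_genes"] == "G1,G2"

    def test_append_only(self, mrna_model):
        sites = site_df([("TX0001", 400, "+", 5, 50)])
        before = sites.copy()
        annotate_sites(sites, [mrna_model])
        assert sites.equals(before)


class TestMetagene:
    def test_transcript_extremes(self, mrna_model):
        density, skipped = metagene(
            site_df([("TX0001", 0, "+", 5, 50)]), [mrna_model]
        )
        assert density[0] == 1.0 and skipped == 0  # first 5'UTR base -> bin 1
        density, _ = metagene(site_df([("TX0001", 999, "+", 5, 50)]), [mrna_model])
        assert density[19] == 1.0  # last 3'UTR base -> bin 20

    def test_cds_midpoint_bin(self, mrna_model):
        # CDS fraction (450-150)/600 = 0.5 -> bin 6 + floor(0.5*12) = 12
        density, _ = metagene(site_df([("TX0001", 450, "+", 5, 50)]), [mrna_model])
        assert density[11] == 1.0

    def test_density_normalised(self, mrna_model):
        sites = site_df([("TX0001", p, "+", 5, 50) for p in (0, 10, 400, 500, 900)])
        density, skipped = metagene(sites, [mrna_model])
        assert density.sum() == pytest.approx(1.0, abs=1e-12)
        assert skipped == 0

    def test_missing_region_skipped(self):
        noncoding = GeneModel("G3", "G3.1", "TX0003", "+", exons=[(0, 500)])
        density, skipped = metagene(site_df([("TX0003", 10, "+", 5, 50)]), [noncoding])
        assert skipped == 1 and density.sum() == 0


class TestMotif:
    def test_one_hot_flank_and_center(self):
        ref = {"TX0001": "AAAAAAAAAA" + "ACGTACGTAG" + "C" + "GGGTACGTAC" + "AAAAAAAAAA"}
        mat, score = motif_matrix(site_df([("TX0001", 20, "+", 5, 50)]), ref, flank=10)
        m = mat.set_index("offset")
        assert m.loc[0, "C"] == 1.0
        assert m.loc[1, "G"] == 1.0 and m.loc[2, "G"] == 1.0 and m.loc[3, "G"] == 1.0
        assert m.loc[-1, "G"] == 1.0  # last base of upstream flank
        assert score > 1.0

    def test_out_of_bounds_site_skipped(self):
        ref = {"TX0001": "ACGTC"}
        mat, _ = motif_matrix(site_df([("TX0001", 2, "+", 5, 50)]), ref, flank=10)
        assert mat[list("ACGT")].isna().all().all()

    def test_planted_ggg_context_enriched(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        # plant C followed by GGG at spaced positions
        seq = list(seq)
        positions = list(range(100, 1900, 100))
        for p in positions:
            seq[p] = "C"
            seq[p + 1 : p + 4] = ["G", "G", "G"]
        ref = {"TX0001": "".join(seq)}
        sites = site_df([("TX0001", p, "+", 5, 50) for p in positions])
        mat, score = motif_matrix(sites, ref)
        m = mat.set_index("offset")
        assert m.loc[1, "G"] == 1.0 and m.loc[3, "G"] == 1.0
        assert score > 2.0


class TestCpm:
    def test_single_gene_normalisation(self, mrna_model):
        reads = [make_read("A" * 50, start=100 + k, name=f"r{k}") for k in range(10)]
        out = gene_cpm(reads, [mrna_model])
        assert out.loc[0, "count"] == 10 and out.loc[0, "cpm"] == pytest.approx(1e6)

    def test_ambiguous_read_unassigned(self, mrna_model):
        other = GeneModel("G2", "G2.1", "TX0001", "+", exons=[(0, 1000)])
        reads = [make_read("A" * 50, start=100)]
        out = gene_cpm(reads, [mrna_model, other])
        assert out["count"].sum() == 0

    def test_cpm_sums_to_million(self, mrna_model):
        g2 = GeneModel("G2", "G2.1", "TX0002", "+", exons=[(0, 500)])
        reads = [make_read("A" * 50, start=k * 10, name=f"a{k}") for k in range(7)] + [
            make_read("A" * 50, start=k * 10, ref="TX0002", name=f"b{k}") for k in range(3)
        ]
        out = gene_cpm(reads, [mrna_model, g2])
        assert out["cpm"].sum() == pytest.approx(1e6)

    def test_uniform_duplication_log2fc(self, mrna_model):
        g2 = GeneModel("G2", "G2.1", "TX0002", "+", exons=[(0, 500)])
        unique = [make_read("A" * 50, start=k * 9, name=f"a{k}") for k in range(5)] + [
            make_read("A" * 50, start=k * 9, ref="TX0002", name=f"b{k}") for k in range(5)
        ]
        doubled = unique + [
            make_read(r.seq, start=r.start, ref=r.ref, name=r.name + "_dup") for r in unique
        ]
        out = cpm_with_without_dedup(doubled, unique, [mrna_model, g2])
        # uniform 2x duplication: CPM unchanged, counts halve
        assert np.allclose(out["log2fc"], 0.0)
        assert (out["count_all"] == 2 * out["count_dedup"]).all()


class TestCompareLibraries:
    def test_identical_tables(self):
        a = site_df(
            [("TX", 1, "+", 5, 50), ("TX", 2, "+", 10, 40), ("TX", 3, "+", 20, 30)]
        )
        shared, summary = compare_libraries(a, a.copy())
        assert summary["n_shared"] == 3
        assert summary["spearman_rho"] == pytest.approx(1.0)
        assert (shared["fisher_p"] == 1.0).all()
        assert summary["n_dms"] == 0

    def test_fisher_matches_hypergeometric_oracle(self):
        a = site_df([("TX", 1, "+", 10, 20)])
        b = site_df([("TX", 1, "+", 0, 20)])
        shared, _ = compare_libraries(a, b)
        # two-sided Fisher: sum over the hypergeometric support of all
        # outcomes no more probable than the observed table
        # margins: 10 candidate bases among 40 observations, 20 drawn by
        # library a; a's candidate count follows hypergeom(40, 10, 20)
        rv = sps.hypergeom(40, 10, 20)
        p_obs = rv.pmf(10)
        oracle = sum(rv.pmf(k) for k in range(11) if rv.pmf(k) <= p_obs * (1 + 1e-12))
        assert shared.loc[0, "fisher_p"] == pytest.approx(oracle, rel=1e-9)

    def test_disjoint_tables_warn(self):
        a = site_df([("TX", 1, "+", 5, 50)])
        b = site_df([("TX", 2, "+", 5, 50)])
        with pytest.warns(UserWarning, match="no shared sites"):
            shared, summary = compare_libraries(a, b)
        assert summary["n_shared"] == 0 and len(shared) == 0
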