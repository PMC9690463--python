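"""Distribution/overlap/classification reports and gene-interval overlap."""

import numpy as np
import pandas as pd
import pytest

from metaqtl.meta import MQTL
from metaqtl.reporting import (
    GeneFeature,
    classify_mqtls,
    cm_to_bp,
    distribution_table,
    genes_in_mqtl,
    load_published_distribution,
    load_published_mqtl_summary,
    load_published_overlap,
    overlap_table,
    read_gff3_genes,
    tier_counts,
)

from test_meta import make_projected
from metaqtl.meta import fit_mixture, extract_mqtls


def make_mqtl(mqtl_id="MQTL1.1", chromosome="1H", peak=50.0, members=None,
              stress_counts=None, meta_r2=0.1):
    members = members or ["q0"]
    stress_counts = stress_counts or {"drought": len(members)}
    return MQTL(mqtl_id=mqtl_id, chromosome=chromosome, peak_cm=peak,
                ci95_lo_cm=peak - 2, ci95_hi_cm=peak + 2, members=members,
                stress_counts=stress_counts, meta_r2=meta_r2, meta_r2_max=meta_r2)


class TestDistributionTable:
    def test_totals_from_objects(self):
        proj = make_projected([10.0] * 3 + [60.0] * 2, [2.0] * 5,
                              stresses=["drought"] * 3 + ["salinity"] * 2)
        fit = fit_mixture([p.consensus_peak_cm for p in proj], [2.0] * 5, K=2)
        mqtls, _ = extract_mqtls(fit, proj, "1H")
        table = distribution_table(proj, mqtls)
        assert table.qtl_total() == 5
        assert table.mqtl_total() == len(mqtls)
        assert table.qtls.loc["1H", "drought"] == 3

    def test_empty_inputs_give_zero_tables(self):
        table = distribution_table([], [])
        assert table.qtl_total() == 0 and table.mqtl_total() == 0

    def test_input_order_invariance(self):
        proj = make_projected([10.0, 11.0, 60.0], [2.0] * 3,
                              stresses=["drought", "salinity", "mineral"])
        mq = make_mqtl(members=[p.qtl_id for p in proj],
                       stress_counts={"drought": 1, "salinity": 1, "mineral": 1})
        t1 = distribution_table(proj, [mq])
        t2 = distribution_table(proj[::-1], [mq])
        pd.testing.assert_frame_equal(t1.qtls, t2.qtls)


class TestPublishedFixtures:
    def test_distribution_margins(self):
        dist = load_published_distribution()
        assert dist.qtl_total() == 585
        assert dist.mqtl_total() == 128
        assert dist.qtl_by_stress()["salinity"] == 206
        assert dist.qtl_by_chromosome()["2H"] == 120
        assert dist.mqtl_by_chromosome()["2H"] == 23
        assert dist.mqtl_by_stress()["salinity"] == 44

    def test_overlap_membership_sums(self):
        overlap = load_published_overlap()
        assert overlap.loc["MQTL6.3", "total"] == 38
        assert overlap.loc["MQTL4.8", "total"] == 36
        assert overlap.loc["MQTL4.8", "n_stresses"] == 5
        assert overlap.loc["MQTL1.2", "total"] == 14
        assert overlap.loc["MQTL7.6", "total"] == 12
        # single-stress salinity-only loci called out in the study
        for mqtl_id in ["MQTL2.9", "MQTL4.1", "MQTL5.1", "MQTL5.3", "MQTL7.5"]:
            assert overlap.loc[mqtl_id, "n_stresses"] == 1
            assert overlap.loc[mqtl_id, "salinity"] == overlap.loc[mqtl_id, "total"]

    def test_summary_tier_counts(self):
        summary = load_published_mqtl_summary()
        tiers = tier_counts(classify_mqtls(summary["r2_meta"].to_dict()))
        assert tiers["mega"] == 3
        assert tiers["major"] == 8


class TestOverlapTable:
    def test_row_sums_equal_membership(self):
        mq = make_mqtl(members=[f"q{i}" for i in range(7)],
                       stress_counts={"drought": 4, "salinity": 3})
        table = overlap_table([mq])
        assert table.loc["MQTL1.1", "total"] == 7
        assert table.loc["MQTL1.1", "n_stresses"] == 2

    def test_single_member_single_stress(self):
        table = overlap_table([make_mqtl()])
        assert table.loc["MQTL1.1", "total"] == 1
        assert table.loc["MQTL1.1", "n_stresses"] == 1


class TestClassify:
    def test_boundaries_are_exclusive_above(self):
        got = {c.mqtl_id: c.tier for c in classify_mqtls(
            {"a": 0.30, "b": 0.31, "c": 0.20, "d": 0.21, "e": 0.05})}
        assert got == {"a": "major", "b": "mega", "c": "ordinary",
                       "d": "major", "e": "ordinary"}

    def test_all_small_r2(self):
        tiers = tier_counts(classify_mqtls({"a": 0.05, "b": 0.05}))
        assert tiers == {"ordinary": 2, "major": 0, "mega": 0}

    def test_missing_r2_warns_and_is_ordinary(self):
        (c,) = classify_mqtls({"a": float("nan")})
        assert c.tier == "ordinary" and c.warning == "missing r2"

    def test_tiers_partition(self):
        rng = np.random.default_rng(3)
        r2s = {f"m{i}": float(r) for i, r in enumerate(rng.uniform(0, 0.6, 40))}
        cls = classify_mqtls(r2s)
        assert len(cls) == 40
        assert sum(tier_counts(cls).values()) == 40


class TestGenesInMQTL:
    @pytest.fixture
    def anchors(self):
        return pd.DataFrame({
            "marker": ["a", "b", "c"],
            "chromosome": ["1H"] * 3,
            "cm": [0.0, 50.0, 100.0],
            "bp": [0.0, 5e7, 1e8],
        })

    def test_linear_anchor_interpolation(self, anchors):
        bp, extrapolated = cm_to_bp(25.0, anchors, "1H")
        assert bp == pytest.approx(2.5e7)
        assert not extrapolated

    def test_gene_selection_by_hand(self, anchors):
        genes = [GeneFeature(f"g{i}", "1H", i * 10**7 + 1, i * 10**7 + 5000)
                 for i in range(10)]
        mq = make_mqtl(peak=30.0)
        mq = MQTL(**{**mq.__dict__, "ci95_lo_cm": 10.0, "ci95_hi_cm": 40.0})
        hits, extrapolated = genes_in_mqtl(mq, anchors, genes)
        # bp interval [1e7, 4e7]: g1 (1e7+1) through g3 overlap; g4 starts
        # one bp past the closed upper bound
        assert [g.gene_id for g in hits] == ["g1", "g2", "g3"]
        assert not extrapolated

    def test_boundary_gene_included(self, anchors):
        gene = GeneFeature("edge", "1H", int(4e7), int(4e7))  # abuts hi bound
        mq = MQTL(**{**make_mqtl().__dict__, "ci95_lo_cm": 10.0, "ci95_hi_cm": 40.0})
        hits, _ = genes_in_mqtl(mq, anchors, [gene])
        assert [g.gene_id for g in hits] == ["edge"]

    def test_enlarging_ci_never_removes_genes(self, anchors, rng):
        genes = [GeneFeature(f"g{i}", "1H", int(s), int(s) + 4999)
                 for i, s in enumerate(np.sort(rng.uniform(0, 9e7, 25)))]
        base = MQTL(**{**make_mqtl().__dict__, "ci95_lo_cm": 30.0, "ci95_hi_cm": 50.0})
        wide = MQTL(**{**make_mqtl().__dict__, "ci95_lo_cm": 20.0, "ci95_hi_cm": 70.0})
        small, _ = genes_in_mqtl(base, anchors, genes)
        large, _ = genes_in_mqtl(wide, anchors, genes)
        assert {g.gene_id for g in small} <= {g.gene_id for g in large}

    def test_gff3_reader(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1H\tsrc\tgene\t100\t500\t.\t+\t.\tID=geneA\n"
            "1H\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=geneA.1;Parent=geneA\n"
            "2H\tsrc\tgene\t900\t1500\t.\t-\t.\tID=geneB\n"
        )
        genes = read_gff3_genes(gff)
        assert [(g.gene_id, g.chromosome, g.start_bp, g.end_bp) for g in genes] == [
            ("geneA", "1H", 100, 500), ("geneB", "2H", 900, 1500)]
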