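"""CTSS aggregation, window counting, normalisation and signal metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cagecompare import (
    CountMatrix,
    CTSSTable,
    ExpressionProfile,
    GeneModel,
    ReadSet,
    platform_preset,
    simulate_cage,
    simulate_rnaseq,
)
from cagecompare.quantify import (
    assign_ctss_to_genes,
    count_ctss,
    gene_counts_cage,
    gene_counts_rnaseq,
    normalize,
    signal_metrics,
    tss_distance_profile,
)

from conftest import null_platform, single_gene_setup


def _cage_readset(rows, sample="s"):
    df = pd.DataFrame(
        rows, columns=["chrom", "strand", "pos5", "origin_gene"]
    )
    df["raw_leading_base"] = "A"
    df["shifted_by"] = 0
    df["g_added"] = False
    return ReadSet(sample, "cage", df)


def _gene(gene_id, tss, strand="+", length=600, chrom="chr1"):
    if strand == "+":
        exons = [(tss, tss + length)]
    else:
        exons = [(tss - length + 1, tss + 1)]
    return GeneModel(gene_id, chrom, strand, tss, exons)


class TestCountCtss:
    def test_aggregates_identical_positions(self):
        rs = _cage_readset([("chr1", "+", 100, "g1")] * 3)
        ctss = count_ctss(rs)
        assert len(ctss.table) == 1
        assert ctss.table.iloc[0]["count"] == 3

    def test_empty_readset(self):
        rs = ReadSet("s", "cage", pd.DataFrame())
        assert len(count_ctss(rs).table) == 0

    def test_conserves_totals_with_rrna(self, small_reference, flat_expression):
        genome, genes = small_reference
        platform = platform_preset("heliscope_cage")
        rs = simulate_cage(genome, genes, flat_expression, platform, 20_000, seed=1)
        ctss = count_ctss(rs)
        assert ctss.total + ctss.rrna_count == len(rs)

    def test_rejects_fragments(self):
        rs = ReadSet("s", "rnaseq", pd.DataFrame())
        with pytest.raises(ValueError):
            count_ctss(rs)


class TestWindowCounting:
    def test_closed_window_boundary(self):
        gene = _gene("g1", 5000)
        inside = CTSSTable("s", pd.DataFrame(
            [("chr1", 5500, "+", 2)], columns=["chrom", "pos", "strand", "count"]
        ))
        outside = CTSSTable("s", pd.DataFrame(
            [("chr1", 5501, "+", 2)], columns=["chrom", "pos", "strand", "count"]
        ))
        assert gene_counts_cage(inside, [gene]).counts.loc["g1", "s"] == 2
        assert gene_counts_cage(outside, [gene]).counts.loc["g1", "s"] == 0

    def test_equidistant_tie_goes_to_smaller_id(self):
        genes = [_gene("gB", 5000), _gene("gA", 5500)]
        ctss = CTSSTable("s", pd.DataFrame(
            [("chr1", 5250, "+", 7)], columns=["chrom", "pos", "strand", "count"]
        ))
        cm = gene_counts_cage(ctss, genes)
        assert cm.counts.loc["gA", "s"] == 7
        assert cm.counts.loc["gB", "s"] == 0

    def test_strand_must_match(self):
        gene = _gene("g1", 5000, strand="-")
        ctss = CTSSTable("s", pd.DataFrame(
            [("chr1", 5000, "+", 4)], columns=["chrom", "pos", "strand", "count"]
        ))
        assert gene_counts_cage(ctss, [gene]).counts.loc["g1", "s"] == 0

    def test_unbiased_sim_matches_truth_labels(self, small_reference, flat_expression):
        genome, genes = small_reference
        rs = simulate_cage(genome, genes, flat_expression, null_platform(),
                           30_000, seed=2)
        cm = gene_counts_cage(count_ctss(rs), genes)
        truth = rs.reads["origin_gene"].value_counts()
        for g in genes:
            assert cm.counts.loc[g.gene_id, "flat"] == truth.get(g.gene_id, 0)

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_agrees_with_per_read_nearest_tss_scan(self, data):
        n_genes = data.draw(st.integers(2, 5))
        tss_list = sorted(
            data.draw(
                st.lists(st.integers(1000, 9000), min_size=n_genes,
                         max_size=n_genes, unique=True)
            )
        )
        genes = [_gene(f"g{i}", t) for i, t in enumerate(tss_list)]
        positions = data.draw(
            st.lists(st.integers(500, 9500), min_size=1, max_size=60, unique=True)
        )
        tab = CTSSTable("s", pd.DataFrame(
            [("chr1", p, "+", 1) for p in positions],
            columns=["chrom", "pos", "strand", "count"],
        ))
        assigned = assign_ctss_to_genes(tab, genes, window=500)
        for pos, got in zip(tab.table["pos"], assigned):
            best = None
            for g in genes:
                d = abs(pos - g.tss)
                if d <= 500 and (best is None or (d, g.gene_id) < best):
                    best = (d, g.gene_id)
            assert got == (best[1] if best else None)

    def test_empty_gene_set_rejected(self):
        ctss = CTSSTable("s", pd.DataFrame())
        with pytest.raises(ValueError):
            gene_counts_cage(ctss, [])


class TestRnaseqCounting:
    def test_intronic_fragment_not_counted(self):
        gene = GeneModel("g1", "chr1", "+", 1000, [(1000, 1100), (1500, 1600)])
        df = pd.DataFrame(
            [("chr1", "+", 1200, 1235, "g1")],
            columns=["chrom", "strand", "start", "end", "origin_gene"],
        )
        cm = gene_counts_rnaseq(ReadSet("s", "rnaseq", df), [gene])
        assert cm.counts.loc["g1", "s"] == 0

    def test_single_base_overlap_counted(self):
        gene = GeneModel("g1", "chr1", "+", 1000, [(1000, 1100)])
        df = pd.DataFrame(
            [("chr1", "+", 1099, 1134, "g1"), ("chr1", "+", 1100, 1135, "g1")],
            columns=["chrom", "strand", "start", "end", "origin_gene"],
        )
        cm = gene_counts_rnaseq(ReadSet("s", "rnaseq", df), [gene])
        assert cm.counts.loc["g1", "s"] == 1

    def test_opposite_strand_counted_by_default(self):
        gene = GeneModel("g1", "chr1", "+", 1000, [(1000, 1100)])
        df = pd.DataFrame(
            [("chr1", "-", 1050, 1085, "g1")],
            columns=["chrom", "strand", "start", "end", "origin_gene"],
        )
        rs = ReadSet("s", "rnaseq", df)
        assert gene_counts_rnaseq(rs, [gene]).counts.loc["g1", "s"] == 1
        assert gene_counts_rnaseq(rs, [gene], stranded=True).counts.loc["g1", "s"] == 0

    def test_unbiased_sim_matches_truth_labels(self, small_reference, flat_expression):
        genome, genes = small_reference
        rs = simulate_rnaseq(genome, genes, flat_expression, null_platform(),
                             20_000, seed=3)
        cm = gene_counts_rnaseq(rs, genes)
        truth = rs.reads["origin_gene"].value_counts()
        for g in genes:
            if g.gene_class == "rrna":
                continue
            assert cm.counts.loc[g.gene_id, "flat"] == truth.get(g.gene_id, 0)

    def test_rejects_cage_input(self):
        rs = ReadSet("s", "cage", pd.DataFrame())
        with pytest.raises(ValueError):
            gene_counts_rnaseq(rs, [_gene("g1", 1000)])


class TestNormalize:
    def _cm(self, counts, libs, lengths=None):
        return CountMatrix(pd.DataFrame(counts), pd.Series(libs), lengths=lengths)

    def test_tpm_definition(self):
        cm = self._cm({"s": {"g1": 5}}, {"s": 1e6})
        assert normalize(cm, "tpm_tags").loc["g1", "s"] == 5.0

    def test_rpkm_definition(self):
        cm = self._cm({"s": {"g1": 100}}, {"s": 2e6},
                      lengths=pd.Series({"g1": 2000.0}))
        assert normalize(cm, "rpkm").loc["g1", "s"] == 25.0

    def test_zero_gene_stays_zero(self):
        cm = self._cm({"s": {"g1": 0}}, {"s": 1e6}, lengths=pd.Series({"g1": 500.0}))
        assert normalize(cm, "tpm_tags").loc["g1", "s"] == 0.0
        assert normalize(cm, "rpkm").loc["g1", "s"] == 0.0

    def test_rpkm_needs_lengths(self):
        cm = self._cm({"s": {"g1": 1}}, {"s": 1e6})
        with pytest.raises(ValueError):
            normalize(cm, "rpkm")

    def test_tpm_columns_sum_to_assigned_fraction(self, small_reference,
                                                  flat_expression):
        genome, genes = small_reference
        rs = simulate_cage(genome, genes, flat_expression, null_platform(),
                           10_000, seed=5)
        ctss = count_ctss(rs)
        cm = gene_counts_cage(ctss, genes)
        tpm = normalize(cm, "tpm_tags")
        assigned_fraction = cm.counts["flat"].sum() / ctss.total
        assert tpm["flat"].sum() == pytest.approx(1e6 * assigned_fraction)


class TestSignalMetrics:
    def test_unbiased_cage_promoter_rate_is_one(self, small_reference,
                                                flat_expression):
        genome, genes = small_reference
        rs = simulate_cage(genome, genes, flat_expression, null_platform(),
                           5000, seed=6)
        m = signal_metrics(rs, genes)
        assert m["promoter_rate"] == 1.0
        assert m["rrna_rate"] == 0.0

    def test_all_rrna_reads(self):
        df = pd.DataFrame(
            {
                "chrom": "chr1", "strand": "+", "pos5": [10, 11],
                "raw_leading_base": "A", "origin_gene": "rrna",
                "shifted_by": 0, "g_added": False,
            }
        )
        with pytest.warns(UserWarning):
            m = signal_metrics(ReadSet("s", "cage", df), [_gene("g1", 1000)])
        assert m["rrna_rate"] == 1.0
        assert m["promoter_rate"] == 0.0

    def test_empty_readset_rejected(self):
        with pytest.raises(ValueError):
            signal_metrics(ReadSet("s", "cage", pd.DataFrame()), [_gene("g1", 100)])

    def test_conservation_of_read_totals(self, small_reference, flat_expression):
        genome, genes = small_reference
        platform = platform_preset("illumina_cage")
        rs = simulate_cage(genome, genes, flat_expression, platform, 20_000, seed=7)
        ctss = count_ctss(rs)
        cm = gene_counts_cage(ctss, genes)
        assigned = cm.counts["flat"].sum()
        outside = ctss.total - assigned
        assert assigned + outside + ctss.rrna_count == len(rs)


class TestDistanceProfile:
    def test_unbiased_curve_saturates_at_zero(self, small_reference,
                                              flat_expression):
        genome, genes = small_reference
        rs = simulate_cage(genome, genes, flat_expression, null_platform(),
                           5000, seed=8)
        curve = tss_distance_profile(rs, genes, max_dist=20)
        assert curve.iloc[0] == 1.0

    def test_tstretch_curve_saturates_by_run_length(self, small_reference,
                                                    flat_expression):
        genome, genes = small_reference
        platform = null_platform(tstretch_shift_enabled=True, tstretch_min_run=4)
        rs = simulate_cage(genome, genes, flat_expression, platform, 5000, seed=9)
        curve = tss_distance_profile(rs, genes, max_dist=30)
        assert curve.loc[15] == 1.0
        assert curve.iloc[0] < 1.0

    def test_monotone_for_arbitrary_reads(self):
        rng = np.random.default_rng(0)
        rows = [("chr1", "+", int(p), "g1") for p in rng.integers(0, 5000, 200)]
        rs = _cage_readset(rows)
        curve = tss_distance_profile(rs, [_gene("g1", 2500)], max_dist=100)
        assert (np.diff(curve.to_numpy()) >= 0).all()
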