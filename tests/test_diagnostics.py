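"""Planted-bias recovery and identity nulls for every diagnostic."""

import numpy as np
import pandas as pd
import pytest

from cagecompare import (
    CTSSTable,
    ReferenceConfig,
    generate_reference,
    sample_expression,
    simulate_cage,
)
from cagecompare.diagnostics import (
    correlate_at_resolution,
    detect_tstretch_shifts,
    estimate_g_addition_rate,
    platform_specific_tss,
    relative_expression_by_ecop15i,
    relative_expression_by_gc,
    scan_ecop15i_context,
    smooth_ctss,
    start_base_activity,
)
from cagecompare.quantify import count_ctss, gene_counts_cage, normalize

from conftest import null_platform


@pytest.fixture(scope="module")
def reference():
    return generate_reference(ReferenceConfig(n_genes=200), seed=21)


@pytest.fixture(scope="module")
def expression(reference):
    _, genes = reference
    return sample_expression(genes, seed=22, log_sd=1.0, sample_id="x")


def _tpm(genome, genes, expr, platform, depth, seed):
    ctss = count_ctss(simulate_cage(genome, genes, expr, platform, depth, seed=seed))
    cm = gene_counts_cage(ctss, genes)
    return normalize(cm, "tpm_tags").iloc[:, 0], ctss


def _ctss(rows):
    return CTSSTable(
        "s", pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
    )


class TestIdentityNulls:
    """Every diagnostic must return an exact null on X == Y."""

    def test_gc_report_null(self, reference, expression):
        genome, genes = reference
        tpm, _ = _tpm(genome, genes, expression, null_platform(), 50_000, 1)
        gc = pd.Series({g.gene_id: g.promoter_gc for g in genes})
        rep = relative_expression_by_gc(tpm, tpm, gc)
        assert rep.slope == 0.0
        medians = rep.strata["median_log2"].dropna()
        assert (medians == 0).all()

    def test_ecop15i_report_null(self, reference, expression):
        genome, genes = reference
        tpm, _ = _tpm(genome, genes, expression, null_platform(), 50_000, 2)
        classes = scan_ecop15i_context(genes, genome)
        rep = relative_expression_by_ecop15i(tpm, tpm, classes)
        assert rep.difference == 0.0

    def test_start_base_null(self, reference, expression):
        genome, genes = reference
        _, ctss = _tpm(genome, genes, expression, null_platform(), 50_000, 3)
        _, medians = start_base_activity(ctss, ctss, genome)
        for med in medians.values():
            assert med == 0.0 or np.isnan(med)

    def test_tstretch_null_when_disabled(self, reference, expression):
        genome, genes = reference
        _, a = _tpm(genome, genes, expression, null_platform(), 50_000, 4)
        _, b = _tpm(genome, genes, expression, null_platform(), 50_000, 5)
        rep = detect_tstretch_shifts(a, b, genome)
        assert rep.n_shifted == 0

    def test_platform_specific_null(self, reference, expression):
        genome, genes = reference
        _, ctss = _tpm(genome, genes, expression, null_platform(), 50_000, 6)
        res = platform_specific_tss(ctss, ctss)
        assert res["x_only"] == set() and res["y_only"] == set()


class TestGcBias:
    def test_recovers_planted_slope(self, reference, expression):
        genome, genes = reference
        gc = pd.Series({g.gene_id: g.promoter_gc for g in genes})
        expected = -2.0 / np.log(2.0)
        slopes = []
        for seed in range(10):
            x, _ = _tpm(genome, genes, expression,
                        null_platform(gc_bias_coef=-2.0), 100_000, 100 + seed)
            y, _ = _tpm(genome, genes, expression, null_platform(),
                        100_000, 200 + seed)
            slopes.append(relative_expression_by_gc(x, y, gc).slope)
        assert abs(np.mean(slopes) - expected) / abs(expected) < 0.15

    def test_pcr_free_null_slope_small(self, reference, expression):
        genome, genes = reference
        gc = pd.Series({g.gene_id: g.promoter_gc for g in genes})
        x, _ = _tpm(genome, genes, expression, null_platform(), 100_000, 7)
        truth = expression.abundance / expression.abundance.sum() * 1e6
        rep = relative_expression_by_gc(x, truth, gc)
        assert abs(rep.slope) <= 0.2

    def test_needs_two_bins(self, expression):
        tpm = expression.abundance * 1e6
        with pytest.raises(ValueError):
            relative_expression_by_gc(tpm, tpm, tpm * 0 + 0.5, n_bins=1)


class TestEcoP15I:
    def test_context_classes_match_planted_offsets(self, reference):
        genome, genes = reference
        classes = scan_ecop15i_context(genes, genome)
        for g in genes:
            if not g.antisense_site_offsets:
                assert classes[g.gene_id] == "none"
            elif min(g.antisense_site_offsets) <= 400:
                assert classes[g.gene_id] == "antisense_le_max"
            else:
                assert classes[g.gene_id] == "antisense_gt_max"

    def test_recovers_planted_boost(self, reference, expression):
        genome, genes = reference
        classes = scan_ecop15i_context(genes, genome)
        diffs = []
        for seed in range(10):
            x, _ = _tpm(genome, genes, expression,
                        null_platform(ecop15i_boost=1.5), 100_000, 300 + seed)
            y, _ = _tpm(genome, genes, expression, null_platform(),
                        100_000, 400 + seed)
            diffs.append(relative_expression_by_ecop15i(x, y, classes).difference)
        assert abs(np.mean(diffs) - np.log2(1.5)) <= 0.15

    def test_unit_boost_gives_no_contrast(self, reference, expression):
        genome, genes = reference
        classes = scan_ecop15i_context(genes, genome)
        x, _ = _tpm(genome, genes, expression, null_platform(), 100_000, 8)
        y, _ = _tpm(genome, genes, expression, null_platform(), 100_000, 9)
        rep = relative_expression_by_ecop15i(x, y, classes)
        assert abs(rep.difference) <= 0.1


class TestStartBase:
    def test_recovers_linker_preference_ordering(self, reference, expression):
        genome, genes = reference
        weights = {"A": 1.0, "C": 0.6, "G": 1.3, "T": 1.0}
        x = null_platform(first_base_weights=weights)
        _, cx = _tpm(genome, genes, expression, x, 100_000, 10)
        _, cy = _tpm(genome, genes, expression, null_platform(), 100_000, 11)
        _, med = start_base_activity(cx, cy, genome, min_count=5)
        assert med["G"] > max(med["A"], med["T"])
        assert med["C"] < min(med["A"], med["T"])
        assert abs(med["A"] - med["T"]) < 0.2

    def test_disjoint_positions_warn(self, reference):
        genome, _ = reference
        a = _ctss([("chrS", 1000, "+", 9)])
        b = _ctss([("chrS", 5000, "+", 9)])
        with pytest.warns(UserWarning):
            table, med = start_base_activity(a, b, genome)
        assert table.empty


class TestTstretch:
    def test_exact_planted_recovery(self, reference):
        genome, genes = reference
        # flat expression so every gene clears the count threshold
        expr = sample_expression(genes, seed=30, log_sd=0.2, sample_id="flat")
        shifted = simulate_cage(
            genome, genes, expr,
            null_platform(tstretch_shift_enabled=True, tstretch_min_run=4),
            100_000, seed=31,
        )
        reference_reads = simulate_cage(genome, genes, expr, null_platform(),
                                        100_000, seed=32)
        rep = detect_tstretch_shifts(
            count_ctss(shifted), count_ctss(reference_reads), genome,
            min_run=4, min_count=5,
        )
        planted = {
            (g.chrom, g.tss, g.strand) for g in genes
            if g.tss_t_run >= 4 and g.gene_class != "rrna"
        }
        flagged = {
            (r["chrom"], r["pos"], r["strand"]) for _, r in rep.shifts.iterrows()
        }
        assert flagged == planted
        assert rep.fraction == rep.n_shifted / rep.n_examined

    def test_run_lengths_reported(self, reference):
        genome, genes = reference
        expr = sample_expression(genes, seed=30, log_sd=0.2, sample_id="flat")
        shifted = simulate_cage(
            genome, genes, expr,
            null_platform(tstretch_shift_enabled=True, tstretch_min_run=4),
            60_000, seed=33,
        )
        ref = simulate_cage(genome, genes, expr, null_platform(), 60_000, seed=34)
        rep = detect_tstretch_shifts(count_ctss(shifted), count_ctss(ref), genome)
        runs = {g.tss: g.tss_t_run for g in genes}
        for _, r in rep.shifts.iterrows():
            assert r["run_length"] == runs[r["pos"]]


class TestSmoothing:
    def test_zero_halfwidth_is_identity(self):
        ctss = _ctss([("chr1", 10, "+", 4), ("chr1", 12, "+", 2)])
        out = smooth_ctss(ctss, halfwidth=0)
        assert out["count"].tolist() == [4.0, 2.0]

    def test_isolated_peak_spreads_evenly(self):
        ctss = _ctss([("chr1", 10, "+", 3)])
        out = smooth_ctss(ctss, halfwidth=1).set_index("pos")["count"]
        assert out.loc[9] == out.loc[10] == out.loc[11] == 1.0

    def test_total_signal_conserved(self):
        ctss = _ctss([("chr1", 10, "+", 3), ("chr1", 30, "-", 7)])
        out = smooth_ctss(ctss, halfwidth=1)
        assert out["count"].sum() == pytest.approx(10.0)

    def test_smoothing_rescues_jittered_correlation(self, reference):
        genome, genes = reference
        expr = sample_expression(genes, seed=40, log_sd=1.0, sample_id="j")
        wins = 0
        for seed in range(20):
            a = count_ctss(simulate_cage(genome, genes, expr,
                                         null_platform(jitter_frac=0.5),
                                         30_000, seed=500 + seed))
            b = count_ctss(simulate_cage(genome, genes, expr,
                                         null_platform(jitter_frac=0.5),
                                         30_000, seed=600 + seed))
            rho_raw, rho_smooth = correlate_at_resolution(a, b)
            if rho_smooth > rho_raw:
                wins += 1
        assert wins >= 18


class TestPlatformSpecific:
    def test_count_exactly_ten_is_not_a_candidate(self):
        a = _ctss([("chr1", 100, "+", 10)])
        b = _ctss([("chr1", 200, "+", 1)])
        res = platform_specific_tss(a, b, min_count=10)
        assert res["x_only"] == set()

    def test_planted_exclusive_peak_unneighbored(self):
        a = _ctss([("chr1", 100, "+", 50), ("chr1", 900, "+", 50)])
        b = _ctss([("chr1", 900, "+", 50), ("chr1", 110, "+", 2)])
        res = platform_specific_tss(a, b, neighborhood_bp=20)
        assert ("chr1", 100, "+") in res["x_only"]
        assert ("chr1", 100, "+") in res["x_unneighbored"]

    def test_neighbored_peak_excluded(self):
        a = _ctss([("chr1", 100, "+", 50)])
        b = _ctss([("chr1", 110, "+", 3)])
        res = platform_specific_tss(a, b, neighborhood_bp=20)
        assert res["x_only"] == {("chr1", 100, "+")}
        assert res["x_unneighbored"] == set()


class TestGAddition:
    def test_forced_addition_rate_is_one(self, reference, expression):
        genome, genes = reference
        reads = simulate_cage(genome, genes, expression,
                              null_platform(g_add_prob=1.0), 20_000, seed=50)
        rate, n = estimate_g_addition_rate(reads, genome, genes)
        assert rate == 1.0
        assert n > 0

    def test_no_addition_rate_is_zero(self, reference, expression):
        genome, genes = reference
        reads = simulate_cage(genome, genes, expression, null_platform(),
                              20_000, seed=51)
        rate, _ = estimate_g_addition_rate(reads, genome, genes)
        assert rate == 0.0
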