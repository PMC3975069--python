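"""Platform-bias diagnostics.

Gene-level diagnostics compare two expression profiles (tags-per-million)
stratified by sequence context: promoter/exon GC content and the presence
of antisense-strand EcoP15I recognition sites near the TSS.  Single-base
diagnostics compare two CTSS tables: start-base activity ratios
(nontemplated-G / linker-preference artifacts), T-run downstream shifting
(fill-and-lock artifact), 3-base smoothing, and platform-exclusive TSS
calls.  Everything here *diagnoses* bias; nothing corrects counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .models import CTSSTable, GeneModel, ReadSet, SyntheticGenome
from .synth import scan_antisense_sites, tss_t_run_length

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class RelativeExpressionReport:
    """Per-stratum medians of log2(X/Y) plus optional slope/contrast."""

    strata: pd.DataFrame  # index: stratum label; n_genes, median_log2, iqr
    slope: float | None = None  # log2-ratio change per unit covariate
    difference: float | None = None  # focal-stratum minus reference-stratum median
    low_n_strata: list[str] = field(default_factory=list)


@dataclass
class TSSShiftReport:
    """Reference TSSs whose signal moved past a leading T run."""

    shifts: pd.DataFrame  # chrom, pos, strand, run_length, counts_before/after
    n_shifted: int
    n_examined: int

    @property
    def fraction(self) -> float:
        return self.n_shifted / self.n_examined if self.n_examined else 0.0


def _paired_log_ratio(
    expr_x: pd.Series, expr_y: pd.Series, pseudocount: float
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """log2 ratios over genes detected (> 0) in both profiles."""
    common = expr_x.index.intersection(expr_y.index)
    x = expr_x[common]
    y = expr_y[common]
    detected = (x > 0) & (y > 0)
    x, y = x[detected], y[detected]
    return x, y, np.log2(x + pseudocount) - np.log2(y + pseudocount)


def relative_expression_by_gc(
    expr_x: pd.Series,
    expr_y: pd.Series,
    gc_per_gene: pd.Series,
    n_bins: int = 10,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> RelativeExpressionReport:
    """Median log2(X/Y) in equal-width GC bins, plus a least-squares slope.

    A PCR-amplified platform X measured against a PCR-free reference Y
    shows a systematic trend of the ratio with GC; the fitted slope (in
    log2 units per unit GC fraction) quantifies it.  With the simulator's
    natural-log GC coefficient ``b`` planted on X only, the expected slope
    is ``b / ln 2``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x, y, ratio = _paired_log_ratio(expr_x, expr_y, pseudocount)
    gc = pd.Series(gc_per_gene, dtype=float)[ratio.index]
    lo, hi = float(gc.min()), float(gc.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(gc.to_numpy(), edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        vals = ratio.to_numpy()[which == b]
        label = f"[{edges[b]:.3f},{edges[b + 1]:.3f})"
        if len(vals) == 0:
            rows.append((label, 0, np.nan, np.nan))
        else:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append((label, len(vals), med, q3 - q1))
    strata = pd.DataFrame(
        rows, columns=["stratum", "n_genes", "median_log2", "iqr"]
    ).set_index("stratum")
    if gc.nunique() > 1:
        slope = float(np.polyfit(gc.to_numpy(), ratio.to_numpy(), 1)[0])
    else:
        slope = 0.0
    return RelativeExpressionReport(strata=strata, slope=slope)


def scan_ecop15i_context(
    genes: list[GeneModel],
    genome: SyntheticGenome,
    max_dist: int = 400,
    scan_range: int = 800,
) -> pd.Series:
    """Classify genes by the nearest downstream antisense EcoP15I site.

    Scans the sense strand 0..``scan_range`` bp downstream of each TSS
    for CTGCTG (an antisense-strand CAGCAG); the class is ``none``,
    ``antisense_le_max`` (minimal offset <= ``max_dist``) or
    ``antisense_gt_max``.  A TSS too close to the contig end for a full
    scan is flagged with a warning.
    """
    classes = {}
    for g in genes:
        if g.chrom not in genome:
            raise KeyError(f"genome lacks {g.chrom}")
        clen = len(genome.chromosomes[g.chrom])
        room = clen - g.tss if g.strand == "+" else g.tss + 1
        if room < scan_range + 6:
            warnings.warn(f"{g.gene_id}: partial EcoP15I scan ({room} bp available)")
        offsets = scan_antisense_sites(genome, g.chrom, g.tss, g.strand, scan_range)
        if not offsets:
            classes[g.gene_id] = "none"
        elif min(offsets) <= max_dist:
            classes[g.gene_id] = "antisense_le_max"
        else:
            classes[g.gene_id] = "antisense_gt_max"
    return pd.Series(classes, name="ecop15i_class")


def relative_expression_by_ecop15i(
    expr_x: pd.Series,
    expr_y: pd.Series,
    classes: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_stratum_n: int = 10,
) -> RelativeExpressionReport:
    """Median log2(X/Y) per EcoP15I class and the le_max-minus-none contrast.

    An extra internal cleavage opportunity inflates tag yield on the PCR
    CAGE platform, so genes with a near antisense site are overestimated:
    with a planted boost ``k`` the contrast approaches ``log2 k``.
    """
    _, _, ratio = _paired_log_ratio(expr_x, expr_y, pseudocount)
    cls = pd.Series(classes)[ratio.index]
    rows, low_n = [], []
    for label in ("none", "antisense_le_max", "antisense_gt_max"):
        vals = ratio[cls == label].to_numpy()
        if len(vals) == 0:
            rows.append((label, 0, np.nan, np.nan))
            low_n.append(label)
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append((label, len(vals), med, q3 - q1))
        if len(vals) < min_stratum_n:
            low_n.append(label)
    strata = pd.DataFrame(
        rows, columns=["stratum", "n_genes", "median_log2", "iqr"]
    ).set_index("stratum")
    diff = strata.loc["antisense_le_max", "median_log2"] - strata.loc["none", "median_log2"]
    return RelativeExpressionReport(strata=strata, difference=float(diff), low_n_strata=low_n)


def _tpm_by_key(ctss: CTSSTable) -> pd.Series:
    total = ctss.total
    return ctss.counts_by_key() / total * 1e6


def start_base_activity(
    ctss_x: CTSSTable,
    ctss_y: CTSSTable,
    genome: SyntheticGenome,
    min_count: int = 5,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-start-base distribution of log2 TPM ratios at shared positions.

    Positions with at least ``min_count`` tags in both samples are kept;
    the base is the genomic base at the position read on the CTSS strand.
    Returns the per-position table and the per-base median summary.
    """
    kx = ctss_x.counts_by_key()
    ky = ctss_y.counts_by_key()
    shared = kx.index[kx >= min_count].intersection(ky.index[ky >= min_count])
    if len(shared) == 0:
        warnings.warn("no shared positions at the requested count threshold")
        return (
            pd.DataFrame(columns=["base", "log2_ratio"]),
            {b: float("nan") for b in "ACGT"},
        )
    tx = _tpm_by_key(ctss_x)[shared]
    ty = _tpm_by_key(ctss_y)[shared]
    bases = [genome.sense_base(c, p, s) for c, p, s in shared]
    table = pd.DataFrame(
        {"base": bases, "log2_ratio": np.log2(tx.to_numpy() / ty.to_numpy())},
        index=shared,
    )
    medians = {
        b: float(table.loc[table["base"] == b, "log2_ratio"].median())
        for b in "ACGT"
    }
    return table, medians


def detect_tstretch_shifts(
    ctss_shifted: CTSSTable,
    ctss_reference: CTSSTable,
    genome: SyntheticGenome,
    min_run: int = 4,
    min_count: int = 5,
) -> TSSShiftReport:
    """Find reference TSSs displaced past a leading T run in the other table.

    A reference position with ``>= min_count`` tags whose sense-strand
    sequence starts with a T run of length ``L >= min_run`` is flagged
    when the shifted table has ``>= min_count`` tags at the strand-aware
    position L bp downstream but fewer than ``min_count`` at the position
    itself.  ``n_examined`` counts all reference positions above the
    count threshold.
    """
    ref = ctss_reference.table
    examined = ref[ref["count"] >= min_count]
    shifted_counts = ctss_shifted.counts_by_key()
    rows = []
    for _, row in examined.iterrows():
        chrom, pos, strand = row["chrom"], int(row["pos"]), row["strand"]
        run = tss_t_run_length(genome, chrom, pos, strand)
        if run < min_run:
            continue
        downstream = pos + run if strand == "+" else pos - run
        after = int(shifted_counts.get((chrom, downstream, strand), 0))
        before = int(shifted_counts.get((chrom, pos, strand), 0))
        if after >= min_count and before < min_count:
            rows.append((chrom, pos, strand, run, before, after))
    shifts = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "run_length", "counts_before", "counts_after"],
    )
    return TSSShiftReport(shifts=shifts, n_shifted=len(shifts), n_examined=len(examined))


def smooth_ctss(ctss: CTSSTable, halfwidth: int = 1) -> pd.DataFrame:
    """Moving-average CTSS signal: value at p = mean over [p-h, p+h].

    Absent positions count as zero, so smoothing spreads an isolated peak
    of c tags into 2h+1 positions of c/(2h+1) each (total conserved).
    Returns a float-valued table (chrom, pos, strand, count).
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    if halfwidth == 0:
        return ctss.table.astype({"count": float})
    width = 2 * halfwidth + 1
    acc: dict[tuple, float] = {}
    for _, row in ctss.table.iterrows():
        share = row["count"] / width
        for off in range(-halfwidth, halfwidth + 1):
            key = (row["chrom"], int(row["pos"]) + off, row["strand"])
            acc[key] = acc.get(key, 0.0) + share
    out = pd.DataFrame(
        [(c, p, s, v) for (c, p, s), v in acc.items()],
        columns=["chrom", "pos", "strand", "count"],
    )
    return out.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def _spearman_shared(a: pd.Series, b: pd.Series) -> float:
    shared = a.index.intersection(b.index)
    if len(shared) < 2:
        return float("nan")
    return float(spearmanr(a[shared].to_numpy(), b[shared].to_numpy()).statistic)


def correlate_at_resolution(
    ctss_x: CTSSTable, ctss_y: CTSSTable, halfwidth: int = 1
) -> tuple[float, float]:
    """Spearman over shared nonzero positions, raw and after smoothing.

    Sub-base-pair disagreements (1 bp jitter between platforms) depress
    the raw single-base correlation; averaging over 2h+1 bases restores
    it.
    """
    raw = _spearman_shared(ctss_x.counts_by_key(), ctss_y.counts_by_key())
    sx = smooth_ctss(ctss_x, halfwidth).set_index(["chrom", "pos", "strand"])["count"]
    sy = smooth_ctss(ctss_y, halfwidth).set_index(["chrom", "pos", "strand"])["count"]
    return raw, _spearman_shared(sx, sy)


def platform_specific_tss(
    ctss_x: CTSSTable,
    ctss_y: CTSSTable,
    min_count: int = 10,
    neighbor_count: int = 3,
    neighborhood_bp: int = 20,
) -> dict[str, set]:
    """Partition strong TSS calls into shared and platform-exclusive sets.

    A candidate has *more than* ``min_count`` tags in at least one table
    (strictly greater).  ``x_only`` candidates exceed the threshold in X
    but not Y; ``x_unneighbored`` further lack any Y position with
    ``>= neighbor_count`` tags within ``+/- neighborhood_bp`` on the same
    strand (the truly platform-specific calls).
    """
    kx = ctss_x.counts_by_key()
    ky = ctss_y.counts_by_key()
    keys = kx.index.union(ky.index)
    cx = kx.reindex(keys, fill_value=0)
    cy = ky.reindex(keys, fill_value=0)
    cand = (cx > min_count) | (cy > min_count)
    x_only = set(keys[(cx > min_count) & (cy <= min_count)])
    y_only = set(keys[(cy > min_count) & (cx <= min_count)])
    shared = set(keys[cand]) - x_only - y_only

    def unneighbored(only: set, other: pd.Series) -> set:
        strong = other[other >= neighbor_count]
        by_cs: dict[tuple, np.ndarray] = {}
        for (c, p, s) in strong.index:
            by_cs.setdefault((c, s), []).append(p)
        by_cs = {k: np.sort(v) for k, v in by_cs.items()}
        out = set()
        for c, p, s in only:
            arr = by_cs.get((c, s))
            if arr is None:
                out.add((c, p, s))
                continue
            lo = np.searchsorted(arr, p - neighborhood_bp)
            hi = np.searchsorted(arr, p + neighborhood_bp, side="right")
            if lo >= hi:
                out.add((c, p, s))
        return out

    return {
        "x_only": x_only,
        "y_only": y_only,
        "shared": shared,
        "x_unneighbored": unneighbored(x_only, ky),
        "y_unneighbored": unneighbored(y_only, kx),
    }


def estimate_g_addition_rate(
    reads: ReadSet, genome: SyntheticGenome, genes: list[GeneModel]
) -> tuple[float, int]:
    """Estimate the nontemplated 5' G-addition probability from raw tags.

    Restricted to tags from genes whose TSS base and strand-aware upstream
    base are both non-G: there a raw leading G can only be nontemplated,
    so the fraction of G-leading tags estimates the addition rate
    directly.  Returns (rate, number of informative tags).
    """
    if reads.kind != "cage":
        raise ValueError("requires CAGE reads")
    informative = []
    for g in genes:
        if g.gene_class == "rrna":
            continue
        tss_base = genome.sense_base(g.chrom, g.tss, g.strand)
        up = g.tss - 1 if g.strand == "+" else g.tss + 1
        up_base = genome.sense_base(g.chrom, up, g.strand)
        if tss_base != "G" and up_base != "G":
            informative.append(g.gene_id)
    df = reads.non_rrna
    sub = df[df["origin_gene"].isin(informative)]
    if len(sub) == 0:
        raise ValueError("no informative tags for G-addition estimation")
    rate = float((sub["raw_leading_base"] == "G").mean())
    return rate, len(sub)
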