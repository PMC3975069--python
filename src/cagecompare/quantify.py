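"""CTSS tables, gene-level counting and normalisation.

CAGE tags are aggregated at single-base resolution and assigned to genes
by a closed +/-500 bp window around each annotated TSS (the distance at
which the promoter signal ratio saturates); positions falling inside
several windows go to the nearest TSS, ties to the lexicographically
smallest gene id.  RNA-seq fragments count for a gene when they overlap
any of its exons by at least one base.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .models import CountMatrix, CTSSTable, GeneModel, ReadSet

__all__ = [
    "CTSSTable",
    "CountMatrix",
    "count_ctss",
    "gene_counts_cage",
    "gene_counts_rnaseq",
    "normalize",
    "signal_metrics",
    "tss_distance_profile",
]

DEFAULT_WINDOW = 500


def count_ctss(reads: ReadSet) -> CTSSTable:
    """Aggregate CAGE reads to (chrom, pos, strand) counts.

    Ribosomal-labelled reads are excluded from the table and reported via
    ``rrna_count``, so ``table total + rrna_count == len(reads)``.
    """
    if reads.kind != "cage":
        raise ValueError("count_ctss requires CAGE-type reads")
    rr = reads.rrna_count
    df = reads.non_rrna
    if len(df) == 0:
        return CTSSTable(reads.sample_id, pd.DataFrame(), rrna_count=rr)
    tab = (
        df.groupby(["chrom", "pos5", "strand"], sort=True)
        .size()
        .rename("count")
        .reset_index()
        .rename(columns={"pos5": "pos"})
    )
    return CTSSTable(reads.sample_id, tab, rrna_count=rr)


def _nearest_tss_assignment(
    positions: np.ndarray, tss_sorted: np.ndarray, ids_sorted: np.ndarray, window: int
) -> np.ndarray:
    """Assign each position to the nearest TSS within ``window`` (ties ->
    smallest gene id); returns an object array with None for unassigned."""
    out = np.full(len(positions), None, dtype=object)
    if len(tss_sorted) == 0:
        return out
    los = np.searchsorted(tss_sorted, positions - window, side="left")
    his = np.searchsorted(tss_sorted, positions + window, side="right")
    for k, pos in enumerate(positions):
        best_d, best_id = None, None
        for j in range(los[k], his[k]):
            d = abs(int(pos) - int(tss_sorted[j]))
            if d <= window and (
                best_d is None or d < best_d or (d == best_d and ids_sorted[j] < best_id)
            ):
                best_d, best_id = d, ids_sorted[j]
        out[k] = best_id
    return out


def assign_ctss_to_genes(
    ctss: CTSSTable, genes: list[GeneModel], window: int = DEFAULT_WINDOW
) -> pd.Series:
    """Per-CTSS-row gene assignment (None when outside every window)."""
    if window <= 0:
        raise ValueError("window must be positive")
    if not genes:
        raise ValueError("empty gene set")
    tab = ctss.table
    assigned = np.full(len(tab), None, dtype=object)
    for (chrom, strand), sub in tab.groupby(["chrom", "strand"], sort=False):
        cand = sorted(
            ((g.tss, g.gene_id) for g in genes if g.chrom == chrom and g.strand == strand)
        )
        tss_sorted = np.array([t for t, _ in cand], dtype=int)
        ids_sorted = np.array([gid for _, gid in cand], dtype=object)
        assigned[sub.index.to_numpy()] = _nearest_tss_assignment(
            sub["pos"].to_numpy(), tss_sorted, ids_sorted, window
        )
    return pd.Series(assigned, index=tab.index)


def gene_counts_cage(
    tables: CTSSTable | list[CTSSTable],
    genes: list[GeneModel],
    window: int = DEFAULT_WINDOW,
) -> CountMatrix:
    """Gene x sample CAGE counts via the TSS-window rule.

    Library size per sample is the total of mapped non-ribosomal tags
    (assigned or not), so TPM columns sum to 1e6 times the assigned
    fraction.
    """
    if isinstance(tables, CTSSTable):
        tables = [tables]
    gene_ids = [g.gene_id for g in genes]
    counts = {}
    libsizes = {}
    for ctss in tables:
        assigned = assign_ctss_to_genes(ctss, genes, window)
        col = pd.Series(0, index=gene_ids, dtype=int)
        mask = assigned.notna()
        if mask.any():
            sums = ctss.table.loc[mask, "count"].groupby(assigned[mask]).sum()
            col.loc[sums.index] = sums.astype(int)
        counts[ctss.sample_id] = col
        libsizes[ctss.sample_id] = ctss.total
    lengths = pd.Series({g.gene_id: g.exonic_length for g in genes}, dtype=float)
    return CountMatrix(pd.DataFrame(counts), pd.Series(libsizes), lengths=lengths)


def _assign_fragments(reads: ReadSet, genes: list[GeneModel], stranded: bool) -> pd.Series:
    """Per-fragment gene assignment by >=1 bp exon overlap.

    Multi-gene overlaps resolve to the gene whose nearest overlapping
    exon start is closest to the fragment start, then smallest gene id.
    """
    df = reads.non_rrna
    out = np.full(len(df), None, dtype=object)
    exons: dict[str, list[tuple[int, int, str, str]]] = {}
    for g in genes:
        for s, e in g.exons:
            exons.setdefault(g.chrom, []).append((s, e, g.gene_id, g.strand))
    for chrom, recs in exons.items():
        recs.sort()
    for (chrom, strand), sub in df.groupby(["chrom", "strand"], sort=False):
        recs = exons.get(chrom)
        if not recs:
            continue
        S = np.array([r[0] for r in recs])
        E = np.array([r[1] for r in recs])
        max_end = np.maximum.accumulate(E)  # scan bound for overlap search
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        hi = np.searchsorted(S, ends, side="left")  # exons with s < frag end
        res = np.full(len(sub), None, dtype=object)
        for k in range(len(sub)):
            best = None  # (|frag start - exon start|, gene_id)
            j = hi[k] - 1
            while j >= 0 and max_end[j] > starts[k]:
                s, e, gid, gstrand = recs[j]
                if e > starts[k] and not (stranded and gstrand != strand):
                    d = abs(int(starts[k]) - s)
                    if best is None or (d, gid) < best:
                        best = (d, gid)
                j -= 1
            if best is not None:
                res[k] = best[1]
        out[np.searchsorted(df.index.to_numpy(), sub.index.to_numpy())] = res
    return pd.Series(out, index=df.index)


def gene_counts_rnaseq(
    read_sets: ReadSet | list[ReadSet],
    genes: list[GeneModel],
    stranded: bool = False,
) -> CountMatrix:
    """Gene x sample RNA-seq counts by exon overlap (unstranded default)."""
    if isinstance(read_sets, ReadSet):
        read_sets = [read_sets]
    if not genes:
        raise ValueError("empty gene set")
    gene_ids = [g.gene_id for g in genes]
    counts = {}
    libsizes = {}
    for rs in read_sets:
        if rs.kind != "rnaseq":
            raise ValueError("gene_counts_rnaseq requires fragment-type reads")
        assigned = _assign_fragments(rs, genes, stranded)
        col = pd.Series(0, index=gene_ids, dtype=int)
        vc = assigned.dropna().value_counts()
        col.loc[vc.index] = vc.astype(int)
        counts[rs.sample_id] = col
        libsizes[rs.sample_id] = len(rs.non_rrna)
    lengths = pd.Series({g.gene_id: g.exonic_length for g in genes}, dtype=float)
    return CountMatrix(pd.DataFrame(counts), pd.Series(libsizes), lengths=lengths)


def normalize(counts: CountMatrix, method: str = "tpm_tags") -> pd.DataFrame:
    """Library-size normalisation: tags per million or RPKM."""
    lib = counts.library_sizes
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    if method == "tpm_tags":
        return counts.counts / lib * 1e6
    if method == "rpkm":
        if counts.lengths is None:
            raise ValueError("rpkm requires gene lengths")
        per_kb = counts.counts.div(counts.lengths / 1e3, axis=0)
        return per_kb / (lib / 1e6)
    raise ValueError(f"unknown normalisation {method!r}")


def signal_metrics(
    reads: ReadSet, genes: list[GeneModel], window: int = DEFAULT_WINDOW
) -> dict[str, float]:
    """Promoter/exon signal rate and ribosomal fraction for one sample.

    ``promoter_rate`` is the fraction of mapped non-ribosomal reads inside
    any gene's TSS window (CAGE) or overlapping any exon (RNA-seq);
    ``rrna_rate`` is the ribosomal fraction of all reads.
    """
    total = len(reads)
    if total == 0:
        raise ValueError("signal metrics undefined for an empty ReadSet")
    rr = reads.rrna_count
    n_non = total - rr
    if n_non == 0:
        warnings.warn("all reads ribosomal; promoter_rate reported as 0")
        return {"promoter_rate": 0.0, "rrna_rate": 1.0, "mapped_total": float(total)}
    if reads.kind == "cage":
        ctss = count_ctss(reads)
        assigned = assign_ctss_to_genes(ctss, genes, window)
        inside = int(ctss.table.loc[assigned.notna(), "count"].sum())
    else:
        assigned = _assign_fragments(reads, genes, stranded=False)
        inside = int(assigned.notna().sum())
    return {
        "promoter_rate": inside / n_non,
        "rrna_rate": rr / total,
        "mapped_total": float(total),
    }


def tss_distance_profile(
    reads: ReadSet, genes: list[GeneModel], max_dist: int = 1000
) -> pd.Series:
    """Cumulative fraction of tags within d bp of the nearest same-strand TSS.

    The curve is monotone nondecreasing in d; its saturation point is the
    evidence for the promoter-window width choice.
    """
    if reads.kind != "cage":
        raise ValueError("tss_distance_profile requires CAGE reads")
    df = reads.non_rrna
    if len(df) == 0:
        raise ValueError("empty ReadSet")
    dists = np.full(len(df), np.iinfo(np.int64).max, dtype=np.int64)
    arr_pos = df["pos5"].to_numpy()
    for (chrom, strand), sub in df.groupby(["chrom", "strand"], sort=False):
        tss = np.sort([g.tss for g in genes if g.chrom == chrom and g.strand == strand])
        if len(tss) == 0:
            continue
        pos = sub["pos5"].to_numpy()
        right = np.searchsorted(tss, pos)
        d = np.full(len(pos), np.iinfo(np.int64).max, dtype=np.int64)
        ok = right < len(tss)
        d[ok] = np.abs(tss[right[ok]] - pos[ok])
        okl = right > 0
        d[okl] = np.minimum(d[okl], np.abs(pos[okl] - tss[right[okl] - 1]))
        idx = sub.index.to_numpy()
        dists[np.searchsorted(df.index.to_numpy(), idx)] = d
    ds = np.arange(max_dist + 1)
    frac = np.array([(dists <= d).mean() for d in ds])
    return pd.Series(frac, index=ds, name="capture_fraction")
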