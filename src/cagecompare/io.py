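"""Readers and writers for the plain-text formats used by the pipeline.

Genomes travel as FASTA, gene models as BED12 plus a sidecar TSV carrying
the planted-context fields, CTSS tables as BED6, read sets as BED6 plus a
truth sidecar, count matrices as TSV with a ``#library_sizes`` header
line, and run configurations as YAML.  Every writer's output round-trips
through the corresponding reader.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import CountMatrix, CTSSTable, GeneModel, ReadSet, SyntheticGenome


class FormatError(ValueError):
    pass


# -- FASTA ------------------------------------------------------------------


def write_fasta(genome: SyntheticGenome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> SyntheticGenome:
    chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return SyntheticGenome(chroms)


# -- gene models: BED12 + sidecar TSV ---------------------------------------

_SIDECAR_COLS = [
    "gene_id",
    "gene_class",
    "promoter_gc",
    "exonic_gc",
    "antisense_site_offsets",
    "tss_t_run",
]


def write_gene_models(genes: list[GeneModel], bed_path: str | Path,
                      sidecar_path: str | Path) -> None:
    with open(bed_path, "w") as fh:
        for g in genes:
            start, end = g.span
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - start) for s, e in g.exons)
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            g.chrom, start, end, g.gene_id, 0, g.strand,
                            start, start, "0", len(g.exons), sizes, starts,
                        ],
                    )
                )
                + "\n"
            )
    rows = [
        {
            "gene_id": g.gene_id,
            "gene_class": g.gene_class,
            "promoter_gc": repr(g.promoter_gc),
            "exonic_gc": repr(g.exonic_gc),
            "antisense_site_offsets": ",".join(map(str, g.antisense_site_offsets)),
            "tss_t_run": g.tss_t_run,
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=_SIDECAR_COLS).to_csv(sidecar_path, sep="\t", index=False)


def read_gene_models(bed_path: str | Path, sidecar_path: str | Path) -> list[GeneModel]:
    side = pd.read_csv(
        sidecar_path, sep="\t", dtype={"antisense_site_offsets": str},
        float_precision="round_trip",
    ).fillna({"antisense_site_offsets": ""})
    side = side.set_index("gene_id")
    genes = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(f"{bed_path}:{lineno}: expected 12 BED fields")
            try:
                chrom, start, end, name, _score, strand = fields[:6]
                start, end = int(start), int(end)
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{bed_path}:{lineno}: {exc}") from None
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{bed_path}:{lineno}: block count mismatch")
            exons = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            tss = start if strand == "+" else end - 1
            if name not in side.index:
                raise FormatError(f"{bed_path}:{lineno}: {name} missing from sidecar")
            meta = side.loc[name]
            off_field = str(meta["antisense_site_offsets"])
            try:
                gene = GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    exons=exons,
                    gene_class=str(meta["gene_class"]),
                    promoter_gc=float(meta["promoter_gc"]),
                    exonic_gc=float(meta["exonic_gc"]),
                    antisense_site_offsets=(
                        [int(x) for x in off_field.split(",")] if off_field else []
                    ),
                    tss_t_run=int(meta["tss_t_run"]),
                )
            except ValueError as exc:
                raise FormatError(f"{bed_path}:{lineno}: {exc}") from None
            genes.append(gene)
    return genes


# -- CTSS: BED6 --------------------------------------------------------------


def write_ctss(ctss: CTSSTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample={ctss.sample_id} rrna_count={ctss.rrna_count}\n")
        for _, row in ctss.table.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['pos'] + 1}\tctss\t"
                f"{row['count']}\t{row['strand']}\n"
            )


def read_ctss(path: str | Path, sample_id: str | None = None) -> CTSSTable:
    rows = []
    rrna_count = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for token in line.lstrip("# ").split():
                    key, _, val = token.partition("=")
                    if key == "sample" and sample_id is None:
                        sample_id = val
                    elif key == "rrna_count":
                        rrna_count = int(val)
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED fields")
            try:
                rows.append(
                    (fields[0], int(fields[1]), fields[5], int(fields[4]))
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    table = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
    return CTSSTable(sample_id or str(path), table, rrna_count=rrna_count)


# -- read sets: BED6 + truth sidecar ----------------------------------------


def write_reads(reads: ReadSet, bed_path: str | Path,
                sidecar_path: str | Path | None = None) -> None:
    with open(bed_path, "w") as fh:
        fh.write(f"# sample={reads.sample_id} kind={reads.kind}\n")
        if reads.kind == "cage":
            for _, r in reads.reads.iterrows():
                fh.write(
                    f"{r['chrom']}\t{r['pos5']}\t{r['pos5'] + 1}\t"
                    f"{r['origin_gene']}\t1\t{r['strand']}\n"
                )
        else:
            for _, r in reads.reads.iterrows():
                fh.write(
                    f"{r['chrom']}\t{r['start']}\t{r['end']}\t"
                    f"{r['origin_gene']}\t1\t{r['strand']}\n"
                )
    if sidecar_path is not None and reads.kind == "cage":
        reads.reads[["raw_leading_base", "shifted_by", "g_added"]].to_csv(
            sidecar_path, sep="\t", index=False
        )


def read_reads(bed_path: str | Path,
               sidecar_path: str | Path | None = None) -> ReadSet:
    sample_id, kind = str(bed_path), "cage"
    rows = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for token in line.lstrip("# ").split():
                    key, _, val = token.partition("=")
                    if key == "sample":
                        sample_id = val
                    elif key == "kind":
                        kind = val
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{bed_path}:{lineno}: expected 6 BED fields")
            rows.append((f[0], int(f[1]), int(f[2]), f[3], f[5]))
    if kind == "cage":
        df = pd.DataFrame(
            {
                "chrom": [r[0] for r in rows],
                "strand": [r[4] for r in rows],
                "pos5": [r[1] for r in rows],
                "raw_leading_base": "N",
                "origin_gene": [r[3] for r in rows],
                "shifted_by": 0,
                "g_added": False,
            }
        )
        if sidecar_path is not None:
            side = pd.read_csv(sidecar_path, sep="\t")
            df["raw_leading_base"] = side["raw_leading_base"].to_numpy()
            df["shifted_by"] = side["shifted_by"].to_numpy()
            df["g_added"] = side["g_added"].to_numpy()
    else:
        df = pd.DataFrame(
            {
                "chrom": [r[0] for r in rows],
                "strand": [r[4] for r in rows],
                "start": [r[1] for r in rows],
                "end": [r[2] for r in rows],
                "origin_gene": [r[3] for r in rows],
            }
        )
    return ReadSet(sample_id, kind, df)


# -- count matrices: TSV with library-size header ---------------------------


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        libs = "\t".join(
            f"{counts.library_sizes[c]:.10g}" for c in counts.counts.columns
        )
        fh.write(f"#library_sizes\t{libs}\n")
        counts.counts.rename_axis("gene_id").to_csv(fh, sep="\t")


def read_counts(path: str | Path, lengths: pd.Series | None = None) -> CountMatrix:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        libs = None
        if first.startswith("#library_sizes"):
            libs = [float(x) for x in first.split("\t")[1:]]
            data = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            data = pd.read_csv(fh, sep="\t", index_col=0)
    data.index.name = None
    if libs is None:
        warnings.warn(f"{path}: no #library_sizes header; inferring from column sums")
        library_sizes = data.sum(axis=0).astype(float)
    else:
        if len(libs) != data.shape[1]:
            raise FormatError(f"{path}: library-size header length mismatch")
        library_sizes = pd.Series(libs, index=data.columns)
    return CountMatrix(data, library_sizes, lengths=lengths)


# -- YAML configuration ------------------------------------------------------


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a YAML mapping")
    return data
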