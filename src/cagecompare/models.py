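"""Core domain types shared across the toolkit.

Conventions
-----------
All genomic coordinates are 0-based, half-open.  "Upstream" and
"downstream" are strand-aware: for a plus-strand gene upstream of the TSS
is ``tss - 1`` and downstream positions increase; for a minus-strand gene
upstream is ``tss + 1`` and downstream positions decrease.  The
"sense-strand sequence" of a minus-strand gene is the reverse complement
of the forward genome string.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class SyntheticGenome:
    """A small reference genome: chromosome name -> ACGT string."""

    chromosomes: dict[str, str]

    def sense_base(self, chrom: str, pos: int, strand: str) -> str:
        """Base at ``pos`` read on ``strand`` (complemented on minus)."""
        base = self.chromosomes[chrom][pos]
        return base.translate(COMPLEMENT) if strand == "-" else base

    def sense_slice(self, chrom: str, start: int, length: int, strand: str) -> str:
        """``length`` bases read 5'->3' on ``strand`` starting at ``start``.

        On the minus strand this walks leftwards from ``start`` and
        complements, so the result is the sense-strand sequence a
        transcript starting at ``start`` would begin with.
        """
        seq = self.chromosomes[chrom]
        if strand == "+":
            return seq[start : start + length]
        lo = max(0, start - length + 1)
        return revcomp(seq[lo : start + 1])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes


@dataclass
class GeneModel:
    """Strand-aware gene annotation anchored at a single TSS.

    ``antisense_site_offsets`` lists distances (bp, >= 0) from the TSS to
    sense-strand CTGCTG motifs downstream, i.e. EcoP15I recognition sites
    (CAGCAG) sitting on the antisense strand relative to the gene.
    ``tss_t_run`` is the length of the genomic T homopolymer starting at
    the TSS on the sense strand (0 if the TSS base is not T).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: list[tuple[int, int]]
    gene_class: str = "coding"  # coding | histone_like | rrna
    promoter_gc: float = 0.0
    exonic_gc: float = 0.0
    antisense_site_offsets: list[int] = field(default_factory=list)
    tss_t_run: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        for s, e in exons:
            if e <= s:
                raise ValueError(f"empty exon in {self.gene_id}")
        self.exons = exons
        five_prime = exons[0][0] if self.strand == "+" else exons[-1][1] - 1
        if five_prime != self.tss:
            raise ValueError(
                f"{self.gene_id}: 5'-most exon boundary {five_prime} != tss {self.tss}"
            )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def polyadenylated(self) -> bool:
        return self.gene_class == "coding"

    def spliced_to_genomic(self, offset: int) -> int:
        """Map a spliced (transcript) coordinate to a genomic position."""
        if offset < 0 or offset >= self.exonic_length:
            raise IndexError(offset)
        if self.strand == "+":
            for s, e in self.exons:
                if offset < e - s:
                    return s + offset
                offset -= e - s
        else:
            for s, e in reversed(self.exons):
                if offset < e - s:
                    return e - 1 - offset
                offset -= e - s
        raise AssertionError("unreachable")


@dataclass
class ExpressionProfile:
    """Relative molar abundances of annotated, quantifiable genes.

    ``quantifiable_fraction`` is the fraction of the RNA mass that maps to
    annotated genes at all; the remainder stands for ribosomal RNA and
    transcripts absent from the reference.  Abundances sum to one over the
    annotated genes.
    """

    sample_id: str
    abundance: pd.Series
    quantifiable_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.quantifiable_fraction <= 1.0:
            raise ValueError("quantifiable_fraction must be in (0, 1]")
        a = pd.Series(self.abundance, dtype=float)
        if (a < 0).any():
            raise ValueError("negative abundances")
        total = float(a.sum())
        if total <= 0:
            raise ValueError("abundances sum to zero")
        self.abundance = a / total

    def relabel(self, sample_id: str) -> "ExpressionProfile":
        return replace(self, sample_id=sample_id)


@dataclass
class MixtureSpec:
    """Ordered list of (label, mass_ratio_A, mass_ratio_B)."""

    mixtures: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        for label, a, b in self.mixtures:
            if a < 0 or b < 0:
                raise ValueError(f"negative ratio in {label}")
            if abs(a + b - 1.0) > 1e-9:
                raise ValueError(f"ratios of {label} do not sum to 1")

    @classmethod
    def paper_panel(cls) -> "MixtureSpec":
        ratios = [1.0, 0.99, 0.95, 0.90, 0.50, 0.0]
        return cls(
            [(f"{int(round(r * 100))}:{int(round((1 - r) * 100))}", r, 1.0 - r) for r in ratios]
        )


@dataclass
class PlatformModel:
    """Bundle of bias parameters defining one platform's readout distortion.

    Parameters
    ----------
    g_add_prob:
        Probability that reverse transcription appends a nontemplated G to
        the cDNA 5' end (PCR CAGE protocols; ~0.87 in the literature).
    first_base_weights:
        Relative capture efficiency by the genomic base at the TSS,
        modelling linker first-base preference.
    gc_bias_coef:
        Natural-log-linear slope of amplification weight against GC
        fraction (centred at 0.5); 0 for PCR-free protocols.
    ecop15i_boost:
        Multiplicative over-representation of genes carrying an
        antisense-strand EcoP15I site within ``ecop15i_max_dist`` bp of
        the TSS (extra cleavage opportunity during tag release).
    tstretch_shift_enabled:
        Fill-and-lock artifact of the single-molecule protocol: observed
        starts are displaced downstream past a genomic T run of length
        >= ``tstretch_min_run`` at the TSS.
    polya_select / polya_escape_rate:
        Oligo(dT) selection: non-polyadenylated (histone-like) transcripts
        survive only with ``polya_escape_rate``.
    rrna_rate_mean / rrna_rate_sd:
        Per-replicate ribosomal-RNA read fraction, drawn once per sample.
    jitter_frac:
        Fraction of reads whose true start is tss +/- 1 bp, giving CTSS
        peaks realistic single-base shapes.
    """

    platform: str
    g_add_prob: float = 0.0
    first_base_weights: dict[str, float] = field(
        default_factory=lambda: {"A": 1.0, "C": 1.0, "G": 1.0, "T": 1.0}
    )
    gc_bias_coef: float = 0.0
    ecop15i_boost: float = 1.0
    ecop15i_max_dist: int = 400
    tstretch_shift_enabled: bool = False
    tstretch_min_run: int = 4
    polya_select: bool = False
    polya_escape_rate: float = 0.05
    rrna_rate_mean: float = 0.02
    rrna_rate_sd: float = 0.005
    jitter_frac: float = 0.05
    fragment_length: int = 35

    def __post_init__(self) -> None:
        for p in (self.g_add_prob, self.polya_escape_rate, self.jitter_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.ecop15i_boost < 1.0:
            raise ValueError("ecop15i_boost must be >= 1")
        if any(w <= 0 for w in self.first_base_weights.values()):
            raise ValueError("first_base_weights must be positive")


_PRESETS = {
    # PCR-free single-molecule CAGE: no G addition, no amplification bias,
    # but fill-and-lock shifts starts past TSS T runs.
    "heliscope_cage": dict(
        g_add_prob=0.0,
        gc_bias_coef=0.0,
        ecop15i_boost=1.0,
        tstretch_shift_enabled=True,
        rrna_rate_mean=0.05,
        rrna_rate_sd=0.01,
    ),
    # PCR-amplified CAGE: G addition (~87%), GC-dependent amplification,
    # EcoP15I internal-site boost, G-favouring / C-disfavouring linkers.
    "illumina_cage": dict(
        g_add_prob=0.87,
        first_base_weights={"A": 1.0, "C": 0.6, "G": 1.3, "T": 1.0},
        gc_bias_coef=-1.5,
        ecop15i_boost=1.5,
        tstretch_shift_enabled=False,
        rrna_rate_mean=0.02,
        rrna_rate_sd=0.005,
    ),
    # PolyA-selected, PCR-amplified fragment sequencing.
    "rnaseq": dict(
        gc_bias_coef=-1.0,
        polya_select=True,
        polya_escape_rate=0.05,
        rrna_rate_mean=0.10,
        rrna_rate_sd=0.04,
    ),
}


def platform_preset(name: str, **overrides) -> PlatformModel:
    """Return a :class:`PlatformModel` preset, optionally overridden."""
    if name not in _PRESETS:
        raise KeyError(f"unknown platform preset {name!r}; choose from {sorted(_PRESETS)}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return PlatformModel(platform=name, **params)


CAGE_READ_COLUMNS = [
    "chrom",
    "strand",
    "pos5",
    "raw_leading_base",
    "origin_gene",
    "shifted_by",
    "g_added",
]
RNASEQ_READ_COLUMNS = ["chrom", "strand", "start", "end", "origin_gene"]


@dataclass
class ReadSet:
    """Simulated aligned records for one sample, with truth labels.

    ``kind`` is ``"cage"`` (single 5' position per read, after the
    mismatch-trimming convention) or ``"rnaseq"`` (fragment interval).
    CAGE records keep the raw leading base observed before trimming, the
    signed artifact displacement ``shifted_by`` and a ``g_added`` truth
    flag; ribosomal reads carry ``origin_gene == "rrna"``.
    """

    sample_id: str
    kind: str
    reads: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in ("cage", "rnaseq"):
            raise ValueError(f"bad ReadSet kind {self.kind!r}")
        cols = CAGE_READ_COLUMNS if self.kind == "cage" else RNASEQ_READ_COLUMNS
        if len(self.reads) == 0:
            self.reads = pd.DataFrame(columns=cols)
        missing = set(cols) - set(self.reads.columns)
        if missing:
            raise ValueError(f"ReadSet missing columns {sorted(missing)}")
        self.reads = self.reads.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def rrna_count(self) -> int:
        if len(self.reads) == 0:
            return 0
        return int((self.reads["origin_gene"] == "rrna").sum())

    @property
    def non_rrna(self) -> pd.DataFrame:
        return self.reads[self.reads["origin_gene"] != "rrna"]


@dataclass
class CTSSTable:
    """Per-(chromosome, position, strand) tag counts at 1 bp resolution.

    One table per sample; ribosomal reads are excluded from the table and
    carried as ``rrna_count``.  ``total + rrna_count`` equals the number
    of CAGE reads in the originating sample.
    """

    sample_id: str
    table: pd.DataFrame  # columns chrom, pos, strand, count
    rrna_count: int = 0

    def __post_init__(self) -> None:
        cols = ["chrom", "pos", "strand", "count"]
        if len(self.table) == 0:
            self.table = pd.DataFrame(columns=cols).astype(
                {"pos": int, "count": int}, errors="ignore"
            )
            return
        missing = set(cols) - set(self.table.columns)
        if missing:
            raise ValueError(f"CTSSTable missing columns {sorted(missing)}")
        t = self.table[cols].copy()
        if (t["count"] < 1).any():
            raise ValueError("CTSS counts must be positive")
        t = t.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
        if t.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) keys in CTSS table")
        t["pos"] = t["pos"].astype(int)
        t["count"] = t["count"].astype(int)
        self.table = t

    @property
    def total(self) -> int:
        return int(self.table["count"].sum()) if len(self.table) else 0

    def counts_by_key(self) -> pd.Series:
        return self.table.set_index(["chrom", "pos", "strand"])["count"]


@dataclass
class CountMatrix:
    """Gene x sample integer counts with library sizes.

    ``library_sizes`` are total mapped non-ribosomal reads per sample (the
    normalisation denominator); ``lengths`` are exonic lengths in bp and
    are only required for RPKM.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(int)
        self.library_sizes = pd.Series(self.library_sizes, dtype=float)[
            self.counts.columns
        ]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if (self.counts.to_numpy().max(initial=0) > self.library_sizes.max()
                if len(self.counts) else False):
            raise ValueError("count exceeds library size")
        if self.lengths is not None:
            self.lengths = pd.Series(self.lengths, dtype=float)[self.counts.index]
            if (self.lengths <= 0).any():
                raise ValueError("gene lengths must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)


def gene_index(genes: list[GeneModel]) -> dict[str, GeneModel]:
    idx = {g.gene_id: g for g in genes}
    if len(idx) != len(genes):
        raise ValueError("duplicate gene_ids")
    return idx


def rng_from_seed(seed) -> np.random.Generator:
    return np.random.default_rng(seed)
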