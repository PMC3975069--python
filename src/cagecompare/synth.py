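"""Synthetic reference, expression and read-set generation.

The generator emits a small genome plus gene models with *planted*
sequence contexts — promoter/exon GC strata, sense-strand CTGCTG motifs
(antisense-strand EcoP15I sites) at controlled offsets from the TSS,
genomic T runs starting at the TSS, non-polyadenylated histone-like genes
and one ribosomal gene — and then simulates platform-distorted CAGE tags
and RNA-seq fragments over it.  Every stored context field is recomputed
from the emitted sequence, so downstream diagnostics can be validated by
parameter recovery against known truth.

Simulation operates on aligned coordinates plus a recorded raw leading
base; base-calling errors and the alignment step itself are out of scope
(quality filters act upstream of everything modelled here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    CAGE_READ_COLUMNS,
    RNASEQ_READ_COLUMNS,
    COMPLEMENT,
    ExpressionProfile,
    GeneModel,
    PlatformModel,
    ReadSet,
    SyntheticGenome,
    rng_from_seed,
)

ECOP15I_SENSE_MOTIF = "CTGCTG"  # EcoP15I site (CAGCAG) on the antisense strand
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CHAR2IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
# complement of index i is 3 - i (A<->T, C<->G)


class ConfigError(ValueError):
    pass


class SizingError(ValueError):
    pass


@dataclass
class ReferenceConfig:
    """Sizing and stratification of the synthetic reference.

    Fractions select gene strata: ``frac_ecop15i_near`` genes get a
    sense-strand CTGCTG planted within ``ecop15i_max_dist`` bp downstream
    of the TSS, ``frac_ecop15i_far`` beyond it (up to ``scan_range``);
    ``frac_tstretch`` genes start with a genomic T run of length drawn in
    ``[tstretch_min_run, 15]``; ``frac_histone`` genes are flagged
    non-polyadenylated.  One ribosomal gene is appended when
    ``include_rrna``.
    """

    n_genes: int = 200
    chrom_name: str = "chrS"
    chrom_length: int | None = None  # None -> sized automatically
    spacing: int = 1000
    flank: int = 600
    gene_length_range: tuple[int, int] = (1500, 3000)
    n_exons_range: tuple[int, int] = (1, 4)
    gc_range: tuple[float, float] = (0.30, 0.70)
    frac_ecop15i_near: float = 0.25
    frac_ecop15i_far: float = 0.15
    ecop15i_max_dist: int = 400
    scan_range: int = 800
    frac_tstretch: float = 0.10
    tstretch_min_run: int = 4
    frac_histone: float = 0.05
    include_rrna: bool = True
    pad: int = 1000

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        fracs = (
            self.frac_ecop15i_near,
            self.frac_ecop15i_far,
            self.frac_tstretch,
            self.frac_histone,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ConfigError("stratum fractions must lie in [0, 1]")
        if self.frac_ecop15i_near + self.frac_ecop15i_far > 1:
            raise ConfigError("EcoP15I strata fractions exceed 1")
        if self.spacing < 1000:
            raise ConfigError("genes require >= 1 kb spacing")


def _write_sense(arr: np.ndarray, tss: int, strand: str, offset: int, text: str) -> None:
    """Write ``text`` on the sense strand starting ``offset`` bp downstream of tss."""
    idx = np.array([_CHAR2IDX[c] for c in text], dtype=np.uint8)
    if strand == "+":
        arr[tss + offset : tss + offset + len(text)] = idx
    else:
        arr[tss - offset - len(text) + 1 : tss - offset + 1] = (3 - idx)[::-1]


def _read_sense(arr: np.ndarray, tss: int, strand: str, offset: int, length: int) -> str:
    if strand == "+":
        idx = arr[tss + offset : tss + offset + length]
    else:
        idx = 3 - arr[tss - offset - length + 1 : tss - offset + 1][::-1]
    return _BASE_BYTES[idx].tobytes().decode()


def _scrub_motif(arr: np.ndarray, tss: int, strand: str, span: int) -> None:
    """Destroy accidental CTGCTG occurrences downstream of the TSS."""
    window = _read_sense(arr, tss, strand, 0, span)
    start = 0
    while True:
        hit = window.find(ECOP15I_SENSE_MOTIF, start)
        if hit < 0:
            break
        _write_sense(arr, tss, strand, hit + 2, "A")
        window = window[: hit + 2] + "A" + window[hit + 3 :]
        start = hit + 1


def _gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def scan_antisense_sites(
    genome: SyntheticGenome, chrom: str, tss: int, strand: str, scan_range: int = 800
) -> list[int]:
    """Offsets of sense-strand CTGCTG motifs within ``scan_range`` bp downstream."""
    seq = genome.sense_slice(chrom, tss, scan_range + len(ECOP15I_SENSE_MOTIF), strand)
    offsets = []
    start = 0
    while True:
        hit = seq.find(ECOP15I_SENSE_MOTIF, start)
        if hit < 0 or hit > scan_range:
            break
        offsets.append(hit)
        start = hit + 1
    return offsets


def tss_t_run_length(genome: SyntheticGenome, chrom: str, tss: int, strand: str,
                     max_run: int = 30) -> int:
    """Length of the sense-strand T homopolymer starting exactly at the TSS."""
    seq = genome.sense_slice(chrom, tss, max_run, strand)
    run = 0
    for b in seq:
        if b != "T":
            break
        run += 1
    return run


def promoter_gc(genome: SyntheticGenome, chrom: str, tss: int, halfwidth: int = 500) -> float:
    seq = genome.chromosomes[chrom]
    lo = max(0, tss - halfwidth)
    hi = min(len(seq), tss + halfwidth + 1)
    return _gc_fraction(seq[lo:hi])


def exonic_gc(genome: SyntheticGenome, gene: GeneModel) -> float:
    seq = genome.chromosomes[gene.chrom]
    return _gc_fraction("".join(seq[s:e] for s, e in gene.exons))


def generate_reference(
    config: ReferenceConfig | None = None, seed: int | np.random.Generator = 0
) -> tuple[SyntheticGenome, list[GeneModel]]:
    """Generate a genome and gene models with planted sequence contexts.

    Genes are laid left to right with at least ``config.spacing`` bp
    between them; strands, lengths, exon counts and GC targets are drawn
    per gene.  All stored context fields (``promoter_gc``, ``exonic_gc``,
    ``antisense_site_offsets``, ``tss_t_run``) are recomputed from the
    emitted sequence after planting, so they agree with the FASTA exactly.
    """
    config = config or ReferenceConfig()
    rng = rng_from_seed(seed)
    n = config.n_genes
    total_genes = n + (1 if config.include_rrna else 0)

    lengths = rng.integers(*config.gene_length_range, size=total_genes, endpoint=True)
    blocks = lengths + 2 * config.flank
    required = config.pad * 2 + int(blocks.sum()) + config.spacing * max(total_genes - 1, 0)
    if config.chrom_length is not None and config.chrom_length < required:
        raise SizingError(
            f"chrom_length {config.chrom_length} < required {required} for "
            f"{total_genes} genes at >= {config.spacing} bp spacing"
        )
    chrom_len = config.chrom_length or required

    # stratum assignment (disjoint EcoP15I strata, independent T/histone strata)
    idx = rng.permutation(n)
    n_near = int(round(config.frac_ecop15i_near * n))
    n_far = int(round(config.frac_ecop15i_far * n))
    near_set = set(idx[:n_near])
    far_set = set(idx[n_near : n_near + n_far])
    tstretch_set = set(rng.permutation(n)[: int(round(config.frac_tstretch * n))])
    histone_set = set(rng.permutation(n)[: int(round(config.frac_histone * n))])

    gc_targets = rng.uniform(*config.gc_range, size=total_genes)

    # base-index array (0..3 = ACGT); background sequence at mid GC
    arr = rng.integers(0, 4, size=chrom_len, dtype=np.uint8)

    genes: list[GeneModel] = []
    cursor = config.pad
    plans = []
    for i in range(total_genes):
        gene_len = int(lengths[i])
        start = cursor + config.flank
        end = start + gene_len
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else end - 1
        gc = float(gc_targets[i])
        pg, pat = gc / 2.0, (1.0 - gc) / 2.0
        region_lo = cursor
        region_hi = cursor + int(blocks[i])
        arr[region_lo:region_hi] = rng.choice(
            4, size=region_hi - region_lo, p=[pat, pg, pg, pat]
        ).astype(np.uint8)

        is_rrna = config.include_rrna and i == total_genes - 1
        t_run = 0
        if not is_rrna and i in tstretch_set:
            t_run = int(rng.integers(config.tstretch_min_run, 16))
            _write_sense(arr, tss, strand, 0, "T" * t_run)
            if _read_sense(arr, tss, strand, t_run, 1) == "T":
                _write_sense(arr, tss, strand, t_run, "A")
        else:
            # keep natural T runs at the TSS below the shifting threshold
            lead = _read_sense(arr, tss, strand, 0, config.tstretch_min_run)
            if lead == "T" * config.tstretch_min_run:
                _write_sense(arr, tss, strand, config.tstretch_min_run - 1, "A")

        _scrub_motif(arr, tss, strand, config.scan_range + len(ECOP15I_SENSE_MOTIF))
        if not is_rrna and i in near_set:
            lo = max(20, t_run + 2)
            off = int(rng.integers(lo, config.ecop15i_max_dist + 1))
            _write_sense(arr, tss, strand, off, ECOP15I_SENSE_MOTIF)
        elif not is_rrna and i in far_set:
            off = int(rng.integers(config.ecop15i_max_dist + 1, config.scan_range - 5))
            _write_sense(arr, tss, strand, off, ECOP15I_SENSE_MOTIF)

        plans.append((i, start, end, strand, tss, is_rrna))
        cursor = region_hi + config.spacing

    seq = _BASE_BYTES[arr].tobytes().decode()
    genome = SyntheticGenome({config.chrom_name: seq})

    n_exons_lo, n_exons_hi = config.n_exons_range
    for i, start, end, strand, tss, is_rrna in plans:
        gene_len = end - start
        n_exons = int(rng.integers(n_exons_lo, n_exons_hi + 1))
        exons = _split_exons(start, end, n_exons, rng)
        if is_rrna:
            gene_id, gene_class = "rrna", "rrna"
            exons = [(start, end)]
        else:
            gene_id = f"g{i:05d}"
            gene_class = "histone_like" if i in histone_set else "coding"
        gene = GeneModel(
            gene_id=gene_id,
            chrom=config.chrom_name,
            strand=strand,
            tss=tss,
            exons=exons,
            gene_class=gene_class,
        )
        gene.promoter_gc = promoter_gc(genome, gene.chrom, tss)
        gene.exonic_gc = exonic_gc(genome, gene)
        gene.antisense_site_offsets = scan_antisense_sites(
            genome, gene.chrom, tss, strand, config.scan_range
        )
        gene.tss_t_run = tss_t_run_length(genome, gene.chrom, tss, strand)
        genes.append(gene)
    return genome, genes


def _split_exons(start: int, end: int, n_exons: int, rng) -> list[tuple[int, int]]:
    """Split [start, end) into alternating exon/intron blocks (>=60/30 bp)."""
    length = end - start
    n_segments = 2 * n_exons - 1
    while n_segments > 1 and length < 60 * n_exons + 30 * (n_exons - 1):
        n_exons -= 1
        n_segments = 2 * n_exons - 1
    if n_segments == 1:
        return [(start, end)]
    mins = np.where(np.arange(n_segments) % 2 == 0, 60, 30)
    extra = length - int(mins.sum())
    cuts = np.sort(rng.integers(0, extra + 1, size=n_segments - 1))
    sizes = mins + np.diff(np.concatenate([[0], cuts, [extra]]))
    bounds = start + np.concatenate([[0], np.cumsum(sizes)])
    return [(int(bounds[k]), int(bounds[k + 1])) for k in range(0, n_segments, 2)]


# ---------------------------------------------------------------------------
# expression profiles and mixtures


def sample_expression(
    genes: list[GeneModel],
    seed: int | np.random.Generator = 0,
    log_sd: float = 2.0,
    quantifiable_fraction: float = 1.0,
    sample_id: str = "sample",
) -> ExpressionProfile:
    """Draw log-normal relative abundances over non-ribosomal genes."""
    if log_sd <= 0:
        raise ConfigError("log_sd must be positive")
    ids = [g.gene_id for g in genes if g.gene_class != "rrna"]
    if not ids:
        raise ConfigError("no quantifiable genes to draw expression for")
    rng = rng_from_seed(seed)
    raw = np.exp(rng.normal(0.0, log_sd, size=len(ids)))
    return ExpressionProfile(
        sample_id=sample_id,
        abundance=pd.Series(raw, index=ids),
        quantifiable_fraction=quantifiable_fraction,
    )


def compose_mixture(
    profile_a: ExpressionProfile,
    profile_b: ExpressionProfile,
    mass_ratio_a: float,
    sample_id: str | None = None,
) -> ExpressionProfile:
    """Mix two RNA pools by mass, accounting for quantifiable fractions.

    With mass ratio ``r`` and quantifiable fractions ``qA``, ``qB``, the
    share of quantifiable (mappable, annotated) reads contributed by pool
    A is ``r*qA / (r*qA + (1-r)*qB)`` — the *effective* ratio, which
    differs from the molar ratio whenever ``qA != qB``.
    """
    if not 0.0 <= mass_ratio_a <= 1.0:
        raise ValueError("mass_ratio_a must lie in [0, 1]")
    if set(profile_a.abundance.index) != set(profile_b.abundance.index):
        raise ValueError("profiles cover different gene universes")
    r, qa, qb = mass_ratio_a, profile_a.quantifiable_fraction, profile_b.quantifiable_fraction
    wa, wb = r * qa, (1.0 - r) * qb
    b = profile_b.abundance[profile_a.abundance.index]
    mix = wa * profile_a.abundance + wb * b
    label = sample_id or f"mix_{int(round(r * 100))}"
    return ExpressionProfile(
        sample_id=label, abundance=mix, quantifiable_fraction=wa + wb
    )


def effective_share(
    profile_a: ExpressionProfile, profile_b: ExpressionProfile, mass_ratio_a: float
) -> float:
    """Quantifiable-read share of pool A in a mass mixture."""
    wa = mass_ratio_a * profile_a.quantifiable_fraction
    wb = (1.0 - mass_ratio_a) * profile_b.quantifiable_fraction
    return wa / (wa + wb)


def sample_counts(
    profile: ExpressionProfile, depth: int, seed: int | np.random.Generator = 0
) -> tuple[pd.Series, int]:
    """Multinomial gene counts for one sequencing run of ``depth`` reads.

    Each read is quantifiable with probability ``quantifiable_fraction``;
    quantifiable reads fall on genes with the profile's abundances.
    Returns (gene counts, number of non-quantifiable reads).
    """
    rng = rng_from_seed(seed)
    n_quant = int(rng.binomial(depth, profile.quantifiable_fraction))
    p = profile.abundance.to_numpy()
    counts = rng.multinomial(n_quant, p / p.sum())
    return pd.Series(counts, index=profile.abundance.index), depth - n_quant


def simulate_nb_replicates(
    n_genes: int,
    depth: int,
    phi: float,
    n_reps: int = 3,
    log_sd: float = 2.0,
    seed: int | np.random.Generator = 0,
    prefix: str = "rep",
) -> pd.DataFrame:
    """Replicate gene counts from a common-dispersion negative binomial.

    Per-gene means are log-normal relative abundances scaled to ``depth``;
    counts are gamma-Poisson draws with ``Var = m + phi * m**2``.  With
    ``phi == 0`` the draws are Poisson.
    """
    rng = rng_from_seed(seed)
    raw = np.exp(rng.normal(0.0, log_sd, size=n_genes))
    means = raw / raw.sum() * depth
    cols = {}
    for r in range(n_reps):
        if phi <= 0:
            cols[f"{prefix}{r + 1}"] = rng.poisson(means)
        else:
            lam = rng.gamma(shape=1.0 / phi, scale=phi * means)
            cols[f"{prefix}{r + 1}"] = rng.poisson(lam)
    return pd.DataFrame(cols, index=[f"g{i:05d}" for i in range(n_genes)])


# ---------------------------------------------------------------------------
# read-level simulation


def _draw_rrna_rate(platform: PlatformModel, rng) -> float:
    if platform.rrna_rate_mean <= 0:
        return 0.0
    return float(np.clip(rng.normal(platform.rrna_rate_mean, platform.rrna_rate_sd), 0.0, 1.0))


def _cage_gene_weights(
    genes: dict[str, GeneModel], expr: ExpressionProfile,
    genome: SyntheticGenome, platform: PlatformModel,
) -> pd.Series:
    w = {}
    for gid, a in expr.abundance.items():
        g = genes[gid]
        base = genome.sense_base(g.chrom, g.tss, g.strand)
        weight = a * platform.first_base_weights.get(base, 1.0)
        weight *= np.exp(platform.gc_bias_coef * (g.promoter_gc - 0.5))
        if g.antisense_site_offsets and min(g.antisense_site_offsets) <= platform.ecop15i_max_dist:
            weight *= platform.ecop15i_boost
        w[gid] = weight
    return pd.Series(w)


def simulate_cage(
    genome: SyntheticGenome,
    genes: list[GeneModel],
    expr: ExpressionProfile,
    platform: PlatformModel,
    depth: int,
    seed: int | np.random.Generator = 0,
) -> ReadSet:
    """Simulate aligned CAGE tag 5' positions with platform artifacts.

    Sampling weight per gene folds in linker first-base preference,
    GC-dependent amplification and the EcoP15I internal-site boost.  Each
    read then passes, in order: (1) nontemplated G addition with
    ``g_add_prob`` — when the strand-aware upstream genomic base is G the
    aligned 5' end moves 1 bp upstream (the artifact is indistinguishable
    from a templated start), otherwise the mismatching leading G is
    recorded and trimmed so the position is unchanged; (2) fill-and-lock
    T-run displacement: a read starting inside a TSS T run of length
    ``>= tstretch_min_run`` is reported at the first base past the run.
    A ``jitter_frac`` fraction of reads initiates at tss +/- 1.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = rng_from_seed(seed)
    gidx = {g.gene_id: g for g in genes}
    missing = set(expr.abundance.index) - set(gidx)
    if missing:
        raise ValueError(f"expression covers unknown genes {sorted(missing)[:3]}")
    if depth == 0:
        return ReadSet(expr.sample_id, "cage", pd.DataFrame(columns=CAGE_READ_COLUMNS))

    rrna_genes = [g for g in genes if g.gene_class == "rrna"]
    rate = _draw_rrna_rate(platform, rng) if rrna_genes else 0.0
    n_rrna = int(rng.binomial(depth, rate)) if rate > 0 else 0
    n_quant = depth - n_rrna

    weights = _cage_gene_weights(gidx, expr, genome, platform)
    p = weights.to_numpy() / weights.sum()
    gene_counts = rng.multinomial(n_quant, p)

    chunks = []
    for gid, count in zip(weights.index, gene_counts):
        if count == 0:
            continue
        chunks.append(_cage_reads_for_gene(gidx[gid], count, genome, platform, rng))
    if n_rrna > 0:
        rg = rrna_genes[0]
        chunks.append(
            pd.DataFrame(
                {
                    "chrom": rg.chrom,
                    "strand": rg.strand,
                    "pos5": np.full(n_rrna, rg.tss),
                    "raw_leading_base": genome.sense_base(rg.chrom, rg.tss, rg.strand),
                    "origin_gene": "rrna",
                    "shifted_by": 0,
                    "g_added": False,
                }
            )
        )
    df = (
        pd.concat(chunks, ignore_index=True)
        if chunks
        else pd.DataFrame(columns=CAGE_READ_COLUMNS)
    )
    if len(df):
        df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    return ReadSet(expr.sample_id, "cage", df)


def _cage_reads_for_gene(
    gene: GeneModel, count: int, genome: SyntheticGenome,
    platform: PlatformModel, rng,
) -> pd.DataFrame:
    sgn = 1 if gene.strand == "+" else -1
    # jitter: transcription initiates at tss +/- 1 (sense) for a small fraction
    jitter = np.zeros(count, dtype=int)
    if platform.jitter_frac > 0:
        mask = rng.random(count) < platform.jitter_frac
        jitter[mask] = rng.choice([-1, 1], size=int(mask.sum()))
    start = gene.tss + sgn * jitter  # genomic position of the true 5' base

    seq = genome.chromosomes[gene.chrom]

    def sense_at(pos_arr):
        bases = np.array([seq[p] for p in pos_arr])
        if gene.strand == "-":
            bases = np.array([b.translate(COMPLEMENT) for b in bases])
        return bases

    start_base = sense_at(start)
    pos5 = start.copy()
    raw = start_base.copy()
    shifted = np.zeros(count, dtype=int)

    g_added = (
        rng.random(count) < platform.g_add_prob
        if platform.g_add_prob > 0
        else np.zeros(count, dtype=bool)
    )
    if g_added.any():
        up = start - sgn  # strand-aware 1 bp upstream
        up_base = sense_at(up)
        raw[g_added] = "G"
        move = g_added & (up_base == "G")  # templated-looking: alignment extends
        pos5[move] = up[move]
        shifted[move] = -1  # 1 bp upstream in sense coordinates

    if (
        platform.tstretch_shift_enabled
        and gene.tss_t_run >= platform.tstretch_min_run
    ):
        run = gene.tss_t_run
        off = sgn * (pos5 - gene.tss)  # sense offset of the reported start
        in_run = (off >= 0) & (off < run)
        pos5[in_run] = gene.tss + sgn * run
        shifted[in_run] = run - off[in_run]

    return pd.DataFrame(
        {
            "chrom": gene.chrom,
            "strand": gene.strand,
            "pos5": pos5,
            "raw_leading_base": raw,
            "origin_gene": gene.gene_id,
            "shifted_by": shifted,
            "g_added": g_added,
        }
    )


def simulate_rnaseq(
    genome: SyntheticGenome,
    genes: list[GeneModel],
    expr: ExpressionProfile,
    platform: PlatformModel,
    depth: int,
    seed: int | np.random.Generator = 0,
) -> ReadSet:
    """Simulate polyA-selected RNA-seq fragments (5' ends uniform in exons).

    With ``polya_select`` on, non-polyadenylated (histone-like) transcripts
    survive selection only with ``polya_escape_rate``; gene weight also
    folds in GC-dependent amplification on exonic GC.  Fragments are
    ``fragment_length`` bp in spliced coordinates, clipped at the
    transcript 3' end; per-sample ribosomal carryover is drawn as in CAGE.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = rng_from_seed(seed)
    gidx = {g.gene_id: g for g in genes}
    missing = set(expr.abundance.index) - set(gidx)
    if missing:
        raise ValueError(f"expression covers unknown genes {sorted(missing)[:3]}")
    if depth == 0:
        return ReadSet(expr.sample_id, "rnaseq", pd.DataFrame(columns=RNASEQ_READ_COLUMNS))

    w = {}
    for gid, a in expr.abundance.items():
        g = gidx[gid]
        weight = a * np.exp(platform.gc_bias_coef * (g.exonic_gc - 0.5))
        if platform.polya_select and not g.polyadenylated and g.gene_class != "rrna":
            weight *= platform.polya_escape_rate
        w[gid] = weight
    weights = pd.Series(w)
    if weights.sum() <= 0:
        n_quant_possible = False
    else:
        n_quant_possible = True

    rrna_genes = [g for g in genes if g.gene_class == "rrna"]
    rate = _draw_rrna_rate(platform, rng) if rrna_genes else 0.0
    n_rrna = int(rng.binomial(depth, rate)) if rate > 0 else 0
    n_quant = depth - n_rrna

    chunks = []
    if n_quant_possible and n_quant > 0:
        p = weights.to_numpy() / weights.sum()
        gene_counts = rng.multinomial(n_quant, p)
        for gid, count in zip(weights.index, gene_counts):
            if count == 0:
                continue
            chunks.append(_rnaseq_reads_for_gene(gidx[gid], count, platform, rng))
    if n_rrna > 0:
        chunks.append(_rnaseq_reads_for_gene(rrna_genes[0], n_rrna, platform, rng,
                                             label="rrna"))
    df = (
        pd.concat(chunks, ignore_index=True)
        if chunks
        else pd.DataFrame(columns=RNASEQ_READ_COLUMNS)
    )
    if len(df):
        df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    return ReadSet(expr.sample_id, "rnaseq", df)


def _rnaseq_reads_for_gene(
    gene: GeneModel, count: int, platform: PlatformModel, rng, label: str | None = None
) -> pd.DataFrame:
    L = gene.exonic_length
    flen = platform.fragment_length
    u = rng.integers(0, L, size=count)
    last = np.minimum(u + flen, L) - 1
    g1 = np.array([gene.spliced_to_genomic(int(x)) for x in u])
    g2 = np.array([gene.spliced_to_genomic(int(x)) for x in last])
    start = np.minimum(g1, g2)
    end = np.maximum(g1, g2) + 1
    return pd.DataFrame(
        {
            "chrom": gene.chrom,
            "strand": gene.strand,
            "start": start,
            "end": end,
            "origin_gene": label or gene.gene_id,
        }
    )
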