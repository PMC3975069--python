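import numpy as np
import pandas as pd
import pytest

from cagecompare import (
    ExpressionProfile,
    GeneModel,
    PlatformModel,
    ReferenceConfig,
    SyntheticGenome,
    generate_reference,
    sample_expression,
)


def null_platform(**overrides) -> PlatformModel:
    """A platform with every artifact mechanism switched off."""
    params = dict(
        g_add_prob=0.0,
        gc_bias_coef=0.0,
        ecop15i_boost=1.0,
        tstretch_shift_enabled=False,
        polya_select=False,
        rrna_rate_mean=0.0,
        rrna_rate_sd=0.0,
        jitter_frac=0.0,
    )
    params.update(overrides)
    return PlatformModel(platform="null", **params)


@pytest.fixture(scope="session")
def small_reference():
    cfg = ReferenceConfig(n_genes=60)
    return generate_reference(cfg, seed=11)


@pytest.fixture(scope="session")
def flat_expression(small_reference):
    _, genes = small_reference
    return sample_expression(genes, seed=5, log_sd=0.3, sample_id="flat")


def single_gene_setup(
    tss_seq: str = "ACGTACGTAC",
    upstream_base: str = "A",
    strand: str = "+",
    length: int = 3000,
):
    """A one-gene genome with a controlled TSS-proximal sequence."""
    rng = np.random.default_rng(99)
    seq = list("".join(rng.choice(list("ACGT"), size=length)))
    if strand == "+":
        tss = 1000
        seq[tss - 1] = upstream_base
        for i, b in enumerate(tss_seq):
            seq[tss + i] = b
        exons = [(tss, tss + 800)]
    else:
        tss = 1800
        comp = str.maketrans("ACGT", "TGCA")
        seq[tss + 1] = upstream_base.translate(comp)
        for i, b in enumerate(tss_seq):
            seq[tss - i] = b.translate(comp)
        exons = [(tss - 800 + 1, tss + 1)]
    genome = SyntheticGenome({"chr1": "".join(seq)})
    from cagecompare.synth import exonic_gc, promoter_gc, tss_t_run_length

    gene = GeneModel("g1", "chr1", strand, tss, exons)
    gene.promoter_gc = promoter_gc(genome, "chr1", tss)
    gene.exonic_gc = exonic_gc(genome, gene)
    gene.tss_t_run = tss_t_run_length(genome, "chr1", tss, strand)
    expr = ExpressionProfile("one", pd.Series({"g1": 1.0}))
    return genome, [gene], expr
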