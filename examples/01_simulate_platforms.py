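"""Simulate one RNA pool on three platforms and compare signal quality.

Builds a small synthetic reference, draws an expression profile, and
sequences it as PCR-free CAGE, PCR-amplified CAGE and polyA-selected
RNA-seq.  The printed promoter/exon signal rates and ribosomal fractions
show each platform's readout character: CAGE tags concentrate at TSS
windows, and the RNA-seq ribosomal carryover is the most variable knob.
"""

from cagecompare import (
    ReferenceConfig,
    generate_reference,
    platform_preset,
    sample_expression,
    simulate_cage,
    simulate_rnaseq,
)
from cagecompare.quantify import signal_metrics

genome, genes = generate_reference(ReferenceConfig(n_genes=150), seed=1)
expr = sample_expression(genes, seed=2, log_sd=1.5, sample_id="pool")

for name, simulate, depth in [
    ("heliscope_cage", simulate_cage, 50_000),
    ("illumina_cage", simulate_cage, 50_000),
    ("rnaseq", simulate_rnaseq, 30_000),
]:
    reads = simulate(genome, genes, expr, platform_preset(name), depth, seed=3)
    m = signal_metrics(reads, genes)
    print(
        f"{name:16s} promoter/exon rate {m['promoter_rate']:.3f}  "
        f"rRNA rate {m['rrna_rate']:.3f}  mapped {int(m['mapped_total'])}"
    )
# A promoter rate near 1 means nearly every tag lands within 500 bp of an
# annotated TSS (or inside exons for RNA-seq); the rRNA rate is the
# unintended-signal fraction drawn per replicate.
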