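"""End-to-end synthetic study: simulate, quantify, compare, diagnose.

``run_demo`` reproduces the full analysis cycle on synthetic data — a
two-source mixture panel profiled by a PCR-free and a PCR-amplified CAGE
platform plus RNA-seq, followed by reproducibility metrics, clustering,
effective-ratio recovery and every bias diagnostic — writing all
artifacts in the package's text formats under one report directory.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare, diagnostics, io, mixing, quantify, reproducibility, synth
from .models import platform_preset

log = logging.getLogger("cagecompare")

_KNOWN_KEYS = {
    "seed",
    "n_genes",
    "depth_cage",
    "depth_rnaseq",
    "n_replicates",
    "mixture_ratios",
    "quantifiable_fraction_a",
    "quantifiable_fraction_b",
    "log_sd",
    "window",
    "min_count",
    "n_bins",
    "fdr",
    "top_n",
    "n_bootstrap",
    "platform_overrides",
}


@dataclass
class RunConfig:
    """Serializable configuration; a run is reproducible from it alone."""

    seed: int = 0
    n_genes: int = 150
    depth_cage: int = 50_000
    depth_rnaseq: int = 30_000
    n_replicates: int = 3
    mixture_ratios: list[float] = field(
        default_factory=lambda: [1.0, 0.99, 0.95, 0.90, 0.50, 0.0]
    )
    quantifiable_fraction_a: float = 0.84
    quantifiable_fraction_b: float = 0.36
    log_sd: float = 2.0
    window: int = 500
    min_count: int = 5
    n_bins: int = 10
    fdr: float = 0.05
    top_n: int = 8000
    n_bootstrap: int = 100
    platform_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(io.read_yaml(path))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def preset(self, name: str):
        return platform_preset(name, **self.platform_overrides.get(name, {}))


def _tpm_col(cm, sample: str) -> pd.Series:
    return quantify.normalize(cm, "tpm_tags")[sample]


def run_demo(config: RunConfig | None = None, outdir: str | Path = "demo_out") -> dict:
    """Run the full synthetic study and write a report directory.

    Returns a dict of headline numbers (also written to ``summary.yaml``).
    """
    config = config or RunConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, force=False)
    log.info("demo run with seed=%d -> %s", config.seed, out)
    master = np.random.default_rng(config.seed)

    def subseed() -> int:
        return int(master.integers(2**31))

    io.write_yaml(config.to_dict(), out / "config.yaml")

    # reference + expression
    ref_cfg = synth.ReferenceConfig(n_genes=config.n_genes)
    genome, genes = synth.generate_reference(ref_cfg, seed=subseed())
    io.write_fasta(genome, out / "genome.fa")
    io.write_gene_models(genes, out / "genes.bed", out / "genes.tsv")
    expr_a = synth.sample_expression(
        genes, seed=subseed(), log_sd=config.log_sd,
        quantifiable_fraction=config.quantifiable_fraction_a, sample_id="poolA",
    )
    expr_b = synth.sample_expression(
        genes, seed=subseed(), log_sd=config.log_sd,
        quantifiable_fraction=config.quantifiable_fraction_b, sample_id="poolB",
    )

    heli = config.preset("heliscope_cage")
    illu = config.preset("illumina_cage")
    rseq = config.preset("rnaseq")

    # mixture panel on the PCR-free platform
    panel_tables = []
    for r in config.mixture_ratios:
        profile = synth.compose_mixture(expr_a, expr_b, r)
        reads = synth.simulate_cage(genome, genes, profile, heli,
                                    config.depth_cage, seed=subseed())
        ctss = quantify.count_ctss(reads)
        io.write_ctss(ctss, out / f"ctss_heliscope_{profile.sample_id}.bed")
        panel_tables.append(ctss)
    panel_counts = quantify.gene_counts_cage(panel_tables, genes, config.window)
    io.write_counts(panel_counts, out / "counts_panel_heliscope.tsv")

    # replicates of both pure pools on both CAGE platforms
    rep_counts = {}
    for platform, label in ((heli, "heliscope"), (illu, "illumina")):
        for expr in (expr_a, expr_b):
            tables = []
            for i in range(config.n_replicates):
                reads = synth.simulate_cage(
                    genome, genes, expr.relabel(f"{expr.sample_id}_rep{i + 1}"),
                    platform, config.depth_cage, seed=subseed(),
                )
                tables.append(quantify.count_ctss(reads))
            rep_counts[(label, expr.sample_id)] = quantify.gene_counts_cage(
                tables, genes, config.window
            )
    rnaseq_reads = synth.simulate_rnaseq(
        genome, genes, expr_a, rseq, config.depth_rnaseq, seed=subseed()
    )
    rnaseq_counts = quantify.gene_counts_rnaseq(rnaseq_reads, genes)
    io.write_counts(rnaseq_counts, out / "counts_rnaseq_poolA.tsv")

    # reproducibility on the PCR-free pool-A replicates
    reps = rep_counts[("heliscope", "poolA")]
    io.write_counts(reps, out / "counts_replicates_heliscope_poolA.tsv")
    rho = reproducibility.spearman_pairwise(reps)
    rho.to_csv(out / "spearman_replicates.tsv", sep="\t")
    fit = reproducibility.estimate_common_dispersion(
        reps, min_genes=min(50, max(5, config.n_genes // 3))
    )
    pd.DataFrame([dataclasses.asdict(fit)]).to_csv(
        out / "dispersion_fit.tsv", sep="\t", index=False
    )

    # clustering of the mixture panel
    dendro = compare.cluster_with_bootstrap(
        panel_counts, top_n=config.top_n, n_bootstrap=config.n_bootstrap,
        seed=subseed(),
    )
    (out / "panel_dendrogram.nwk").write_text(dendro.to_newick() + "\n")

    # differential genes + cross-platform overlap of up-sets
    de_sets = {}
    for label in ("heliscope", "illumina"):
        de = compare.differential_genes(
            rep_counts[(label, "poolB")], rep_counts[(label, "poolA")], fdr=config.fdr
        )
        de.table.rename_axis("gene_id").to_csv(out / f"de_{label}.tsv", sep="\t")
        de_sets[label] = de.up
    venn = compare.overlap_sets(de_sets)

    # effective-ratio recovery from the 50:50 panel sample
    tpm_panel = quantify.normalize(panel_counts, "tpm_tags")
    pure_a_col = tpm_panel.iloc[:, config.mixture_ratios.index(1.0)]
    pure_b_col = tpm_panel.iloc[:, config.mixture_ratios.index(0.0)]
    mix_col = tpm_panel.iloc[:, config.mixture_ratios.index(0.50)]
    alphas = np.linspace(0, 1, 101)
    objective = mixing.ratio_objective(pure_a_col, pure_b_col, mix_col, alphas)
    objective.rename_axis("alpha").to_csv(out / "alpha_objective.tsv", sep="\t")
    alpha_star = mixing.estimate_effective_ratio(pure_a_col, pure_b_col, mix_col)

    # bias diagnostics: pool A on all platforms
    heli_a = rep_counts[("heliscope", "poolA")]
    illu_a = rep_counts[("illumina", "poolA")]
    gc_prom = pd.Series({g.gene_id: g.promoter_gc for g in genes})
    gc_exon = pd.Series({g.gene_id: g.exonic_gc for g in genes})
    illu_tpm = _tpm_col(illu_a, illu_a.samples[0])
    heli_tpm = _tpm_col(heli_a, heli_a.samples[0])
    rseq_tpm = _tpm_col(rnaseq_counts, rnaseq_counts.samples[0])

    gc_report = diagnostics.relative_expression_by_gc(
        illu_tpm, rseq_tpm, gc_prom, n_bins=config.n_bins
    )
    gc_report.strata.to_csv(out / "gc_bias_illumina_vs_rnaseq.tsv", sep="\t")
    gc_rnaseq = diagnostics.relative_expression_by_gc(
        rseq_tpm, heli_tpm, gc_exon, n_bins=config.n_bins
    )
    gc_rnaseq.strata.to_csv(out / "gc_bias_rnaseq_vs_heliscope.tsv", sep="\t")

    classes = diagnostics.scan_ecop15i_context(genes, genome)
    eco = diagnostics.relative_expression_by_ecop15i(illu_tpm, rseq_tpm, classes)
    eco.strata.to_csv(out / "ecop15i_bias.tsv", sep="\t")

    # single-base diagnostics on fresh single replicates of pool A
    heli_reads = synth.simulate_cage(genome, genes, expr_a, heli,
                                     config.depth_cage, seed=subseed())
    illu_reads = synth.simulate_cage(genome, genes, expr_a, illu,
                                     config.depth_cage, seed=subseed())
    heli_ctss = quantify.count_ctss(heli_reads)
    illu_ctss = quantify.count_ctss(illu_reads)
    table, base_medians = diagnostics.start_base_activity(
        illu_ctss, heli_ctss, genome, min_count=config.min_count
    )
    table.to_csv(out / "start_base_ratios.tsv", sep="\t")
    shift = diagnostics.detect_tstretch_shifts(
        heli_ctss, illu_ctss, genome, min_count=config.min_count
    )
    shift.shifts.to_csv(out / "tstretch_shifts.tsv", sep="\t", index=False)
    rho_raw, rho_smooth = diagnostics.correlate_at_resolution(illu_ctss, heli_ctss)
    specific = diagnostics.platform_specific_tss(illu_ctss, heli_ctss)

    summary = {
        "seed": config.seed,
        "replicate_spearman_min": float(
            rho.to_numpy()[~np.eye(len(rho), dtype=bool)].min()
        ),
        "relative_se_pct": 100.0 * fit.relative_se,
        "alpha_star_pct": 100.0 * alpha_star,
        "effective_share_50_50_pct": 100.0
        * synth.effective_share(expr_a, expr_b, 0.5),
        "gc_slope_illumina_vs_rnaseq": gc_report.slope,
        "ecop15i_contrast_log2": eco.difference,
        "start_base_median_log2": base_medians,
        "tstretch_shifted": shift.n_shifted,
        "tstretch_examined": shift.n_examined,
        "ctss_spearman_raw": rho_raw,
        "ctss_spearman_smoothed": rho_smooth,
        "platform_specific_x_only": len(specific["x_only"]),
        "platform_specific_x_unneighbored": len(specific["x_unneighbored"]),
        "de_up_common": venn["regions"][("heliscope", "illumina")],
        "de_up_heliscope_only": venn["regions"][("heliscope",)],
        "de_up_illumina_only": venn["regions"][("illumina",)],
    }
    io.write_yaml(summary, out / "summary.yaml")
    log.info("demo complete: %s", out / "summary.yaml")
    return summary
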