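"""Sample-level comparisons.

Hierarchical clustering of expression profiles on Spearman distance over
the most highly expressed genes, with gene-bootstrap support values; a
Wald-style negative-binomial differential test with Benjamini–Hochberg
control; and exact Venn-region overlap counts for named gene sets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .models import CountMatrix, rng_from_seed
from .reproducibility import estimate_common_dispersion


@dataclass
class Dendrogram:
    """Average-linkage merge tree with gene-bootstrap clade supports.

    ``supports`` maps each internal clade (frozenset of sample labels,
    excluding the root) to the fraction of ``B`` gene-resampled trees
    containing the same clade.
    """

    samples: list[str]
    linkage_matrix: np.ndarray
    supports: dict[frozenset, float]
    n_bootstrap: int
    distances: pd.DataFrame

    def nearest_neighbor(self, sample: str) -> str:
        d = self.distances.loc[sample].drop(sample)
        return str(d.idxmin())

    def to_newick(self) -> str:
        n = len(self.samples)
        Z = self.linkage_matrix

        def render(node: int) -> tuple[str, float, frozenset]:
            if node < n:
                return self.samples[node], 0.0, frozenset([self.samples[node]])
            a, b, height = int(Z[node - n, 0]), int(Z[node - n, 1]), Z[node - n, 2]
            ra, ha, la = render(a)
            rb, hb, lb = render(b)
            clade = la | lb
            label = ""
            if clade in self.supports:
                label = f"{self.supports[clade]:.3f}"
            text = f"({ra}:{(height - ha) / 2:.6g},{rb}:{(height - hb) / 2:.6g}){label}"
            return text, height, clade

        text, _, _ = render(2 * n - 2)
        return text + ";"


def _clades(Z: np.ndarray, samples: list[str]) -> set[frozenset]:
    n = len(samples)
    members: list[frozenset] = [frozenset([s]) for s in samples]
    clades = set()
    for a, b, _, _ in Z:
        clade = members[int(a)] | members[int(b)]
        members.append(clade)
        if 1 < len(clade) < n:
            clades.add(clade)
    return clades


def _spearman_linkage(data: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    corr = data.corr(method="spearman")
    dist = 1.0 - corr
    condensed = squareform(dist.to_numpy(), checks=False)
    return linkage(condensed, method="average"), dist


def cluster_with_bootstrap(
    matrix: CountMatrix | pd.DataFrame,
    top_n: int = 8000,
    n_bootstrap: int = 1000,
    seed: int | np.random.Generator = 0,
    method: str = "average",
) -> Dendrogram:
    """Cluster samples on 1 - Spearman over the top expressed genes.

    Genes are ranked by mean expression across samples and the ``top_n``
    highest retained; support for each clade is the fraction of
    ``n_bootstrap`` gene resamples (with replacement, same size) whose
    tree contains the same clade.  Spearman distance makes the result
    invariant to monotone per-sample transforms, so raw counts and TPM
    give the same tree.
    """
    data = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    if data.shape[1] < 3:
        raise ValueError("need at least three samples to cluster")
    rng = rng_from_seed(seed)
    if top_n > data.shape[0]:
        warnings.warn(f"top_n={top_n} exceeds {data.shape[0]} genes; using all")
        top_n = data.shape[0]
    ranked = data.mean(axis=1).sort_values(ascending=False, kind="mergesort")
    top = data.loc[ranked.index[:top_n]]

    def tree(df: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
        Z, dist = _spearman_linkage(df)
        return Z, dist

    Z, dist = tree(top)
    samples = list(data.columns)
    observed = _clades(Z, samples)
    hits = {clade: 0 for clade in observed}
    for _ in range(n_bootstrap):
        rows = rng.integers(0, len(top), size=len(top))
        Zb, _ = tree(top.iloc[rows])
        boot = _clades(Zb, samples)
        for clade in observed & boot:
            hits[clade] += 1
    supports = {c: hits[c] / n_bootstrap for c in observed} if n_bootstrap else {}
    return Dendrogram(
        samples=samples,
        linkage_matrix=Z,
        supports=supports,
        n_bootstrap=n_bootstrap,
        distances=dist,
    )


@dataclass
class DifferentialResult:
    table: pd.DataFrame  # gene, log2fc, z, p, q
    up: set  # significantly higher in condition A
    down: set
    phi: float
    fdr: float


def differential_genes(
    counts_a: CountMatrix,
    counts_b: CountMatrix,
    fdr: float = 0.05,
    pseudocount: float = 0.5,
) -> DifferentialResult:
    """Wald-style NB test for per-gene differences between two conditions.

    Library-size-scaled condition means are compared on the log scale,
    with standard error ``sqrt(1/sum(xA) + 1/sum(xB) + 2*phi)`` where
    ``phi`` is the common overdispersion pooled across conditions (0 when
    neither condition has replicates).  Two-sided normal p-values are
    Benjamini–Hochberg adjusted.
    """
    genes = counts_a.counts.index
    if not genes.equals(counts_b.counts.index):
        raise ValueError("conditions cover different gene sets")
    phis = []
    for cm in (counts_a, counts_b):
        if cm.counts.shape[1] >= 2:
            try:
                phis.append(estimate_common_dispersion(cm).phi)
            except ValueError:
                pass
    if not phis:
        warnings.warn("no replicated condition: testing with phi = 0")
    phi = float(np.mean(phis)) if phis else 0.0

    all_lib = pd.concat([counts_a.library_sizes, counts_b.library_sizes])
    mean_lib = all_lib.mean()

    def cond_stats(cm: CountMatrix) -> tuple[pd.Series, pd.Series]:
        s = (cm.library_sizes / mean_lib).sum()
        total = cm.counts.sum(axis=1).astype(float)
        return total, (total + pseudocount) / s

    tot_a, mu_a = cond_stats(counts_a)
    tot_b, mu_b = cond_stats(counts_b)
    nonzero = (tot_a + tot_b) > 0
    se = np.sqrt(
        1.0 / (tot_a[nonzero] + pseudocount)
        + 1.0 / (tot_b[nonzero] + pseudocount)
        + 2.0 * phi
    )
    logfc = np.log(mu_a[nonzero]) - np.log(mu_b[nonzero])
    z = logfc / se
    p = 2.0 * norm.sf(np.abs(z))
    q = pd.Series(
        multipletests(p, alpha=fdr, method="fdr_bh")[1], index=z.index
    )
    table = pd.DataFrame(
        {
            "log2fc": logfc / np.log(2.0),
            "z": z,
            "p": p,
            "q": q,
        }
    )
    sig = table.index[table["q"] <= fdr]
    up = set(sig[table.loc[sig, "z"] > 0])
    down = set(sig[table.loc[sig, "z"] < 0])
    return DifferentialResult(table=table, up=up, down=down, phi=phi, fdr=fdr)


def overlap_sets(named_sets: dict[str, set]) -> dict:
    """Exact Venn-region counts for two or more named sets.

    Returns region counts keyed by the sorted tuple of member names (each
    element counted in exactly one region) plus the common fraction
    ``|intersection of all| / |union of all|``.
    """
    names = list(named_sets)
    if len(names) < 2:
        raise ValueError("need at least two sets")
    sets = {k: set(v) for k, v in named_sets.items()}
    universe = set().union(*sets.values())
    regions = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo), set())
            regions[tuple(sorted(combo))] = len(inside - outside)
    inter_all = set.intersection(*sets.values())
    common_fraction = len(inter_all) / len(universe) if universe else 0.0
    return {"regions": regions, "common_fraction": common_fraction}
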