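"""Replicate-concordance metrics.

Two complementary views of technical reproducibility: pairwise Spearman
correlation of gene counts (depth-dependent: deeper libraries correlate
higher), and a depth-independent *relative standard error* defined as the
square root of a common negative-binomial overdispersion fitted across
replicates.  A relative SE of 0.10 means replicate expression values
scatter around their mean with a ~10% coefficient of variation beyond
counting noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import spearmanr

from .models import CountMatrix

PHI_BRACKET = (1e-6, 1.0)


@dataclass
class DispersionFit:
    """Common NB overdispersion and derived relative standard error."""

    phi: float
    relative_se: float
    n_genes_used: int
    log_likelihood: float


def spearman_pairwise(matrix: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Spearman matrix with midrank ties.

    Each pair is computed over genes nonzero in at least one of the two
    samples; a constant vector within a pair makes the correlation
    undefined and raises.
    """
    data = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    cols = list(data.columns)
    if len(cols) < 2:
        raise ValueError("need at least two samples")
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            x = data[a].to_numpy(dtype=float)
            y = data[b].to_numpy(dtype=float)
            keep = (x != 0) | (y != 0)
            x, y = x[keep], y[keep]
            if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
                raise ValueError(f"correlation undefined for pair ({a}, {b})")
            rho = spearmanr(x, y).statistic
            out.loc[a, b] = out.loc[b, a] = rho
    return out


def _nb_conditional_loglik(phi: float, x: np.ndarray) -> float:
    """Common-dispersion NB log-likelihood conditional on per-gene totals.

    For ``n`` replicates of near-equal library size sharing a gene mean,
    conditioning on the gene total removes the mean and leaves (up to
    terms free of ``phi``)::

        sum_i lnG(x_i + r) - n lnG(r) + lnG(n r) - lnG(z + n r),  r = 1/phi

    summed over genes.  Unlike a profile likelihood with plug-in means,
    this is approximately unbiased at small replicate numbers.
    """
    n = x.shape[1]
    r = 1.0 / max(phi, 1e-12)
    z = x.sum(axis=1)
    ll = (
        gammaln(x + r).sum(axis=1)
        - n * gammaln(r)
        + gammaln(n * r)
        - gammaln(z + n * r)
    )
    return float(ll.sum())


def _golden_section_max(f, lo: float, hi: float, tol: float = 1e-6) -> float:
    """Maximise a unimodal function on [lo, hi] by golden-section search."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def estimate_common_dispersion(
    replicates: CountMatrix | pd.DataFrame,
    library_sizes: pd.Series | None = None,
    min_mean: float = 5.0,
    min_genes: int = 50,
) -> DispersionFit:
    """Fit one NB overdispersion shared by all genes across replicates.

    Genes with mean count below ``min_mean`` are dropped (they carry
    little dispersion information).  The likelihood is conditioned on
    each gene's total count, removing the unknown gene means (library
    sizes are assumed near-equal across replicates, which holds for
    technical replicates sequenced to the same depth); the result is
    invariant to uniform library-size rescaling.  ``phi`` is maximised
    over ``[1e-6, 1]`` by golden-section search.
    """
    if isinstance(replicates, CountMatrix):
        data = replicates.counts
        library_sizes = replicates.library_sizes
    else:
        data = replicates
        if library_sizes is None:
            library_sizes = data.sum(axis=0).astype(float)
    if data.shape[1] < 2:
        raise ValueError("need at least two replicate columns")
    x = data.to_numpy(dtype=float)
    keep = x.mean(axis=1) >= min_mean
    if keep.sum() < min_genes:
        raise ValueError(
            f"only {int(keep.sum())} genes with mean count >= {min_mean}; "
            f"need {min_genes}"
        )
    x = x[keep]
    f = lambda phi: _nb_conditional_loglik(phi, x)
    phi_hat = _golden_section_max(f, *PHI_BRACKET)
    return DispersionFit(
        phi=phi_hat,
        relative_se=float(np.sqrt(phi_hat)),
        n_genes_used=int(keep.sum()),
        log_likelihood=f(phi_hat),
    )
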