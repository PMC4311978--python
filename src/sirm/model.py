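"""Log-probability kernels of the generative model.

The model couples three pieces:

1. A Chinese restaurant process prior over partitions Z with concentration
   xi, so the number of clusters K is learned rather than fixed.
2. A stochastic block model for the latent binary connectome A: edges are
   Bernoulli with a probability rho_ab that depends only on the clusters of
   the endpoints, and rho_ab has a Beta(alpha, beta) prior.  rho is always
   integrated out analytically (Beta-Bernoulli conjugacy), so the collapsed
   likelihood of A given Z is a product of Beta-function ratios over block
   sufficient statistics.
3. A Dirichlet-compound-multinomial (DirMul) forward model for the observed
   streamline counts: for seed region i, the row of counts over the n-1
   other regions is DirMul with pseudo-count delta_t on true connections
   (a_ij = 1) and delta_f on false ones.

Multiple subjects share the partition Z but have independent connectomes
A^(m) and block probabilities rho^(m), so per-subject likelihood terms add.

All computation is in log space via log-gamma; no factorials or Beta
functions are evaluated directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import betaln, gammaln

from .core import Adjacency, HyperParams, Partition, StreamlineData

__all__ = [
    "BlockProbabilities",
    "BlockSufficientStats",
    "crp_log_prob",
    "crp_predictive",
    "block_stats",
    "irm_marginal_loglik",
    "dirmul_row_loglik",
    "dirmul_matrix_loglik",
    "joint_log_posterior",
    "posterior_rho",
]


@dataclass(frozen=True)
class BlockProbabilities:
    """K x K symmetric matrix of cluster-to-cluster connection probabilities."""

    rho: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rho, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("rho must be square")
        if np.any(r < 0) or np.any(r > 1):
            raise ValueError("rho entries must lie in [0, 1]")
        if not np.allclose(r, r.T):
            raise ValueError("rho must be symmetric")
        object.__setattr__(self, "rho", r)

    @property
    def K(self) -> int:
        return int(self.rho.shape[0])


@dataclass(frozen=True)
class BlockSufficientStats:
    """Edge/non-edge counts per block pair, over unordered dyads i < j.

    ``n1[a, b]`` is the number of present edges between clusters a and b and
    ``n0[a, b]`` the number of absent dyads; within-cluster blocks count each
    unordered pair once, and the symmetric (a, b)/(b, a) entries are pooled
    views of the same block.
    """

    n1: np.ndarray
    n0: np.ndarray

    def __post_init__(self) -> None:
        if self.n1.shape != self.n0.shape:
            raise ValueError("n1 and n0 must have the same shape")
        if np.any(self.n1 < 0) or np.any(self.n0 < 0):
            raise ValueError("block counts must be non-negative")

    @property
    def K(self) -> int:
        return int(self.n1.shape[0])

    @property
    def total_dyads(self) -> int:
        iu = np.triu_indices(self.K)
        return int(self.n1[iu].sum() + self.n0[iu].sum())


def crp_log_prob(partition: Partition, xi: float) -> float:
    """Exchangeable CRP partition log-probability.

    log P(Z) = K log(xi) + sum_k log (m_k - 1)! - sum_{i=0}^{N-1} log(xi + i);
    invariant to the order in which nodes are seated.
    """
    if xi <= 0:
        raise ValueError("xi must be positive")
    sizes = partition.sizes
    n = partition.n
    return float(
        partition.K * np.log(xi)
        + gammaln(sizes).sum()
        - np.log(xi + np.arange(n)).sum()
    )


def crp_predictive(sizes: Sequence[int], xi: float) -> np.ndarray:
    """Unnormalized seating weights for one node given the others.

    Returns ``[m_1, ..., m_K, xi]``: occupancy for each existing cluster and
    the concentration xi for a new cluster.  The shared denominator
    (N - 1 + xi) cancels in Gibbs ratios and is omitted.
    """
    if xi <= 0:
        raise ValueError("xi must be positive")
    sizes = np.asarray(sizes, dtype=float)
    return np.append(sizes, xi)


def block_stats(adjacency: Adjacency, partition: Partition) -> BlockSufficientStats:
    """Sufficient statistics of the collapsed block likelihood.

    Counts present edges and absent dyads per block pair over unordered
    dyads i < j; the diagonal of A never enters.
    """
    if adjacency.n != partition.n:
        raise ValueError("adjacency and partition sizes differ")
    z = partition.onehot()
    sizes = partition.sizes
    pair_edges = z.T @ adjacency.edges.astype(np.int64) @ z
    n1 = pair_edges.copy()
    np.fill_diagonal(n1, np.diag(pair_edges) // 2)
    dyads = np.outer(sizes, sizes)
    np.fill_diagonal(dyads, sizes * (sizes - 1) // 2)
    return BlockSufficientStats(n1=n1, n0=dyads - n1)


def irm_marginal_loglik(stats: BlockSufficientStats, alpha: float, beta: float) -> float:
    """Collapsed log-likelihood of A given Z, with rho integrated out.

    Sum over block pairs a <= b of log B(alpha + n1, beta + n0) - log
    B(alpha, beta).  For several subjects, call once per subject with that
    subject's stats (same Z) and add.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    iu = np.triu_indices(stats.K)
    n1, n0 = stats.n1[iu], stats.n0[iu]
    return float((betaln(alpha + n1, beta + n0) - betaln(alpha, beta)).sum())


def dirmul_row_loglik(
    counts_row: np.ndarray,
    adj_row: np.ndarray,
    delta_t: float,
    delta_f: float,
) -> float:
    """Log DirMul pmf of one seed row of streamline counts.

    Both rows must already exclude the self entry (length n - 1).  The
    Dirichlet parameter is delta_t where the adjacency row is 1 and delta_f
    where it is 0; the multinomial coefficient is included so the pmf
    normalizes (it cancels in all sampling ratios).
    """
    if delta_t <= 0 or delta_f <= 0:
        raise ValueError("delta_t and delta_f must be positive")
    s = np.asarray(counts_row, dtype=np.int64)
    a = np.asarray(adj_row)
    if s.shape != a.shape:
        raise ValueError("count and adjacency rows must align")
    alpha = np.where(a == 1, delta_t, delta_f)
    total_alpha = alpha.sum()
    total = s.sum()
    return float(
        gammaln(total + 1)
        - gammaln(s + 1).sum()
        + gammaln(total_alpha)
        - gammaln(total_alpha + total)
        + (gammaln(alpha + s) - gammaln(alpha)).sum()
    )


def dirmul_matrix_loglik(
    streamlines: StreamlineData,
    adjacency: Adjacency,
    delta_t: float,
    delta_f: float,
) -> float:
    """Sum of dirmul_row_loglik over all seed rows (diagonal excluded)."""
    if delta_t <= 0 or delta_f <= 0:
        raise ValueError("delta_t and delta_f must be positive")
    s = streamlines.counts
    n = s.shape[0]
    if adjacency.n != n:
        raise ValueError("streamline and adjacency sizes differ")
    off = ~np.eye(n, dtype=bool)
    alpha = np.where(adjacency.edges == 1, delta_t, delta_f)
    row_alpha = np.where(off, alpha, 0.0).sum(axis=1)
    totals = np.where(off, s, 0).sum(axis=1)
    per_row = (
        gammaln(totals + 1)
        - np.where(off, gammaln(s + 1), 0.0).sum(axis=1)
        + gammaln(row_alpha)
        - gammaln(row_alpha + totals)
        + np.where(off, gammaln(alpha + s) - gammaln(alpha), 0.0).sum(axis=1)
    )
    return float(per_row.sum())


def joint_log_posterior(
    streamlines: Sequence[StreamlineData],
    adjacencies: Sequence[Adjacency],
    partition: Partition,
    hp: HyperParams,
) -> float:
    """Joint log-density of (Z, {A^(m)}, {S^(m)}) up to a constant.

    CRP prior on Z, plus per subject the collapsed block likelihood of
    A^(m) given Z and the DirMul likelihood of S^(m) given A^(m).  Used to
    rank posterior samples for the MAP estimate.
    """
    if len(streamlines) != len(adjacencies):
        raise ValueError("need one adjacency per subject")
    total = crp_log_prob(partition, hp.xi)
    for s, a in zip(streamlines, adjacencies):
        if s.n != partition.n or a.n != partition.n:
            raise ValueError("inconsistent matrix dimensions")
        total += irm_marginal_loglik(block_stats(a, partition), hp.alpha, hp.beta)
        total += dirmul_matrix_loglik(s, a, hp.delta_t, hp.delta_f)
    return float(total)


def posterior_rho(
    adjacency: Adjacency,
    partition: Partition,
    alpha: float = 1.0,
    beta: float = 1.0,
) -> BlockProbabilities:
    """Posterior mean of the block connection probabilities rho.

    Beta posterior mean per block: (alpha + n1) / (alpha + beta + n1 + n0).
    Blocks with no dyads (singleton cluster with itself) fall back to the
    prior mean alpha / (alpha + beta).
    """
    stats = block_stats(adjacency, partition)
    rho = (alpha + stats.n1) / (alpha + beta + stats.n1 + stats.n0)
    return BlockProbabilities(rho=rho)
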