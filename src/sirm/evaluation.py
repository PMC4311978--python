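"""Parcellation quality and interpretation statistics.

Adjusted mutual information (AMI) scores the similarity of two partitions
while correcting for chance agreement under the hypergeometric permutation
model, so parcellations with different cluster counts are comparable.  The
community ratio r_c separates community-like clusters (dense within-cluster
streamlines, r_c near 1) from profile-based clusters that group regions by
shared external targets (r_c near 0).  Cluster probability maps and color
interpolation turn the posterior co-assignment matrix into per-region
uncertainty read-outs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import exp, lgamma, log

import numpy as np

from .core import Partition, StreamlineData

logger = logging.getLogger("sirm")

__all__ = [
    "ContingencyTable",
    "ami",
    "expected_mutual_information",
    "community_ratio",
    "cluster_probability_map",
    "interpolate_colors",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Co-occurrence counts between two partitions of the same N nodes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or np.any(c < 0):
            raise ValueError("contingency counts must be a non-negative matrix")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_partitions(cls, z1: Partition, z2: Partition) -> "ContingencyTable":
        if z1.n != z2.n:
            raise ValueError("partitions must cover the same nodes")
        counts = np.zeros((z1.K, z2.K), dtype=np.int64)
        np.add.at(counts, (z1.assignment, z2.assignment), 1)
        return cls(counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginal(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginal(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def _entropy(marginal: np.ndarray, n: int) -> float:
    p = marginal[marginal > 0] / n
    return float(-(p * np.log(p)).sum())


def _mutual_information(table: ContingencyTable) -> float:
    n = table.n
    a = table.row_marginal
    b = table.col_marginal
    mi = 0.0
    for i, j in zip(*np.nonzero(table.counts)):
        nij = table.counts[i, j]
        mi += nij / n * log(n * nij / (a[i] * b[j]))
    return mi


def expected_mutual_information(table: ContingencyTable) -> float:
    """Expected MI between two partitions with these marginals under the
    hypergeometric (random permutation) model.

    Sums, for every cell (i, j), n_ij/N * log(N n_ij / (a_i b_j)) weighted
    by the hypergeometric probability of drawing n_ij overlaps; evaluated
    with log-gamma for numerical safety.
    """
    n = table.n
    a = table.row_marginal
    b = table.col_marginal
    lg = lgamma
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                log_pmf = (
                    lg(ai + 1)
                    + lg(bj + 1)
                    + lg(n - ai + 1)
                    + lg(n - bj + 1)
                    - lg(n + 1)
                    - lg(nij + 1)
                    - lg(ai - nij + 1)
                    - lg(bj - nij + 1)
                    - lg(n - ai - bj + nij + 1)
                )
                emi += nij / n * log(n * nij / (ai * bj)) * exp(log_pmf)
    return emi


def ami(z1: Partition, z2: Partition) -> float:
    """Adjusted mutual information between two partitions.

    AMI = (MI - EMI) / (max(H1, H2) - EMI) with the max-entropy
    normalization.  Invariant to cluster relabelling; 1 for identical
    non-trivial partitions.  If both partitions are a single cluster the
    denominator vanishes; by convention the score is 1 (logged).
    """
    table = ContingencyTable.from_partitions(z1, z2)
    h1 = _entropy(table.row_marginal, table.n)
    h2 = _entropy(table.col_marginal, table.n)
    denom_base = max(h1, h2)
    if denom_base == 0.0:
        logger.info("both partitions are trivial (one cluster); AMI defined as 1")
        return 1.0
    mi = _mutual_information(table)
    emi = expected_mutual_information(table)
    denom = denom_base - emi
    if denom == 0.0:
        return 1.0 if mi >= denom_base else 0.0
    return (mi - emi) / denom


def community_ratio(
    streamlines: StreamlineData,
    partition: Partition,
) -> tuple[np.ndarray, np.ndarray]:
    """Within-cluster streamline fraction r_c per cluster and per node.

    Expects symmetrized counts.  For cluster c, r_c is the number of
    streamlines between members of c (each unordered pair once) divided by
    all streamlines touching c (within plus between, between pairs counted
    fully toward both clusters they touch).  r_c near 1 marks a community;
    near 0 a profile-based cluster or hub.  A singleton has no internal
    dyads so r_c = 0; a cluster with no incident streamlines at all has an
    undefined ratio, reported as NaN.

    Returns (per-cluster ratios, per-node scores).
    """
    s = streamlines.counts
    if not np.array_equal(s, s.T):
        raise ValueError("community_ratio expects symmetrized counts (S + S^T)")
    if streamlines.n != partition.n:
        raise ValueError("streamlines and partition sizes differ")
    z = partition.onehot()
    blocks = z.T @ s @ z  # blocks[c, k] = streamline mass between clusters c and k
    within = np.diag(blocks) / 2.0  # each unordered within pair counted twice
    between = blocks.sum(axis=1) - np.diag(blocks)
    denom = within + between
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(denom > 0, within / denom, np.nan)
    node_scores = ratios[partition.assignment]
    return ratios, node_scores


def cluster_probability_map(coassign: np.ndarray, region: int) -> np.ndarray:
    """Row of E[M] for one region: its probability of sharing a cluster with
    every other region (self-entry 1)."""
    coassign = np.asarray(coassign)
    if not 0 <= region < coassign.shape[0]:
        raise IndexError(f"region index {region} out of range")
    return coassign[region].copy()


def interpolate_colors(coassign: np.ndarray, map_colors: np.ndarray) -> np.ndarray:
    """Blend per-region colors by co-assignment uncertainty.

    c_i = sum_j m_ij chat_j / sum_j m_ij, with chat_j the reference (MAP)
    color of region j as an RGB triple in [0, 1].  A region co-assigned
    half-and-half to a red and a yellow cluster comes out orange.
    """
    m = np.asarray(coassign, dtype=float)
    colors = np.asarray(map_colors, dtype=float)
    if colors.ndim != 2 or colors.shape[0] != m.shape[0] or colors.shape[1] != 3:
        raise ValueError("map_colors must be an N x 3 RGB array")
    if np.any(colors < 0) or np.any(colors > 1):
        raise ValueError("color components must lie in [0, 1]")
    weights = m.sum(axis=1)
    if np.any(weights <= 0):
        raise ValueError("each co-assignment row must have positive mass")
    return (m @ colors) / weights[:, None]
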