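"""Forward simulation from the generative model.

Everything the sampler infers can be planted here: a partition drawn from
the Chinese restaurant process, a connectome drawn block-Bernoulli from a
planted partition and block probabilities, and streamline counts drawn
Dirichlet-multinomial from the connectome.  The twelve-node toy network
(three equal clusters) comes in two regimes — ``community`` with heavy
diagonal block probabilities and ``profile`` with heavy off-diagonal ones —
and is the smallest setting in which the two clustering interpretations
separate cleanly.

Default row totals are 1000 streamlines per seed region, a realistic order
of magnitude for region-level probabilistic tractography after aggregating
seed voxels; it is configurable everywhere.
"""

from __future__ import annotations

import numpy as np

from .core import Adjacency, Partition, StreamlineData
from .model import BlockProbabilities

__all__ = [
    "sample_partition",
    "sample_network",
    "sample_streamlines",
    "make_toy",
    "DEFAULT_ROW_TOTAL",
]

DEFAULT_ROW_TOTAL = 1000


def sample_partition(n: int, xi: float, rng: np.random.Generator) -> Partition:
    """Draw a partition of n nodes by sequential CRP seating."""
    if n < 1:
        raise ValueError("need at least one node")
    if xi <= 0:
        raise ValueError("xi must be positive")
    z = np.zeros(n, dtype=np.int64)
    sizes: list[int] = []
    for i in range(n):
        w = np.array(sizes + [xi], dtype=float)
        c = int(rng.choice(w.size, p=w / w.sum()))
        z[i] = c
        if c == len(sizes):
            sizes.append(1)
        else:
            sizes[c] += 1
    return Partition(z)


def sample_network(
    partition: Partition,
    rho: BlockProbabilities,
    rng: np.random.Generator,
) -> Adjacency:
    """Draw a symmetric binary network with block-wise edge probabilities.

    Each unordered dyad (i, j), i < j, is an independent Bernoulli draw
    with probability rho[cluster(i), cluster(j)]; the diagonal stays zero.
    """
    if rho.K != partition.K:
        raise ValueError(f"rho is {rho.K}x{rho.K} but partition has K={partition.K}")
    n = partition.n
    z = partition.assignment
    p = rho.rho[np.ix_(z, z)]
    iu = np.triu_indices(n, k=1)
    a = np.zeros((n, n), dtype=np.uint8)
    draws = (rng.random(iu[0].size) < p[iu]).astype(np.uint8)
    a[iu] = draws
    a += a.T
    return Adjacency(a)


def sample_streamlines(
    adjacency: Adjacency,
    delta_t: float,
    delta_f: float,
    row_totals: int | np.ndarray = DEFAULT_ROW_TOTAL,
    rng: np.random.Generator | None = None,
) -> StreamlineData:
    """Draw streamline counts row by row from the forward model.

    For seed region i a probability vector over the n - 1 targets is drawn
    from Dirichlet(delta_t on true connections, delta_f on false ones) and
    T_i streamlines are distributed multinomially.  Marginally the counts
    follow the Dirichlet-compound-multinomial pmf exactly.
    """
    if delta_t <= 0 or delta_f <= 0:
        raise ValueError("delta_t and delta_f must be positive")
    if rng is None:
        rng = np.random.default_rng()
    n = adjacency.n
    totals = np.broadcast_to(np.asarray(row_totals, dtype=np.int64), (n,))
    if np.any(totals < 0):
        raise ValueError("row totals must be non-negative")
    s = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        targets = np.arange(n) != i
        alpha = np.where(adjacency.edges[i, targets] == 1, delta_t, delta_f)
        if totals[i] == 0:
            continue
        x = rng.dirichlet(alpha)
        s[i, targets] = rng.multinomial(totals[i], x)
    return StreamlineData(s, regions=adjacency.regions)


def make_toy(
    regime: str,
    rng: np.random.Generator,
    rho_strong: float = 0.9,
    rho_weak: float = 0.05,
) -> tuple[Partition, BlockProbabilities, Adjacency]:
    """Twelve-node toy network: three equal clusters of four.

    ``community`` puts the strong probability on the diagonal blocks (dense
    within, sparse between); ``profile`` reverses it, so cluster-mates share
    targets without connecting to each other.  Default probabilities
    0.9/0.05 give a strong contrast; both are configurable.
    """
    if regime not in ("community", "profile"):
        raise ValueError("regime must be 'community' or 'profile'")
    partition = Partition(np.repeat(np.arange(3), 4))
    k = partition.K
    if regime == "community":
        rho = np.full((k, k), rho_weak)
        np.fill_diagonal(rho, rho_strong)
    else:
        rho = np.full((k, k), rho_strong)
        np.fill_diagonal(rho, rho_weak)
    block = BlockProbabilities(rho)
    adjacency = sample_network(partition, block, rng)
    return partition, block, adjacency
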