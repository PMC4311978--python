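"""Block Gibbs sampling over (Z, {A^(m)}) and posterior summaries.

Three pipelines share one sampler core:

* ``sirm`` — joint inference from streamline counts: every sweep resamples
  each latent edge of each subject from its full conditional (collapsed
  block prior odds times the DirMul likelihood ratio of the two affected
  seed rows), then each node's cluster assignment from the collapsed
  posterior over existing clusters plus a new one.
* ``birm`` — the adjacencies are observed (pre-thresholded or estimated
  elsewhere) and held fixed; only Z is sampled.
* ``flat`` — connectivity estimation with a uniform prior P(A) ∝ 1; only
  the edges are sampled and clustering plays no role.  Feeding the MAP
  connectomes of a flat run into a ``birm`` run is the two-stage pipeline.

The block-model parameter rho is never instantiated: Beta-Bernoulli
conjugacy lets every conditional be computed from the block sufficient
statistics (n1, n0), which the sampler maintains incrementally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from math import exp, lgamma, log
from typing import Sequence

import numpy as np
from scipy.special import betaln

from .core import (
    Adjacency,
    HyperParams,
    Partition,
    Sample,
    SampleChain,
    StreamlineData,
)
from .model import (
    BlockSufficientStats,
    block_stats,
    crp_log_prob,
    dirmul_matrix_loglik,
    irm_marginal_loglik,
)

logger = logging.getLogger("sirm")

__all__ = [
    "SamplerConfig",
    "run_sampler",
    "birm_pipeline",
    "initial_adjacency",
    "map_estimate",
    "coassignment_expectation",
    "credible_interval_K",
]

_MODES = {"sirm": "sirm", "birm": "birm", "flat": "flat", "flata": "flat"}


@dataclass(frozen=True)
class SamplerConfig:
    """Run-length and mode settings for the Gibbs sampler.

    ``prior_only`` drops every likelihood term from the assignment update so
    the chain targets the bare CRP prior; ``fix_partition`` freezes Z at its
    initial value so the edge sampler targets P(A | S, Z).  Both are
    sampler-validation switches, not analysis modes.
    """

    sweeps: int = 2000
    burn_in: int = 1000
    thinning: int = 2
    seed: int = 0
    mode: str = "sirm"
    prior_only: bool = False
    fix_partition: bool = False
    log_every: int = 100

    def __post_init__(self) -> None:
        if not (self.sweeps > self.burn_in >= 0):
            raise ValueError("need sweeps > burn_in >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        mode = _MODES.get(self.mode.lower())
        if mode is None:
            raise ValueError(f"unknown mode {self.mode!r}; use sirm, birm or flat")
        object.__setattr__(self, "mode", mode)

    def to_dict(self) -> dict:
        return {
            "sweeps": self.sweeps,
            "burn_in": self.burn_in,
            "thinning": self.thinning,
            "seed": self.seed,
            "mode": self.mode,
            "prior_only": self.prior_only,
        }


# ---------------------------------------------------------------------------
# Sampler state with incremental block sufficient statistics
# ---------------------------------------------------------------------------


class _GibbsState:
    """Mutable sampler state: z, per-subject A, and cached statistics.

    Hyperparameters are held as plain positive floats; the public entry
    point validates the stronger delta_t > delta_f contract.
    """

    def __init__(
        self,
        z: np.ndarray,
        adjacencies: list[np.ndarray],
        counts: list[np.ndarray] | None,
        xi: float,
        alpha: float,
        beta: float,
        delta_t: float,
        delta_f: float,
    ) -> None:
        if min(xi, alpha, beta, delta_t, delta_f) <= 0:
            raise ValueError("all hyperparameters must be positive")
        self.z = np.asarray(z, dtype=np.int64).copy()
        self.N = self.z.size
        self.A = [np.asarray(a, dtype=np.int64).copy() for a in adjacencies]
        self.M = len(self.A)
        self.S = None if counts is None else [np.asarray(s, dtype=np.int64) for s in counts]
        self.T = None if counts is None else [s.sum(axis=1) for s in self.S]
        self.deg = [a.sum(axis=1) for a in self.A]
        self.xi, self.alpha, self.beta = xi, alpha, beta
        self.delta_t, self.delta_f = delta_t, delta_f
        self._rebuild_block_stats()

    # -- bookkeeping -------------------------------------------------------

    def _rebuild_block_stats(self) -> None:
        part = Partition(self.z)
        self.z = part.assignment  # canonical labels
        self.K = part.K
        self.sizes = part.sizes.astype(np.int64)
        self.n1 = []
        self.n0 = []
        for a in self.A:
            st = block_stats(Adjacency(a.astype(np.uint8)), part)
            self.n1.append(st.n1.astype(np.int64))
            self.n0.append(st.n0.astype(np.int64))

    def stats(self, m: int) -> BlockSufficientStats:
        return BlockSufficientStats(n1=self.n1[m].copy(), n0=self.n0[m].copy())

    # -- edge update -------------------------------------------------------

    def edge_log_odds(self, i: int, j: int, m: int, block_prior: bool) -> float:
        """Log odds of a_ij = 1 vs 0 given everything else.

        The two affected seed rows both enter (s_ij and s_ji are separate
        observations); `block_prior` selects the collapsed IRM prior on the
        dyad versus the flat P(A) ∝ 1.
        """
        if i == j:
            raise ValueError("no self-dyads")
        dT, dF = self.delta_t, self.delta_f
        a_cur = self.A[m][i, j]
        lo = 0.0
        for r, c in ((i, j), (j, i)):
            s_rc = int(self.S[m][r, c])
            base = dT * self.deg[m][r] + dF * (self.N - 1 - self.deg[m][r])
            base -= dT if a_cur else dF
            a1, a0 = base + dT, base + dF
            t = int(self.T[m][r])
            lo += (lgamma(a1) - lgamma(a1 + t) + lgamma(dT + s_rc) - lgamma(dT)) - (
                lgamma(a0) - lgamma(a0 + t) + lgamma(dF + s_rc) - lgamma(dF)
            )
        if block_prior:
            bi, bj = self.z[i], self.z[j]
            n1p = self.n1[m][bi, bj] - a_cur
            n0p = self.n0[m][bi, bj] - (1 - a_cur)
            lo += log(self.alpha + n1p) - log(self.beta + n0p)
        return lo

    def set_edge(self, i: int, j: int, m: int, value: int) -> None:
        old = self.A[m][i, j]
        if old == value:
            return
        self.A[m][i, j] = self.A[m][j, i] = value
        d = 1 if value else -1
        self.deg[m][i] += d
        self.deg[m][j] += d
        bi, bj = self.z[i], self.z[j]
        self.n1[m][bi, bj] += d
        self.n0[m][bi, bj] -= d
        if bi != bj:
            self.n1[m][bj, bi] += d
            self.n0[m][bj, bi] -= d

    def update_edge(self, i: int, j: int, m: int, rng: np.random.Generator, block_prior: bool) -> None:
        lo = self.edge_log_odds(i, j, m, block_prior)
        # p1 = sigmoid(lo), sampled in log space for stability
        p1 = 1.0 / (1.0 + exp(-lo)) if lo > -35 else exp(lo)
        self.set_edge(i, j, m, int(rng.random() < p1))

    # -- assignment update -------------------------------------------------

    def _remove_node(self, i: int) -> list[np.ndarray]:
        """Detach node i from its cluster; returns per-subject edge counts
        r[k] from i into each remaining cluster."""
        c = int(self.z[i])
        rs = []
        for m in range(self.M):
            nbr = self.A[m][i] == 1
            rs.append(np.bincount(self.z[nbr], minlength=self.K).astype(np.int64))
        self.sizes[c] -= 1
        for m, r in enumerate(rs):
            n1, n0 = self.n1[m], self.n0[m]
            d = self.sizes - r
            n1[c, :] -= r
            n1[:, c] -= r
            n1[c, c] += r[c]
            n0[c, :] -= d
            n0[:, c] -= d
            n0[c, c] += d[c]
        if self.sizes[c] == 0:
            keep = np.arange(self.K) != c
            self.sizes = self.sizes[keep]
            sel = np.ix_(keep, keep)
            for m in range(self.M):
                self.n1[m] = self.n1[m][sel]
                self.n0[m] = self.n0[m][sel]
                rs[m] = rs[m][keep]
            self.z[self.z > c] -= 1
            self.K -= 1
        self.z[i] = -1
        return rs

    def _insert_node(self, i: int, c: int, rs: list[np.ndarray]) -> None:
        if c == self.K:  # open a new cluster
            self.sizes = np.append(self.sizes, 0)
            for m in range(self.M):
                self.n1[m] = np.pad(self.n1[m], ((0, 1), (0, 1)))
                self.n0[m] = np.pad(self.n0[m], ((0, 1), (0, 1)))
                rs[m] = np.append(rs[m], 0)
            self.K += 1
        for m, r in enumerate(rs):
            n1, n0 = self.n1[m], self.n0[m]
            d = self.sizes - r
            n1[c, :] += r
            n1[:, c] += r
            n1[c, c] -= r[c]
            n0[c, :] += d
            n0[:, c] += d
            n0[c, c] -= d[c]
        self.sizes[c] += 1
        self.z[i] = c

    def assignment_log_weights(self, rs: list[np.ndarray], prior_only: bool) -> np.ndarray:
        """Unnormalized log weights over K existing clusters plus a new one,
        for a node whose edges into cluster k number r[k] (per subject)."""
        logw = np.log(np.append(self.sizes.astype(float), self.xi))
        if prior_only:
            return logw
        a, b = self.alpha, self.beta
        for m, r in enumerate(rs):
            n1, n0 = self.n1[m], self.n0[m]
            add1 = r[None, :].astype(float)
            add0 = (self.sizes - r)[None, :].astype(float)
            cur = betaln(a + n1, b + n0)
            logw[: self.K] += (betaln(a + n1 + add1, b + n0 + add0) - cur).sum(axis=1)
            logw[self.K] += float(
                (betaln(a + r, b + (self.sizes - r)) - betaln(a, b)).sum()
            )
        return logw

    def update_assignment(self, i: int, rng: np.random.Generator, prior_only: bool) -> None:
        rs = self._remove_node(i)
        logw = self.assignment_log_weights(rs, prior_only)
        logw -= logw.max()
        w = np.exp(logw)
        c = int(rng.choice(w.size, p=w / w.sum()))
        self._insert_node(i, c, rs)

    # -- log densities -----------------------------------------------------

    def log_posterior(self, mode: str, prior_only: bool) -> float:
        if prior_only:
            return crp_log_prob(Partition(self.z), self.xi)
        total = 0.0
        if mode in ("sirm", "birm"):
            total += crp_log_prob(Partition(self.z), self.xi)
            for m in range(self.M):
                total += irm_marginal_loglik(self.stats(m), self.alpha, self.beta)
        if mode in ("sirm", "flat") and self.S is not None:
            for m in range(self.M):
                total += dirmul_matrix_loglik(
                    StreamlineData(self.S[m]),
                    Adjacency(self.A[m].astype(np.uint8)),
                    self.delta_t,
                    self.delta_f,
                )
        return float(total)


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def initial_adjacency(streamlines: StreamlineData, delta_t: float, delta_f: float) -> Adjacency:
    """Greedy flat-prior start for A: a single pass over dyads keeps an edge
    whenever toggling it on raises the DirMul likelihood, given the edges
    decided so far."""
    n = streamlines.n
    state = _GibbsState(
        z=np.zeros(n, dtype=np.int64),
        adjacencies=[np.zeros((n, n), dtype=np.int64)],
        counts=[streamlines.counts],
        xi=1.0,
        alpha=1.0,
        beta=1.0,
        delta_t=delta_t,
        delta_f=delta_f,
    )
    for i in range(n - 1):
        for j in range(i + 1, n):
            if state.edge_log_odds(i, j, 0, block_prior=False) > 0:
                state.set_edge(i, j, 0, 1)
    return Adjacency(state.A[0].astype(np.uint8))


def _crp_draw(n: int, xi: float, rng: np.random.Generator) -> np.ndarray:
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
    return z


# ---------------------------------------------------------------------------
# Sampler driver
# ---------------------------------------------------------------------------


def run_sampler(
    data: Sequence[StreamlineData | Adjacency],
    hp: HyperParams,
    config: SamplerConfig,
    initial_partition: Partition | None = None,
) -> SampleChain:
    """Run the block Gibbs sampler and return the retained chain.

    ``data`` holds one matrix per subject: streamline counts for the
    ``sirm`` and ``flat`` modes, binary adjacencies for ``birm``.  One sweep
    updates every edge dyad of every subject (subject-major, lexicographic
    dyads; skipped for ``birm``) and then every node assignment in a fresh
    random permutation (skipped for ``flat``).  Chains are bit-reproducible
    given the seed.
    """
    if len(data) == 0:
        raise ValueError("need at least one subject")
    mode = config.mode
    ns = {d.n for d in data}
    if len(ns) != 1:
        raise ValueError(f"subjects disagree on region count: {sorted(ns)}")
    n = ns.pop()
    rng = np.random.default_rng(config.seed)

    if mode == "birm":
        if not all(isinstance(d, Adjacency) for d in data):
            raise TypeError("birm mode requires binary adjacency matrices")
        counts = None
        adjs = [d.edges.astype(np.int64) for d in data]
    else:
        if not all(isinstance(d, StreamlineData) for d in data):
            raise TypeError(f"{mode} mode requires streamline count matrices")
        counts = [d.counts for d in data]
        adjs = [
            initial_adjacency(d, hp.delta_t, hp.delta_f).edges.astype(np.int64)
            for d in data
        ]

    if initial_partition is not None:
        z0 = initial_partition.assignment.copy()
    elif mode == "flat":
        z0 = np.zeros(n, dtype=np.int64)
    else:
        z0 = _crp_draw(n, hp.xi, rng)

    state = _GibbsState(
        z=z0,
        adjacencies=adjs,
        counts=counts,
        xi=hp.xi,
        alpha=hp.alpha,
        beta=hp.beta,
        delta_t=hp.delta_t,
        delta_f=hp.delta_f,
    )

    dyads = [(i, j) for i in range(n - 1) for j in range(i + 1, n)]
    # adjacencies never change in birm mode; build the output tuple once
    fixed_adjs = (
        tuple(Adjacency(a.astype(np.uint8)) for a in state.A) if mode == "birm" else None
    )
    samples: list[Sample] = []
    for sweep in range(1, config.sweeps + 1):
        if mode in ("sirm", "flat") and not config.prior_only:
            block_prior = mode == "sirm"
            for m in range(state.M):
                for i, j in dyads:
                    state.update_edge(i, j, m, rng, block_prior)
        if mode in ("sirm", "birm") and not config.fix_partition:
            for i in rng.permutation(n):
                state.update_assignment(int(i), rng, config.prior_only)
        if sweep > config.burn_in and (sweep - config.burn_in - 1) % config.thinning == 0:
            part = Partition(state.z.copy())
            adj_out = fixed_adjs or tuple(
                Adjacency(a.astype(np.uint8)) for a in state.A
            )
            lp = state.log_posterior(mode, config.prior_only)
            samples.append(Sample(part, adj_out, lp))
        if config.log_every and sweep % config.log_every == 0:
            logger.info(
                "sweep %d/%d  K=%d  log-posterior=%.2f",
                sweep,
                config.sweeps,
                state.K,
                state.log_posterior(mode, config.prior_only),
            )

    meta = {
        "mode": mode,
        "n_regions": n,
        "n_subjects": len(data),
        "hyperparameters": hp.to_dict(),
        "sampler": config.to_dict(),
    }
    return SampleChain(samples, meta=meta)


def birm_pipeline(
    streamlines: Sequence[StreamlineData],
    hp: HyperParams,
    config: SamplerConfig,
) -> tuple[SampleChain, list[Adjacency]]:
    """Two-stage pipeline: flat-prior MAP connectomes, then cluster them.

    Stage one runs the edge sampler under P(A) ∝ 1 and takes the MAP
    adjacency per subject; stage two fixes those adjacencies and samples Z
    with the relational model.  Returns (partition chain, MAP adjacencies).
    """
    flat_cfg = replace(config, mode="flat")
    flat_chain = run_sampler(list(streamlines), hp, flat_cfg)
    _, map_adjs = map_estimate(flat_chain)
    birm_cfg = replace(config, mode="birm", seed=config.seed + 1)
    chain = run_sampler(list(map_adjs), hp, birm_cfg)
    return chain, list(map_adjs)


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------


def map_estimate(chain: SampleChain) -> tuple[Partition, tuple[Adjacency, ...]]:
    """Sample with the highest joint log-posterior (earliest wins ties)."""
    if len(chain) == 0:
        raise ValueError("empty chain")
    best = max(range(len(chain)), key=lambda s: (chain.samples[s].log_posterior, -s))
    s = chain.samples[best]
    return s.partition, s.adjacencies


def coassignment_expectation(chain: SampleChain) -> np.ndarray:
    """Posterior co-assignment probabilities E[M], M = Z^T Z per sample.

    Entry (i, j) is the fraction of samples in which regions i and j share
    a cluster; symmetric with unit diagonal.
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    n = chain.samples[0].partition.n
    acc = np.zeros((n, n))
    for s in chain.samples:
        z = s.partition.assignment
        acc += z[:, None] == z[None, :]
    return acc / len(chain)


def credible_interval_K(chain: SampleChain, level: float = 0.95) -> tuple[int, int, int]:
    """Equal-tailed credible interval for the number of clusters K.

    Empirical quantiles at (1-level)/2 and 1-(1-level)/2 of the per-sample
    K, rounded outward to integers; returns (low, high, high - low).
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    ks = chain.cluster_counts
    tail = (1.0 - level) / 2.0
    lo = int(np.floor(np.quantile(ks, tail)))
    hi = int(np.ceil(np.quantile(ks, 1.0 - tail)))
    return lo, hi, hi - lo
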