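from collections import Counter

import numpy as np
import pytest

from sirm import (
    Adjacency,
    HyperParams,
    Partition,
    SampleChain,
    Sample,
    SamplerConfig,
    StreamlineData,
    ami,
    birm_pipeline,
    block_stats,
    coassignment_expectation,
    credible_interval_K,
    crp_log_prob,
    initial_adjacency,
    irm_marginal_loglik,
    map_estimate,
    run_sampler,
    make_toy,
    sample_network,
    sample_streamlines,
)
from sirm.inference import _GibbsState
from sirm.model import BlockProbabilities

from conftest import all_partitions


def exact_partition_posterior(adj, hp):
    """Brute-force collapsed posterior P(Z | A) over all set partitions."""
    parts = all_partitions(adj.n)
    logps = np.array(
        [
            crp_log_prob(p, hp.xi)
            + irm_marginal_loglik(block_stats(adj, p), hp.alpha, hp.beta)
            for p in parts
        ]
    )
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    return dict(zip(parts, probs))


class TestSamplerConfig:
    def test_contracts(self):
        with pytest.raises(ValueError):
            SamplerConfig(sweeps=10, burn_in=10)
        with pytest.raises(ValueError):
            SamplerConfig(thinning=0)
        with pytest.raises(ValueError):
            SamplerConfig(mode="bogus")
        assert SamplerConfig(mode="flatA").mode == "flat"


class TestGibbsStateBookkeeping:
    def test_incremental_stats_match_recomputation(self, hp, rng):
        """After many edge and assignment moves the cached block statistics
        must equal a from-scratch recount."""
        n = 10
        planted = Partition(rng.integers(0, 3, size=n))
        r = np.full((3, 3), 0.2)
        np.fill_diagonal(r, 0.8)
        adj = sample_network(Partition(np.sort(planted.assignment)), BlockProbabilities(r), rng)
        sd = sample_streamlines(adj, 1.0, 0.05, 200, rng)
        state = _GibbsState(
            z=rng.integers(0, 2, size=n),
            adjacencies=[adj.edges],
            counts=[sd.counts],
            xi=1.0,
            alpha=1.0,
            beta=1.0,
            delta_t=1.0,
            delta_f=0.05,
        )
        for _ in range(5):
            for i in range(n - 1):
                for j in range(i + 1, n):
                    state.update_edge(i, j, 0, rng, block_prior=True)
            for i in rng.permutation(n):
                state.update_assignment(int(i), rng, prior_only=False)
        fresh = block_stats(Adjacency(state.A[0].astype(np.uint8)), Partition(state.z))
        # cached labels may be a relabelling of canonical ones; compare via sorted blocks
        canon = Partition(state.z)
        cached = state.stats(0)
        relabel = {old: new for old, new in zip(state.z, canon.assignment)}
        order = [old for old, _ in sorted(relabel.items(), key=lambda kv: kv[1])]
        assert np.array_equal(cached.n1[np.ix_(order, order)], fresh.n1)
        assert np.array_equal(cached.n0[np.ix_(order, order)], fresh.n0)

    def test_edge_odds_uninformative_case(self):
        """With delta_t = delta_f and alpha = beta = 1 on fresh stats the
        full conditional of a dyad is even odds."""
        s = np.array([[0, 9, 4], [7, 0, 2], [1, 3, 0]])
        state = _GibbsState(
            z=np.zeros(3, dtype=np.int64),
            adjacencies=[np.zeros((3, 3), dtype=np.int64)],
            counts=[s],
            xi=1.0,
            alpha=1.0,
            beta=1.0,
            delta_t=0.7,
            delta_f=0.7,
        )
        assert state.edge_log_odds(0, 1, 0, block_prior=False) == pytest.approx(0.0)

    def test_zero_count_dyad_disfavoured_under_flat_prior(self):
        """If i and j exchange no streamlines while both rows carry many
        counts elsewhere, the flat-prior conditional puts P(a_ij = 1) < 1/2."""
        s = np.zeros((4, 4), dtype=np.int64)
        s[0, 2] = s[0, 3] = s[1, 2] = s[1, 3] = 200
        s[2, 0] = s[3, 0] = s[2, 1] = s[3, 1] = 200
        state = _GibbsState(
            z=np.zeros(4, dtype=np.int64),
            adjacencies=[np.ones((4, 4), dtype=np.int64) - np.eye(4, dtype=np.int64)],
            counts=[s],
            xi=1.0,
            alpha=1.0,
            beta=1.0,
            delta_t=1.0,
            delta_f=0.05,
        )
        assert state.edge_log_odds(0, 1, 0, block_prior=False) < 0.0


class TestRunSampler:
    def test_same_seed_identical_chains(self, hp, rng):
        _, _, adj = make_toy("community", rng)
        sd = sample_streamlines(adj, 1.0, 0.05, 100, rng)
        cfg = SamplerConfig(sweeps=30, burn_in=10, thinning=1, seed=5, log_every=0)
        c1 = run_sampler([sd], hp, cfg)
        c2 = run_sampler([sd], hp, cfg)
        assert [s.partition for s in c1] == [s.partition for s in c2]
        assert np.array_equal(c1.log_posteriors, c2.log_posteriors)
        for s1, s2 in zip(c1, c2):
            for a1, a2 in zip(s1.adjacencies, s2.adjacencies):
                assert np.array_equal(a1.edges, a2.edges)

    def test_mode_input_contracts(self, hp, planted_community, small_streamlines):
        _, adj = planted_community
        cfg = SamplerConfig(sweeps=2, burn_in=1, log_every=0)
        with pytest.raises(TypeError):
            run_sampler([adj], hp, cfg)  # sirm needs counts
        with pytest.raises(TypeError):
            run_sampler([small_streamlines], hp, SamplerConfig(sweeps=2, burn_in=1, mode="birm", log_every=0))
        with pytest.raises(ValueError):
            run_sampler([], hp, cfg)

    def test_mixed_sizes_rejected(self, hp, small_streamlines):
        other = StreamlineData(np.zeros((4, 4), dtype=int))
        with pytest.raises(ValueError):
            run_sampler([small_streamlines, other], hp, SamplerConfig(sweeps=2, burn_in=1, log_every=0))

    def test_birm_recovers_community_toy(self, hp, rng):
        partition, _, adj = make_toy("community", rng)
        cfg = SamplerConfig(sweeps=400, burn_in=200, thinning=1, seed=2, mode="birm", log_every=0)
        chain = run_sampler([adj], hp, cfg)
        map_part, _ = map_estimate(chain)
        assert map_part.K == 3
        assert ami(map_part, partition) == pytest.approx(1.0)

    def test_partition_frequencies_match_enumeration_4_nodes(self, hp):
        """Collapsed Gibbs long-run frequencies against the exactly
        enumerated posterior over all 15 partitions of a 4-node graph."""
        a = np.array(
            [[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]], dtype=np.uint8
        )
        adj = Adjacency(a)
        exact = exact_partition_posterior(adj, hp)
        cfg = SamplerConfig(sweeps=8000, burn_in=500, thinning=1, seed=9, mode="birm", log_every=0)
        chain = run_sampler([adj], hp, cfg)
        freq = Counter(s.partition for s in chain)
        total = len(chain)
        tv = 0.5 * sum(abs(freq.get(p, 0) / total - q) for p, q in exact.items())
        assert tv <= 0.05

    def test_large_xi_splits_disconnected_pair(self, rng):
        """With no edge between two nodes and a huge concentration, the CRP
        term dominates and the pair occupies separate clusters."""
        adj = Adjacency(np.zeros((2, 2), dtype=np.uint8))
        hp = HyperParams(xi=500.0)
        cfg = SamplerConfig(sweeps=300, burn_in=100, thinning=1, seed=1, mode="birm", log_every=0)
        chain = run_sampler([adj], hp, cfg)
        frac_split = np.mean(chain.cluster_counts == 2)
        assert frac_split > 0.95

    def test_prior_only_matches_crp_mean(self):
        """Likelihood switched off: the sampled number of clusters must match
        the closed-form CRP expectation sum_i xi / (xi + i)."""
        n, xi = 12, 1.0
        adj = Adjacency(np.zeros((n, n), dtype=np.uint8))
        hp = HyperParams(xi=xi)
        cfg = SamplerConfig(
            sweeps=4000, burn_in=500, thinning=1, seed=4, mode="birm",
            prior_only=True, log_every=0,
        )
        chain = run_sampler([adj], hp, cfg)
        ks = chain.cluster_counts.astype(float)
        expected = np.sum(xi / (xi + np.arange(n)))
        batches = ks[: len(ks) // 35 * 35].reshape(35, -1).mean(axis=1)
        se = batches.std(ddof=1) / np.sqrt(len(batches))
        assert abs(ks.mean() - expected) <= 3 * max(se, 1e-3)

    def test_multi_subject_sharing_partition(self, hp, rng):
        partition, rho, _ = make_toy("community", rng)
        data = []
        for _ in range(3):
            adj = sample_network(partition, rho, rng)
            data.append(sample_streamlines(adj, 1.0, 0.05, 300, rng))
        cfg = SamplerConfig(sweeps=400, burn_in=200, thinning=1, seed=8, log_every=0)
        chain = run_sampler(data, hp, cfg)
        map_part, map_adjs = map_estimate(chain)
        assert len(map_adjs) == 3
        assert ami(map_part, partition) >= 0.9


class TestInitialAdjacency:
    def test_strong_contrast_recovers_edges(self, rng):
        partition, _, adj = make_toy("community", rng)
        sd = sample_streamlines(adj, 1.0, 0.05, 1000, rng)
        est = initial_adjacency(sd, 1.0, 0.05)
        agreement = (est.edges == adj.edges)[np.triu_indices(12, 1)].mean()
        assert agreement >= 0.9


class TestBirmPipeline:
    def test_two_stage_recovery(self, hp, rng):
        # three subjects: the flat-prior stage must recover each connectome
        # and the clustering stage the shared planted partition
        partition, rho, _ = make_toy("community", rng)
        true_adjs, data = [], []
        for _ in range(3):
            adj = sample_network(partition, rho, rng)
            true_adjs.append(adj)
            data.append(sample_streamlines(adj, 1.0, 0.05, 1000, rng))
        cfg = SamplerConfig(sweeps=300, burn_in=150, thinning=1, seed=3, mode="birm", log_every=0)
        chain, map_adjs = birm_pipeline(data, hp, cfg)
        assert len(map_adjs) == 3
        iu = np.triu_indices(12, 1)
        for est, true in zip(map_adjs, true_adjs):
            assert (est.edges == true.edges)[iu].mean() >= 0.9
        map_part, _ = map_estimate(chain)
        assert ami(map_part, partition) >= 0.9


class TestSummaries:
    def _chain(self, logps, partitions=None):
        adj = Adjacency(np.zeros((3, 3), dtype=np.uint8))
        partitions = partitions or [Partition([0, 0, 0])] * len(logps)
        return SampleChain([Sample(p, (adj,), lp) for p, lp in zip(partitions, logps)])

    def test_map_single_sample(self):
        chain = self._chain([-4.2])
        part, adjs = map_estimate(chain)
        assert part == Partition([0, 0, 0]) and len(adjs) == 1

    def test_map_tie_goes_to_earliest(self):
        parts = [Partition([0, 0, 0]), Partition([0, 0, 1]), Partition([0, 1, 1])]
        chain = self._chain([-10.0, -5.0, -5.0], parts)
        part, _ = map_estimate(chain)
        assert part == parts[1]

    def test_map_empty_chain(self):
        with pytest.raises(ValueError):
            map_estimate(SampleChain([]))

    def test_coassignment_identical_chain_is_block_matrix(self):
        p = Partition([0, 0, 1])
        chain = self._chain([-1.0, -1.0], [p, p])
        m = coassignment_expectation(chain)
        expected = (p.assignment[:, None] == p.assignment[None, :]).astype(float)
        assert np.array_equal(m, expected)

    def test_coassignment_half_and_half(self):
        chain = self._chain([-1.0, -1.0], [Partition([0, 0, 1]), Partition([0, 1, 1])])
        m = coassignment_expectation(chain)
        assert m[0, 1] == pytest.approx(0.5)
        assert m[1, 2] == pytest.approx(0.5)
        assert np.array_equal(np.diag(m), np.ones(3))
        assert np.array_equal(m, m.T)

    def test_credible_interval_degenerate(self):
        chain = self._chain([-1.0] * 5)
        assert credible_interval_K(chain) == (1, 1, 0)

    def test_credible_interval_rare_tail_excluded(self):
        # 98 samples at K = 3, 2 at K = 4: the rare tail falls outside the
        # equal-tailed 95% interval
        adj = Adjacency(np.zeros((4, 4), dtype=np.uint8))
        parts = [Partition([0, 1, 2, 2])] * 98 + [Partition([0, 1, 2, 3])] * 2
        chain = SampleChain([Sample(p, (adj,), -1.0) for p in parts])
        assert credible_interval_K(chain, level=0.95) == (3, 3, 0)

    def test_credible_interval_bad_level(self):
        with pytest.raises(ValueError):
            credible_interval_K(self._chain([-1.0]), level=1.5)
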