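# Methods

## Model

A parcellation **Z** of N brain regions is drawn from a Chinese restaurant
process with concentration ξ: seating region by region, an existing cluster
k is chosen with weight m_k (its occupancy) and a new cluster with weight
ξ.  The exchangeable partition probability used throughout is

    P(Z | ξ) = ξ^K · ∏_k (m_k − 1)! / ∏_{i=0}^{N−1} (ξ + i).

Given **Z**, each subject's structural connectome **A**⁽ᵐ⁾ is a symmetric
binary matrix with zero diagonal whose dyads are Bernoulli with block
probability ρ⁽ᵐ⁾_ab ~ Beta(α, β), a depending only on the endpoint
clusters.  Subjects share **Z** but have independent **A**⁽ᵐ⁾ and ρ⁽ᵐ⁾, so
their likelihood terms add.  ρ is always integrated out analytically
(Beta-Bernoulli conjugacy): with n1/n0 the present/absent dyad counts of a
block (within-cluster blocks over unordered pairs i < j, the two symmetric
off-diagonal blocks pooled), the collapsed likelihood is a product of
B(α + n1, β + n0)/B(α, β) over block pairs a ≤ b.  `posterior_rho` is a
read-out of the Beta posterior means, never a sampler state; collapsing
mixes faster and removes tunables.

The observed streamline counts enter through a Dirichlet-compound-
multinomial forward model per seed row: row i of **S**, restricted to its
n − 1 possible targets, is DirMul with pseudo-count δ_T on true connections
(a_ij = 1) and δ_F on false ones.  The latent per-row streamline
probability vectors are marginalized by this pmf and never instantiated.
The self entry is excluded from every row (a region seeds no streamlines to
itself); nonzero input diagonals are zeroed with a warning rather than
rejected, since real tractography exports sometimes carry them.  The
multinomial coefficient is kept in the row pmf — it cancels in every
sampling ratio but makes the density normalize, which the tests exploit.

## Hyperparameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| ξ | CRP concentration (unitless) | 1 | weak preference for few clusters; the likelihood dominates K in practice |
| α, β | Beta prior on block probabilities | 1, 1 | uninformative uniform prior |
| δ_T | Dirichlet pseudo-count, true connections | 1.0 | order-1 mass per true target |
| δ_F | Dirichlet pseudo-count, false connections | 0.05 | small but nonzero tractography leakage; δ_T > δ_F is enforced |
| sweeps / burn-in / thinning | chain length | 2000 / 1000 / 2 | comfortable for N ≲ 200; tests and the demo use shorter chains that already mix on toy sizes |

All are overridable per run and recorded in every run's manifest.

## Sampler

One sweep of the block Gibbs sampler updates, in order: every latent edge
dyad of every subject (subject-major, lexicographic dyads; `sirm` and
`flat` modes), then every region's assignment in a fresh random permutation
(`sirm` and `birm`).  Any valid scan order leaves the stationary
distribution unchanged; this one was chosen for cache-friendliness and
reproducibility.

An edge's full conditional multiplies the collapsed block prior odds
(α + n1′)/(β + n0′) — primed counts exclude the dyad itself; replaced by
1:1 under the flat prior — with the DirMul likelihood ratio of *both*
affected seed rows, since s_ij and s_ji are separate observations.  An
assignment update removes the region (deleting its cluster if emptied),
scores every existing cluster plus one new cluster by CRP weight times the
change in collapsed block likelihood across subjects, and resamples.  The
new-cluster term uses the analytic prior predictive (fresh Beta); no
auxiliary variables are needed because ρ is collapsed.  Block sufficient
statistics are maintained incrementally and checked against from-scratch
recounts in the tests.

Initialization: **Z** starts from a CRP(ξ) draw; each **A**⁽ᵐ⁾ starts from
a greedy pass that turns each edge on when the flat-prior DirMul odds favour
it given the edges decided so far — cheap and data-informed.  The MAP
estimate is the retained sample with the highest joint log-posterior
(earliest sample on ties), the standard chain-argmax convention.

Two validation-only switches exist in `SamplerConfig`: `prior_only` drops
all likelihood terms so the sampled K distribution can be checked against
the closed-form CRP mean Σ_i ξ/(ξ + i), and `fix_partition` freezes **Z**
so edge frequencies can be checked against exact enumeration.  Neither is
an analysis mode.

The two-stage pipeline (`birm_pipeline`) first runs the `flat` mode and
takes each subject's MAP connectome, then clusters those fixed adjacencies
with the relational model; its second stage derives its seed from the
first's (seed + 1) so the two chains are independent but reproducible.

## Posterior summaries

* Co-assignment expectation E[**M**]: fraction of samples in which two
  regions share a cluster; symmetric, unit diagonal.  Rows of E[**M**] are
  the cluster probability maps; `interpolate_colors` blends reference (MAP)
  colors by co-assignment weights, c_i = Σ_j m_ij ĉ_j / Σ_j m_ij.
* Credible interval on K: equal-tailed empirical quantiles of the
  per-sample cluster count, rounded outward to integers.
* AMI uses the hypergeometric-model expected mutual information and the
  max-entropy normalization, (MI − EMI)/(max(H₁, H₂) − EMI), computed with
  log-gamma.  The doubly degenerate case (both partitions a single cluster)
  has a vanishing denominator; the score is defined as 1 and logged.
* Community ratio r_c uses the symmetrized counts **S**′ = **S** + **S**ᵀ:
  within-cluster streamlines counted once per unordered pair, between-
  cluster streamlines attributed fully to both touching clusters.  A
  singleton cluster scores 0 (it has no internal dyads); a cluster with no
  incident streamlines at all is reported as missing (NaN) to distinguish
  "no data" from "pure hub".

## Synthetic data

The generator draws from exactly the model above: CRP partitions,
block-Bernoulli networks, and DirMul streamline rows (Dirichlet probability
vector then multinomial counts, which marginally matches the analytic pmf —
verified empirically in the tests).  The twelve-node toy has three equal
clusters with block probabilities 0.9/0.05 (community regime) or 0.05/0.9
(profile regime); the contrast values are this package's choice of a
strong, clearly separated setting.  Default row totals are 1000 streamlines
per seed region, a realistic region-level order of magnitude after
aggregating seed voxels.

What a green test establishes: the sampler targets the exact posterior on
enumerable instances, and the full pipeline recovers partitions planted
under its own generative assumptions at strong contrast.  What it does not:
real tractography violates the model in known ways — streamline counts are
distance-biased, noise is spatially structured rather than exchangeable
within blocks, and regions are not stochastically identical within a
cluster — so recovery on synthetic data bounds, but does not guarantee,
performance on acquired data.

## Numerical choices

* All densities in log space via log-gamma; Beta functions via `betaln`.
* Assignment sampling normalizes weights after subtracting the maximum log
  weight; edge sampling uses a numerically safe sigmoid.
* Cluster labels are kept contiguous inside the sampler and canonicalized
  (order of first appearance) whenever a partition is emitted or compared,
  so label permutations never masquerade as distinct states.
* Matrix files are TSV (CSV accepted by delimiter sniffing); chains are
  newline-delimited JSON with a sidecar metadata header.

## Limitations

Single-site assignment updates split merged clusters slowly; on ambiguous
data prefer longer chains (no split-merge moves are implemented).  The
model is undirected and degree-uncorrected by design; Poisson count models,
overlapping or hierarchical clusters, and empirical-Bayes hyperparameter
estimation are out of scope.  A single 12-node subject at toy contrast is
genuinely ambiguous about merging two of the three planted clusters — the
posterior, not the sampler; multi-subject runs resolve it.
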