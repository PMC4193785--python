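# Methods

## Problem and model

`copulaclust` partitions the row-actors of a real-valued N×M
actor-by-feature matrix **X** into clusters of *positionally equivalent*
actors: actors whose whole profiles of feature weights co-move, rather
than actors that are densely connected to each other. The matrix is the
adjacency matrix of a weighted bipartite network; a zero weight is an
absent edge and is treated as an ordinary, informative value (which
features an actor does *not* express is part of its position).

The statistical model is a copula model per candidate cluster. For a
subset of k actors, the M columns of their (transformed) rows are
treated as i.i.d. draws from a k-variate distribution whose dependence
is an exchangeable one-parameter Archimedean copula
C(u) = ψ(ψ⁻¹(u₁) + … + ψ⁻¹(u_k)); the margins are left fully
nonparametric and are estimated per actor. Three families are
implemented, all restricted to positive dependence (similarity is the
notion of interest; negative dependence does not make two actors
positionally equivalent):

| family  | generator ψ(t)                  | θ domain   | independence  |
|---------|---------------------------------|------------|---------------|
| Gumbel  | exp(−t^(1/θ))                   | θ ∈ [1, 50]  | θ = 1       |
| Clayton | (1+t)^(−1/θ)                    | θ ∈ (0, 50]  | θ → 0⁺      |
| Frank   | −θ⁻¹ log(1−(1−e^(−θ))e^(−t))    | θ ∈ (0, 100] | θ → 0⁺      |

The upper caps mark where each family is numerically comonotone in
double precision; θ beyond them is rejected rather than silently
accepted.

## The pipeline

1. **Margins.** Each actor's row is mapped through its own rescaled
   empirical CDF: value ↦ (maximum rank under ties)/(M+1). The M/(M+1)
   rescaling is the canonical maximum-pseudo-likelihood convention; the
   raw ECDF assigns 1 to the row maximum, which makes every Archimedean
   log-density infinite. Maximum-rank ties keep equal inputs equal, as a
   literal ECDF does. A constant row is a hard error: its margin carries
   no ordinal information, and jittering it would fabricate dependence.
2. **Per-subset likelihood.** For every actor subset of size ≥ 2 the
   copula log-likelihood ℓ(θ) = Σ_m log c_θ(û_{i1,m},…,û_{ik,m}) is
   maximised over θ by bounded derivative-free scalar search
   (`scipy.optimize.minimize_scalar`, method `bounded`) on a log scale —
   log θ for Clayton/Frank, log(θ−1) for Gumbel — with absolute
   tolerance 1e−6 on the transformed coordinate. ℓ is unimodal in
   practice; derivative-free search avoids fragile gradients of the
   density recursions. Perfectly comonotone rows legitimately drive θ̂
   to the cap; that is flagged (`at_bound`), not an error.
3. **Partition optimisation.** The objective is the *global
   log-likelihood*: the sum of the blocks' maximised log-likelihoods
   over all partitions whose blocks have ≥ 2 members (singleton blocks
   are not in the feasible set). The argmax is exact, found by dynamic
   programming over subset bitmasks (best singleton-free cover of every
   mask, ~3^N work) — provably identical to exhaustive enumeration of
   all singleton-free partitions, which is also provided and used as the
   test oracle. Subset fits are memoised; a full run needs exactly
   2^N − N − 1 of them (502 at N = 9).
4. **Output.** Blocks are reported in decreasing order of their cluster
   log-likelihood, together with θ̂ per block and the global value.
   Residual low-dependence actors therefore appear in the last block.

Ties in the partition objective are broken deterministically: fewer
blocks first, then the lexicographically smallest block list (by actor
position in the input). Exact float ties are essentially impossible on
real data; the rule exists so results are reproducible bit for bit.

## Numerical evaluation of the densities

The d-dimensional Archimedean density requires the d-th derivative of
the generator. Symbolic differentiation is unstable and slow beyond
d ≈ 4, so each family uses a closed recursion, evaluated entirely in
log space:

* **Clayton** has the closed product form
  log c = Σ_{j=1}^{d−1} log(1+jθ) − (1+θ)Σ log uᵢ − (d+1/θ)·log S,
  with S = Σ uᵢ^(−θ) − d + 1 accumulated by `logsumexp` so θ near the
  cap cannot overflow.
* **Gumbel**: (−1)^d ψ^(d)(t) = ψ(t) t^(−d) Σ_k a_{d,k} t^(kα) with
  α = 1/θ and the cancellation-free two-term recursion
  a_{d+1,k} = α a_{d,k−1} + (d−kα) a_{d,k}; every term is nonnegative
  for α ≤ 1, so the recursion is exact to relative rounding error.
* **Frank**: (−1)^d ψ^(d)(t) = θ⁻¹ Li_{1−d}(x) with
  x = Π(1−e^(−θuᵢ)) / (1−e^(−θ))^(d−1) < 1; the negative-order
  polylogarithm is expanded through Eulerian numbers,
  Li_{−n}(x) = Σ_k ⟨n,k⟩ x^(n−k) / (1−x)^(n+1), built by their additive
  recursion in log space. The factors log(1−e^(−θu)) are computed as
  `log1p(−exp(−θu))`: for near-comonotone columns at large θ the direct
  form rounds x onto the pole at 1 and returns +inf, while the `log1p`
  form keeps 1−x representable in log space. As a final guard, log x is
  clamped strictly below 0 by one denormal step.

Density arguments are clipped into [1e−10, 1−1e−10] before evaluation:
rank-based pseudo-observations never touch the boundary by
construction, but simulated inputs can after float rounding. Exact 0/1
coordinates are rejected for densities; CDFs handle them analytically
(groundedness and uniform margins hold exactly).

Dimension is capped at 64: beyond that the recursion coefficients leave
double range, and the exact partition search is long infeasible anyway
(its own guard is N = 18, cost ~3^N).

## Sampling

Sampling uses the Marshall–Olkin frailty construction: draw a positive
frailty V with Laplace transform ψ — Gamma(1/θ) for Clayton, positive
α-stable with α = 1/θ for Gumbel (Chambers–Mallows–Stuck), a
logarithmic-series variable with p = 1−e^(−θ) for Frank
(`scipy.stats.logser`) — then set Uᵢ = ψ(Eᵢ/V) with i.i.d. unit
exponentials Eᵢ. This is exact for every dimension and deterministic
given a seed. Gumbel at θ = 1 degenerates to V ≡ 1 (independence) and
is special-cased. Samplers are validated against closed-form Kendall's
τ (θ/(θ+2) for Clayton, 1−1/θ for Gumbel, the Debye-function formula
for Frank) and marginal-uniformity tests.

## The synthetic-data generator

`simulate.benchmark_scenario(s, M)` reproduces a 9-scenario benchmark
grid: N = 10 actors in three planted clusters of sizes 3/4/3 with
dependence θ = 4/3/4, one Archimedean family per scenario
(Gumbel/Clayton/Frank cycling), and margins Normal(0,1) (scenarios
1–3), Poisson(4) (4–6) or a Pareto(scale 1, shape 2) /
Exponential(rate 0.5) / LogNormal(0,1) mix (7–9), at item counts
M ∈ {20, 50, 100, 250}. Each cluster is built by sampling M points from
its d-dimensional copula and mapping coordinates through the margin's
quantile function (Sklar's converse). Margin parameters are named
explicitly because shorthand like Pa(1,2) is ambiguous about
scale/shape order.

What the generator emulates: exchangeable within-cluster dependence
with exactly known strength, independent clusters, i.i.d. items, and
(via Poisson margins) heavy ties that exercise the tie convention. What
it does not emulate: between-cluster dependence, non-exchangeable
(e.g. hierarchical) dependence, item heterogeneity, missingness, or
margins that vary within a cluster beyond the mixed scenarios 7–9. A
green recovery test therefore establishes correctness of the estimator
and search under the stated model, not robustness to arbitrary real
data.

`run_experiment` replicates generate → cluster → compare; success is
*exact* set-of-sets equality with the planted partition (the strictest
sensible reading — one misplaced actor is a failure). Per-replicate
seeds are spawned from the master seed with `SeedSequence`, so
experiments are reproducible bit for bit. The default replication is 10
(a desk-scale reduction of the reference 50); any failure at 10 reps
should be re-judged at 50 before being called a defect.

## Design choices where the design was open

* **Family for real data**: not selected a priori; the recommended
  procedure (and the CLI default) runs all three families and reports
  the one with the highest global log-likelihood. On the packaged
  voting matrix all three return the identical partition; Gumbel
  attains the highest value.
* **ECDF boundary/tie conventions** (M/(M+1), maximum rank) are
  declared here, not inherited: the alternative average-rank convention
  would split tied votes, which contradicts an ECDF reading of the data.
* **Abstention in the voting fixture** (the single 0) is an ordinary
  third value in that row's ECDF.
* **θ search ranges** equal the admissible domains (lower ends offset
  by 1e−6 where the domain is open); boundary hits are flagged.

## Known limitations

* Exact search scales as ~3^N subsets; the hard guard at N = 18 refuses
  larger inputs with a pointer to subsample. Agglomerative or
  size-capped heuristics are deliberately out of scope.
* Singleton clusters are not representable; loner actors end up
  absorbed into the residual (lowest-likelihood) block.
* One family per run; per-cluster family selection is not attempted.
* Archimedean exchangeability means within-cluster dependence is
  symmetric; role structure with asymmetric dependence needs richer
  copulas (vines, nesting) that are out of scope.
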