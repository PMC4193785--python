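# copulaclust

Copula-based clustering of weighted bipartite networks into groups of
**positionally equivalent** actors.

Many systems are naturally an actor-by-feature weight matrix — judges ×
issues voted on, countries × product categories exported, customers ×
products bought. Classical community detection groups actors that are
densely connected *to each other*; positional analysis instead groups
actors that play the *same role*, i.e. whose whole profiles of feature
weights co-move. `copulaclust` operationalises positional equivalence
as multivariate positive dependence and finds the optimal grouping
exactly, without fixing the number of clusters in advance.

## The method

Given an N×M real matrix **X** (rows = actors, columns = features,
zero = absent edge, treated as informative):

1. Each actor's row is rank-transformed through its own rescaled
   empirical CDF, û_im = rank(x_im)/(M+1), leaving the margins fully
   nonparametric.
2. For every actor subset G of size k ≥ 2, the copula pseudo
   log-likelihood
   ℓ_G(θ) = Σ_{m=1}^{M} log c_θ(û_{i₁m}, …, û_{i_km})
   is maximised over θ, where c_θ is a one-parameter Archimedean copula
   density (Gumbel, Clayton or Frank), evaluated in any dimension by
   stable log-space recursions.
3. Over all partitions π of the actors into blocks of size ≥ 2, the
   **global log-likelihood** Σ_{G∈π} max_θ ℓ_G(θ) is maximised exactly
   (dynamic programming over subsets, provably equal to exhaustive
   enumeration).
4. The optimal partition is returned with blocks ordered by decreasing
   cluster log-likelihood; weakly dependent leftovers surface in the
   last, residual block.

A seeded simulator generates planted-cluster benchmark networks
(copula sample → marginal quantile transform per cluster) and an
experiment harness measures exact-recovery success rates.

## Worked example

The package ships a 9-justice × 26-issue signed voting matrix
(+1 majority, −1 minority, one abstention 0). Clustering it:

```sh
copulaclust cluster src/copulaclust/data/supreme_court.csv
```

prints (the best of the three Archimedean families, here Gumbel):

```
copula family : gumbel
clusters      : 3
global loglik : 237.3366

cluster 1: {Scalia, Thomas}  theta=50.0000  loglik=126.3555  (theta at search bound)
cluster 2: {Breyer, Ginsburg, Stevens, Souter}  theta=2.0540  loglik=80.6813
cluster 3: {O'Connor, Kennedy, Rehnquist}  theta=1.2829  loglik=30.2998
```

Reading it: Scalia and Thomas voted identically on all 26 issues, so
their pseudo-observations are comonotone and θ̂ sits at the search cap
(flagged) with the largest block likelihood; the four-justice liberal
wing forms the second cluster; the remaining three justices, who agree
on about half the issues, form the residual third cluster. Moving
Rehnquist into the first cluster strictly lowers the global
log-likelihood — the optimum genuinely prefers this grouping.

The same from Python:

```python
from copulaclust import supreme_court, cluster_bipartite
res = cluster_bipartite(supreme_court(), "gumbel")
print(res.partition.blocks, res.global_loglik)
```

Simulation benchmark (10 actors in planted 3/4/3 clusters, Clayton
copula, Normal(0,1) margins, θ = 4/3/4, M = 50 items):

```sh
$ copulaclust experiment --scenario 2 --items 50 --reps 3 --seed 5
scenario S2 M=50 fit=clayton: 3/3 exact recoveries (100%)
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the number of clusters found on the packaged
voting matrix (best family of three), and exact-recovery percentages
for seeded planted-cluster experiments (Clayton/Normal at M = 100, 50
and 20; Frank/Normal at M = 50), writing one JSON object keyed by
target id with the computed value and the problem size used.

## Layout

- `src/copulaclust/copulas.py` — Archimedean CDFs, log-densities
  (any d ≥ 2) and frailty samplers
- `src/copulaclust/margins.py` — empirical margins, pseudo-observations
- `src/copulaclust/likelihood.py` — per-subset θ maximisation
- `src/copulaclust/partition.py` — singleton-free partition
  enumeration and the exact subset DP
- `src/copulaclust/simulate.py` — planted-cluster generator and
  success-rate experiments
- `src/copulaclust/io.py`, `cli.py` — matrix/result IO, packaged
  fixture, `copulaclust` command line
- `docs/methods.md` — model, conventions, numerics and limitations
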