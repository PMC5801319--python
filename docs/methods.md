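# Methods

## Model and procedure

detectdim treats test dimensionality as a covariance-sign problem. Under a
multidimensional item response model with an approximate simple structure,
two items conditioned on the test's composite ability covary positively when
they measure the same dominant dimension and negatively otherwise. The
analysis has three stages:

1. **Conditional covariance estimation.** For each item pair (i, j) the
   examinees are stratified on an observed proxy for the composite ability
   and the within-stratum covariance of the two item scores is averaged with
   stratum-size weights. Two proxies are used and their estimates averaged:
   the *pairwise rest score* (number correct excluding both items) and the
   *total score*. Conditioning on a score that excludes the pair biases the
   estimate upward (the pair's own dimension is under-represented in the
   proxy); conditioning on a score that includes it biases downward; the
   average largely cancels the two. Each proxy alone is available via
   `conditioning="rest"` / `"total"`.
2. **Partition maximization.** The DETECT index of a partition is the signed
   average of the pairwise conditional covariances (sign +1 within clusters,
   −1 across), reported ×100 so that the conventional interpretation bands
   (0.1 and 1.0) apply. The partition maximizing the index, `P*`, is the
   detected structure and its value is `D*`.
3. **Classification.** `D* < 0.1`: essentially unidimensional;
   `0.1 ≤ D* ≤ 1.0`: moderate multidimensionality; `D* > 1.0`: sizable
   multidimensionality (boundary values fall in the middle band). The ratio
   index `r` (signed sum over absolute sum of conditional covariances)
   measures how simple the detected structure is; `r > 0.8` is read as
   approximately simple structure.

Assumptions: responses are dichotomous, examinees are exchangeable, items
are monotone in ability, and the observed number-correct score is an
adequate ordering proxy for the composite ability. The method is
nonparametric — no item response function is fitted.

## Tunable parameters

| parameter | default | meaning and rationale |
| --- | --- | --- |
| `min_group` | 20 examinees | Minimum stratum size for the conditioning score; adjacent sparse score levels are pooled (low end upward, deficient top folded back) until every stratum reaches it. Small strata make the within-stratum covariance nearly raw noise, and the subsequent maximization converts pair-level noise into spuriously many clusters; ~20 per stratum is the usual thick-matching choice for observed-score conditioning and gives cluster counts that track the generating design at both N=100 and N=1,000. Raising it much further (e.g. 40 at N=100) leaves too few strata to control ability at all and the estimates collapse toward unconditional covariances. |
| `conditioning` | `"both"` | Bias-cancelling average described above. |
| `max_clusters` | 12 | Cap on the cluster count considered by the search. |
| `method` | `"auto"` | Exhaustive enumeration of all set partitions up to 8 items (batched over a cached co-membership table up to 10), agglomerative heuristic beyond. Exhaustive is available explicitly up to 12 items. |
| `refine` | `True` | Greedy single-item polishing of each agglomerative cut (see below). |
| `on_degenerate` | `"drop"` | All-0/all-1 items carry no covariance information; they are dropped with a warning and reported (label −1), or raise if `"raise"`. |

Within-stratum covariances use the maximum-likelihood denominator (m), which
keeps every estimate of 0/1 scores inside [−0.25, 0.25] — a bound that the
unbiased (m−1) form violates for tiny strata — and is still unbiased under
the independence null.

## Partition search

Agglomerative average-linkage clustering of the items on the dissimilarity
`max(C) − C` supplies nested candidate partitions; every cut at k = 1 …
`max_clusters` is evaluated, and each cut is polished by best-improvement
single-item reassignment (moving an item to another cluster, or to a new
singleton while below the cap, whenever that strictly raises the
within-cluster covariance sum — equivalently the DETECT index). Ties across
candidates resolve toward fewer clusters; the whole search is deterministic.
Refinement matters: raw linkage cuts attain the exhaustive optimum on only
about half of random 8-item covariance matrices, polished cuts on ≈98%, and
by construction the heuristic can never exceed the exhaustive value. The
exhaustive enumerator (restricted-growth strings) is the correctness anchor
in the tests.

## The synthetic-data generator

The simulator emulates a blueprint-like multidimensional test: 40 items in
four equal blocks with fixed direction angles. With 2 dimensions the blocks
have (factor-1, factor-2) angles (15°, 75°), (30°, 60°), (60°, 30°),
(75°, 15°), so each factor has items measuring it more strongly than the
other; with 4 dimensions every block loads on a cyclic factor pair (1,2),
(2,3), (3,4), (4,1) at (15°, 75°) and exactly two loadings per item.
Multidimensional discrimination (MDISC) is log-normal with the underlying
normal at mean 0, sd 0.25 (read as log-scale parameters, the standard
simulation convention; the raw-scale reading would put the median at ≈0.97
instead of 1 — immaterial, but the log-scale reading is the field's usual
one). Discriminations are `MDISC·cos(angle)`; the easiness intercept is
`MDISC·z` with `z` standard normal, untruncated; the guessing floor `c` (0
or 0.25) is shared by all items of a form; abilities are multivariate normal
with an exact equicorrelation matrix (ρ = 0.3 or 0.7 on every off-diagonal).

What it does **not** emulate: real item banks have idiosyncratic loading
patterns rather than four clean angle blocks, non-normal and possibly
heteroscedastic ability distributions, speededness, missing responses and
polytomous formats. Passing simulation tests therefore shows the estimator
recovers clean planted structure under the stated model, not that it
resolves the messier structure of operational data.

## The simulation study

The crossed study runs dims {2, 4} × ρ {0.3, 0.7} × N {100, 1000} ×
c {0, 0.25}, 100 replicated forms per condition (the acceptance script runs
exactly this; a `--reps` flag scales it down for quick looks). Every
replication draws its generator substream from
`SeedSequence(master_seed, spawn_key=(condition_index, rep_index))`, so any
single cell reruns identically in isolation and results are independent of
execution order. "Detected number of dimensions" is the cluster count of the
maximizing partition; summaries are plain means over replications, and the
adjusted Rand index against the generating blocks is recorded per
replication.

A known property visible in these summaries: maximizing the index over
partitions on the *same* sample that produced the covariance estimates
carries an upward optimization bias of the order of the pairwise noise, so
small-sample (N=100) mean `D*` values sit above the large-sample ones, and
adding a guessing floor — which attenuates the covariances themselves — can
lower the maximized value at N=1,000 while raising the detected cluster
count everywhere. Removing that bias requires maximizing on one half-sample
and evaluating on the other, a sample-splitting scheme deliberately outside
this package's scope.

## Numerical choices and degenerate inputs

- The conditional-covariance matrix keeps a NaN diagonal; no code path reads it.
- Index ties during search are broken toward fewer clusters with an absolute
  tolerance of 1e-12; greedy refinement requires a strict gain above the same
  tolerance, which with the monotone objective guarantees termination.
- The ratio index raises on an all-zero covariance matrix (undefined).
- `rest_score` requires at least 3 items; covariance estimation requires
  N ≥ 2·`min_group` and at least 3 non-degenerate items.
- Exam subjects that fail (e.g. entirely degenerate blocks) are reported
  with an error field without aborting the remaining subjects; blank cells in
  a response file are a hard parse error unless `missing="incorrect"`
  (omitted answers scored wrong, the licensing-exam convention).

## Known limitations

- Single-sample maximization inflates `D*` in small samples (see above); the
  interpretation bands are calibrated for the index, not for its small-sample
  optimism.
- The heuristic search is exact only empirically (vs. exhaustive enumeration
  up to 12 items); no optimality guarantee exists for 40-item tests.
- Contiguous-block blueprints are assumed for exam splitting; interleaved
  item orders need an explicit blueprint file mapping.
- Non-compensatory multidimensionality, polytomous items and missing-data
  mechanisms are out of scope.
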