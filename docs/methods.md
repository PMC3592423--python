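# Methods

## Preprocessing model

The pipeline assumes a compendium of arrays pooled from many independent
experiments, each with its own scale and laboratory offsets.

* **Quality control** operates on a precomputed per-chip metrics table
  (scale factor, BioB spike-in call, RLE/NUSE center and IQR); probe-level
  model fitting that produces those metrics is platform-specific and out
  of scope — the package starts from numbers. A chip passes iff its scale
  factor is within 3-fold of its *experiment's* mean scale factor, BioB is
  present, RLE is centered within 0.075 of 0, NUSE within 0.075 of 1, and
  both IQRs are ≤ 0.75. Note the 3-fold band is taken around a mean that
  includes the outliers themselves; in small experiments a single extreme
  chip can drag the band (this mirrors the stated procedure and is
  documented rather than "fixed").
* **Log centering** maps to log2 and subtracts, per gene, the mean over
  the chips of the same experiment — removing multiplicative batch
  effects exactly when they are per-experiment constants.
* **Quantile normalization** forces all chips onto the mean empirical
  distribution, jointly across experiments by default
  (`joint_quantiles=False` switches to within-experiment). Ties receive
  the mean of the target values their positions span (the common
  dialect). On tie-free data the map is idempotent; with ties a fully
  tied column collapses to the overall target mean, so strict idempotency
  holds only in the continuous (tie-free) regime — the realistic one for
  expression values.
* **IQR filter** (default 0.65 on the log scale, linear interpolation
  between order statistics) removes genes without the dynamic range MI
  estimation needs; a constant profile carries no rankable signal.
* **Probe-set clustering**: probe-sets mapping to no gene or to more than
  3 genes are discarded; the rest are clustered by the transitive closure
  of gene sharing (union-find) and each cluster keeps its
  fewest-target probe-set, ties broken by lexicographic id for
  determinism.

## Mutual information estimator

MI is estimated on rank-transformed profiles with the B-spline
(fuzzy-binning) estimator: basis functions of order *k* (default 3) on a
uniform knot vector with *k*-fold end knots over [0, M−k+1], M = 10 bins
by default; rank r maps linearly onto that interval. Order 1 degenerates
to hard histogram binning, which is the regime in which exact
contingency-table MI is available as an independent oracle (the test
suite exploits this). Basis evaluation goes through
`scipy.interpolate.BSpline.design_matrix`; tests verify it against a
direct Cox–de Boor recursion.

Rank transformation makes every profile a permutation of 1..m, so all
genes share one marginal distribution (the column means of the basis
table) and one marginal entropy, computed once. Ties are broken by
original position (stable sort): ties are rare after normalization and a
deterministic rule beats a randomized one for reproducibility.

Entropies are natural-log; MI values are in nats and clamped at 0 (the
estimator can go infinitesimally negative through floating-point
cancellation). Note that with fuzzy binning MI(x, x) is *not* exactly the
marginal entropy — the joint of a profile with itself does not collapse
to a diagonal unless each observation occupies a single bin (order 1).

## Pooled permutation null and edge calling

Because all rank-transformed profiles are permutations of the same set,
the MI of (identity, random permutation) is distributed identically to
the MI of any profile against a random permutation of any other. One pool
of P permutation MI samples therefore serves every pair. An observed MI
is significant when it beats at least a fraction 1−ε of the pool
(count semantics; the stored threshold is the smallest sample with that
many samples strictly below it, so significance ⇔ MI ≥ threshold).
Defaults ε = 1e-4 with P = 1e5; the precondition P·ε ≥ 1 keeps the
quantile resolvable. The builder requires a seed and records it, with all
other parameters, in the output network's metadata.

## Block schedule

The symmetric all-pairs computation is partitioned into p×p blocks;
processor j at stage i computes block (j, (j+i) mod p) for stages
0..⌊p/2⌋. For even p the final stage assigns each block pair twice
(half-flagged, each owner computing half). The schedule's contract is
coverage — every unordered block pair exactly once — and the driver
treats blocks as order-independent work units, so the inferred network is
identical for any worker count. Actual multi-process execution is not
implemented; the schedule is the logical partitioning.

## DPI pruning

Edge (i,k) is removed iff some common neighbour j of the *input* network
satisfies MI(i,k) ≤ (1−tolerance)·min(MI(i,j), MI(j,k)). Mark-and-sweep
(all decisions against the pre-pruning network) makes the result
independent of iteration order. The inequalities are non-strict, so an
exactly tied triangle loses all three edges at tolerance 0 — a positive
tolerance is the escape hatch. Default tolerance 0.

## Random-walk ranking and extraction

Transition probabilities are MI row-normalised: w_ij = MI(i,j)/Σ_k
MI(i,k). The ranking iterates R ← r·P + (1−r)·(WᵀR + d·P) from R = P,
where d is the rank mass sitting on edge-less nodes — redirecting
dangling mass to the preference vector keeps the chain well defined
without requiring connectivity (a strict mode refuses dangling nodes
instead). Convergence is L1 change < 1e-10 (cap 1000 iterations; typical
networks converge in tens). Restart probability defaults to r = 0.3 and
is always settable; mass Σ R = 1 is conserved exactly at every step.

Extraction appends non-seed genes in decreasing R (ties by gene id) and
tests connectivity of the growing induced subgraph incrementally with a
union-find (the node set only grows, so no recomputation is needed),
stopping at the first connected state.

## Network statistics

Path length and diameter are over connected pairs only (a single giant
component dominates real co-expression networks; an edgeless network
reports them as absent). Random-graph expectations are L_rand =
ln n / ln⟨k⟩ and C_rand = ⟨k⟩/n. Betweenness is unnormalised
shortest-path betweenness (flag for pair-count normalisation). Hubs
default to degree ≥ 50.

The power-law fit is least squares on (log k, log P(k)) over observed
degrees with P(k) > 0, **weighted by √count**: the sampling variance of a
log-proportion scales inversely with its count, and unweighted least
squares lets the one-node tail flatten the slope well below the true
exponent on preferential-attachment graphs. The weighting leaves exact
power-law inputs exact. A parallel fit of the cumulative distribution is
reported as a robustness check, and near-zero slopes are flagged as flat.

The modularity test counts connected components of the subgraph induced
by a gene set and compares against random node sets of equal size
(distributionally identical to relabelling all genes by a random
permutation, but cheaper). The empirical p-value uses the +1 correction,
so it is never 0 at finite shuffles. Because the statistic is discrete,
these p-values are super-uniform (conservative) under the null rather
than exactly uniform; the tests check validity, P(p ≤ q) ≤ q.

## Synthetic benchmark

The generator emulates benchmark-style recovery experiments with a
transparent model rather than wrapping an external simulator:

* **Topology**: preferential attachment, edges oriented from
  earlier-attached to later-attached node — a weakly connected DAG with a
  power-law degree tail. Default average degree 2.
* **Expression**: root genes are standard normal per sample; a regulated
  gene is f(Σ s_w x_w / √deg) + N(0, σ²), with random ±1 edge signs
  (activation/repression) and f ∈ {identity, centered logistic, centered
  logistic with 10× slope} for linear / sigmoidal / steep interactions.
  Defaults: 100 genes, 200 observations, noise σ = 0.1 (a low-noise
  regime in units of the unit-variance roots).
* Cyclic truths are evaluated by a fixed number of update sweeps (10) or
  rejected in strict mode.

What this does and does not show: passing recovery tests demonstrates
that the estimator, null, and pruning interact correctly on data whose
dependence structure is known — it does not certify performance on real
microarray data, whose noise is heteroskedastic, whose regulation is
dynamic, and whose sampling is biased toward particular conditions. No
distributional equivalence to SynTReN/GNW kinetics is claimed.

Scoring: precision/recall/F over undirected edge sets (inference is
undirected, so truth direction is ignored); AUROC/AUPR over all possible
pairs from a confidence map via scikit-learn. The challenge-style batch
score estimates AUROC/AUPR p-values against a null of random rankings
(vectorised permutation of the label vector) and combines them as the
mean of −log10 geometric-mean p-values across networks; it accepts
externally supplied three-column gold standards, which are not bundled.

## Problem sizes in tests and the acceptance script

The test suite and acceptance script run the full pipeline at 100 genes ×
200 observations (the benchmark scale), with permutation pools of 1e4,
brute-force cross-checks on 15-node graphs × 100 replicates, dense-solve
walk checks up to 50 nodes, and 2000-node graphs for degree-distribution
fits — sizes at which exhaustive oracles remain exact and runs complete
in seconds on one CPU.

## Known limitations

* No probe-level (CEL) processing; QC consumes a precomputed metrics
  table.
* Parallelism is logical only (the block schedule); execution is single
  process.
* The edge-call threshold is a global quantile; no per-pair FDR control.
* DPI with tolerance 0 removes all edges of exactly tied triangles.
* Least-squares power-law fitting is a diagnostic, not an MLE exponent
  estimate.
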