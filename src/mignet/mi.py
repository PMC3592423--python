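"""Rank-transformed B-spline mutual information with a pooled permutation null.

The estimator follows the B-spline (fuzzy binning) approach of Daub et al.:
each observation distributes unit weight over up to ``order`` adjacent bins
through B-spline basis functions, giving smoother probability estimates than
a hard histogram, and MI is computed as ``H(X) + H(Y) - H(X, Y)`` from the
resulting bin probabilities.

Profiles are first rank-transformed.  Because MI is invariant (in the
population sense) under monotone transformations, replacing values by their
ranks loses nothing — and it buys two things:

* every profile becomes a permutation of ``1..m``, so all genes share the
  same marginal distribution and marginal entropy, computable once;
* a single pool of random-permutation MI values is a valid permutation null
  for *every* gene pair, reducing permutation testing for all ``n*(n-1)/2``
  pairs to one pool of ``P`` permutations.

An edge is called significant when its MI beats at least a fraction
``1 - epsilon`` of the pooled null samples.

The all-pairs computation is organised over the block schedule of
:func:`block_schedule` (the logical partitioning a distributed-memory run
would use); block results are order-independent, so the edge set does not
depend on how many workers consume the blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.interpolate import BSpline

from .expression import ExpressionMatrix

__all__ = [
    "SplineBasis",
    "NullModel",
    "BlockAssignment",
    "BlockSchedule",
    "rank_transform",
    "build_spline_basis",
    "entropy",
    "mutual_information",
    "pairwise_mi",
    "build_null",
    "block_schedule",
    "all_pairs_mi",
]

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# rank transform
# ---------------------------------------------------------------------------

def rank_transform(profile: np.ndarray) -> np.ndarray:
    """Replace each value by its ascending rank in ``1..m``.

    Ties are broken by original position (stable sort), so the output is
    always a permutation of ``1..m`` and deterministic.
    """
    profile = np.asarray(profile, dtype=float)
    m = profile.shape[0]
    if m < 2:
        raise ValueError("rank transform needs at least 2 observations")
    order = np.argsort(profile, kind="stable")
    ranks = np.empty(m, dtype=np.int64)
    ranks[order] = np.arange(1, m + 1)
    return ranks


def rank_matrix(matrix: ExpressionMatrix) -> np.ndarray:
    """Row-wise rank transform of an expression matrix (n x m int array)."""
    return np.vstack([rank_transform(row) for row in matrix.values])


# ---------------------------------------------------------------------------
# B-spline basis
# ---------------------------------------------------------------------------

@dataclass
class SplineBasis:
    """Per-rank B-spline bin weights shared by all rank-transformed genes.

    ``weights[r - 1]`` holds the ``bins`` basis-function values for rank
    ``r``; each row sums to one (partition of unity) and has at most
    ``order`` consecutive nonzero entries.
    """

    m: int
    bins: int
    order: int
    weights: np.ndarray = field(repr=False)

    def marginal_probabilities(self) -> np.ndarray:
        """Bin probabilities of any rank-transformed profile of length m.

        After rank transformation every profile contains each rank exactly
        once, so the marginal is simply the column mean of the weight table
        — identical for all genes.
        """
        return self.weights.mean(axis=0)

    def marginal_entropy(self) -> float:
        """Shared marginal entropy H (nats) of rank-transformed profiles."""
        return entropy(self.marginal_probabilities())


def build_spline_basis(m: int, bins: int = 10, order: int = 3) -> SplineBasis:
    """Evaluate the B-spline bin weights for every rank value ``1..m``.

    B-spline basis functions of the given ``order`` (polynomial degree
    ``order - 1``) are placed on a uniform knot vector over
    ``[0, bins - order + 1]`` with ``order``-fold end knots; rank ``r`` is
    mapped linearly onto that interval and the ``bins`` basis functions are
    evaluated there.  ``order=1`` degenerates to hard (histogram) binning.
    """
    if order < 1:
        raise ValueError("spline order must be >= 1")
    if bins < order:
        raise ValueError(f"need bins >= order, got bins={bins} order={order}")
    if m < bins:
        raise ValueError(f"need m >= bins, got m={m} bins={bins}")
    k = order
    knots = np.concatenate(
        [np.zeros(k), np.arange(1, bins - k + 1, dtype=float),
         np.full(k, bins - k + 1, dtype=float)]
    )
    z = np.arange(m, dtype=float) / (m - 1) * (bins - k + 1)
    weights = BSpline.design_matrix(z, knots, k - 1).toarray()
    return SplineBasis(m=m, bins=bins, order=order, weights=weights)


# ---------------------------------------------------------------------------
# entropies and MI
# ---------------------------------------------------------------------------

def entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats, with the 0*log(0) = 0 convention."""
    p = np.asarray(p, dtype=float).ravel()
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def _weights_for(ranks: np.ndarray, basis: SplineBasis) -> np.ndarray:
    ranks = np.asarray(ranks)
    if ranks.shape[-1] != basis.m:
        raise ValueError(
            f"rank vector length {ranks.shape[-1]} does not match basis m={basis.m}"
        )
    return basis.weights[ranks - 1]


def mutual_information(
    ranks_x: np.ndarray, ranks_y: np.ndarray, basis: SplineBasis
) -> float:
    """B-spline MI (nats) between two rank vectors of length ``basis.m``.

    Marginal bin probabilities are sample means of the per-observation bin
    weights; joint probabilities are means of weight outer products.  The
    estimate is symmetric in its arguments and clamped to be nonnegative.
    """
    wx = _weights_for(ranks_x, basis)
    wy = _weights_for(ranks_y, basis)
    hx = entropy(wx.mean(axis=0))
    hy = entropy(wy.mean(axis=0))
    joint = wx.T @ wy / basis.m
    mi = hx + hy - entropy(joint)
    return max(mi, 0.0)


def pairwise_mi(
    matrix: ExpressionMatrix, basis: SplineBasis | None = None,
    bins: int = 10, order: int = 3,
) -> np.ndarray:
    """Symmetric n x n matrix of rank-transformed B-spline MI values (nats).

    The diagonal holds each gene's (shared) marginal entropy.
    """
    if matrix.n_genes < 2:
        raise ValueError("need at least 2 genes")
    if basis is None:
        basis = build_spline_basis(matrix.n_chips, bins=bins, order=order)
    ranks = rank_matrix(matrix)
    w = basis.weights[ranks - 1]          # n x m x bins
    h_marg = basis.marginal_entropy()     # same for every gene
    n, m = matrix.n_genes, matrix.n_chips
    out = np.full((n, n), h_marg)
    for i in range(n):
        joint = np.einsum("ma,jmb->jab", w[i], w[i + 1:]) / m
        for off, pab in enumerate(joint):
            mi = max(2.0 * h_marg - entropy(pab), 0.0)
            out[i, i + 1 + off] = mi
            out[i + 1 + off, i] = mi
    return out


# ---------------------------------------------------------------------------
# pooled permutation null
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    """Sorted pool of permutation-null MI samples and the edge threshold.

    ``threshold`` is the smallest sample value with at least a fraction
    ``1 - epsilon`` of the samples strictly below it; an observed MI is
    significant iff it beats at least that fraction of the pool.
    """

    samples: np.ndarray = field(repr=False)
    epsilon: float
    threshold: float
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    def is_significant(self, mi: float | np.ndarray) -> np.ndarray:
        """True where ``mi`` beats >= (1 - epsilon) of the null samples."""
        need = int(np.ceil((1.0 - self.epsilon) * self.n_samples))
        below = np.searchsorted(self.samples, np.asarray(mi), side="left")
        return below >= need


def build_null(
    m: int,
    P_perm: int,
    basis: SplineBasis | None = None,
    epsilon: float = 1e-4,
    seed: int = 0,
    bins: int = 10,
    order: int = 3,
) -> NullModel:
    """Pooled permutation null for all gene pairs at sample size ``m``.

    Each null sample is the MI between the identity rank vector and an
    independent uniformly random permutation of ``1..m`` — after rank
    transformation this is distributed identically to the MI between any
    fixed profile and a random permutation of any other, so one pool serves
    every pair.
    """
    if P_perm < 1:
        raise ValueError("need at least one permutation")
    if P_perm * epsilon < 1:
        raise ValueError(
            f"epsilon={epsilon} is not resolvable with {P_perm} permutations; "
            f"need P_perm >= 1/epsilon = {1.0 / epsilon:.0f}"
        )
    if basis is None:
        basis = build_spline_basis(m, bins=bins, order=order)
    rng = np.random.default_rng(seed)
    w_id = basis.weights                      # identity ranks 1..m
    h2 = 2.0 * basis.marginal_entropy()
    samples = np.empty(P_perm)
    chunk = 256
    for start in range(0, P_perm, chunk):
        size = min(chunk, P_perm - start)
        perms = np.argsort(rng.random((size, m)), axis=1)   # uniform perms
        w_p = basis.weights[perms]                          # size x m x bins
        joints = np.einsum("ma,smb->sab", w_id, w_p) / m
        for s in range(size):
            samples[start + s] = max(h2 - entropy(joints[s]), 0.0)
    samples.sort()
    need = int(np.ceil((1.0 - epsilon) * P_perm))
    # smallest sample with >= `need` samples strictly below it
    base = samples[need - 1] if need >= 1 else -np.inf
    idx = int(np.searchsorted(samples, base, side="right"))
    threshold = float(samples[idx]) if idx < P_perm else float(samples[-1])
    return NullModel(
        samples=samples, epsilon=epsilon, threshold=threshold, seed=seed
    )


# ---------------------------------------------------------------------------
# block schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockAssignment:
    stage: int
    rank: int
    block_row: int
    block_col: int
    half: bool = False


@dataclass
class BlockSchedule:
    """Stage-wise assignment of adjacency-matrix blocks to processor ranks.

    The symmetric n x n MI matrix is partitioned into p x p blocks; only the
    upper triangle of block pairs needs computing.  At stage ``i`` processor
    ``j`` computes block ``(j, (j + i) mod p)``.  When ``p`` is even, the
    final stage assigns each block pair to two processors (the circular
    shift wraps onto itself); those assignments carry ``half=True`` and each
    processor computes half the block.
    """

    p: int
    assignments: list[BlockAssignment]

    def covered_pairs(self) -> dict[tuple[int, int], float]:
        """Unordered block pair -> total computation share (should be 1)."""
        cover: dict[tuple[int, int], float] = {}
        for a in self.assignments:
            key = tuple(sorted((a.block_row, a.block_col)))
            cover[key] = cover.get(key, 0.0) + (0.5 if a.half else 1.0)
        return cover


def block_schedule(p: int) -> BlockSchedule:
    """Circular-shift schedule covering every unordered block pair once."""
    if p < 1:
        raise ValueError("need at least one processor")
    n_stages = p // 2 + 1
    assignments: list[BlockAssignment] = []
    for stage in range(n_stages):
        for rank in range(p):
            col = (rank + stage) % p
            half = p % 2 == 0 and stage == n_stages - 1
            assignments.append(
                BlockAssignment(
                    stage=stage, rank=rank, block_row=rank,
                    block_col=col, half=half,
                )
            )
    return BlockSchedule(p=p, assignments=assignments)


# ---------------------------------------------------------------------------
# all-pairs driver
# ---------------------------------------------------------------------------

def all_pairs_mi(
    matrix: ExpressionMatrix,
    bins: int = 10,
    order: int = 3,
    epsilon: float = 1e-4,
    P_perm: int = 100_000,
    seed: int = 0,
    workers: int = 1,
    null: NullModel | None = None,
) -> nx.Graph:
    """Infer the MI network: all-pairs MI thresholded by the pooled null.

    Returns an undirected :class:`networkx.Graph` whose edges carry the MI
    value in attribute ``weight``; only pairs whose MI beats at least a
    fraction ``1 - epsilon`` of the null pool become edges.  Inference
    parameters are recorded in ``graph.graph``.  The computation iterates
    over the logical blocks of :func:`block_schedule`, and its result is
    independent of the ``workers`` count.
    """
    if matrix.n_genes < 2:
        raise ValueError("need at least 2 genes to infer a network")
    if workers < 1:
        raise ValueError("workers must be >= 1")
    basis = build_spline_basis(matrix.n_chips, bins=bins, order=order)
    if null is None:
        null = build_null(
            matrix.n_chips, P_perm, basis=basis, epsilon=epsilon, seed=seed
        )
    ranks = rank_matrix(matrix)
    w = basis.weights[ranks - 1]
    h2 = 2.0 * basis.marginal_entropy()
    n, m = matrix.shape
    genes = matrix.gene_ids

    net = nx.Graph()
    net.add_nodes_from(genes)
    net.graph.update(
        bins=bins, order=order, epsilon=null.epsilon,
        P_perm=null.n_samples, seed=null.seed, threshold=null.threshold,
    )

    # iterate gene pairs through the logical block partition; any block
    # execution order (hence any worker count) yields the same edge set
    schedule = block_schedule(workers)
    bounds = np.linspace(0, n, workers + 1).astype(int)
    seen_blocks: set[tuple[int, int]] = set()
    for a in schedule.assignments:
        key = tuple(sorted((a.block_row, a.block_col)))
        if key in seen_blocks:
            continue
        seen_blocks.add(key)
        rows = range(bounds[key[0]], bounds[key[0] + 1])
        cols = range(bounds[key[1]], bounds[key[1] + 1])
        for i in rows:
            for j in cols:
                if j <= i:
                    continue
                pab = w[i].T @ w[j] / m
                mi = max(h2 - entropy(pab), 0.0)
                if bool(null.is_significant(mi)):
                    net.add_edge(genes[i], genes[j], weight=float(mi))
    return net
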