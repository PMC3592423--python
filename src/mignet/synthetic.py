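"""Ground-truth network simulation and prediction scoring.

This module makes the inference pipeline testable without any external
download.  It emulates SynTReN-style benchmark experiments with a
transparent generator:

* :func:`sample_topology` draws a scale-free-ish directed regulator ->
  target network by preferential attachment;
* :func:`simulate_expression` propagates per-sample root expression through
  the network, each regulated gene being a linear, sigmoidal or steep
  (saturating, switch-like) function of a signed sum of its regulators,
  plus Gaussian noise;
* :func:`score_prediction` compares an inferred (undirected) network with
  the truth by precision / recall / F-score, and scores a ranked edge list
  by AUROC and AUPR;
* :func:`run_benchmark` runs the full simulate -> infer -> DPI -> score
  loop over repetitions;
* :func:`dream4_score` implements the challenge-style log-transformed
  score over several networks (AUROC/AUPR p-values against a
  random-prediction null), for users who supply external gold standards.

The generator claims no distributional equivalence to SynTReN or GNW; it
reproduces the structure of the experiment (scale-free truth, three
interaction-function families, additive noise), not their kinetic models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from sklearn.metrics import average_precision_score, roc_auc_score

from .dpi import apply_dpi
from .expression import ExpressionMatrix
from .mi import all_pairs_mi, build_spline_basis, pairwise_mi

__all__ = [
    "BenchmarkScore",
    "sample_topology",
    "simulate_expression",
    "score_prediction",
    "random_predictor_f",
    "run_benchmark",
    "read_gold_standard",
    "dream4_score",
]

INTERACTION_KINDS = ("linear", "sigmoidal", "steep")


# ---------------------------------------------------------------------------
# truth networks and expression simulation
# ---------------------------------------------------------------------------

def sample_topology(n: int, avg_degree: float = 2.0, seed: int = 0) -> nx.DiGraph:
    """Scale-free-ish directed truth network by preferential attachment.

    An undirected preferential-attachment graph is grown and each edge is
    oriented from the earlier-attached node to the later one (regulators
    precede their targets), yielding a weakly connected DAG whose degree
    distribution has a power-law tail.  Reproducible under ``seed``.
    """
    if n < 10:
        raise ValueError("need at least 10 genes")
    m_attach = max(1, int(round(avg_degree / 2.0)))
    g = nx.barabasi_albert_graph(n, m_attach, seed=int(seed))
    width = len(str(n - 1))
    name = {i: f"G{i:0{width}d}" for i in g.nodes()}
    truth = nx.DiGraph()
    truth.add_nodes_from(name[i] for i in range(n))
    for u, v in g.edges():
        a, b = (u, v) if u < v else (v, u)   # attachment order = node index
        truth.add_edge(name[a], name[b])
    return truth


def _interaction(kind: str) -> callable:
    if kind == "linear":
        return lambda z: z
    if kind == "sigmoidal":
        return lambda z: 2.0 / (1.0 + np.exp(-z)) - 1.0
    if kind == "steep":
        return lambda z: 2.0 / (1.0 + np.exp(-10.0 * z)) - 1.0
    raise ValueError(f"unknown interaction kind {kind!r}; "
                     f"choose from {INTERACTION_KINDS}")


def simulate_expression(
    truth: nx.DiGraph,
    kind: str = "linear",
    m: int = 200,
    noise_sd: float = 0.1,
    seed: int = 0,
    cycle_sweeps: int = 10,
    strict: bool = False,
) -> ExpressionMatrix:
    """Simulate ``m`` expression samples from a regulator -> target network.

    Per sample, root genes (no regulators) draw from a standard normal;
    each regulated gene is ``f(sum_w s_w * x_w / sqrt(#regulators))`` plus
    ``N(0, noise_sd^2)`` noise, where the signs ``s_w`` (activation +1 /
    repression -1) are drawn once per edge and ``f`` is the interaction
    function of ``kind``.  Genes are evaluated in topological order; a
    cyclic truth network is evaluated by ``cycle_sweeps`` repeated update
    sweeps (or rejected when ``strict``).
    """
    if m < 10:
        raise ValueError("need at least 10 samples")
    f = _interaction(kind)
    rng = np.random.default_rng(seed)
    genes = sorted(truth.nodes())
    idx = {g: i for i, g in enumerate(genes)}
    sign = {
        (u, v): (1.0 if rng.random() < 0.5 else -1.0)
        for u, v in sorted(truth.edges())
    }

    try:
        order = [g for g in nx.topological_sort(truth)]
        sweeps = 1
    except nx.NetworkXUnfeasible:
        if strict:
            raise ValueError("truth network is cyclic")
        order = genes
        sweeps = cycle_sweeps

    x = np.zeros((len(genes), m))
    roots = [g for g in genes if truth.in_degree(g) == 0]
    for g in roots:
        x[idx[g]] = rng.standard_normal(m)
    noise = {
        g: (rng.standard_normal(m) * noise_sd if noise_sd > 0 else 0.0)
        for g in genes if truth.in_degree(g) > 0
    }
    for _ in range(sweeps):
        for g in order:
            regs = list(truth.predecessors(g))
            if not regs:
                continue
            z = sum(sign[(u, g)] * x[idx[u]] for u in regs) / np.sqrt(len(regs))
            x[idx[g]] = f(z) + noise[g]

    chip_ids = [f"S{j:04d}" for j in range(m)]
    return ExpressionMatrix(
        gene_ids=genes, chip_ids=chip_ids,
        experiment_of_chip={c: "sim" for c in chip_ids}, values=x,
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _undirected_pairs(edges) -> set[frozenset]:
    pairs = set()
    for u, v in edges:
        if u != v:
            pairs.add(frozenset((u, v)))
    return pairs


@dataclass
class BenchmarkScore:
    precision: float
    recall: float
    f_score: float
    auroc: float | None = None
    aupr: float | None = None

    def to_dict(self) -> dict:
        return {
            "precision": self.precision, "recall": self.recall,
            "f_score": self.f_score, "auroc": self.auroc, "aupr": self.aupr,
        }


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def score_prediction(
    predicted: nx.Graph,
    truth: nx.Graph | nx.DiGraph,
    scores: dict | None = None,
) -> BenchmarkScore:
    """Precision / recall / F of a predicted network against the truth.

    Edge direction in the truth is ignored — the inference method is
    undirected.  If ``scores`` maps unordered gene pairs (frozensets) to a
    confidence value, AUROC and AUPR are additionally computed over *all*
    possible pairs of truth-network genes (pairs without a score count as
    confidence 0).
    """
    true_pairs = _undirected_pairs(truth.edges())
    if not true_pairs:
        raise ValueError("truth network has no edges")
    pred_pairs = _undirected_pairs(predicted.edges())
    tp = len(pred_pairs & true_pairs)
    precision = tp / len(pred_pairs) if pred_pairs else 0.0
    recall = tp / len(true_pairs)

    auroc = aupr = None
    if scores is not None:
        nodes = sorted(truth.nodes())
        pairs = [frozenset(p) for p in itertools.combinations(nodes, 2)]
        y = np.array([p in true_pairs for p in pairs], dtype=int)
        s = np.array([float(scores.get(p, 0.0)) for p in pairs])
        auroc = float(roc_auc_score(y, s))
        aupr = float(average_precision_score(y, s))
    return BenchmarkScore(
        precision=precision, recall=recall,
        f_score=f_score(precision, recall), auroc=auroc, aupr=aupr,
    )


def random_predictor_f(n_nodes: int, n_true: int, n_predicted: int) -> float:
    """Expected F-score of a uniformly random predictor.

    A predictor choosing ``n_predicted`` of the ``n (n-1) / 2`` possible
    pairs at random has expected precision ``n_true / total`` and expected
    recall ``n_predicted / total``; the F-score of those expectations is
    the baseline an informative method must clear.
    """
    total = n_nodes * (n_nodes - 1) // 2
    if total == 0 or n_true == 0:
        raise ValueError("degenerate truth")
    return f_score(n_true / total, min(n_predicted, total) / total)


# ---------------------------------------------------------------------------
# end-to-end benchmark
# ---------------------------------------------------------------------------

def run_benchmark(
    n: int = 100,
    m: int = 200,
    kind: str = "linear",
    reps: int = 10,
    noise_sd: float = 0.1,
    avg_degree: float = 2.0,
    bins: int = 10,
    order: int = 3,
    epsilon: float = 1e-3,
    P_perm: int = 10_000,
    dpi_tolerance: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate -> infer -> prune -> score, ``reps`` times.

    Returns one row per repetition with precision, recall, F-score, AUROC,
    AUPR of the MI ranking, and the matched random-predictor expected F.
    Per-repetition seeds are derived from ``seed``.
    """
    if reps < 1:
        raise ValueError("need at least one repetition")
    rows = []
    ss = np.random.SeedSequence(seed)
    for rep, child in enumerate(ss.spawn(reps)):
        s1, s2, s3 = child.generate_state(3, dtype=np.uint32) >> np.uint32(1)
        truth = sample_topology(n, avg_degree=avg_degree, seed=int(s1))
        expr = simulate_expression(
            truth, kind=kind, m=m, noise_sd=noise_sd, seed=int(s2)
        )
        net = all_pairs_mi(
            expr, bins=bins, order=order, epsilon=epsilon,
            P_perm=P_perm, seed=int(s3),
        )
        pruned = apply_dpi(net, tolerance=dpi_tolerance)
        basis = build_spline_basis(m, bins=bins, order=order)
        mi_mat = pairwise_mi(expr, basis=basis)
        genes = expr.gene_ids
        scores = {
            frozenset((genes[i], genes[j])): mi_mat[i, j]
            for i in range(n) for j in range(i + 1, n)
        }
        sc = score_prediction(pruned, truth, scores=scores)
        rows.append(
            {
                "rep": rep, "kind": kind, **sc.to_dict(),
                "edges_predicted": pruned.number_of_edges(),
                "edges_true": truth.number_of_edges(),
                "random_f": random_predictor_f(
                    n, len(_undirected_pairs(truth.edges())),
                    max(pruned.number_of_edges(), 1),
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# challenge-style scoring over several gold standards
# ---------------------------------------------------------------------------

def read_gold_standard(path) -> dict[frozenset, int]:
    """Read a three-column gold standard: gene, gene, 0/1 (tab separated)."""
    gold: dict[frozenset, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns")
            a, b, flag = parts
            if a == b:
                raise ValueError(f"{path}:{ln}: self-pair {a!r}")
            gold[frozenset((a, b))] = int(flag)
    if not gold:
        raise ValueError(f"{path}: empty gold standard")
    return gold


def _null_auc_samples(
    y: np.ndarray, n_null: int, rng: np.random.Generator, chunk: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """AUROC and AUPR of random rankings of the label vector ``y``."""
    n = y.size
    npos = int(y.sum())
    nneg = n - npos
    pos_idx = np.arange(1, n + 1)
    aurocs = np.empty(n_null)
    auprs = np.empty(n_null)
    done = 0
    while done < n_null:
        size = min(chunk, n_null - done)
        labels = np.tile(y, (size, 1))
        perm = np.argsort(rng.random((size, n)), axis=1)
        labels = np.take_along_axis(labels, perm, axis=1)
        cum = np.cumsum(labels, axis=1)
        negs_so_far = pos_idx[None, :] - cum
        aurocs[done:done + size] = (
            (labels * (nneg - negs_so_far)).sum(axis=1) / (npos * nneg)
        )
        auprs[done:done + size] = (
            (labels * cum / pos_idx[None, :]).sum(axis=1) / npos
        )
        done += size
    return aurocs, auprs


def dream4_score(
    predictions: list[dict],
    golds: list[dict],
    n_null: int = 10_000,
    seed: int = 0,
) -> dict:
    """Challenge-style overall score for a batch of network predictions.

    For each network, ``predictions[i]`` maps unordered gene pairs
    (frozensets) to confidence scores and ``golds[i]`` maps the evaluated
    pairs to 0/1 truth labels.  AUROC and AUPR are computed per network,
    their p-values estimated against a null of ``n_null`` random rankings,
    and the overall score is the mean of ``-log10`` of the geometric means
    of the AUROC and AUPR p-values across networks.
    """
    if len(predictions) != len(golds) or not golds:
        raise ValueError("need one prediction per gold standard")
    rng = np.random.default_rng(seed)
    per_net = []
    for pred, gold in zip(predictions, golds):
        pairs = sorted(gold, key=sorted)
        y = np.array([gold[p] for p in pairs], dtype=int)
        if y.sum() == 0 or y.sum() == y.size:
            raise ValueError("gold standard needs both positive and negative pairs")
        s = np.array([float(pred.get(p, 0.0)) for p in pairs])
        auroc = float(roc_auc_score(y, s))
        aupr = float(average_precision_score(y, s))
        null_auroc, null_aupr = _null_auc_samples(y, n_null, rng)
        p_auroc = (1 + int((null_auroc >= auroc).sum())) / (1 + n_null)
        p_aupr = (1 + int((null_aupr >= aupr).sum())) / (1 + n_null)
        per_net.append(
            {"auroc": auroc, "aupr": aupr,
             "p_auroc": p_auroc, "p_aupr": p_aupr}
        )
    auroc_score = float(-np.mean([np.log10(d["p_auroc"]) for d in per_net]))
    aupr_score = float(-np.mean([np.log10(d["p_aupr"]) for d in per_net]))
    return {
        "per_network": per_net,
        "auroc_score": auroc_score,
        "aupr_score": aupr_score,
        "overall_score": 0.5 * (auroc_score + aupr_score),
    }
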