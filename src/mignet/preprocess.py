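"""Quality control, normalization and filtering of cross-experiment data.

The pipeline turns a raw (positive, linear-scale) gene x chip matrix pooled
from many microarray experiments into the normalized, filtered matrix the
mutual-information engine consumes:

1. :func:`qc_filter` drops chips failing array-level quality metrics
   (scale-factor outliers within their experiment, absent BioB spike-in,
   off-center or high-spread RLE/NUSE distributions).
2. :func:`log_center` moves values to log2 space and centers each gene
   within each experiment, removing laboratory/batch offsets.
3. :func:`quantile_normalize` forces all chips onto a common empirical
   distribution.
4. :func:`iqr_filter` removes genes whose profiles lack the dynamic range
   (interquartile range) needed for dependable MI estimation.
5. :func:`cluster_probesets` resolves redundant probe-set -> gene maps to
   one representative probe-set per cluster of gene-sharing probe-sets.

Percentiles throughout use linear interpolation between order statistics
(numpy's default), and quantile normalization assigns tied values the mean
of the target values their positions span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "ProbeMap",
    "qc_filter",
    "log_center",
    "quantile_normalize",
    "iqr_filter",
    "cluster_probesets",
    "preprocess_pipeline",
]

#: Columns a QC metrics table must provide (one row per chip).
QC_COLUMNS = (
    "scale_factor",
    "biob_present",
    "rle_center",
    "rle_iqr",
    "nuse_center",
    "nuse_iqr",
)


@dataclass
class ProbeMap:
    """Probe-set -> gene-id map with explicit no-match entries.

    ``entries`` maps each probe-set id to the (possibly empty) set of gene
    identifiers it measures; an empty set marks a ``no_match`` probe-set.
    """

    entries: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = {p: frozenset(g) for p, g in self.entries.items()}

    def no_match(self) -> set[str]:
        return {p for p, g in self.entries.items() if not g}


def qc_filter(
    metrics: pd.DataFrame,
    experiment_of_chip: dict[str, str],
    fold: float = 3.0,
    center_tol: float = 0.075,
    iqr_max: float = 0.75,
) -> list[str]:
    """Chip-level quality control; returns ids of chips that pass.

    A chip is kept iff all of the following hold:

    * its scale factor lies within ``fold``-fold of the mean scale factor
      of its experiment (``mean/fold <= sf <= fold*mean``);
    * the BioB spike-in transcript was called present;
    * relative log expression (RLE) is centered near 0 and normalized
      unscaled standard error (NUSE) near 1, each within ``center_tol``;
    * both RLE and NUSE interquartile ranges are at most ``iqr_max``.

    Parameters
    ----------
    metrics
        Table indexed by chip id with columns :data:`QC_COLUMNS`.
    experiment_of_chip
        Mapping chip id -> experiment label; scale-factor means are taken
        within experiments.
    """
    missing = [c for c in QC_COLUMNS if c not in metrics.columns]
    if missing:
        raise ValueError(f"QC metrics missing columns: {missing}")
    unlabeled = [c for c in metrics.index if c not in experiment_of_chip]
    if unlabeled:
        raise ValueError(f"chips without experiment label: {unlabeled}")
    sf = metrics["scale_factor"].astype(float)
    if (sf <= 0).any():
        bad = list(metrics.index[sf <= 0])
        raise ValueError(f"non-positive scale factor for chips: {bad}")

    labels = pd.Series(
        [experiment_of_chip[c] for c in metrics.index], index=metrics.index
    )
    if labels.empty:
        raise ValueError("empty QC metrics table")
    mean_sf = sf.groupby(labels).transform("mean")

    ok = (
        (sf >= mean_sf / fold)
        & (sf <= mean_sf * fold)
        & metrics["biob_present"].astype(bool)
        & (metrics["rle_iqr"].astype(float) <= iqr_max)
        & (metrics["nuse_iqr"].astype(float) <= iqr_max)
        & (metrics["rle_center"].astype(float).sub(0.0).abs() <= center_tol)
        & (metrics["nuse_center"].astype(float).sub(1.0).abs() <= center_tol)
    )
    return [str(c) for c in metrics.index[ok]]


def log_center(raw: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform and center each gene within each experiment.

    The output value for gene *i* on chip *j* is ``log2(raw[i, j])`` minus
    the mean of ``log2(raw[i, j'])`` over all chips *j'* belonging to the
    same experiment as *j*, so per-experiment, per-gene means are zero.

    Raises
    ------
    ValueError
        If any raw value is non-positive (names the offending gene/chip).
    """
    bad = np.argwhere(~(raw.values > 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive expression value {raw.values[i, j]!r} for gene "
            f"{raw.gene_ids[i]!r} on chip {raw.chip_ids[j]!r}"
        )
    logged = np.log2(raw.values)
    out = np.empty_like(logged)
    for cols in raw.experiment_groups().values():
        block = logged[:, cols]
        out[:, cols] = block - block.mean(axis=1, keepdims=True)
    return raw.copy_with(out)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every chip (column) onto the mean empirical distribution.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; within-column rank order is preserved.  Tied values in
    a column receive the mean of the target values at the positions the
    tie occupies, so the map is well defined and idempotent.
    """
    x = matrix.values
    if not np.all(np.isfinite(x)):
        raise ValueError("quantile normalization requires finite values")
    order = np.argsort(x, axis=0, kind="stable")
    target = np.sort(x, axis=0).mean(axis=1)

    out = np.empty_like(x)
    n = x.shape[0]
    for j in range(x.shape[1]):
        col_sorted = x[order[:, j], j]
        assigned = target.copy()
        # average target values over runs of tied input values
        start = 0
        for end in range(1, n + 1):
            if end == n or col_sorted[end] != col_sorted[start]:
                if end - start > 1:
                    assigned[start:end] = assigned[start:end].mean()
                start = end
        out[order[:, j], j] = assigned
    return matrix.copy_with(out)


def iqr_filter(
    matrix: ExpressionMatrix, threshold: float = 0.65
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes whose profile interquartile range is below ``threshold``.

    IQR is the 75th minus the 25th percentile of the gene's profile, with
    linear interpolation between order statistics.  Returns the filtered
    matrix and the list of removed gene ids.
    """
    if matrix.n_chips < 4:
        raise ValueError("IQR filtering needs at least 4 chips")
    q75, q25 = np.percentile(matrix.values, [75, 25], axis=1)
    iqr = q75 - q25
    keep_mask = iqr >= threshold
    removed = [g for g, k in zip(matrix.gene_ids, keep_mask) if not k]
    kept = [g for g, k in zip(matrix.gene_ids, keep_mask) if k]
    if not kept:
        raise ValueError(
            f"IQR filter at threshold {threshold} removed every gene"
        )
    return matrix.select_genes(kept), removed


def cluster_probesets(
    probe_map: ProbeMap, max_targets: int = 3
) -> tuple[list[str], dict[str, str]]:
    """Collapse gene-sharing probe-sets to one representative each.

    Probe-sets with no matching gene and probe-sets mapping to more than
    ``max_targets`` genes are discarded.  The survivors are clustered by
    the transitive closure of the "shares at least one gene" relation;
    within each cluster the probe-set mapping to the fewest genes is the
    representative (ties broken by lexicographically smallest id).

    Returns
    -------
    representatives
        Sorted list of representative probe-set ids (one per cluster).
    assignment
        Map from every surviving probe-set to its cluster representative.
    """
    if not probe_map.entries:
        raise ValueError("empty probe map")
    surviving = {
        p: genes
        for p, genes in probe_map.entries.items()
        if genes and len(genes) <= max_targets
    }

    # union-find over probe-sets, joined through shared genes
    parent = {p: p for p in surviving}

    def find(p: str) -> str:
        root = p
        while parent[root] != root:
            root = parent[root]
        while parent[p] != root:
            parent[p], p = root, parent[p]
        return root

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_gene: dict[str, str] = {}
    for p in sorted(surviving):
        for g in surviving[p]:
            if g in by_gene:
                union(by_gene[g], p)
            else:
                by_gene[g] = p

    clusters: dict[str, list[str]] = {}
    for p in surviving:
        clusters.setdefault(find(p), []).append(p)

    assignment: dict[str, str] = {}
    representatives: list[str] = []
    for members in clusters.values():
        rep = min(members, key=lambda p: (len(surviving[p]), p))
        representatives.append(rep)
        for p in members:
            assignment[p] = rep
    return sorted(representatives), assignment


def preprocess_pipeline(
    raw: ExpressionMatrix,
    qc_metrics: pd.DataFrame | None = None,
    probe_map: ProbeMap | None = None,
    iqr_threshold: float = 0.65,
    joint_quantiles: bool = True,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Run QC -> log-center -> quantile normalize -> probe clustering -> IQR.

    ``joint_quantiles=False`` runs quantile normalization separately within
    each experiment instead of jointly over all chips.

    Returns the processed matrix and a dict of per-stage removal counts.
    """
    counts: dict[str, int] = {
        "chips_in": raw.n_chips,
        "genes_in": raw.n_genes,
    }
    mat = raw
    if qc_metrics is not None:
        kept = qc_filter(qc_metrics, raw.experiment_of_chip)
        kept_in_matrix = [c for c in mat.chip_ids if c in set(kept)]
        counts["chips_removed_qc"] = mat.n_chips - len(kept_in_matrix)
        mat = mat.select_chips(kept_in_matrix)
    mat = log_center(mat)
    if joint_quantiles:
        mat = quantile_normalize(mat)
    else:
        pieces = mat.to_frame()
        for cols in mat.experiment_groups().values():
            sub = mat.select_chips([mat.chip_ids[j] for j in cols])
            pieces.loc[:, sub.chip_ids] = quantile_normalize(sub).values
        mat = mat.copy_with(pieces.values)
    if probe_map is not None:
        reps, _ = cluster_probesets(probe_map)
        keep = [g for g in mat.gene_ids if g in set(reps)]
        counts["genes_removed_probemap"] = mat.n_genes - len(keep)
        mat = mat.select_genes(keep)
    mat, removed = iqr_filter(mat, threshold=iqr_threshold)
    counts["genes_removed_iqr"] = len(removed)
    counts["chips_out"] = mat.n_chips
    counts["genes_out"] = mat.n_genes
    return mat, counts
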