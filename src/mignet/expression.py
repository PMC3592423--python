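"""Gene x chip expression matrices.

The central in-memory container is :class:`ExpressionMatrix`: an ``n x m``
array of real expression values for ``n`` genes measured on ``m`` chips
(arrays), together with gene identifiers, chip identifiers, and a label
assigning each chip to the experiment (batch) it came from.  Experiment
labels drive per-experiment normalization and quality-control grouping;
after preprocessing the values are dimensionless log-ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Expression values for ``n`` genes over ``m`` chips.

    Parameters
    ----------
    gene_ids
        Unique gene (or probe-set) identifiers, one per row.
    chip_ids
        Unique chip identifiers, one per column.
    experiment_of_chip
        Mapping from chip id to experiment label.  Every chip must have a
        label; chips sharing a label are treated as one experiment.
    values
        ``n x m`` float array, ``values[i, j]`` being the expression of gene
        ``i`` on chip ``j``.
    """

    gene_ids: list[str]
    chip_ids: list[str]
    experiment_of_chip: dict[str, str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n} matrix rows"
            )
        if len(self.chip_ids) != m:
            raise ValueError(
                f"{len(self.chip_ids)} chip ids for {m} matrix columns"
            )
        if len(set(self.gene_ids)) != n:
            dup = _first_duplicate(self.gene_ids)
            raise ValueError(f"duplicate gene id: {dup!r}")
        if len(set(self.chip_ids)) != m:
            dup = _first_duplicate(self.chip_ids)
            raise ValueError(f"duplicate chip id: {dup!r}")
        missing = [c for c in self.chip_ids if c not in self.experiment_of_chip]
        if missing:
            raise ValueError(f"chips without experiment label: {missing}")

    # -- basic geometry -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_chips(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def experiment_labels(self) -> list[str]:
        """Experiment label of each chip, in column order."""
        return [self.experiment_of_chip[c] for c in self.chip_ids]

    def experiment_groups(self) -> dict[str, np.ndarray]:
        """Column indices of each experiment, keyed by label."""
        groups: dict[str, list[int]] = {}
        for j, c in enumerate(self.chip_ids):
            groups.setdefault(self.experiment_of_chip[c], []).append(j)
        return {k: np.asarray(v, dtype=int) for k, v in groups.items()}

    # -- derived views --------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Values as a genes x chips DataFrame (a copy)."""
        return pd.DataFrame(
            self.values.copy(), index=self.gene_ids, columns=self.chip_ids
        )

    def select_genes(self, keep: list[str]) -> "ExpressionMatrix":
        """Row subset, preserving the order given in ``keep``."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in keep]
        return ExpressionMatrix(
            gene_ids=list(keep),
            chip_ids=list(self.chip_ids),
            experiment_of_chip=dict(self.experiment_of_chip),
            values=self.values[idx, :],
        )

    def select_chips(self, keep: list[str]) -> "ExpressionMatrix":
        """Column subset, preserving the order given in ``keep``."""
        pos = {c: j for j, c in enumerate(self.chip_ids)}
        idx = [pos[c] for c in keep]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            chip_ids=list(keep),
            experiment_of_chip={c: self.experiment_of_chip[c] for c in keep},
            values=self.values[:, idx],
        )

    def copy_with(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same ids and labels, new values of identical shape."""
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            chip_ids=list(self.chip_ids),
            experiment_of_chip=dict(self.experiment_of_chip),
            values=np.asarray(values, dtype=float),
        )


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""
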