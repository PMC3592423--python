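"""Text formats: expression TSV, QC tables, probe maps, edge lists, SIF.

All formats are plain tab-separated text:

* expression matrix — first row chip ids, second row experiment labels,
  then one row per gene (gene id followed by m values);
* QC metrics — named columns, one row per chip (column ``chip`` is the id);
* probe map — two columns: probe-set id, comma-separated gene ids (an
  empty second field marks a no-match probe-set);
* network — ``gene_a<TAB>gene_b<TAB>mi`` with ``gene_a < gene_b``
  lexicographically, preceded by ``# key=value`` header comments carrying
  run parameters; or SIF (``gene_a<TAB>mi<TAB>gene_b``) for Cytoscape;
* seed list — one gene id per line, ``#`` comments allowed.

Edge weights are serialized with 6 significant digits by default; pass
``full_precision=True`` for an exact binary round trip.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from .expression import ExpressionMatrix
from .preprocess import QC_COLUMNS, ProbeMap

__all__ = [
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_qc_metrics",
    "read_probe_map",
    "read_network",
    "write_network",
    "read_seed_list",
]


@dataclass
class RunConfig:
    """Parameters of a pipeline run, embedded in every output artifact."""

    iqr_threshold: float = 0.65
    bins: int = 10
    order: int = 3
    epsilon: float = 1e-4
    P_perm: int = 100_000
    dpi_tolerance: float = 0.0
    restart: float = 0.3
    shuffles: int = 102_400
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path) -> ExpressionMatrix:
    """Read an expression TSV; errors carry 1-based line numbers."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise ValueError(f"{path}: need chip row, experiment row and >= 1 gene row")
    chip_row = lines[0].split("\t")
    exp_row = lines[1].split("\t")
    chip_ids = chip_row[1:]
    labels = exp_row[1:]
    if len(labels) != len(chip_ids):
        raise ValueError(
            f"{path}:2: {len(labels)} experiment labels for {len(chip_ids)} chips"
        )
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for ln, line in enumerate(lines[2:], start=3):
        parts = line.split("\t")
        if len(parts) != len(chip_ids) + 1:
            raise ValueError(
                f"{path}:{ln}: expected {len(chip_ids) + 1} fields, got {len(parts)}"
            )
        gid = parts[0]
        if gid in seen:
            raise ValueError(f"{path}:{ln}: duplicate gene id {gid!r}")
        seen.add(gid)
        try:
            vals = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-numeric cell ({exc})") from None
        gene_ids.append(gid)
        rows.append(vals)
    return ExpressionMatrix(
        gene_ids=gene_ids,
        chip_ids=chip_ids,
        experiment_of_chip=dict(zip(chip_ids, labels)),
        values=np.array(rows, dtype=float),
    )


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write an expression TSV; numbers round-trip to full precision."""
    with open(path, "w") as fh:
        fh.write("chip\t" + "\t".join(matrix.chip_ids) + "\n")
        fh.write(
            "experiment\t" + "\t".join(matrix.experiment_labels()) + "\n"
        )
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# QC metrics and probe maps
# ---------------------------------------------------------------------------

def read_qc_metrics(path) -> pd.DataFrame:
    """QC metrics TSV -> DataFrame indexed by chip id."""
    df = pd.read_csv(path, sep="\t", dtype={"chip": str})
    if "chip" not in df.columns:
        raise ValueError(f"{path}: missing 'chip' column")
    missing = [c for c in QC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df["chip"].duplicated().any():
        dup = df["chip"][df["chip"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate chip id {dup!r}")
    return df.set_index("chip")


def read_probe_map(path) -> ProbeMap:
    """Two-column TSV (probe-set, comma-separated genes) -> ProbeMap."""
    entries: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = [parts[0], ""]
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns")
            probe, genes = parts
            if probe in entries:
                raise ValueError(f"{path}:{ln}: duplicate probe-set {probe!r}")
            entries[probe] = frozenset(
                g for g in genes.split(",") if g.strip()
            )
    return ProbeMap(entries=entries)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _canonical_edges(net: nx.Graph):
    edges = []
    for u, v, d in net.edges(data=True):
        a, b = (u, v) if str(u) < str(v) else (v, u)
        edges.append((str(a), str(b), float(d.get("weight", 1.0))))
    return sorted(edges)


def write_network(
    net: nx.Graph, path, fmt: str = "tsv", full_precision: bool = False
) -> None:
    """Write an MI network as a canonical edge list (TSV) or SIF.

    Header comment lines (``# key=value``) carry the graph-level metadata
    in ``net.graph`` (inference parameters, seeds, thresholds).
    """
    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown format {fmt!r}")
    num = "{:.17g}".format if full_precision else "{:.6g}".format
    with open(path, "w") as fh:
        for key in sorted(net.graph):
            fh.write(f"# {key}={net.graph[key]}\n")
        for a, b, w in _canonical_edges(net):
            if fmt == "tsv":
                fh.write(f"{a}\t{b}\t{num(w)}\n")
            else:
                fh.write(f"{a}\t{num(w)}\t{b}\n")


def read_network(path, fmt: str = "tsv") -> nx.Graph:
    """Read an edge list (TSV) or SIF network written by :func:`write_network`."""
    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown format {fmt!r}")
    net = nx.Graph()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    net.graph[key.strip()] = _parse_scalar(val.strip())
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns")
            if fmt == "tsv":
                a, b, w = parts
            else:
                a, w, b = parts
            try:
                weight = float(w)
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-numeric weight {w!r}") from None
            if a == b:
                raise ValueError(f"{path}:{ln}: self-loop on {a!r}")
            if weight < 0:
                raise ValueError(f"{path}:{ln}: negative weight {weight}")
            if net.has_edge(a, b):
                raise ValueError(f"{path}:{ln}: duplicate edge ({a}, {b})")
            net.add_edge(a, b, weight=weight)
    return net


def _parse_scalar(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text in ("True", "False"):
        return text == "True"
    if text == "None":
        return None
    return text


def read_seed_list(path) -> list[str]:
    """One gene id per line; blank lines and ``#`` comments skipped."""
    seeds: list[str] = []
    with open(path) as fh:
        for line in fh:
            body = line.split("#", 1)[0].strip()
            if body:
                seeds.append(body)
    if not seeds:
        raise ValueError(f"{path}: no seed genes found")
    return seeds
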