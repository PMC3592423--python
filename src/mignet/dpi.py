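"""Data processing inequality (DPI) pruning of candidate indirect edges.

If X1 -> X2 -> X3 form a Markov chain, MI(X1, X3) can exceed neither
MI(X1, X2) nor MI(X2, X3).  In an MI network this flags the weakest edge of
a triangle as a candidate indirect interaction: edge (i, k) is removed when
some common neighbour j satisfies ``MI(i,k) <= min(MI(i,j), MI(j,k))``.

Decisions are evaluated against the *input* network (mark-and-sweep), so
the result does not depend on edge iteration order.  The inequalities are
non-strict: in an exactly equal-weight triangle all three edges qualify and
all are removed at tolerance 0; a positive ``tolerance`` softens this by
requiring ``MI(i,k) <= (1 - tolerance) * min(...)``.
"""

from __future__ import annotations

import networkx as nx

__all__ = ["apply_dpi"]


def apply_dpi(net: nx.Graph, tolerance: float = 0.0) -> nx.Graph:
    """Remove candidate indirect edges; surviving weights are unchanged.

    Parameters
    ----------
    net
        Undirected MI network with edge attribute ``weight``.
    tolerance
        Fraction in ``[0, 1)``; an edge survives if its MI exceeds
        ``(1 - tolerance)`` times the smaller MI of every two-edge path
        closing a triangle over it.
    """
    if not 0.0 <= tolerance < 1.0:
        raise ValueError(f"tolerance must be in [0, 1), got {tolerance}")
    factor = 1.0 - tolerance
    weight = {frozenset(e): float(d["weight"]) for *e, d in net.edges(data=True)}

    to_remove = []
    for i, k in net.edges():
        w_ik = weight[frozenset((i, k))]
        common = set(net[i]) & set(net[k])
        for j in common:
            w_ij = weight[frozenset((i, j))]
            w_jk = weight[frozenset((j, k))]
            if w_ik <= factor * min(w_ij, w_jk):
                to_remove.append((i, k))
                break

    out = net.copy()
    out.remove_edges_from(to_remove)
    out.graph["dpi_tolerance"] = tolerance
    out.graph["dpi_removed"] = len(to_remove)
    return out
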