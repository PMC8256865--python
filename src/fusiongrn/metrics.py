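"""Centrality and in-silico perturbation analysis of a GRN.

Two node-importance measures are used. *Degree centrality* is the total
number of connections to and from a node (in-degree + out-degree).
*Stress centrality* (Shimbel stress) counts, over every ordered node pair
(s, t), how many shortest directed s -> t paths pass through a node's
interior — each co-optimal shortest path counts once, unlike betweenness
which splits the credit. High-stress nodes carry regulatory traffic; the
impact of removing a node is measured by how much stress redistributes
across the remaining genes.

The stress fold change on in-silico deletion of node x is, per gene g,

    FC(g) = log2( (stress_after(g) + c) / (stress_before(g) + c) )

with pseudocount c = 1 so that genes with zero stress remain comparable.
The base and pseudocount are exposed; a |FC| > 0.1 threshold classifies a
gene's response as a gain or loss of stress. A node's overall impact is
the mean of |FC| over all other genes.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .builder import GRN

__all__ = [
    "degree_centrality",
    "stress_centrality",
    "in_silico_delete",
    "DeletionImpact",
    "deletion_impact",
    "classify_fc",
    "rank_deletion_impacts",
    "centrality_report",
]


def _as_graph(grn: GRN | nx.DiGraph) -> nx.DiGraph:
    return grn.graph if isinstance(grn, GRN) else grn


def degree_centrality(grn: GRN | nx.DiGraph) -> dict[str, int]:
    """Total degree (in + out) per node."""
    g = _as_graph(grn)
    return {n: g.in_degree(n) + g.out_degree(n) for n in g.nodes}


def stress_centrality(grn: GRN | nx.DiGraph) -> dict[str, int]:
    """Shimbel stress: shortest-path counts through each node's interior.

    Brandes-style accumulation on unweighted directed graphs: one BFS per
    source s yields path counts sigma(s, v) and predecessor lists; the
    dependency of s on v for stress,

        delta_s(v) = sum over successors w of v on shortest paths of
                     sigma(s, v) * (1 + delta_s(w) / sigma(s, w)),

    sums to the number of shortest paths from s through v, so summing
    delta_s(v) over sources gives the stress of v. O(V * E) overall.
    """
    g = _as_graph(grn)
    stress = dict.fromkeys(g.nodes, 0)
    for s in g.nodes:
        dist = {s: 0}
        sigma = {s: 1}
        preds: dict[str, list[str]] = {s: []}
        order: list[str] = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in g.successors(v):
                if w not in dist:
                    dist[w] = dist[v] + 1
                    sigma[w] = 0
                    preds[w] = []
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = dict.fromkeys(order, 0.0)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] * (1.0 + delta[w] / sigma[w])
            if w != s:
                # delta_s(w) counts only paths continuing beyond w: terminal
                # pairs (s, w) enter via the "+1" credited at w's successors.
                stress[w] += int(round(delta[w]))
    return stress


def centrality_report(grn: GRN | nx.DiGraph) -> pd.DataFrame:
    """Degree and stress per node, sorted by stress then degree, descending."""
    deg = degree_centrality(grn)
    stress = stress_centrality(grn)
    frame = pd.DataFrame(
        {
            "gene_id": list(deg),
            "degree": [deg[n] for n in deg],
            "stress": [stress[n] for n in deg],
        }
    )
    return frame.sort_values(
        ["stress", "degree", "gene_id"], ascending=[False, False, True]
    ).reset_index(drop=True)


def in_silico_delete(grn: GRN, node: str) -> GRN:
    """Remove a node and its incident edges; no reachability re-pruning.

    Downstream nodes are deliberately retained even if the deletion
    disconnects them from the root, so that their change in stress is
    measurable. Deleting the root itself is allowed.
    """
    if node not in grn.graph:
        raise KeyError(f"node {node!r} not in GRN")
    g = grn.graph.copy()
    g.remove_node(node)
    return GRN(grn.root, g, ensure_root=False)


@dataclass
class DeletionImpact:
    """Per-gene stress fold change after deleting one node."""

    deleted_node: str
    per_gene_fc: dict[str, float]
    mean_abs_fc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": sorted(self.per_gene_fc),
                "stress_fc": [self.per_gene_fc[g] for g in sorted(self.per_gene_fc)],
            }
        )


def deletion_impact(
    before: GRN,
    deleted: str,
    pseudocount: float = 1.0,
    log_base: float = 2.0,
    stress_before: dict[str, int] | None = None,
) -> DeletionImpact:
    """Stress redistribution caused by deleting one node.

    ``stress_before`` may be supplied to amortize the pre-deletion stress
    computation across many deletions of the same graph.
    """
    if deleted not in before.graph:
        raise KeyError(f"node {deleted!r} not in GRN")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if stress_before is None:
        stress_before = stress_centrality(before)
    after = in_silico_delete(before, deleted)
    stress_after = stress_centrality(after)
    scale = math.log(log_base)
    per_gene_fc = {
        g: math.log((stress_after[g] + pseudocount) / (stress_before[g] + pseudocount))
        / scale
        for g in stress_before
        if g != deleted
    }
    mean_abs = (
        sum(abs(v) for v in per_gene_fc.values()) / len(per_gene_fc)
        if per_gene_fc
        else 0.0
    )
    return DeletionImpact(deleted, per_gene_fc, mean_abs)


def classify_fc(fc: float, threshold: float = 0.1) -> str:
    """Gain/loss/neutral call for one stress fold change (|FC| > threshold)."""
    if fc > threshold:
        return "positive"
    if fc < -threshold:
        return "negative"
    return "neutral"


def rank_deletion_impacts(
    grn: GRN,
    nodes: list[str] | None = None,
    pseudocount: float = 1.0,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Mean absolute stress FC for deleting each node, ranked descending.

    Ties are broken by node id so the ranking is deterministic and
    invariant to node relabelling.
    """
    base_stress = stress_centrality(grn)
    targets = sorted(nodes) if nodes is not None else sorted(grn.graph.nodes)
    rows = []
    for node in targets:
        imp = deletion_impact(
            grn, node, pseudocount=pseudocount, log_base=log_base,
            stress_before=base_stress,
        )
        rows.append((node, imp.mean_abs_fc))
    frame = pd.DataFrame(rows, columns=["gene_id", "mean_abs_stress_fc"])
    return frame.sort_values(
        ["mean_abs_stress_fc", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
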