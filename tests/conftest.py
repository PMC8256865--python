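"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

import fusiongrn as fg


# ---------------------------------------------------------------------------
# oracles (kept deliberately naive and independent of the implementation)
# ---------------------------------------------------------------------------

def stress_oracle(g: nx.DiGraph) -> dict:
    """Exhaustive all-pairs all-shortest-paths stress count."""
    stress = dict.fromkeys(g.nodes, 0)
    for s in g.nodes:
        for t in g.nodes:
            if s == t or not nx.has_path(g, s, t):
                continue
            for path in nx.all_shortest_paths(g, s, t):
                for v in path[1:-1]:
                    stress[v] += 1
    return stress


def degree_oracle(g: nx.DiGraph) -> dict:
    deg = dict.fromkeys(g.nodes, 0)
    for u, v in g.edges:
        deg[u] += 1
        deg[v] += 1
    return deg


def random_digraph(rng: np.random.Generator, n_max: int = 12, p: float = 0.3) -> nx.DiGraph:
    n = int(rng.integers(2, n_max + 1))
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < p:
                g.add_edge(u, v)
    return g


def overlap_oracle(a, b) -> list:
    """O(|a| * |b|) pairwise half-open overlap scan."""
    return [ia for ia in a if any(ia.overlaps(ib) for ib in b)]


def nearest_promoter_oracle(peak, promoters: fg.PromoterMap) -> str | None:
    best, best_d = None, None
    for gene, (chrom, tss, _strand) in promoters.entries.items():
        if chrom != peak.chrom:
            continue
        d = abs(peak.center - tss)
        if best_d is None or d < best_d or (d == best_d and gene < best):
            best, best_d = gene, d
    return best


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def clean_small_data() -> fg.SyntheticDataset:
    """Small preset, zero noise: exact recovery expected everywhere."""
    import dataclasses

    params = dataclasses.replace(
        fg.preset("small", seed=11), sign_flip_rate=0.0, dropout=0.0
    )
    return fg.generate_dataset(params)


@pytest.fixture(scope="session")
def clean_default_data() -> fg.SyntheticDataset:
    """Default preset, zero noise."""
    params = fg.SyntheticParams(sign_flip_rate=0.0, dropout=0.0, seed=29)
    return fg.generate_dataset(params)


@pytest.fixture()
def toy_grn() -> fg.GRN:
    """root -> a -> b -> c plus root -> d (a small rooted DAG)."""
    g = nx.DiGraph()
    g.add_edges_from(
        [("root", "a"), ("a", "b"), ("b", "c"), ("root", "d")]
    )
    return fg.GRN("root", g, ensure_root=False)
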