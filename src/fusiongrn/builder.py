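"""Root-centred gene regulatory network construction.

The GRN is built around a single central regulator (the "root" — here a
leukemic fusion protein, or an intermediate transcription factor) in four
steps:

1. *Regulatory scope*: genes differentially expressed after knockdown of
   the root (FDR < 0.05) bound which genes may enter the network at all.
2. *Direct layer*: root -> gene edges for every scope gene whose promoter
   is the nearest to a root ChIP-seq peak.
3. *Catalog expansion with pruning*: directed TF -> target interactions
   from an external catalog are admitted between scope genes, then the
   graph is restricted to nodes reachable from the root, so every
   retained interaction helps explain connectivity between the root and
   its downstream targets.
4. *Annotation*: nodes carry their knockdown response (logFC, FDR) and a
   CRISPR-screen essentiality category; edges carry provenance
   (direct | catalog) and a sign inferred from the regulator's knockdown.

Edge-sign convention: a target whose expression *falls* when its
regulator is knocked down (logFC < 0) is activated by it ("+"); a target
that rises is repressed ("-"). Edges whose regulator has no knockdown
table stay "unsigned".
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DEGTable",
    "TFCatalog",
    "EssentialityCalls",
    "GRN",
    "regulatory_scope",
    "build_direct_layer",
    "expand_and_prune",
    "infer_edge_sign",
    "apply_edge_signs",
    "classify_essentiality",
    "annotate_nodes",
    "build_grn",
]

DIRECT = "direct"
CATALOG = "catalog"
UNSIGNED = "unsigned"

NONESSENTIAL = "nonessential"
NONSPECIFIC = "nonspecific_essential"
LEUKEMIA_SPECIFIC = "leukemia_specific"


class DEGTable:
    """Per-gene knockdown response: (gene_id, logFC, FDR), gene ids unique."""

    def __init__(self, frame: pd.DataFrame):
        required = {"gene_id", "logFC", "FDR"}
        if not required.issubset(frame.columns):
            raise ValueError(f"DEG table needs columns {sorted(required)}")
        frame = frame[["gene_id", "logFC", "FDR"]].copy()
        frame["logFC"] = pd.to_numeric(frame["logFC"])
        frame["FDR"] = pd.to_numeric(frame["FDR"])
        if frame["gene_id"].duplicated().any():
            dupes = frame.loc[frame["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids in DEG table: {dupes[:5]}")
        if not np.isfinite(frame["logFC"]).all():
            raise ValueError("logFC must be finite")
        if ((frame["FDR"] < 0) | (frame["FDR"] > 1)).any():
            raise ValueError("FDR must lie in [0, 1]")
        self.frame = frame.set_index("gene_id", drop=False)

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, gene: str) -> bool:
        return gene in self.frame.index

    def logfc(self, gene: str) -> float:
        return float(self.frame.at[gene, "logFC"])

    def fdr(self, gene: str) -> float:
        return float(self.frame.at[gene, "FDR"])

    def is_deg(self, gene: str, fdr_threshold: float = 0.05) -> bool:
        return gene in self and self.fdr(gene) < fdr_threshold

    def scope(self, fdr_threshold: float = 0.05) -> set[str]:
        return regulatory_scope(self, fdr_threshold)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DEGTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"gene_id": str}))

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


class TFCatalog:
    """Directed TF -> target interaction edges (deduplicated, no self-edges)."""

    def __init__(self, edges: pd.DataFrame):
        if not {"source", "target"}.issubset(edges.columns):
            raise ValueError("catalog needs columns source, target")
        cols = ["source", "target"] + (
            ["evidence"] if "evidence" in edges.columns else []
        )
        edges = edges[cols].copy()
        self_loops = edges["source"] == edges["target"]
        if self_loops.any():
            warnings.warn(
                f"dropping {int(self_loops.sum())} self-edge(s) from TF catalog",
                stacklevel=2,
            )
            edges = edges[~self_loops]
        edges = edges.drop_duplicates(subset=["source", "target"])
        self.edges = edges.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.edges)

    def pairs(self) -> list[tuple[str, str]]:
        return list(
            zip(self.edges["source"].tolist(), self.edges["target"].tolist())
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TFCatalog":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


@dataclass
class EssentialityCalls:
    """Boolean gene x cell-line essentiality flags with a line partition.

    Cell lines are split into a leukemia panel (e.g. MOLM-13, MV4-11) and
    a non-leukemia panel (e.g. HT-29, HT-1080); the partition drives the
    three-way classification in :func:`classify_essentiality`.
    """

    flags: pd.DataFrame
    leukemia_lines: tuple[str, ...]
    non_leukemia_lines: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.leukemia_lines or not self.non_leukemia_lines:
            raise ValueError("both cell-line partitions must be non-empty")
        missing = (set(self.leukemia_lines) | set(self.non_leukemia_lines)) - set(
            self.flags.columns
        )
        if missing:
            raise ValueError(f"cell lines absent from flags: {sorted(missing)}")
        self.flags = self.flags.astype(bool)

    def __contains__(self, gene: str) -> bool:
        return gene in self.flags.index

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        leukemia_lines: Iterable[str],
        non_leukemia_lines: Iterable[str],
    ) -> "EssentialityCalls":
        """Read long-format calls: columns gene_id, cell_line, essential."""
        long = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "cell_line": str})
        wide = (
            long.pivot_table(
                index="gene_id", columns="cell_line", values="essential",
                aggfunc="max", fill_value=0,
            )
            .astype(bool)
        )
        return cls(wide, tuple(leukemia_lines), tuple(non_leukemia_lines))

    def write_tsv(self, path: str | Path) -> None:
        long = (
            self.flags.astype(int)
            .reset_index(names="gene_id")
            .melt(id_vars="gene_id", var_name="cell_line", value_name="essential")
            .sort_values(["gene_id", "cell_line"])
        )
        long.to_csv(path, sep="\t", index=False)


class GRN:
    """A simple directed graph rooted at a central regulator.

    Thin wrapper over :class:`networkx.DiGraph` that records which node is
    the root and enforces the structural invariants of the build:
    no self-loops, no multi-edges (by construction of DiGraph), and —
    after pruning — every node reachable from the root.
    """

    def __init__(
        self,
        root: str,
        graph: nx.DiGraph | None = None,
        ensure_root: bool = True,
    ):
        self.root = root
        self.graph = graph if graph is not None else nx.DiGraph()
        if ensure_root and root not in self.graph:
            self.graph.add_node(root, is_root=True)
        if root in self.graph:
            self.graph.nodes[root]["is_root"] = True
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"GRN must be simple: self-loops {loops[:3]}")

    # -- container protocol -------------------------------------------------
    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __repr__(self) -> str:
        return (
            f"GRN(root={self.root!r}, nodes={len(self)}, "
            f"edges={self.graph.number_of_edges()})"
        )

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def copy(self) -> "GRN":
        return GRN(self.root, self.graph.copy(), ensure_root=False)

    def is_reachable_from_root(self) -> bool:
        if self.root not in self.graph:
            return False
        reach = nx.descendants(self.graph, self.root) | {self.root}
        return reach == set(self.graph.nodes)

    # -- I/O ----------------------------------------------------------------
    def to_edge_table(self) -> pd.DataFrame:
        rows = [
            (
                u,
                v,
                d.get("provenance", CATALOG),
                d.get("sign", UNSIGNED),
            )
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["source", "target", "provenance", "sign"])

    def to_node_table(self) -> pd.DataFrame:
        rows = []
        for node in sorted(self.graph.nodes):
            d = self.graph.nodes[node]
            rows.append(
                (
                    node,
                    d.get("logfc", np.nan),
                    d.get("fdr", np.nan),
                    int(bool(d.get("bound_by_root", False))),
                    d.get("essentiality", ""),
                    int(bool(d.get("is_root", False))),
                )
            )
        return pd.DataFrame(
            rows,
            columns=["gene_id", "logFC", "FDR", "bound_by_root", "essentiality", "is_root"],
        )

    def write_edge_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#root={self.root}\n")
            self.to_edge_table().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_edge_tsv(cls, path: str | Path, root: str | None = None) -> "GRN":
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#root="):
                root = root or first.strip().split("=", 1)[1]
                frame = pd.read_csv(fh, sep="\t", dtype=str)
            else:
                fh.seek(0)
                frame = pd.read_csv(fh, sep="\t", dtype=str)
        if root is None:
            raise ValueError("root not recorded in file and not supplied")
        g = nx.DiGraph()
        g.add_node(root, is_root=True)
        for r in frame.itertuples(index=False):
            g.add_edge(
                r.source,
                r.target,
                provenance=getattr(r, "provenance", CATALOG),
                sign=getattr(r, "sign", UNSIGNED),
            )
        return cls(root, g, ensure_root=False)

    def write_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        for _n, d in g.nodes(data=True):  # GraphML cannot hold None values
            for k, v in list(d.items()):
                if v is None:
                    d[k] = ""
        nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# build steps
# ---------------------------------------------------------------------------

def regulatory_scope(degs: DEGTable, fdr_threshold: float = 0.05) -> set[str]:
    """Genes with FDR strictly below the threshold (the DEG set)."""
    frame = degs.frame
    return set(frame.loc[frame["FDR"] < fdr_threshold, "gene_id"])


def build_direct_layer(
    root: str, bound: Iterable[str], scope: set[str]
) -> GRN:
    """Direct edges root -> g for every root-bound gene inside the scope.

    The root's own gene is never given a self-loop even if bound.
    """
    g = nx.DiGraph()
    g.add_node(root, is_root=True)
    for gene in sorted(set(bound) & scope):
        if gene == root:
            continue
        g.add_node(gene, bound_by_root=True)
        g.add_edge(root, gene, provenance=DIRECT, sign=UNSIGNED)
    return GRN(root, g, ensure_root=False)


def expand_and_prune(direct: GRN, catalog: TFCatalog, scope: set[str]) -> GRN:
    """Admit catalog edges between scope genes, then prune to the root-reachable subgraph.

    Catalog interactions that do not explain connectivity between the root
    and downstream targets are thereby excluded: an edge survives only if
    its source is reachable from the root over the candidate edge set. The
    root participates only through its ChIP-derived direct edges, so
    catalog edges touching the root id are ignored. Where a catalog edge
    duplicates a direct edge, the direct provenance wins.
    """
    root = direct.root
    candidate = nx.DiGraph()
    candidate.add_node(root, is_root=True)
    for u, v, d in direct.graph.edges(data=True):
        candidate.add_edge(u, v, **d)
    for node, d in direct.graph.nodes(data=True):
        if node in candidate:
            candidate.nodes[node].update(d)
        else:
            candidate.add_node(node, **d)
    for u, v in catalog.pairs():
        if root in (u, v):
            continue
        if u in scope and v in scope and u != v:
            if not candidate.has_edge(u, v):
                candidate.add_edge(u, v, provenance=CATALOG, sign=UNSIGNED)
    keep = nx.descendants(candidate, root) | {root}
    pruned = candidate.subgraph(keep).copy()
    return GRN(root, pruned, ensure_root=False)


def infer_edge_sign(regulator_kd_logfc_of_target: float) -> str:
    """Sign of a regulator -> target edge from the target's KD response.

    logFC < 0 under regulator knockdown means the regulator activates the
    target ("+"); logFC > 0 means repression ("-"). Exactly zero logFC
    cannot occur for a differentially expressed gene and signals malformed
    input.
    """
    lfc = regulator_kd_logfc_of_target
    if lfc == 0:
        raise ValueError("logFC of 0 is not a valid DEG response")
    return "+" if lfc < 0 else "-"


def apply_edge_signs(
    grn: GRN,
    kd_tables: Mapping[str, DEGTable],
    fdr_threshold: float = 0.05,
) -> GRN:
    """Sign every edge whose regulator has a KD table and whose target is a DEG in it.

    ``kd_tables`` maps regulator node id (the root included) to that
    regulator's knockdown DEG table. Edges without usable evidence remain
    "unsigned". Modifies the GRN in place and returns it.
    """
    for u, v, d in grn.graph.edges(data=True):
        table = kd_tables.get(u)
        if table is not None and table.is_deg(v, fdr_threshold):
            d["sign"] = infer_edge_sign(table.logfc(v))
        else:
            d["sign"] = UNSIGNED
    return grn


def classify_essentiality(calls: EssentialityCalls, gene: str) -> str:
    """Three-way CRISPR essentiality category for one gene.

    Essential in any non-leukemia line -> nonspecific_essential (takes
    precedence); otherwise essential in any leukemia line ->
    leukemia_specific; otherwise nonessential. A gene absent from the
    screen is nonessential, with a warning.
    """
    if gene not in calls:
        warnings.warn(
            f"{gene} absent from essentiality calls; treating as nonessential",
            stacklevel=2,
        )
        return NONESSENTIAL
    row = calls.flags.loc[gene]
    if row[list(calls.non_leukemia_lines)].any():
        return NONSPECIFIC
    if row[list(calls.leukemia_lines)].any():
        return LEUKEMIA_SPECIFIC
    return NONESSENTIAL


def annotate_nodes(
    grn: GRN, degs: DEGTable, calls: EssentialityCalls | None = None
) -> GRN:
    """Attach KD response and essentiality category to every node.

    Every non-root node must be present in the DEG table (the scope
    invariant); a missing node is an error, not a silent NaN.
    """
    for node in grn.graph.nodes:
        d = grn.graph.nodes[node]
        if node == grn.root:
            d["is_root"] = True
        else:
            if node not in degs:
                raise ValueError(
                    f"node {node} missing from DEG table; scope invariant violated"
                )
            d["logfc"] = degs.logfc(node)
            d["fdr"] = degs.fdr(node)
        if calls is not None and node != grn.root:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d["essentiality"] = classify_essentiality(calls, node)
    return grn


def build_grn(
    root: str,
    degs: DEGTable,
    bound: Iterable[str],
    catalog: TFCatalog,
    fdr_threshold: float = 0.05,
    kd_tables: Mapping[str, DEGTable] | None = None,
    calls: EssentialityCalls | None = None,
    scope: set[str] | None = None,
) -> GRN:
    """Run the full four-step construction around one root regulator.

    ``scope`` may be supplied to restrict the regulatory scope further
    (e.g. to the genes expressed in one patient sample); it is
    intersected with the DEG-derived scope.
    """
    full_scope = regulatory_scope(degs, fdr_threshold)
    if scope is not None:
        full_scope &= scope
    direct = build_direct_layer(root, bound, full_scope)
    grn = expand_and_prune(direct, catalog, full_scope)
    tables = {root: degs}
    if kd_tables:
        tables.update(kd_tables)
    apply_edge_signs(grn, tables, fdr_threshold)
    annotate_nodes(grn, degs, calls)
    return grn
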