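"""Signed three-node motif analysis over a pair of root-centred GRNs.

Two GRNs — one rooted at the fusion protein (regulator A) and one rooted
at an intermediate transcription factor that A binds and activates
(regulator B) — are merged into one graph. For every downstream target T:

* A -> T and B -> T together with the fixed activating A -> B edge form a
  *feed-forward loop* (FFL);
* B -> T without A -> T forms a *cascade* (A reaches T only through B);
* A -> T alone is not a motif over both regulators and is excluded.

Signs come from each regulator's own knockdown: a target falling on
knockdown (logFC < 0) is activated by that regulator. With A -> B fixed
as activating, the four sign quadrants of (logFC under A KD, logFC under
B KD) map onto four FFL subtypes:

    (-, -) -> C1   both activate the target (coherent)
    (+, +) -> C3   both repress it (direct - , indirect + . - = -; coherent)
    (-, +) -> I1   A activates, B represses (incoherent)
    (+, -) -> I3   A represses, B activates (incoherent)

Cascades are *coherent* when the two knockdown responses share a sign and
*incoherent* otherwise; the C1/C3 pair is exactly the same-sign
half-plane, so the two rules agree. The quadrant -> label map follows
standard FFL nomenclature with the A -> B edge positive and can be
overridden.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .builder import DEGTable, GRN, infer_edge_sign

__all__ = [
    "IntegratedGRN",
    "MotifRecord",
    "CoherenceSummary",
    "integrate_grns",
    "enumerate_motifs",
    "classify_ffl",
    "classify_cascade",
    "classify_motifs",
    "summarize_coherence",
    "motif_table",
]

FFL = "FFL"
CASCADE = "cascade"

COHERENT_FFL_SUBTYPES = ("C1", "C3")
INCOHERENT_FFL_SUBTYPES = ("I1", "I3")

#: quadrant of (sign of logFC under A KD, sign under B KD) -> FFL subtype
DEFAULT_FFL_QUADRANT_MAP: dict[tuple[int, int], str] = {
    (-1, -1): "C1",
    (1, 1): "C3",
    (-1, 1): "I1",
    (1, -1): "I3",
}


@dataclass
class IntegratedGRN:
    """Edge-union of two GRNs with per-edge supporting-regulator tags."""

    root_a: str
    root_b: str
    graph: nx.DiGraph

    def supports(self, u: str, v: str) -> tuple[str, ...]:
        return self.graph.edges[u, v]["support"]


@dataclass
class MotifRecord:
    """One classified (or yet-unclassified) three-node motif target."""

    kind: str  # FFL | cascade
    target: str
    subtype: str | None = None
    logfc_a_kd: float | None = None
    logfc_b_kd: float | None = None
    sign_a: str | None = None  # A -> target edge sign; absent for cascades
    sign_b: str | None = None


def integrate_grns(grn_a: GRN, grn_b: GRN) -> IntegratedGRN:
    """Union the two GRNs, asserting the A -> B frame edge.

    B's root must be a node of A's GRN with a direct A -> B edge,
    otherwise the motif frame (A regulates B, both regulate targets) is
    undefined.
    """
    a, b = grn_a.root, grn_b.root
    if b not in grn_a.graph:
        raise ValueError(f"intermediate root {b!r} is not a node of the {a!r} GRN")
    if not grn_a.graph.has_edge(a, b):
        raise ValueError(f"no {a} -> {b} edge; motif frame undefined")
    union = nx.DiGraph()
    for grn in (grn_a, grn_b):
        for node, d in grn.graph.nodes(data=True):
            if node in union:
                union.nodes[node].update(
                    {k: v for k, v in d.items() if k != "is_root"}
                )
            else:
                union.add_node(node, **{k: v for k, v in d.items() if k != "is_root"})
        for u, v, d in grn.graph.edges(data=True):
            if union.has_edge(u, v):
                tags = set(union.edges[u, v]["support"]) | {grn.root}
                union.edges[u, v]["support"] = tuple(sorted(tags))
            else:
                union.add_edge(u, v, support=(grn.root,), **{
                    k: val for k, val in d.items() if k != "support"
                })
    union.nodes[a]["is_root"] = True
    return IntegratedGRN(a, b, union)


def enumerate_motifs(g: IntegratedGRN) -> list[MotifRecord]:
    """Scan every downstream target for the FFL / cascade pattern.

    Targets regulated by both A and B yield an FFL record; by B only, a
    cascade record; by A only, nothing. Output is sorted by target id.
    """
    a, b = g.root_a, g.root_b
    targets = (set(g.graph.successors(a)) | set(g.graph.successors(b))) - {a, b}
    records = []
    for t in sorted(targets):
        a_reg = g.graph.has_edge(a, t)
        b_reg = g.graph.has_edge(b, t)
        if a_reg and b_reg:
            records.append(MotifRecord(FFL, t))
        elif b_reg:
            records.append(MotifRecord(CASCADE, t))
    return records


def classify_ffl(
    logfc_a_kd: float,
    logfc_b_kd: float,
    quadrant_map: Mapping[tuple[int, int], str] = DEFAULT_FFL_QUADRANT_MAP,
) -> str:
    """FFL subtype from the target's logFC under each regulator's knockdown."""
    if logfc_a_kd == 0 or logfc_b_kd == 0:
        raise ValueError("zero logFC is not a valid DEG response")
    key = (1 if logfc_a_kd > 0 else -1, 1 if logfc_b_kd > 0 else -1)
    return quadrant_map[key]


def classify_cascade(logfc_a_kd: float, logfc_b_kd: float) -> str:
    """Cascade coherence: same knockdown-response sign -> coherent."""
    if logfc_a_kd == 0 or logfc_b_kd == 0:
        raise ValueError("zero logFC is not a valid DEG response")
    return "coherent" if (logfc_a_kd > 0) == (logfc_b_kd > 0) else "incoherent"


def classify_motifs(
    records: list[MotifRecord],
    kd_a: DEGTable,
    kd_b: DEGTable,
    fdr_threshold: float = 0.05,
    quadrant_map: Mapping[tuple[int, int], str] = DEFAULT_FFL_QUADRANT_MAP,
) -> tuple[list[MotifRecord], dict[str, int]]:
    """Fill in signs and subtypes for every target that is a DEG in both knockdowns.

    Targets differentially expressed in only one knockdown carry no
    usable two-regulator sign evidence; they are dropped from the
    classified list and tallied in the returned diagnostics bucket.
    """
    classified: list[MotifRecord] = []
    diagnostics = {"deg_in_a_only": 0, "deg_in_b_only": 0, "deg_in_neither": 0}
    for rec in records:
        in_a = kd_a.is_deg(rec.target, fdr_threshold)
        in_b = kd_b.is_deg(rec.target, fdr_threshold)
        if not (in_a and in_b):
            if in_a:
                diagnostics["deg_in_a_only"] += 1
            elif in_b:
                diagnostics["deg_in_b_only"] += 1
            else:
                diagnostics["deg_in_neither"] += 1
            continue
        lf_a = kd_a.logfc(rec.target)
        lf_b = kd_b.logfc(rec.target)
        out = MotifRecord(
            rec.kind,
            rec.target,
            logfc_a_kd=lf_a,
            logfc_b_kd=lf_b,
            sign_b=infer_edge_sign(lf_b),
        )
        if rec.kind == FFL:
            out.subtype = classify_ffl(lf_a, lf_b, quadrant_map)
            out.sign_a = infer_edge_sign(lf_a)
        else:
            out.subtype = classify_cascade(lf_a, lf_b)
        classified.append(out)
    return classified, diagnostics


@dataclass
class CoherenceSummary:
    """Subtype counts and coherence percentages (one decimal place).

    Percentages are ``None`` (undefined), not zero, when the motif class
    is empty.
    """

    counts: dict[str, int] = field(default_factory=dict)
    ffl_total: int = 0
    cascade_total: int = 0
    ffl_coherent_pct: float | None = None
    cascade_coherent_pct: float | None = None
    cascade_incoherent_pct: float | None = None

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "ffl_total": self.ffl_total,
            "cascade_total": self.cascade_total,
            "ffl_coherent_pct": self.ffl_coherent_pct,
            "cascade_coherent_pct": self.cascade_coherent_pct,
            "cascade_incoherent_pct": self.cascade_incoherent_pct,
        }


def summarize_coherence(records: list[MotifRecord]) -> CoherenceSummary:
    """Per-subtype counts and coherent fractions over classified motifs."""
    counts: dict[str, int] = {
        "C1": 0, "C3": 0, "I1": 0, "I3": 0, "coherent": 0, "incoherent": 0,
    }
    for rec in records:
        if rec.subtype is None:
            raise ValueError(f"unclassified motif record for {rec.target}")
        counts[rec.subtype] += 1
    ffl_total = sum(counts[s] for s in ("C1", "C3", "I1", "I3"))
    cascade_total = counts["coherent"] + counts["incoherent"]
    summary = CoherenceSummary(counts, ffl_total, cascade_total)
    if ffl_total:
        coherent = sum(counts[s] for s in COHERENT_FFL_SUBTYPES)
        summary.ffl_coherent_pct = round(100.0 * coherent / ffl_total, 1)
    if cascade_total:
        summary.cascade_coherent_pct = round(
            100.0 * counts["coherent"] / cascade_total, 1
        )
        summary.cascade_incoherent_pct = round(
            100.0 * counts["incoherent"] / cascade_total, 1
        )
    return summary


def motif_table(records: list[MotifRecord]) -> pd.DataFrame:
    """Classified motifs as a tidy table, sorted by target."""
    rows = [
        (r.target, r.kind, r.subtype, r.logfc_a_kd, r.logfc_b_kd, r.sign_a, r.sign_b)
        for r in sorted(records, key=lambda r: r.target)
    ]
    return pd.DataFrame(
        rows,
        columns=["target", "kind", "subtype", "logfc_a", "logfc_b", "sign_a", "sign_b"],
    )
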