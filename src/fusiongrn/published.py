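"""Recompute headline network summaries from deposited study files.

When the study's exported network tables and knockdown DEG tables are
available locally (they are not shipped with the package), this module
recomputes the quantities reported for the real system: total node count
of the fusion-root GRN, the number of very-high-degree hubs, and the
coherent/incoherent motif fractions from the integrated two-regulator
network.

Expected inputs are plain TSV exports:

* ``grn_a`` / ``grn_b`` — edge lists with a ``#root=NAME`` first line and
  columns ``source, target[, provenance, sign]`` (the format written by
  :meth:`fusiongrn.builder.GRN.write_edge_tsv`);
* ``kd_a`` / ``kd_b`` — DEG tables with columns ``gene_id, logFC, FDR``.
"""

from __future__ import annotations

from pathlib import Path

from .builder import DEGTable, GRN
from .metrics import degree_centrality
from .motifs import classify_motifs, enumerate_motifs, integrate_grns

__all__ = ["summarize_published_network"]


def summarize_published_network(
    grn_a_path: str | Path,
    grn_b_path: str | Path,
    kd_a_path: str | Path,
    kd_b_path: str | Path,
    degree_cutoff: int = 500,
    fdr_threshold: float = 0.05,
) -> dict:
    """Node count, hub count and motif coherence fractions from exported files.

    Returns a dict with ``node_count``, ``high_degree_node_count`` (total
    degree strictly greater than ``degree_cutoff``), ``ffl_coherent_pct``,
    ``cascade_coherent_pct`` and ``cascade_incoherent_pct``.
    """
    grn_a = GRN.read_edge_tsv(grn_a_path)
    grn_b = GRN.read_edge_tsv(grn_b_path)
    kd_a = DEGTable.read_tsv(kd_a_path)
    kd_b = DEGTable.read_tsv(kd_b_path)

    degree = degree_centrality(grn_a)
    integrated = integrate_grns(grn_a, grn_b)
    records = enumerate_motifs(integrated)
    classified, diagnostics = classify_motifs(records, kd_a, kd_b, fdr_threshold)

    from .motifs import summarize_coherence

    summary = summarize_coherence(classified)
    return {
        "node_count": len(grn_a),
        "high_degree_node_count": sum(1 for d in degree.values() if d > degree_cutoff),
        "ffl_coherent_pct": summary.ffl_coherent_pct,
        "cascade_coherent_pct": summary.cascade_coherent_pct,
        "cascade_incoherent_pct": summary.cascade_incoherent_pct,
        "diagnostics": diagnostics,
    }
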