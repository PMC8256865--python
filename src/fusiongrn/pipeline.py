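"""End-to-end assembly of the analysis from raw inputs.

Convenience layer tying the stage modules together: peak processing ->
bound genes -> GRN construction for the fusion root and the intermediate
TF (the latter with the enhancer filter), motif integration and
classification, and the patient-subnetwork workflow. Each helper is a
thin composition of the stage functions; tests exercise the stages
directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .builder import GRN, build_grn
from .genomics import (
    PeakSet,
    annotate_nearest_promoter,
    bound_genes,
    define_enhancers,
    intersect_peaks,
)
from .motifs import (
    CoherenceSummary,
    MotifRecord,
    classify_motifs,
    enumerate_motifs,
    integrate_grns,
    summarize_coherence,
)
from .simulate import SyntheticDataset
from .subnetworks import (
    ClusterAssignment,
    GRNBuildInputs,
    activity_and_conservation,
    cluster_activity,
    derive_subnetworks,
    expressed_gene_sets,
)

__all__ = [
    "root_bound_genes",
    "intermediate_bound_genes",
    "build_root_grn",
    "build_intermediate_grn",
    "MotifAnalysis",
    "run_motif_analysis",
    "SubnetworkAnalysis",
    "run_subnetwork_analysis",
]


def root_bound_genes(data: SyntheticDataset) -> set[str]:
    """Root-bound genes: split-epitope peak intersection, nearest promoter."""
    root_peaks = intersect_peaks(data.peaks["root_n"], data.peaks["root_c"])
    return bound_genes(annotate_nearest_promoter(root_peaks, data.promoters))


def intermediate_bound_genes(
    data: SyntheticDataset, enhancer_filter: bool = True
) -> set[str]:
    """Intermediate-TF bound genes, by default restricted to enhancer peaks."""
    peaks: PeakSet = data.peaks["intermediate"]
    if enhancer_filter:
        enhancers = define_enhancers(data.peaks["h3k27ac"], data.peaks["h3k4me1"])
        peaks = intersect_peaks(peaks, enhancers)
    return bound_genes(annotate_nearest_promoter(peaks, data.promoters))


def build_root_grn(data: SyntheticDataset, annotate: bool = True) -> GRN:
    """The GRN rooted at the fusion protein."""
    return build_grn(
        data.truth.root,
        data.kd_a,
        root_bound_genes(data),
        data.catalog,
        fdr_threshold=data.truth.params.fdr_threshold,
        kd_tables={data.truth.intermediate: data.kd_b},
        calls=data.essentiality if annotate else None,
    )


def build_intermediate_grn(
    data: SyntheticDataset, enhancer_filter: bool = True, annotate: bool = True
) -> GRN:
    """The GRN rooted at the intermediate TF (enhancer-filtered binding)."""
    return build_grn(
        data.truth.intermediate,
        data.kd_b,
        intermediate_bound_genes(data, enhancer_filter),
        data.catalog,
        fdr_threshold=data.truth.params.fdr_threshold,
        calls=data.essentiality if annotate else None,
    )


@dataclass
class MotifAnalysis:
    grn_a: GRN
    grn_b: GRN
    records: list[MotifRecord]
    diagnostics: dict[str, int]
    summary: CoherenceSummary


def run_motif_analysis(data: SyntheticDataset) -> MotifAnalysis:
    """Build both GRNs, integrate, enumerate and classify signed motifs."""
    grn_a = build_root_grn(data, annotate=False)
    grn_b = build_intermediate_grn(data, annotate=False)
    integrated = integrate_grns(grn_a, grn_b)
    records = enumerate_motifs(integrated)
    classified, diagnostics = classify_motifs(
        records, data.kd_a, data.kd_b, data.truth.params.fdr_threshold
    )
    return MotifAnalysis(
        grn_a, grn_b, classified, diagnostics, summarize_coherence(classified)
    )


@dataclass
class SubnetworkAnalysis:
    full_grn: GRN
    activity: pd.DataFrame
    conservation: pd.DataFrame
    clusters: ClusterAssignment


def run_subnetwork_analysis(
    data: SyntheticDataset, k: int = 5, seed: int = 0
) -> SubnetworkAnalysis:
    """Per-sample subnetworks -> activity matrix -> conservation -> k-means."""
    full = build_root_grn(data, annotate=False)
    inputs = GRNBuildInputs(
        data.truth.root,
        data.kd_a,
        root_bound_genes(data),
        data.catalog,
        data.truth.params.fdr_threshold,
    )
    expressed = expressed_gene_sets(data.expression)
    subnets = derive_subnetworks(inputs, expressed)
    activity, conservation = activity_and_conservation(
        subnets, full, data.expression.datasets
    )
    clusters = cluster_activity(activity, k=k, seed=seed)
    return SubnetworkAnalysis(full, activity, conservation, clusters)
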