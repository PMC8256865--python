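"""Patient-cohort subnetwork activity analysis.

Each patient sample induces a *subnetwork* of the full GRN: the build is
re-run with the regulatory scope restricted to the genes expressed in
that sample, so a gene drops out either because it is not expressed or
because losing an upstream TF disconnects it from the root. "Expressed"
means above the grand mean of log2(TPM + 1), computed separately for each
cohort (data set) so cohorts with different depth/composition are
thresholded on their own scale.

Node presence across subnetworks forms a binary activity matrix
(GRN nodes x samples); per-cohort *conservation* is the percentage of a
cohort's samples in which a node is active. Activity patterns are
clustered with k-means (Euclidean, on the raw binary rows); a 2-D UMAP
embedding is available for visualization only and plays no role in the
clustering.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .builder import DEGTable, GRN, TFCatalog, build_grn, regulatory_scope

__all__ = [
    "ExpressionMatrix",
    "GRNBuildInputs",
    "ClusterAssignment",
    "expressed_gene_sets",
    "derive_subnetworks",
    "activity_and_conservation",
    "cluster_activity",
    "umap_embedding",
]


@dataclass
class ExpressionMatrix:
    """TPM matrix (genes x samples) with a cohort label per sample."""

    tpm: pd.DataFrame
    datasets: pd.Series  # sample -> cohort label

    def __post_init__(self) -> None:
        if (self.tpm.values < 0).any():
            raise ValueError("TPM values must be non-negative")
        if self.tpm.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        missing = set(self.tpm.columns) - set(self.datasets.index)
        if missing:
            raise ValueError(f"samples without a dataset label: {sorted(missing)[:5]}")
        self.datasets = self.datasets.loc[list(self.tpm.columns)]

    @property
    def samples(self) -> list[str]:
        return list(self.tpm.columns)

    @classmethod
    def read_tsv(cls, expr_path: str | Path, meta_path: str | Path) -> "ExpressionMatrix":
        """Read gene x sample TPM TSV plus a sample metadata TSV.

        The metadata file needs columns ``sample`` and ``dataset``.
        """
        tpm = pd.read_csv(expr_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        if not {"sample", "dataset"}.issubset(meta.columns):
            raise ValueError("metadata TSV needs columns sample, dataset")
        datasets = meta.set_index("sample")["dataset"]
        return cls(tpm, datasets)

    def write_tsv(self, expr_path: str | Path, meta_path: str | Path) -> None:
        self.tpm.to_csv(expr_path, sep="\t", index_label="gene_id")
        meta = pd.DataFrame(
            {"sample": self.datasets.index, "dataset": self.datasets.values}
        )
        meta.to_csv(meta_path, sep="\t", index=False)


@dataclass
class GRNBuildInputs:
    """Everything needed to (re-)run the GRN construction."""

    root: str
    degs: DEGTable
    bound: set[str]
    catalog: TFCatalog
    fdr_threshold: float = 0.05


@dataclass
class ClusterAssignment:
    """k-means labels (1..k) over activity-matrix rows."""

    labels: pd.Series  # node -> cluster label
    k: int
    seed: int


def expressed_gene_sets(
    expr: ExpressionMatrix,
    pseudocount: float = 1.0,
    per_sample: bool = False,
) -> dict[str, set[str]]:
    """Genes above the mean log2(TPM + pseudocount), per sample.

    By default the threshold for a sample is the grand mean over *all*
    gene x sample entries of its cohort (strict inequality); with
    ``per_sample=True`` each sample is thresholded on its own column
    mean instead.
    """
    log2 = np.log2(expr.tpm + pseudocount)
    out: dict[str, set[str]] = {}
    for dataset, samples in expr.datasets.groupby(expr.datasets).groups.items():
        cols = list(samples)
        if not cols:
            raise ValueError(f"dataset {dataset!r} has no samples")
        block = log2[cols]
        grand_mean = float(block.values.mean())
        for s in cols:
            threshold = float(block[s].mean()) if per_sample else grand_mean
            col = block[s]
            out[s] = set(col.index[col > threshold])
    return out


def derive_subnetworks(
    inputs: GRNBuildInputs, expressed: Mapping[str, set[str]]
) -> dict[str, GRN]:
    """Re-run the GRN build per sample with scope restricted to expressed genes."""
    return {
        sample: build_grn(
            inputs.root,
            inputs.degs,
            inputs.bound,
            inputs.catalog,
            fdr_threshold=inputs.fdr_threshold,
            scope=genes if isinstance(genes, set) else set(genes),
        )
        for sample, genes in expressed.items()
    }


def activity_and_conservation(
    subnets: Mapping[str, GRN],
    full: GRN,
    groups: pd.Series | Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary activity matrix and per-cohort conservation percentages.

    Rows are the full GRN's nodes (the root included — it is present in
    every subnetwork by construction), columns the cohort samples.
    Conservation(g, D) = 100 * (samples of cohort D containing g) / |D|.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    nodes = sorted(full.graph.nodes)
    samples = sorted(subnets)
    extra = [s for s in samples if s not in groups.index]
    if extra:
        raise ValueError(f"samples without a dataset label: {extra[:5]}")
    for s, sub in subnets.items():
        stray = set(sub.graph.nodes) - set(nodes)
        if stray:
            raise ValueError(
                f"subnetwork {s} contains nodes outside the full GRN: {sorted(stray)[:5]}"
            )
    data = {
        s: [1 if n in subnets[s].graph else 0 for n in nodes] for s in samples
    }
    activity = pd.DataFrame(data, index=nodes, dtype=np.int8)
    conservation = {}
    for dataset in sorted(groups.loc[samples].unique()):
        cols = [s for s in samples if groups[s] == dataset]
        conservation[dataset] = 100.0 * activity[cols].mean(axis=1)
    return activity, pd.DataFrame(conservation)


def cluster_activity(
    activity: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterAssignment:
    """k-means over binary activity rows; labels are 1..k, deterministic per seed.

    Clustering runs on the raw binary matrix, never on an embedding.
    Nodes inactive in every sample are clustered along with the rest (they
    gravitate into an "inactive" cluster of their own). ``k`` may not
    exceed the number of nodes active in at least one sample.
    """
    from sklearn.cluster import KMeans

    clusterable = int((activity.sum(axis=1) > 0).sum())
    if k > clusterable:
        raise ValueError(
            f"k={k} exceeds the {clusterable} nodes active in at least one sample"
        )
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(activity.to_numpy(dtype=float))
    # relabel clusters by descending size, ties by first row, for stability
    order = pd.Series(raw).value_counts(sort=True).index
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[r] for r in raw], index=activity.index, name="cluster")
    return ClusterAssignment(labels, k, seed)


def umap_embedding(activity: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """2-D UMAP of activity rows for visualization only."""
    import umap

    reducer = umap.UMAP(n_components=2, random_state=seed)
    coords = reducer.fit_transform(activity.to_numpy(dtype=float))
    return pd.DataFrame(coords, index=activity.index, columns=["umap1", "umap2"])
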