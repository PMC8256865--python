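"""Synthetic regulome generator with planted, recoverable ground truth.

Every input the pipeline consumes can be generated here: a promoter map
on synthetic chromosomes, ChIP peak sets (a split-epitope pair for the
fusion root, an intermediate-TF assay, and H3K27ac/H3K4me1 marks for the
enhancer rule), a TF-interaction catalog, knockdown DEG tables for both
regulators, a three-cohort patient expression matrix, and per-cell-line
CRISPR essentiality calls.

The generator plants a two-regulator architecture mirroring the biology
the pipeline targets: fusion root A binds and activates an intermediate
TF B; shared targets of A and B form feed-forward loops of known subtype;
B-only targets form signed cascades; a small chain of secondary TFs below
B adds network depth; decoy peaks and decoy catalog edges that violate
the scope or reachability rules give every filtering stage nontrivial
work. All planted structure is recorded in a :class:`SyntheticTruth` so
tests can check exact recovery at zero noise and calibrated recovery
under sign-flip noise and expression dropout.

Default sizes and noise levels are chosen to resemble the study system
the pipeline emulates: motif subtype counts give a coherent-FFL fraction
of 71.6% and a coherent-cascade fraction of 72.9%; knockdown effect
sizes are ~1.5 log2 units; the normal-marrow cohort is small (3 samples)
relative to the two leukemia cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .builder import DEGTable, EssentialityCalls, TFCatalog
from .genomics import GenomicInterval, PeakSet, PromoterMap
from .subnetworks import ExpressionMatrix

__all__ = [
    "SyntheticParams",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_regulome",
    "generate_kd_tables",
    "generate_expression_cohort",
    "generate_essentiality",
    "generate_dataset",
    "write_dataset",
    "preset",
]

FFL_SIGN_PATTERNS: dict[str, tuple[int, int]] = {
    "C1": (-1, -1),
    "C3": (1, 1),
    "I1": (-1, 1),
    "I3": (1, -1),
}

#: program -> active cohorts (emulating constitutive, leukemia-restricted,
#: cohort-specific, and silent activity patterns)
ACTIVITY_PROGRAMS: dict[int, frozenset[str]] = {
    1: frozenset({"ALL", "AML", "FBM"}),
    2: frozenset({"ALL", "AML"}),
    3: frozenset({"ALL"}),
    4: frozenset({"AML"}),
    5: frozenset(),
}

LEUKEMIA_LINES = ("MOLM-13", "MV4-11")
NON_LEUKEMIA_LINES = ("HT-29", "HT-1080")

ESSENTIALITY_FRACTIONS = {
    "nonessential": 0.80,
    "nonspecific_essential": 0.12,
    "leukemia_specific": 0.08,
}


@dataclass(frozen=True)
class SyntheticParams:
    """Generation parameters; the defaults define the simulated study system."""

    root: str = "KMT2A-AFF1"
    intermediate: str = "RUNX1"
    n_ffl: dict = field(
        default_factory=lambda: {"C1": 70, "C3": 46, "I1": 27, "I3": 19}
    )
    n_cascade: dict = field(
        default_factory=lambda: {"coherent": 99, "incoherent": 38}
    )
    n_chain_tfs: int = 3
    n_chain_targets_per_tf: int = 15
    n_direct_only: int = 80
    n_orphan_degs: int = 30
    n_background: int = 150
    decoy_peak_rate: float = 0.10
    n_decoy_catalog_edges: int = 40
    sign_flip_rate: float = 0.05
    effect_size: float = 1.5
    dropout: float = 0.05
    n_samples: dict = field(
        default_factory=lambda: {"ALL": 30, "AML": 40, "FBM": 3}
    )
    program_proportions: tuple = (0.25, 0.25, 0.15, 0.15, 0.20)
    fdr_threshold: float = 0.05
    seed: int = 0

    def total_targets(self) -> int:
        return (
            sum(self.n_ffl.values())
            + sum(self.n_cascade.values())
            + self.n_chain_tfs * self.n_chain_targets_per_tf
            + self.n_direct_only
        )

    def validate(self) -> None:
        if not 0 <= self.sign_flip_rate < 0.5:
            raise ValueError("sign_flip_rate must lie in [0, 0.5)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if any(v < 0 for v in self.n_ffl.values()) or any(
            v < 0 for v in self.n_cascade.values()
        ):
            raise ValueError("motif counts must be non-negative")
        if min(self.n_samples.values()) < 1:
            raise ValueError("every cohort needs at least one sample")
        if abs(sum(self.program_proportions) - 1.0) > 1e-9:
            raise ValueError("program proportions must sum to 1")


def preset(name: str, seed: int = 0) -> SyntheticParams:
    """Named parameter presets: small (fast tests), default, large."""
    if name == "default":
        return SyntheticParams(seed=seed)
    if name == "small":
        return SyntheticParams(
            n_ffl={"C1": 8, "C3": 5, "I1": 4, "I3": 3},
            n_cascade={"coherent": 12, "incoherent": 5},
            n_chain_tfs=2,
            n_chain_targets_per_tf=4,
            n_direct_only=10,
            n_orphan_degs=5,
            n_background=40,
            n_decoy_catalog_edges=10,
            n_samples={"ALL": 6, "AML": 8, "FBM": 3},
            seed=seed,
        )
    if name == "large":
        return SyntheticParams(
            n_ffl={"C1": 140, "C3": 92, "I1": 54, "I3": 38},
            n_cascade={"coherent": 198, "incoherent": 76},
            n_chain_tfs=6,
            n_chain_targets_per_tf=15,
            n_direct_only=160,
            n_orphan_degs=60,
            n_background=300,
            n_decoy_catalog_edges=80,
            n_samples={"ALL": 60, "AML": 80, "FBM": 6},
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")


@dataclass
class SyntheticTruth:
    """Everything planted by the generator, for recovery checks."""

    params: SyntheticParams
    root: str
    intermediate: str
    chain_tfs: list[str]
    ffl_targets: dict[str, list[str]]
    cascade_targets: dict[str, list[str]]
    chain_targets: dict[str, list[str]]
    direct_only: list[str]
    orphan_degs: list[str]
    background: list[str]
    sign_patterns: dict[str, tuple[int | None, int | None]]
    planted_edges_a: set[tuple[str, str]]
    planted_edges_b: set[tuple[str, str]]
    planted_edge_signs: dict[tuple[str, str], str]
    planted_motifs: dict[str, tuple[str, str]]
    bound_genes: dict[str, set[str]]
    cluster_labels: dict[str, int]
    essentiality: dict[str, str]

    @property
    def a_nodes(self) -> set[str]:
        """Node set of the planted root-A GRN (root included)."""
        nodes = {self.root, self.intermediate} | set(self.chain_tfs)
        for genes in self.ffl_targets.values():
            nodes |= set(genes)
        for genes in self.cascade_targets.values():
            nodes |= set(genes)
        for genes in self.chain_targets.values():
            nodes |= set(genes)
        nodes |= set(self.direct_only)
        return nodes

    @property
    def all_genes(self) -> list[str]:
        """Every gene in the simulated genome (the root fusion is not a gene)."""
        genes = sorted(self.a_nodes - {self.root})
        return genes + sorted(self.orphan_degs) + sorted(self.background)

    def planted_coherent_ffl_fraction(self) -> float:
        coherent = len(self.ffl_targets["C1"]) + len(self.ffl_targets["C3"])
        total = sum(len(v) for v in self.ffl_targets.values())
        return coherent / total

    # -- JSON round trip ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": asdict(self.params),
            "root": self.root,
            "intermediate": self.intermediate,
            "chain_tfs": self.chain_tfs,
            "ffl_targets": self.ffl_targets,
            "cascade_targets": self.cascade_targets,
            "chain_targets": self.chain_targets,
            "direct_only": self.direct_only,
            "orphan_degs": self.orphan_degs,
            "background": self.background,
            "sign_patterns": {g: list(v) for g, v in self.sign_patterns.items()},
            "planted_edges_a": sorted(list(e) for e in self.planted_edges_a),
            "planted_edges_b": sorted(list(e) for e in self.planted_edges_b),
            "planted_edge_signs": {
                f"{u}\t{v}": s for (u, v), s in self.planted_edge_signs.items()
            },
            "planted_motifs": {g: list(v) for g, v in self.planted_motifs.items()},
            "bound_genes": {k: sorted(v) for k, v in self.bound_genes.items()},
            "cluster_labels": self.cluster_labels,
            "essentiality": self.essentiality,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            params=SyntheticParams(**payload["params"]),
            root=payload["root"],
            intermediate=payload["intermediate"],
            chain_tfs=payload["chain_tfs"],
            ffl_targets=payload["ffl_targets"],
            cascade_targets=payload["cascade_targets"],
            chain_targets=payload["chain_targets"],
            direct_only=payload["direct_only"],
            orphan_degs=payload["orphan_degs"],
            background=payload["background"],
            sign_patterns={
                g: tuple(v) for g, v in payload["sign_patterns"].items()
            },
            planted_edges_a={tuple(e) for e in payload["planted_edges_a"]},
            planted_edges_b={tuple(e) for e in payload["planted_edges_b"]},
            planted_edge_signs={
                tuple(k.split("\t")): s
                for k, s in payload["planted_edge_signs"].items()
            },
            planted_motifs={
                g: tuple(v) for g, v in payload["planted_motifs"].items()
            },
            bound_genes={k: set(v) for k, v in payload["bound_genes"].items()},
            cluster_labels={g: int(c) for g, c in payload["cluster_labels"].items()},
            essentiality=payload["essentiality"],
        )


# ---------------------------------------------------------------------------
# regulome
# ---------------------------------------------------------------------------

_GENES_PER_CHROM = 400
_GENE_SPACING = 10_000  # bp between TSSs; >> peak jitter, so nearest-promoter
_PEAK_HALF_WIDTH = 200  # annotation recovers the intended gene exactly


def _gene_locus(index: int) -> tuple[str, int]:
    chrom = f"chr{index // _GENES_PER_CHROM + 1}"
    tss = _GENE_SPACING + (index % _GENES_PER_CHROM) * _GENE_SPACING
    return chrom, tss


def _peak_near(
    rng: np.random.Generator, chrom: str, tss: int, name: str, jitter: int = 300
) -> GenomicInterval:
    center = tss + int(rng.integers(-jitter, jitter + 1))
    return GenomicInterval(
        chrom, max(0, center - _PEAK_HALF_WIDTH), center + _PEAK_HALF_WIDTH, name
    )


def generate_regulome(
    params: SyntheticParams,
) -> tuple[PromoterMap, dict[str, PeakSet], TFCatalog, SyntheticTruth]:
    """Generate promoters, peak sets, TF catalog, and the planted truth.

    Peak-set keys: ``root_n`` and ``root_c`` (the split-epitope pair whose
    1-bp intersection defines root binding), ``intermediate`` (TF B ChIP),
    ``h3k27ac`` and ``h3k4me1`` (the enhancer-defining marks). Decoy peaks
    are placed near background genes at ``decoy_peak_rate`` per assay and
    are constructed to fail either the intersection, the enhancer, or the
    scope rule.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    b = params.intermediate
    chain_tfs = [f"TF{i + 1:02d}" for i in range(params.n_chain_tfs)]

    counter = 0

    def take(n: int) -> list[str]:
        nonlocal counter
        genes = [f"G{counter + i + 1:04d}" for i in range(n)]
        counter += n
        return genes

    ffl_targets = {sub: take(n) for sub, n in sorted(params.n_ffl.items())}
    cascade_targets = {sub: take(n) for sub, n in sorted(params.n_cascade.items())}
    chain_targets = {tf: take(params.n_chain_targets_per_tf) for tf in chain_tfs}
    direct_only = take(params.n_direct_only)
    orphan_degs = [f"ORPH{i + 1:03d}" for i in range(params.n_orphan_degs)]
    background = [f"BG{i + 1:04d}" for i in range(params.n_background)]

    all_genes = (
        [b]
        + chain_tfs
        + [g for genes in ffl_targets.values() for g in genes]
        + [g for genes in cascade_targets.values() for g in genes]
        + [g for genes in chain_targets.values() for g in genes]
        + direct_only
        + orphan_degs
        + background
    )

    # promoters on synthetic chromosomes, alternating strand
    loci = {}
    entries = {}
    for i, gene in enumerate(all_genes):
        chrom, tss = _gene_locus(i)
        loci[gene] = (chrom, tss)
        entries[gene] = (chrom, tss, "+" if i % 2 == 0 else "-")
    promoters = PromoterMap(entries)

    ffl_all = [g for genes in ffl_targets.values() for g in genes]
    cascade_all = [g for genes in cascade_targets.values() for g in genes]

    # root binding: overlapping split-epitope peak pair at B, FFL targets,
    # and direct-only targets
    root_bound = [b] + ffl_all + direct_only
    root_n_peaks, root_c_peaks = [], []
    for gene in root_bound:
        chrom, tss = loci[gene]
        base = _peak_near(rng, chrom, tss, f"{gene}_rootN")
        shift = int(rng.integers(-150, 151))
        root_n_peaks.append(base)
        root_c_peaks.append(
            GenomicInterval(chrom, base.start + shift, base.end + shift, f"{gene}_rootC")
        )

    # intermediate-TF binding with enhancer support (H3K27ac ∩ H3K4me1)
    b_bound = ffl_all + cascade_all + chain_tfs
    b_peaks, k27_peaks, k4_peaks = [], [], []
    for gene in b_bound:
        chrom, tss = loci[gene]
        pk = _peak_near(rng, chrom, tss, f"{gene}_B")
        b_peaks.append(pk)
        k27_peaks.append(
            GenomicInterval(chrom, pk.start - 100, pk.end + 100, f"{gene}_k27")
        )
        k4_peaks.append(
            GenomicInterval(chrom, pk.start - 50, pk.end + 50, f"{gene}_k4")
        )

    # decoys: split-epitope singletons (fail the 1-bp intersection),
    # enhancer-free B peaks (fail the enhancer rule), and enhancer-backed
    # peaks at unexpressed background genes (fail the scope rule)
    n_decoy = int(round(params.decoy_peak_rate * len(background)))
    decoy_pool = rng.permutation(background)
    for gene in decoy_pool[:n_decoy]:
        chrom, tss = loci[gene]
        root_n_peaks.append(_peak_near(rng, chrom, tss, f"{gene}_decoyN"))
    for gene in decoy_pool[n_decoy : 2 * n_decoy]:
        chrom, tss = loci[gene]
        root_c_peaks.append(_peak_near(rng, chrom, tss, f"{gene}_decoyC"))
    for gene in decoy_pool[2 * n_decoy : 3 * n_decoy]:
        chrom, tss = loci[gene]
        b_peaks.append(_peak_near(rng, chrom, tss, f"{gene}_decoyB"))
    for gene in decoy_pool[3 * n_decoy : 4 * n_decoy]:
        chrom, tss = loci[gene]
        pk = _peak_near(rng, chrom, tss, f"{gene}_decoyB2")
        b_peaks.append(pk)
        k27_peaks.append(
            GenomicInterval(chrom, pk.start - 100, pk.end + 100, f"{gene}_decoyK27")
        )
        k4_peaks.append(
            GenomicInterval(chrom, pk.start - 50, pk.end + 50, f"{gene}_decoyK4")
        )

    peaks = {
        "root_n": PeakSet(root_n_peaks, label=f"{params.root}-N"),
        "root_c": PeakSet(root_c_peaks, label=f"{params.root}-C"),
        "intermediate": PeakSet(b_peaks, label=b),
        "h3k27ac": PeakSet(k27_peaks, label="H3K27ac"),
        "h3k4me1": PeakSet(k4_peaks, label="H3K4me1"),
    }

    # TF-interaction catalog: planted edges plus reachability-violating decoys
    catalog_rows: list[tuple[str, str, str]] = []
    for t in ffl_all + cascade_all + chain_tfs:
        catalog_rows.append((b, t, "planted"))
    for tf, genes in chain_targets.items():
        for t in genes:
            catalog_rows.append((tf, t, "planted"))
    scope_like = ffl_all + cascade_all + direct_only
    half = params.n_decoy_catalog_edges // 2
    for i in range(params.n_decoy_catalog_edges):
        if i < half and orphan_degs:  # in-scope source, unreachable from root
            src = orphan_degs[i % len(orphan_degs)]
            dst = scope_like[int(rng.integers(len(scope_like)))]
        else:  # out-of-scope endpoints entirely
            src = background[int(rng.integers(len(background)))]
            dst = background[int(rng.integers(len(background)))]
            if src == dst:
                continue
        catalog_rows.append((src, dst, "decoy"))
    catalog = TFCatalog(
        pd.DataFrame(catalog_rows, columns=["source", "target", "evidence"])
    )

    # planted sign patterns (sA, sB) in knockdown-logFC sign space
    sign_patterns: dict[str, tuple[int | None, int | None]] = {b: (-1, None)}
    for sub, genes in ffl_targets.items():
        for g in genes:
            sign_patterns[g] = FFL_SIGN_PATTERNS[sub]
    for sub, genes in cascade_targets.items():
        for g in genes:
            s = int(rng.choice([-1, 1]))
            sign_patterns[g] = (s, s) if sub == "coherent" else (s, -s)
    for tf in chain_tfs:  # secondary TFs are coherent cascade intermediates
        s = int(rng.choice([-1, 1]))
        sign_patterns[tf] = (s, s)
    for genes in chain_targets.values():
        for g in genes:
            sign_patterns[g] = (int(rng.choice([-1, 1])), int(rng.choice([-1, 1])))
    for g in direct_only:
        sign_patterns[g] = (int(rng.choice([-1, 1])), None)
    for g in orphan_degs:
        sign_patterns[g] = (int(rng.choice([-1, 1])), None)

    # planted edges
    edges_a: set[tuple[str, str]] = {(params.root, b)}
    edges_a |= {(params.root, t) for t in ffl_all + direct_only}
    edges_a |= {(b, t) for t in ffl_all + cascade_all + chain_tfs}
    for tf, genes in chain_targets.items():
        edges_a |= {(tf, t) for t in genes}
    edges_b: set[tuple[str, str]] = {(b, t) for t in ffl_all + cascade_all + chain_tfs}
    for tf, genes in chain_targets.items():
        edges_b |= {(tf, t) for t in genes}

    def _sign(s: int | None) -> str:
        if s is None:
            return "unsigned"
        return "+" if s < 0 else "-"

    edge_signs: dict[tuple[str, str], str] = {}
    for u, v in edges_a | edges_b:
        if u == params.root:
            edge_signs[(u, v)] = _sign(sign_patterns[v][0])
        elif u == b:
            edge_signs[(u, v)] = _sign(sign_patterns[v][1])
        else:  # chain-TF edges have no KD table: unsigned
            edge_signs[(u, v)] = "unsigned"

    planted_motifs: dict[str, tuple[str, str]] = {}
    for sub, genes in ffl_targets.items():
        for g in genes:
            planted_motifs[g] = ("FFL", sub)
    for sub, genes in cascade_targets.items():
        for g in genes:
            planted_motifs[g] = ("cascade", sub)
    for tf in chain_tfs:
        planted_motifs[tf] = ("cascade", "coherent")

    # activity programs: regulators constitutive, targets mixed
    cluster_labels: dict[str, int] = {params.root: 1, b: 1}
    for tf in chain_tfs:
        cluster_labels[tf] = 1
    assignable = ffl_all + cascade_all + direct_only + [
        g for genes in chain_targets.values() for g in genes
    ]
    programs = rng.choice(
        np.arange(1, 6), size=len(assignable), p=params.program_proportions
    )
    for gene, prog in zip(assignable, programs):
        cluster_labels[gene] = int(prog)

    # essentiality categories; the intermediate TF is planted as the
    # leukemia-specific hub
    categories = list(ESSENTIALITY_FRACTIONS)
    probs = list(ESSENTIALITY_FRACTIONS.values())
    essentiality: dict[str, str] = {b: "leukemia_specific"}
    for gene in all_genes:
        if gene == b:
            continue
        essentiality[gene] = str(rng.choice(categories, p=probs))

    truth = SyntheticTruth(
        params=params,
        root=params.root,
        intermediate=b,
        chain_tfs=chain_tfs,
        ffl_targets=ffl_targets,
        cascade_targets=cascade_targets,
        chain_targets=chain_targets,
        direct_only=direct_only,
        orphan_degs=orphan_degs,
        background=background,
        sign_patterns=sign_patterns,
        planted_edges_a=edges_a,
        planted_edges_b=edges_b,
        planted_edge_signs=edge_signs,
        planted_motifs=planted_motifs,
        bound_genes={
            "root": set(root_bound),
            "intermediate": set(b_bound),
        },
        cluster_labels=cluster_labels,
        essentiality=essentiality,
    )
    return promoters, peaks, catalog, truth


# ---------------------------------------------------------------------------
# knockdown tables
# ---------------------------------------------------------------------------

def generate_kd_tables(
    truth: SyntheticTruth,
    sign_flip_rate: float | None = None,
    effect_size: float | None = None,
    seed: int | None = None,
) -> tuple[DEGTable, DEGTable]:
    """DEG tables for the root (A) and intermediate (B) knockdowns.

    Planted DEGs get |logFC| ~ |Normal(mu, mu/3)| with the planted sign
    (flipped independently with probability ``sign_flip_rate``) and
    FDR ~ Uniform(0, 0.049); everything else gets FDR >= 0.05 and a small
    centred logFC. Flips perturb the observed tables only — the truth
    keeps the planted signs.
    """
    params = truth.params
    eps = params.sign_flip_rate if sign_flip_rate is None else sign_flip_rate
    mu = params.effect_size if effect_size is None else effect_size
    if not 0 <= eps < 0.5:
        raise ValueError("sign_flip_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)

    def magnitude() -> float:
        return max(abs(rng.normal(mu, mu / 3.0)), 1e-3)

    def flip(s: int) -> int:
        return -s if rng.random() < eps else s

    a_deg_rows, b_deg_rows = [], []
    for gene in truth.all_genes:
        s_a, s_b = truth.sign_patterns.get(gene, (None, None))
        if s_a is not None:
            a_deg_rows.append(
                (gene, flip(s_a) * magnitude(), rng.uniform(0.0, 0.049))
            )
        else:
            a_deg_rows.append((gene, rng.normal(0.0, 0.2), rng.uniform(0.05, 1.0)))
        if gene == truth.intermediate:
            # the knocked-down gene itself falls in its own KD
            b_deg_rows.append((gene, -magnitude(), rng.uniform(0.0, 0.049)))
        elif s_b is not None:
            b_deg_rows.append(
                (gene, flip(s_b) * magnitude(), rng.uniform(0.0, 0.049))
            )
        else:
            b_deg_rows.append((gene, rng.normal(0.0, 0.2), rng.uniform(0.05, 1.0)))

    cols = ["gene_id", "logFC", "FDR"]
    return (
        DEGTable(pd.DataFrame(a_deg_rows, columns=cols)),
        DEGTable(pd.DataFrame(b_deg_rows, columns=cols)),
    )


# ---------------------------------------------------------------------------
# expression cohort
# ---------------------------------------------------------------------------

_ACTIVE_LOG2 = (7.0, 0.5)  # log2(TPM+1) mean, sd for expressed entries
_INACTIVE_LOG2 = (0.5, 0.3)


def generate_expression_cohort(
    truth: SyntheticTruth,
    n_samples: dict | None = None,
    dropout: float | None = None,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Three-cohort TPM matrix realizing the planted activity programs.

    Active gene x sample entries are drawn from a high-TPM log-normal,
    inactive ones from a near-zero log-normal; the two modes are far
    enough apart that the per-cohort mean-log2 threshold separates them.
    ``dropout`` silences an active entry with the given probability;
    the two regulator tiers (intermediate TF and chain TFs) are exempt so
    that target activity reflects the target's own expression rather than
    upstream disconnection.
    """
    params = truth.params
    n_samples = dict(params.n_samples if n_samples is None else n_samples)
    p_drop = params.dropout if dropout is None else dropout
    rng = np.random.default_rng(params.seed + 2 if seed is None else seed)

    if min(n_samples.values()) < 1:
        raise ValueError("every cohort needs at least one sample")

    genes = truth.all_genes
    no_dropout = {truth.intermediate} | set(truth.chain_tfs)

    # background genes get a fixed constitutive-on/off split (not part of
    # the planted cluster structure)
    bg_profiles = {
        g: (ACTIVITY_PROGRAMS[1] if i % 2 == 0 else ACTIVITY_PROGRAMS[5])
        for i, g in enumerate(sorted(truth.orphan_degs) + sorted(truth.background))
    }

    sample_ids, sample_sets = [], []
    for dataset in sorted(n_samples):
        for i in range(n_samples[dataset]):
            sample_ids.append(f"{dataset}_{i + 1:03d}")
            sample_sets.append(dataset)

    values = np.zeros((len(genes), len(sample_ids)))
    for gi, gene in enumerate(genes):
        if gene in truth.cluster_labels:
            active_in = ACTIVITY_PROGRAMS[truth.cluster_labels[gene]]
        else:
            active_in = bg_profiles[gene]
        for si, dataset in enumerate(sample_sets):
            active = dataset in active_in
            if active and gene not in no_dropout and rng.random() < p_drop:
                active = False
            mean, sd = _ACTIVE_LOG2 if active else _INACTIVE_LOG2
            log2_val = max(rng.normal(mean, sd), 0.0)
            values[gi, si] = max(2.0 ** log2_val - 1.0, 0.0)

    tpm = pd.DataFrame(values, index=genes, columns=sample_ids)
    datasets = pd.Series(sample_sets, index=sample_ids, name="dataset")
    return ExpressionMatrix(tpm, datasets)


# ---------------------------------------------------------------------------
# essentiality calls
# ---------------------------------------------------------------------------

def generate_essentiality(
    truth: SyntheticTruth, seed: int | None = None
) -> EssentialityCalls:
    """Per-cell-line essentiality flags consistent with the planted categories."""
    rng = np.random.default_rng(truth.params.seed + 3 if seed is None else seed)
    genes = truth.all_genes
    flags = pd.DataFrame(
        False, index=genes, columns=list(NON_LEUKEMIA_LINES + LEUKEMIA_LINES)
    )
    for gene in genes:
        category = truth.essentiality[gene]
        if category == "nonspecific_essential":
            hits = rng.random(len(NON_LEUKEMIA_LINES)) < 0.7
            if not hits.any():
                hits[int(rng.integers(len(NON_LEUKEMIA_LINES)))] = True
            flags.loc[gene, list(NON_LEUKEMIA_LINES)] = hits
            flags.loc[gene, list(LEUKEMIA_LINES)] = (
                rng.random(len(LEUKEMIA_LINES)) < 0.3
            )
        elif category == "leukemia_specific":
            hits = rng.random(len(LEUKEMIA_LINES)) < 0.7
            if not hits.any():
                hits[int(rng.integers(len(LEUKEMIA_LINES)))] = True
            flags.loc[gene, list(LEUKEMIA_LINES)] = hits
    return EssentialityCalls(flags, LEUKEMIA_LINES, NON_LEUKEMIA_LINES)


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """One fully generated input bundle plus its planted truth."""

    promoters: PromoterMap
    peaks: dict[str, PeakSet]
    catalog: TFCatalog
    truth: SyntheticTruth
    kd_a: DEGTable
    kd_b: DEGTable
    expression: ExpressionMatrix
    essentiality: EssentialityCalls


def generate_dataset(params: SyntheticParams) -> SyntheticDataset:
    """Generate every pipeline input from one parameter set and seed."""
    seeds = [
        int(s % (2**31)) for s in np.random.SeedSequence(params.seed).generate_state(4)
    ]
    promoters, peaks, catalog, truth = generate_regulome(
        replace(params, seed=seeds[0])
    )
    truth.params = params  # record the user-facing seed, not the derived one
    kd_a, kd_b = generate_kd_tables(truth, seed=seeds[1])
    expression = generate_expression_cohort(truth, seed=seeds[2])
    calls = generate_essentiality(truth, seed=seeds[3])
    return SyntheticDataset(
        promoters, peaks, catalog, truth, kd_a, kd_b, expression, calls
    )


def write_dataset(data: SyntheticDataset, outdir: str | Path) -> None:
    """Write the bundle in the exact file dialects the pipeline reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    data.promoters.write_tsv(out / "promoters.tsv")
    for key, ps in data.peaks.items():
        ps.write_bed(out / f"peaks_{key}.bed")
    data.catalog.write_tsv(out / "tf_catalog.tsv")
    data.kd_a.write_tsv(out / "kd_root.tsv")
    data.kd_b.write_tsv(out / "kd_intermediate.tsv")
    data.expression.write_tsv(out / "expression_tpm.tsv", out / "samples.tsv")
    data.essentiality.write_tsv(out / "essentiality.tsv")
    data.truth.to_json(out / "truth.json")
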