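"""Genomic interval containers and ChIP-seq peak-level operations.

This module provides the binding side of the GRN workflow: BED-style peak
sets, 1-bp-overlap intersection (used both to define fusion-protein peaks
as the overlap of the N- and C-terminal pulldowns and to define enhancers
as H3K27ac peaks overlapping H3K4me1), nearest-promoter annotation of
peaks, and the two ChIP signal normalizations (exogenous spike-in scaling
and tags-per-10-million library scaling).

Coordinates are BED-style: 0-based, half-open ``[start, end)``. Two
intervals overlap when their half-open intersection is non-empty, i.e. by
at least 1 bp.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "PromoterMap",
    "SpikeInCounts",
    "intersect_peaks",
    "annotate_nearest_promoter",
    "bound_genes",
    "define_enhancers",
    "spikein_scale_factor",
    "tags_per_ten_million",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    ``name`` and ``signal`` (a non-negative tag/read count) are optional
    annotations and do not participate in ordering or equality.
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    signal: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )
        if self.signal is not None and self.signal < 0:
            raise ValueError("signal must be non-negative")

    @property
    def center(self) -> int:
        """Integer midpoint, floor((start + end) / 2)."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class PeakSet:
    """An immutable, sorted, deduplicated collection of peaks for one assay.

    Duplicate ``(chrom, start, end)`` triples are collapsed (first
    occurrence wins); intervals are kept sorted by ``(chrom, start, end)``.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = ""):
        seen: dict[tuple[str, int, int], GenomicInterval] = {}
        for iv in intervals:
            seen.setdefault((iv.chrom, iv.start, iv.end), iv)
        self.intervals: tuple[GenomicInterval, ...] = tuple(
            sorted(seen.values())
        )
        self.label = label

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"PeakSet(label={self.label!r}, n={len(self)})"

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    @classmethod
    def read_bed(cls, path: str | Path, label: str = "") -> "PeakSet":
        """Read a BED3/BED6 file (tab-separated, no header).

        Column 5 (score), when present, is stored as the peak signal;
        strand is ignored for peaks.
        """
        frame = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype={0: str}
        )
        if frame.shape[1] < 3:
            raise ValueError(f"{path}: BED requires >= 3 columns")
        intervals = []
        for row in frame.itertuples(index=False):
            name = str(row[3]) if len(row) > 3 and row[3] != "." else None
            signal = float(row[4]) if len(row) > 4 else None
            intervals.append(
                GenomicInterval(str(row[0]), int(row[1]), int(row[2]), name, signal)
            )
        return cls(intervals, label=label or Path(path).stem)

    def write_bed(self, path: str | Path) -> None:
        has_meta = any(iv.name is not None or iv.signal is not None for iv in self)
        with open(path, "w") as fh:
            for iv in self.intervals:
                if has_meta:
                    score = 0.0 if iv.signal is None else iv.signal
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                        f"{iv.name or '.'}\t{score:g}\t+\n"
                    )
                else:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


class PromoterMap:
    """Mapping gene_id -> (chrom, tss, strand) with unique gene ids.

    TSS positions are 0-based. Strand is stored but not used for distance
    (nearest-promoter annotation is unsigned midpoint-to-TSS).
    """

    def __init__(self, entries: Mapping[str, tuple[str, int, str]]):
        for gene, (chrom, tss, strand) in entries.items():
            if not gene or not chrom:
                raise ValueError("gene_id and chrom must be non-empty")
            if tss < 0:
                raise ValueError(f"tss must be >= 0 for {gene}")
            if strand not in ("+", "-"):
                raise ValueError(f"strand must be + or - for {gene}")
        self.entries: dict[str, tuple[str, int, str]] = dict(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def __getitem__(self, gene: str) -> tuple[str, int, str]:
        return self.entries[gene]

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (tss array, gene-id array), unordered."""
        chroms: dict[str, list[tuple[int, str]]] = {}
        for gene, (chrom, tss, _strand) in self.entries.items():
            chroms.setdefault(chrom, []).append((tss, gene))
        return {
            c: (
                np.array([t for t, _ in pairs], dtype=np.int64),
                np.array([g for _, g in pairs], dtype=object),
            )
            for c, pairs in chroms.items()
        }

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PromoterMap":
        frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        required = {"gene_id", "chrom", "tss", "strand"}
        if not required.issubset(frame.columns):
            raise ValueError(f"{path}: promoter TSV needs columns {sorted(required)}")
        if frame["gene_id"].duplicated().any():
            raise ValueError(f"{path}: duplicate gene ids in promoter map")
        return cls(
            {
                r.gene_id: (r.chrom, int(r.tss), r.strand)
                for r in frame.itertuples(index=False)
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            [(g, c, t, s) for g, (c, t, s) in sorted(self.entries.items())],
            columns=["gene_id", "chrom", "tss", "strand"],
        )
        frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SpikeInCounts:
    """Read counts for one input/IP pair mapped to host and spike-in genomes."""

    hg_reads_input: float
    spike_reads_input: float
    hg_reads_ip: float
    spike_reads_ip: float

    def __post_init__(self) -> None:
        for name in (
            "hg_reads_input",
            "spike_reads_input",
            "hg_reads_ip",
            "spike_reads_ip",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(
                    f"{name} must be > 0 (zero spike-in counts make "
                    "reference normalization unusable)"
                )


def intersect_peaks(a: PeakSet, b: PeakSet) -> PeakSet:
    """Peaks of ``a`` overlapping any peak of ``b`` by at least 1 bp.

    The intervals of ``a`` are returned with their original coordinates —
    the operation identifies which ``a`` peaks are supported by ``b``, it
    does not clip to the overlap fragment. Hence it is deliberately
    asymmetric in its arguments.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, ivs in b.by_chrom().items():
        trees[chrom] = IntervalTree.from_tuples((iv.start, iv.end) for iv in ivs)
    kept = [
        iv
        for iv in a
        if iv.chrom in trees and trees[iv.chrom].overlaps(iv.start, iv.end)
    ]
    return PeakSet(kept, label=a.label)


def define_enhancers(h3k27ac: PeakSet, h3k4me1: PeakSet) -> PeakSet:
    """Operational enhancers: H3K27ac peaks overlapping H3K4me1 by >= 1 bp."""
    out = intersect_peaks(h3k27ac, h3k4me1)
    out.label = "enhancer"
    return out


def annotate_nearest_promoter(
    peaks: PeakSet, promoters: PromoterMap
) -> dict[GenomicInterval, str | None]:
    """Assign each peak to the gene with the TSS nearest its midpoint.

    Distance is unsigned |peak_center - tss| on the same chromosome;
    strand is ignored. Ties are broken by lexicographically smallest
    gene_id so annotation is deterministic. A peak on a chromosome with
    no promoter maps to ``None`` (unannotated), not an error.

    The full per-chromosome distance scan is vectorised; for the peak/
    promoter set sizes this workflow handles (10^3-10^5) this is fast and
    avoids edge cases of a search-tree shortcut.
    """
    per_chrom = promoters.by_chrom()
    annotation: dict[GenomicInterval, str | None] = {}
    for iv in peaks:
        if iv.chrom not in per_chrom:
            annotation[iv] = None
            continue
        tss, genes = per_chrom[iv.chrom]
        dist = np.abs(tss - iv.center)
        winners = genes[dist == dist.min()]
        annotation[iv] = min(winners)
    return annotation


def bound_genes(annotation: Mapping[GenomicInterval, str | None]) -> set[str]:
    """The set of genes hit by at least one annotated peak."""
    return {g for g in annotation.values() if g is not None}


def spikein_scale_factor(c: SpikeInCounts) -> float:
    """Exogenous spike-in scale factor for reference normalization.

    alpha = (spike_input / hg_input) / (spike_ip / hg_ip). Multiplying the
    raw host-genome IP signal by alpha equalizes the spike:host ratio
    between input and IP, so equal ratios imply no adjustment (alpha = 1).
    """
    input_ratio = c.spike_reads_input / c.hg_reads_input
    ip_ratio = c.spike_reads_ip / c.hg_reads_ip
    return input_ratio / ip_ratio


def tags_per_ten_million(signal: float, library_total: float) -> float:
    """Scale a tag count to a 10-million-tag library."""
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    if signal < 0:
        raise ValueError("signal must be non-negative")
    return signal * 1e7 / library_total
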