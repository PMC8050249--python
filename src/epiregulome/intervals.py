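"""Coordinate arithmetic shared by all pipeline stages.

All coordinates are 0-based, half-open (BED dialect): an interval covers
bases ``start`` .. ``end - 1``.  The transcription start site (TSS) of a
minus-strand gene is ``end - 1``, the standard strand-aware convention.
A symmetric window "TSS ± k" is realized as the half-open interval
``[tss - k, tss + k + 1)`` so that exactly ``k`` bases flank the TSS on
each side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "MergedPeak",
    "NearestGene",
    "merge_intervals",
    "nearest_gene",
    "classify_region",
    "make_windows",
    "tss_window",
    "total_overlap",
]

# promoter half-widths used throughout: H3K4me3 peaks are promoter features
# (TSS +/- 2 kb), H3K27ac distal analyses exclude TSS +/- 2.5 kb
PROXIMAL_FLANK = {"H3K4me3": 2_000, "H3K27ac": 2_500}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        # floor midpoint; used for peak-to-window CNA assignment
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """Gene with strand-aware TSS.

    ``biotype`` matters for promoter definitions: only protein-coding
    genes define proximal windows.
    """

    gene_id: str
    interval: GenomicInterval
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if self.strand == "+" else iv.end - 1


@dataclass(frozen=True)
class MergedPeak:
    """Consensus peak: union of >=1-bp-overlapping per-sample peak calls."""

    interval: GenomicInterval
    support: frozenset = field(default_factory=frozenset)

    @property
    def n_support(self) -> int:
        return len(self.support)

    @property
    def peak_id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}"


@dataclass(frozen=True)
class NearestGene:
    """Nearest-gene assignment for one peak.

    ``distance`` is 0 when the peak overlaps the gene body; otherwise the
    gap in bp, signed negative when the peak lies left (5' in genome
    coordinates) of the gene.  ``gene_id`` is None when no gene exists on
    the peak's chromosome ("unassigned").  ``tie`` flags that another gene
    was equidistant (resolved to the leftmost start, then smallest id).
    """

    gene_id: str | None
    distance: int
    tie: bool = False

    @property
    def assigned(self) -> bool:
        return self.gene_id is not None


def merge_intervals(
    peaks_by_sample: Mapping[str, Iterable[GenomicInterval]],
) -> list[MergedPeak]:
    """Merge per-sample peak calls that overlap by >= 1 bp.

    Touching intervals ([10,20) and [20,30)) do NOT merge under the
    half-open convention.  Each merged peak records the set of samples
    that contributed at least one overlapping input peak.
    """
    records: list[tuple[str, int, int, str]] = []
    for sample, ivs in peaks_by_sample.items():
        for iv in ivs:
            if not isinstance(iv, GenomicInterval):
                raise TypeError(f"sample {sample}: not a GenomicInterval: {iv!r}")
            records.append((iv.chrom, iv.start, iv.end, sample))
    records.sort(key=lambda r: (r[0], r[1], r[2]))

    merged: list[MergedPeak] = []
    cur: list | None = None  # [chrom, start, end, set(samples)]
    for chrom, start, end, sample in records:
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].add(sample)
        else:
            if cur is not None:
                merged.append(
                    MergedPeak(GenomicInterval(cur[0], cur[1], cur[2]), frozenset(cur[3]))
                )
            cur = [chrom, start, end, {sample}]
    if cur is not None:
        merged.append(
            MergedPeak(GenomicInterval(cur[0], cur[1], cur[2]), frozenset(cur[3]))
        )
    return merged


def _signed_gap(peak: GenomicInterval, gene_iv: GenomicInterval) -> int:
    """0 on overlap; else gap bp, negative when peak is left of the gene."""
    if peak.overlaps(gene_iv):
        return 0
    if peak.end <= gene_iv.start:
        return -(gene_iv.start - peak.end)
    return peak.start - gene_iv.end


def nearest_gene(
    peak: GenomicInterval | MergedPeak, genes: Sequence[GeneModel]
) -> NearestGene:
    """Assign a peak to its nearest gene on the same chromosome.

    Distance is 0 for gene-body overlap, else the gap between closest
    ends.  Ties (equal |distance|) break to the leftmost gene start, then
    lexicographically smallest gene_id; a tie is flagged in the result.
    """
    iv = peak.interval if isinstance(peak, MergedPeak) else peak
    best: tuple[int, int, str] | None = None
    best_signed = 0
    n_at_best = 0
    for g in genes:
        if g.interval.chrom != iv.chrom:
            continue
        d = _signed_gap(iv, g.interval)
        key = (abs(d), g.interval.start, g.gene_id)
        if best is None or key < best:
            if best is None or abs(d) != best[0]:
                n_at_best = 1
            else:
                n_at_best += 1
            best = key
            best_signed = d
        elif abs(d) == best[0]:
            n_at_best += 1
    if best is None:
        return NearestGene(None, 0)
    return NearestGene(best[2], best_signed, tie=n_at_best > 1)


def tss_window(gene: GeneModel, flank: int) -> GenomicInterval:
    """Half-open window [tss - flank, tss + flank + 1), clipped at 0."""
    tss = gene.tss
    return GenomicInterval(gene.interval.chrom, max(0, tss - flank), tss + flank + 1)


def classify_region(
    peak: GenomicInterval | MergedPeak,
    genes: Sequence[GeneModel],
    mark: str,
) -> str:
    """Classify a peak as 'proximal' or 'distal' for a histone mark.

    A peak is proximal when it overlaps the TSS window of any
    protein-coding gene (TSS +/- 2 kb for H3K4me3, +/- 2.5 kb for
    H3K27ac).  Downstream, H3K4me3 analyses keep proximal peaks
    (promoters) and H3K27ac enhancer analyses keep distal peaks.
    """
    if mark not in PROXIMAL_FLANK:
        raise ValueError(f"unknown mark {mark!r}; expected one of {sorted(PROXIMAL_FLANK)}")
    flank = PROXIMAL_FLANK[mark]
    iv = peak.interval if isinstance(peak, MergedPeak) else peak
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        if iv.overlaps(tss_window(g, flank)):
            return "proximal"
    return "distal"


def make_windows(
    chrom_sizes: Mapping[str, int], width: int = 100_000, step: int = 10_000
) -> list[GenomicInterval]:
    """Sliding windows per chromosome; trailing partial windows dropped.

    A chromosome of length L >= width yields floor((L - width)/step) + 1
    windows; shorter chromosomes yield none.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    out: list[GenomicInterval] = []
    for chrom, length in chrom_sizes.items():
        if length < width:
            continue
        n = (length - width) // step + 1
        for i in range(n):
            s = i * step
            out.append(GenomicInterval(chrom, s, s + width))
    return out


def total_overlap(window: GenomicInterval, exclusions: Iterable[GenomicInterval]) -> int:
    """Bp of ``window`` covered by the union of ``exclusions`` (counted once)."""
    segs = sorted(
        (max(window.start, e.start), min(window.end, e.end))
        for e in exclusions
        if e.chrom == window.chrom and e.start < window.end and window.start < e.end
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in segs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered
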