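"""Normalized per-sample signal over merged peaks, tracks and profiles.

The occupancy matrix follows a fixed normalization ladder:
raw -> input_subtracted -> scaled_10M -> log2 -> quantile_normalized.
Counts are input-subtracted after scaling both libraries to 10 M mapped
reads, clamped at zero (enrichment-over-input semantics), offset by a
pseudocount before log2, and finally quantile-normalized across samples
against the mean-of-sorted-columns reference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .intervals import GeneModel, GenomicInterval, MergedPeak

__all__ = [
    "SignalMatrix",
    "TrackVector",
    "quantile_normalize",
    "build_signal_matrix",
    "select_features",
    "pairwise_correlation",
    "hierarchical_cluster",
    "make_track",
    "tss_profile",
    "preprocess_expression",
]

STAGES = ("raw", "input_subtracted", "scaled_10M", "log2", "quantile_normalized")


@dataclass
class SignalMatrix:
    """Feature x sample signal with normalization-stage provenance."""

    values: pd.DataFrame
    stage: str = "raw"
    features: list[MergedPeak] | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def advanced(self, values: pd.DataFrame, stage: str) -> "SignalMatrix":
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise ValueError(f"stage cannot go back from {self.stage} to {stage}")
        return replace(self, values=values, stage=stage)


@dataclass
class TrackVector:
    """Browser-style sliding-window read density for one chromosome."""

    chrom: str
    values: np.ndarray  # reads-per-million per window
    width: int = 200
    step: int = 20

    @property
    def starts(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.step


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean-of-sorted-columns distribution.

    After normalization the sorted columns are identical; applying the
    transform twice equals applying it once.
    """
    x = df.values.astype(float)
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[order[:, j], j] = ref
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def build_signal_matrix(
    ip_counts: pd.DataFrame,
    input_counts: pd.DataFrame,
    ip_lib_sizes: pd.Series,
    input_lib_sizes: pd.Series,
    features: Sequence[MergedPeak] | None = None,
    pseudocount: float = 1.0,
) -> SignalMatrix:
    """Input-subtracted, 10M-scaled, log2, quantile-normalized occupancy.

    cell = log2(max(ip*1e7/lib_ip - input*1e7/lib_input, 0) + pseudocount),
    then quantile normalization across samples.
    """
    if list(ip_counts.index) != list(input_counts.index):
        for a, b in zip(ip_counts.index, input_counts.index):
            if a != b:
                raise ValueError(f"feature mismatch between IP and input: {a!r} vs {b!r}")
        raise ValueError("IP and input feature sets differ in length")
    if list(ip_counts.columns) != list(input_counts.columns):
        raise ValueError("IP and input sample sets differ")
    if (ip_counts.values < 0).any() or (input_counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    ip_lib = ip_lib_sizes.reindex(ip_counts.columns).astype(float)
    in_lib = input_lib_sizes.reindex(ip_counts.columns).astype(float)
    if (ip_lib <= 0).any() or (in_lib <= 0).any():
        raise ValueError("library sizes must be positive")

    scaled = ip_counts.div(ip_lib, axis=1) * 1e7 - input_counts.div(in_lib, axis=1) * 1e7
    clamped = scaled.clip(lower=0.0)
    logged = np.log2(clamped + pseudocount)
    qn = quantile_normalize(logged)
    return SignalMatrix(
        values=qn,
        stage="quantile_normalized",
        features=list(features) if features is not None else None,
        params={"pseudocount": pseudocount, "scale": 1e7},
    )


AUTOSOMES = None  # any chrom not named chrX/chrY/chrM is treated as autosomal


def _is_autosome(chrom: str) -> bool:
    return chrom.lower().lstrip("chr") not in {"x", "y", "m", "mt"}


def select_features(
    matrix: SignalMatrix,
    min_support: int = 2,
    autosomes_only: bool = True,
    region_class: Mapping[str, str] | None = None,
    keep_class: str | None = None,
    top_n: int | None = None,
) -> SignalMatrix:
    """Keep supported, autosomal, correctly-classed, most-variable features.

    ``region_class`` maps peak_id -> 'proximal'/'distal'; when given with
    ``keep_class`` only that class is retained.  Features are ranked by
    across-sample variance (ties broken by genomic position) and the top
    ``top_n`` kept, returned in variance order.
    """
    if matrix.features is None:
        raise ValueError("select_features requires feature (peak) annotations")
    feats = matrix.features
    ids = list(matrix.values.index)
    keep_idx = []
    for i, (pid, pk) in enumerate(zip(ids, feats)):
        if pk.n_support < min_support:
            continue
        if autosomes_only and not _is_autosome(pk.interval.chrom):
            continue
        if region_class is not None and keep_class is not None:
            if region_class.get(pid) != keep_class:
                continue
        keep_idx.append(i)

    sub = matrix.values.iloc[keep_idx]
    sub_feats = [feats[i] for i in keep_idx]
    var = sub.var(axis=1, ddof=1).values
    pos = [(f.interval.chrom, f.interval.start, f.interval.end) for f in sub_feats]
    order = sorted(range(len(sub_feats)), key=lambda i: (-var[i], pos[i]))
    if top_n is not None:
        order = order[:top_n]
    out = replace(
        matrix,
        values=sub.iloc[order],
        features=[sub_feats[i] for i in order],
    )
    out.params = dict(matrix.params, min_support=min_support, top_n=top_n)
    return out


def pairwise_correlation(matrix: SignalMatrix | pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Pearson correlation of the signal columns."""
    df = matrix.values if isinstance(matrix, SignalMatrix) else matrix
    corr = df.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def hierarchical_cluster(
    matrix: SignalMatrix | pd.DataFrame,
    method: str = "average",
    metric: str = "pearson",
) -> tuple[np.ndarray, list[str]]:
    """Cluster samples; returns (scipy linkage matrix, leaf order).

    Default distance is 1 - Pearson correlation with average linkage;
    ``metric='euclidean'`` clusters on raw columns instead.  The result
    depends only on the sample profiles, not their input order.
    """
    df = matrix.values if isinstance(matrix, SignalMatrix) else matrix
    samples = list(df.columns)
    # canonicalize column order so permuted inputs give the same tree
    canon = sorted(samples)
    df = df[canon]
    if metric == "pearson":
        d = 1.0 - pairwise_correlation(df).values
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2, 0.0, None)
        z = hierarchy.linkage(squareform(d, checks=False), method=method)
    else:
        z = hierarchy.linkage(df.values.T, method=method, metric=metric)
    leaves = hierarchy.leaves_list(z)
    return z, [canon[i] for i in leaves]


def make_track(
    read_intervals: Sequence[GenomicInterval],
    chrom: str,
    chrom_length: int,
    lib_size: float,
    width: int = 200,
    step: int = 20,
) -> TrackVector:
    """Per-million read count over sliding windows on one chromosome.

    A read contributes to every window it overlaps by >= 1 bp.
    """
    if chrom_length < width:
        return TrackVector(chrom, np.zeros(0), width, step)
    n = (chrom_length - width) // step + 1
    acc = np.zeros(n + 1)
    for iv in read_intervals:
        if iv.chrom != chrom:
            continue
        # windows with start in (iv.start - width, iv.end) overlap the read
        first = max(0, (iv.start - width) // step + 1)
        last = min(n - 1, (iv.end - 1) // step)
        if first <= last:
            acc[first] += 1
            acc[last + 1] -= 1
    vals = np.cumsum(acc[:-1]) * 1e6 / lib_size
    return TrackVector(chrom, vals, width, step)


def tss_profile(
    read_intervals: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    lib_size: float,
    flank: int = 2_000,
    bin_size: int = 40,
) -> np.ndarray:
    """Aggregate reads-per-million density over TSS +/- flank.

    Returns ``2*flank/bin_size`` bins (100 by default) running 5'->3':
    minus-strand genes are mirrored before averaging, so bin 0 is the
    most upstream bin for every gene.  A read counts in every bin it
    overlaps.
    """
    n_bins = (2 * flank) // bin_size
    if n_bins <= 0:
        raise ValueError("flank/bin_size give no bins")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in read_intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    total = np.zeros(n_bins)
    for g in genes:
        tss = g.tss
        lo = tss - flank
        binned = np.zeros(n_bins)
        for iv in by_chrom.get(g.interval.chrom, ()):
            first = max(0, (iv.start - lo) // bin_size)
            last = min(n_bins - 1, (iv.end - 1 - lo) // bin_size)
            if iv.end <= lo or iv.start >= lo + 2 * flank:
                continue
            if first <= last:
                binned[int(first): int(last) + 1] += 1
        if g.strand == "-":
            binned = binned[::-1]
        total += binned
    if len(genes) == 0:
        return total
    return total * 1e6 / (lib_size * len(genes))


def preprocess_expression(
    rpkm_values: pd.DataFrame,
    gene_chroms: Mapping[str, str] | None = None,
    min_rpkm: float = 0.5,
    top_n: int = 10_000,
    offset: float = 0.1,
) -> pd.DataFrame:
    """Clustering-ready expression matrix.

    Keeps autosomal genes with RPKM >= min_rpkm in at least one sample,
    log2-transforms with the stated offset, quantile-normalizes, and
    returns the ``top_n`` most variable genes.
    """
    keep = rpkm_values.max(axis=1) >= min_rpkm
    if gene_chroms is not None:
        auto = pd.Series(
            {g: _is_autosome(gene_chroms.get(g, "chr1")) for g in rpkm_values.index}
        )
        keep &= auto.reindex(rpkm_values.index).fillna(False)
    sub = rpkm_values.loc[keep]
    logged = np.log2(sub + offset)
    qn = quantile_normalize(logged)
    var = qn.var(axis=1, ddof=1)
    top = var.sort_values(ascending=False).index[:top_n]
    return qn.loc[top]
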