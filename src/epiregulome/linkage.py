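"""Peak-to-nearest-gene linkage and the enrichment statistic.

For each stratum (mark x region class x direction) the peaks are split
into differential and non-differential sets, each peak is assigned its
nearest gene, and the association between differential occupancy and
concordant differential expression is summarized as a ratio of
proportions with a Pearson chi-square test on the 2x2 table::

    enrichment = (k_diff / n_diff) / (k_nondiff / n_nondiff)

where k counts peaks whose nearest gene is differentially expressed in
the *matching* direction (a peak up in tumor matches only genes up in
tumor).  Peaks with no gene on their chromosome are excluded from both
numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, GenomicInterval, MergedPeak, classify_region, nearest_gene

__all__ = [
    "EnrichmentTable",
    "link_peaks_to_genes",
    "enrichment_ratio",
    "chi_square_2x2",
    "summarize_enrichment",
]

UP_IN_TUMOR = "up_in_tumor"
UP_IN_NORMAL = "up_in_normal"


@dataclass
class EnrichmentTable:
    """2x2 linkage counts for one stratum.

    n_diff / n_nondiff: assigned differential / non-differential peaks;
    k_diff / k_nondiff: those whose nearest gene is differentially
    expressed in the matching direction.
    """

    mark: str
    region_class: str
    direction: str
    n_diff: int
    k_diff: int
    n_nondiff: int
    k_nondiff: int

    def __post_init__(self) -> None:
        if not (0 <= self.k_diff <= self.n_diff):
            raise ValueError("k_diff must satisfy 0 <= k <= n")
        if not (0 <= self.k_nondiff <= self.n_nondiff):
            raise ValueError("k_nondiff must satisfy 0 <= k <= n")


def enrichment_ratio(tbl: EnrichmentTable) -> float | None:
    """(k_diff/n_diff) / (k_nondiff/n_nondiff); None when undefined.

    Undefined (rather than infinite) when either denominator stratum is
    empty or k_nondiff = 0.
    """
    if tbl.n_diff == 0 or tbl.n_nondiff == 0 or tbl.k_nondiff == 0:
        return None
    return (tbl.k_diff / tbl.n_diff) / (tbl.k_nondiff / tbl.n_nondiff)


def chi_square_2x2(
    tbl: EnrichmentTable, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (1 df) on [[k_d, n_d-k_d], [k_n, n_n-k_n]].

    No continuity correction by default.  A table with an all-zero row,
    column or margin has statistic 0 and p = 1.
    """
    obs = np.array(
        [
            [tbl.k_diff, tbl.n_diff - tbl.k_diff],
            [tbl.k_nondiff, tbl.n_nondiff - tbl.k_nondiff],
        ],
        dtype=float,
    )
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if total == 0 or (row == 0).any() or (col == 0).any():
        return 0.0, 1.0
    exp = np.outer(row, col) / total
    diff = np.abs(obs - exp)
    if continuity_correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff ** 2 / exp).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def link_peaks_to_genes(
    diff_peaks: Mapping[str, str],
    nondiff_peaks: Sequence[str],
    diff_genes: Mapping[str, str],
    genes: Sequence[GeneModel],
    peak_intervals: Mapping[str, GenomicInterval],
) -> pd.DataFrame:
    """Nearest-gene assignment with direction matching per peak.

    ``diff_peaks`` maps peak_id -> direction; ``diff_genes`` maps
    gene_id -> direction.  The two peak sets must be disjoint.  Returns
    one row per peak: peak_id, is_diff, direction (or None), gene_id,
    distance, matched (nearest gene DE in the same direction).
    """
    overlap = set(diff_peaks) & set(nondiff_peaks)
    if overlap:
        raise ValueError(f"peak sets overlap: {sorted(overlap)[:3]} ...")
    gene_list = list(genes)
    rows = []
    for pid in list(diff_peaks) + list(nondiff_peaks):
        iv = peak_intervals[pid]
        hit = nearest_gene(iv, gene_list)
        is_diff = pid in diff_peaks
        direction = diff_peaks.get(pid)
        matched = bool(
            hit.assigned
            and is_diff
            and diff_genes.get(hit.gene_id) == direction
        )
        rows.append(
            {
                "peak_id": pid,
                "is_diff": is_diff,
                "direction": direction,
                "gene_id": hit.gene_id,
                "distance": hit.distance,
                "assigned": hit.assigned,
                "matched": matched,
            }
        )
    return pd.DataFrame(rows)


def _stratum_counts(
    diff_peaks: Mapping[str, str],
    nondiff_peaks: Sequence[str],
    diff_genes: Mapping[str, str],
    nearest: Mapping[str, str | None],
    direction: str,
) -> tuple[int, int, int, int]:
    n_diff = k_diff = n_nondiff = k_nondiff = 0
    for pid, d in diff_peaks.items():
        if d != direction:
            continue
        gid = nearest[pid]
        if gid is None:
            continue
        n_diff += 1
        if diff_genes.get(gid) == direction:
            k_diff += 1
    for pid in nondiff_peaks:
        gid = nearest[pid]
        if gid is None:
            continue
        n_nondiff += 1
        if diff_genes.get(gid) == direction:
            k_nondiff += 1
    return n_diff, k_diff, n_nondiff, k_nondiff


def summarize_enrichment(
    peaks_by_mark: Mapping[str, Sequence[MergedPeak]],
    diff_calls_by_mark: Mapping[str, Mapping[str, str]],
    diff_genes: Mapping[str, str],
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """All-strata report: 2 marks x 2 region classes x 2 directions.

    ``diff_calls_by_mark[mark]`` maps peak_id -> direction for the
    differential peaks; every other peak of that mark is
    non-differential.  Strata with no differential peaks are still
    emitted, with enrichment None.
    """
    gene_list = list(genes)
    rows = []
    for mark in sorted(peaks_by_mark):
        peaks = peaks_by_mark[mark]
        calls = dict(diff_calls_by_mark.get(mark, {}))
        ivs = {p.peak_id: p.interval for p in peaks}
        classes = {
            p.peak_id: classify_region(p.interval, gene_list, mark) for p in peaks
        }
        nearest_map = {
            pid: nearest_gene(iv, gene_list).gene_id for pid, iv in ivs.items()
        }
        for region_class in ("proximal", "distal"):
            ids = [pid for pid in ivs if classes[pid] == region_class]
            dp = {pid: calls[pid] for pid in ids if pid in calls}
            ndp = [pid for pid in ids if pid not in calls]
            for direction in (UP_IN_NORMAL, UP_IN_TUMOR):
                n_d, k_d, n_n, k_n = _stratum_counts(
                    dp, ndp, diff_genes, nearest_map, direction
                )
                tbl = EnrichmentTable(mark, region_class, direction, n_d, k_d, n_n, k_n)
                enr = enrichment_ratio(tbl)
                stat, p = chi_square_2x2(tbl)
                rows.append(
                    {
                        "mark": mark,
                        "region_class": region_class,
                        "direction": direction,
                        "n_diff": n_d,
                        "k_diff": k_d,
                        "n_nondiff": n_n,
                        "k_nondiff": k_n,
                        "enrichment": np.nan if enr is None else round(enr, 2),
                        "chi2": stat,
                        "p": p,
                    }
                )
    return pd.DataFrame(rows)
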