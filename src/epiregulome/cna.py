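"""Copy-number-alteration inference from pooled-input coverage.

Autosomes are tiled with 100-kb windows sliding by 10 kb.  Per window
and sample, coverage = (read pairs scaled to 10 M) / (effective window
size in kb), where the effective size excludes bases under peaks or
blacklisted regions.  Tumor coverage is normalized to the average of
the per-normal median coverages (a scalar), log2-transformed, and
standardized within each tumor sample across its retained windows; a
window is a gain at z >= z_thresh and a loss at z <= -z_thresh
(inclusive).  Peaks inherit the CNA state of the window whose midpoint
is closest to the peak center.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, MergedPeak, total_overlap

__all__ = [
    "CNACall",
    "effective_window_size",
    "window_coverage",
    "coverage_table",
    "normalize_and_zscore",
    "call_cna",
    "assign_peak_cna",
    "cna_overlap_summary",
    "merge_call_segments",
]

GAIN, LOSS, NEUTRAL = "gain", "loss", "neutral"


@dataclass(frozen=True)
class CNACall:
    window_id: str
    sample: str
    state: str
    z: float


def effective_window_size(
    window: GenomicInterval,
    peaks: Sequence[GenomicInterval] = (),
    blacklist: Sequence[GenomicInterval] = (),
) -> float:
    """Window kb minus kb overlapped by the union of peaks and blacklist.

    Overlapping exclusions are counted once.  0 means the window is
    fully masked and must be excluded from coverage.
    """
    excluded = total_overlap(window, list(peaks) + list(blacklist))
    return (window.length - excluded) / 1000.0


def window_coverage(
    read_pairs: float, lib_read_pairs: float, effective_kb: float
) -> float:
    """(read_pairs * 1e7 / lib_read_pairs) / effective_kb."""
    if effective_kb <= 0:
        raise ValueError("effective window size must be positive")
    if lib_read_pairs <= 0:
        raise ValueError("library size must be positive")
    return (read_pairs * 1e7 / lib_read_pairs) / effective_kb


def coverage_table(
    windows: Sequence[GenomicInterval],
    read_pairs: pd.DataFrame,
    lib_sizes: pd.Series,
    peaks: Sequence[GenomicInterval] = (),
    blacklist: Sequence[GenomicInterval] = (),
    min_reads: int = 100,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-window, per-sample coverage plus the retained-window mask.

    A window is excluded when its effective size is 0 or when any
    sample has fewer than ``min_reads`` read pairs in it (default 100).
    Returns (coverage over retained windows, effective kb per retained
    window).
    """
    ids = [f"{w.chrom}:{w.start}-{w.end}" for w in windows]
    if list(read_pairs.index) != ids:
        read_pairs = read_pairs.reindex(ids)
        if read_pairs.isna().any().any():
            raise ValueError("read_pairs rows do not match the window set")
    eff = pd.Series(
        [effective_window_size(w, peaks, blacklist) for w in windows],
        index=ids, name="effective_kb",
    )
    retained = (eff > 0) & (read_pairs.min(axis=1) >= min_reads)
    sub = read_pairs.loc[retained]
    eff_sub = eff.loc[retained]
    lib = lib_sizes.reindex(read_pairs.columns).astype(float)
    cov = sub.mul(1e7).div(lib, axis=1).div(eff_sub, axis=0)
    return cov, eff_sub


def normalize_and_zscore(
    coverage: pd.DataFrame,
    normal_samples: Sequence[str],
    tumor_samples: Sequence[str],
    mode: str = "scalar",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log2 ratios to the normal panel and per-tumor-sample z-scores.

    ``mode='scalar'`` (default): the denominator is one number, the
    mean over normal samples of each sample's median coverage across
    retained windows.  ``mode='per_window'``: each window is instead
    normalized to its own mean coverage across the normal panel.
    Z-scores standardize each tumor sample's log2 ratios to mean 0 / sd
    1 across its retained windows.
    """
    for s in list(normal_samples) + list(tumor_samples):
        if s not in coverage.columns:
            raise ValueError(f"sample {s!r} missing from coverage table")
    if mode == "scalar":
        denom = float(np.mean([coverage[s].median() for s in normal_samples]))
        if denom <= 0:
            raise ValueError("normal-panel median coverage is zero; cannot normalize")
        ratio = coverage[list(tumor_samples)] / denom
    elif mode == "per_window":
        denom_w = coverage[list(normal_samples)].mean(axis=1)
        if (denom_w <= 0).any():
            raise ValueError("zero normal-panel coverage in some windows")
        ratio = coverage[list(tumor_samples)].div(denom_w, axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    log2r = np.log2(ratio.clip(lower=1e-12))
    z = (log2r - log2r.mean(axis=0)) / log2r.std(axis=0, ddof=0)
    return log2r, z


def call_cna(z: pd.DataFrame, z_thresh: float = 3.0) -> list[CNACall]:
    """Gain at z >= z_thresh, loss at z <= -z_thresh (inclusive)."""
    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    calls = []
    for sample in z.columns:
        col = z[sample]
        for wid, val in col.items():
            if np.isnan(val):
                continue
            if val >= z_thresh:
                state = GAIN
            elif val <= -z_thresh:
                state = LOSS
            else:
                state = NEUTRAL
            calls.append(CNACall(wid, sample, state, float(val)))
    return calls


def _parse_window_id(wid: str) -> tuple[str, int, int]:
    chrom, _, rng = wid.rpartition(":")
    s, _, e = rng.partition("-")
    return chrom, int(s), int(e)


def assign_peak_cna(
    peak: GenomicInterval | MergedPeak,
    calls: Sequence[CNACall],
    sample: str,
) -> str:
    """CNA state of the retained window nearest the peak center.

    Nearest = smallest |peak center - window midpoint|; ties go to the
    lower-coordinate window.  'unassigned' when the sample has no
    retained window on the peak's chromosome.
    """
    iv = peak.interval if isinstance(peak, MergedPeak) else peak
    center = iv.center
    best: tuple[int, int] | None = None  # (|dist|, window start)
    best_state = "unassigned"
    for c in calls:
        if c.sample != sample:
            continue
        chrom, s, e = _parse_window_id(c.window_id)
        if chrom != iv.chrom:
            continue
        mid = (s + e) // 2
        key = (abs(center - mid), s)
        if best is None or key < best:
            best = key
            best_state = c.state
    return best_state


def cna_overlap_summary(
    peak_sets: Mapping[str, Sequence[MergedPeak]],
    calls: Sequence[CNACall],
    samples: Sequence[str],
) -> pd.DataFrame:
    """Fraction of peaks assigned gain/loss/neutral per sample and set."""
    rows = []
    for set_name, peaks in peak_sets.items():
        for sample in samples:
            states = [assign_peak_cna(p, calls, sample) for p in peaks]
            n = sum(1 for s in states if s != "unassigned")
            row = {"peak_set": set_name, "sample": sample, "n_assigned": n}
            for state in (GAIN, LOSS, NEUTRAL):
                row[f"frac_{state}"] = (
                    sum(1 for s in states if s == state) / n if n else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)


def merge_call_segments(calls: Sequence[CNACall]) -> pd.DataFrame:
    """Merge runs of overlapping windows with the same non-neutral state.

    Sliding windows overlap, so adjacent calls are correlated; segment-
    level summaries report each contiguous gain/loss run once.
    """
    rows = []
    by_sample: dict[str, list[tuple[str, int, int, str]]] = {}
    for c in calls:
        if c.state == NEUTRAL:
            continue
        chrom, s, e = _parse_window_id(c.window_id)
        by_sample.setdefault(c.sample, []).append((chrom, s, e, c.state))
    for sample, recs in sorted(by_sample.items()):
        recs.sort()
        cur = None
        for chrom, s, e, state in recs:
            if (
                cur is not None
                and cur[0] == chrom
                and cur[3] == state
                and s <= cur[2]
            ):
                cur[2] = max(cur[2], e)
                cur[4] += 1
            else:
                if cur is not None:
                    rows.append(dict(zip(
                        ("chrom", "start", "end", "state", "n_windows", "sample"),
                        (*cur[:4], cur[4], sample))))
                cur = [chrom, s, e, state, 1]
        if cur is not None:
            rows.append(dict(zip(
                ("chrom", "start", "end", "state", "n_windows", "sample"),
                (*cur[:4], cur[4], sample))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state", "n_windows", "sample"])
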