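"""Synthetic inputs with the statistical structure the pipeline assumes.

Emulates a tumor-vs-normal histone ChIP-seq + RNA-seq study design:
group-structured negative-binomial counts for genes and peaks, per-sample
peak calls in promoter/distal space for two marks (H3K4me3 promoter-biased,
H3K27ac enhancer-biased), pooled-input coverage over sliding windows with
injected copy-number segments, and a configurable coupling between
differential peaks and differential expression of their nearest genes.

The negative binomial is parameterized mean-dispersion:
``var = mu + phi * mu**2``.  Copy-number segments scale IP and input
counts multiplicatively and identically (input coverage approximates copy
number; IP gains are then partly CN-driven, as in real data).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as eio
from .intervals import GeneModel, GenomicInterval, make_windows, nearest_gene

__all__ = [
    "CNASegment",
    "SimConfig",
    "SimTruth",
    "MarkData",
    "default_cna_segments",
    "simulate_genome",
    "simulate_peaks_and_counts",
    "simulate_expression",
    "simulate_window_read_pairs",
    "cna_truth_window_sets",
    "write_simulation",
]

UP_IN_TUMOR = "up_in_tumor"
UP_IN_NORMAL = "up_in_normal"
MARKS = ("H3K4me3", "H3K27ac")


@dataclass(frozen=True)
class CNASegment:
    chrom: str
    start: int
    end: int
    sample: str
    copy_ratio: float  # 1 = neutral, 2 = one-copy gain (diploid), 0.5 = loss

    def as_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the motivating design: 3 normal vs 4 tumor samples
    (the cohort used for differential and linkage analysis), strong
    effects (mean |log2FC| = 3, i.e. 8-fold) against an NB dispersion of
    0.1, and a 2 x 10 Mb genome so the 100-kb/10-kb window machinery runs
    over ~2,000 windows at desk scale.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 800
    n_peaks_per_mark: int = 600
    n_normal: int = 3
    n_tumor: int = 4
    frac_diff_peaks: float = 0.2
    frac_de_genes: float = 0.15
    coupling: float = 0.6
    effect_log2fc: float = 3.0
    dispersion: float = 0.1
    lib_size_range: tuple[int, int] = (8_000_000, 12_000_000)
    cna_segments: list[CNASegment] = field(default_factory=list)
    blacklist_frac: float = 0.01
    # mark-specific placement: fraction of H3K4me3 peaks within TSS +/- 2 kb,
    # fraction of H3K27ac peaks outside TSS +/- 2.5 kb
    frac_promoter_k4: float = 0.8
    frac_distal_k27: float = 0.8
    peak_presence_prob: float = 0.9
    peak_mean_scale: float = 200.0  # mean IP count per peak at a 10 M library
    input_density_per_kb: float = 20.0  # mean input count per peak kb at 10 M
    # pooled input (all libraries of a case combined) is deep and 100-kb
    # windows average local noise, so per-window counts are large with
    # little extra-Poisson variance
    window_read_mean: float = 2000.0  # mean pooled-input pairs per 100-kb window
    window_dispersion: float = 0.002
    window_propensity_sd: float = 0.03  # regional (mappability-like) lognormal sd

    def __post_init__(self) -> None:
        for name in ("frac_diff_peaks", "frac_de_genes", "coupling",
                     "blacklist_frac", "frac_promoter_k4", "frac_distal_k27",
                     "peak_presence_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.chrom_length < 1_000_000:
            raise ValueError("chrom_length must be >= 1 Mb")
        if self.lib_size_range[0] <= 0 or self.lib_size_range[1] < self.lib_size_range[0]:
            raise ValueError("lib_size_range must be positive and ordered")
        if self.dispersion < 0 or self.window_dispersion < 0:
            raise ValueError("dispersions must be >= 0")
        for seg in self.cna_segments:
            if not (0 <= seg.start < seg.end <= self.chrom_length):
                raise ValueError(f"CN segment {seg} exceeds chromosome bounds")

    @property
    def normal_samples(self) -> list[str]:
        return [f"N{i + 1}" for i in range(self.n_normal)]

    @property
    def tumor_samples(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_tumor)]

    @property
    def samples(self) -> list[str]:
        return self.normal_samples + self.tumor_samples

    @property
    def groups(self) -> dict[str, str]:
        g = {s: "normal" for s in self.normal_samples}
        g.update({s: "tumor" for s in self.tumor_samples})
        return g


def default_cna_segments(cfg: SimConfig) -> list[CNASegment]:
    """One 200-kb gain (copy_ratio 2) and one 200-kb loss (0.5) per tumor
    sample, staggered across chromosomes.

    Copy-number alterations are a hallmark of the tumor type this design
    emulates, so every tumor sample carries them.  200 kb spans 11 full
    100-kb/10-kb sliding windows, comfortably above the 5-window
    recovery floor, while keeping altered windows a few percent of the
    genome per sample — CNAs are focal events, and a per-sample z-score
    is only sensitive when most windows stay neutral.
    """
    segs = []
    for i, sample in enumerate(cfg.tumor_samples):
        chrom = f"chr{(i % cfg.n_chrom) + 1}"
        other = f"chr{((i + 1) % cfg.n_chrom) + 1}"
        segs.append(CNASegment(chrom, 2_000_000 + i * 600_000,
                               2_200_000 + i * 600_000, sample, 2.0))
        segs.append(CNASegment(other, 6_000_000 + i * 600_000,
                               6_200_000 + i * 600_000, sample, 0.5))
    return segs


@dataclass
class SimTruth:
    """Ground truth of the generated cohort."""

    diff_peaks: dict[str, dict[str, str]] = field(default_factory=dict)  # mark -> peak_id -> direction
    de_genes: dict[str, str] = field(default_factory=dict)  # gene_id -> direction
    cna_segments: list[CNASegment] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "diff_peaks": self.diff_peaks,
            "de_genes": self.de_genes,
            "cna_segments": [dataclasses.asdict(s) for s in self.cna_segments],
        }


@dataclass
class MarkData:
    """Everything generated for one histone mark."""

    mark: str
    consensus: list[GenomicInterval]
    peak_calls: dict[str, list[GenomicInterval]]
    ip_counts: pd.DataFrame
    input_counts: pd.DataFrame
    ip_lib_sizes: pd.Series
    input_lib_sizes: pd.Series


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB draw with var = mu + phi*mu^2 (Poisson when phi = 0)."""
    mu = np.asarray(mu, dtype=float)
    if phi == 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _rng(cfg: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, *stream])


def simulate_genome(
    cfg: SimConfig,
) -> tuple[dict[str, int], list[GeneModel], list[GenomicInterval]]:
    """Chromosome sizes, gene models and blacklist intervals.

    Genes are placed uniformly (strand random, ~90% protein-coding); the
    blacklist tiles ~``blacklist_frac`` of the genome with 5-kb intervals
    on a 50-kb grid, so blacklist intervals never overlap each other.
    """
    rng = _rng(cfg, 1)
    chrom_sizes = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chrom)}

    max_gene_len = 20_000
    if cfg.chrom_length <= max_gene_len:
        raise ValueError("chromosomes too short to place genes")
    per_chrom_capacity = cfg.n_chrom * (cfg.chrom_length // 2_000)
    if cfg.n_genes > per_chrom_capacity:
        raise ValueError(f"cannot place {cfg.n_genes} genes on this genome")

    chroms = list(chrom_sizes)
    gene_chrom = rng.choice(len(chroms), size=cfg.n_genes)
    lengths = rng.integers(2_000, max_gene_len + 1, size=cfg.n_genes)
    starts = np.array([
        rng.integers(0, cfg.chrom_length - L) for L in lengths
    ])
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    coding = rng.random(cfg.n_genes) < 0.9

    order = np.lexsort((starts, gene_chrom))
    genes = []
    for rank, idx in enumerate(order):
        genes.append(
            GeneModel(
                gene_id=f"gene{rank + 1:04d}",
                interval=GenomicInterval(
                    chroms[gene_chrom[idx]], int(starts[idx]), int(starts[idx] + lengths[idx])
                ),
                strand=str(strands[idx]),
                biotype="protein_coding" if coding[idx] else "lincRNA",
            )
        )

    blacklist: list[GenomicInterval] = []
    if cfg.blacklist_frac > 0:
        tile, grid = 5_000, 50_000
        n_tiles = int(round(cfg.blacklist_frac * cfg.n_chrom * cfg.chrom_length / tile))
        slots = [
            (c, s)
            for c in chroms
            for s in range(0, cfg.chrom_length - tile + 1, grid)
        ]
        take = rng.choice(len(slots), size=min(n_tiles, len(slots)), replace=False)
        for i in sorted(take):
            c, s = slots[i]
            blacklist.append(GenomicInterval(c, s, s + tile))

    return chrom_sizes, genes, blacklist


def _place_peaks(
    rng: np.random.Generator,
    cfg: SimConfig,
    genes: Sequence[GeneModel],
    blacklist: Sequence[GenomicInterval],
    mark: str,
) -> list[GenomicInterval]:
    """Consensus peak locations with mark-appropriate TSS geometry."""
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    tss_by_chrom: dict[str, np.ndarray] = {
        c: np.sort(np.array([g.tss for g in genes
                             if g.biotype == "protein_coding" and g.interval.chrom == c]))
        for c in chroms
    }
    bl_by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chroms}
    for b in blacklist:
        bl_by_chrom[b.chrom].append(b)

    if mark == "H3K4me3":
        frac_prox, wlo, whi, prox_jitter, distal_gap = (
            cfg.frac_promoter_k4, 1_000, 3_000, 500, 3_000)
    else:
        frac_prox, wlo, whi, prox_jitter, distal_gap = (
            1.0 - cfg.frac_distal_k27, 1_000, 5_000, 1_500, 4_000)

    n_prox = int(round(frac_prox * cfg.n_peaks_per_mark))
    n_distal = cfg.n_peaks_per_mark - n_prox
    coding_tss = [(g.interval.chrom, g.tss) for g in genes if g.biotype == "protein_coding"]

    def min_tss_dist(chrom: str, pos: int) -> float:
        arr = tss_by_chrom[chrom]
        if arr.size == 0:
            return np.inf
        i = np.searchsorted(arr, pos)
        cands = arr[max(0, i - 1): i + 1]
        return float(np.min(np.abs(cands - pos)))

    def overlaps_blacklist(iv: GenomicInterval) -> bool:
        return any(iv.overlaps(b) for b in bl_by_chrom[iv.chrom])

    candidates: list[GenomicInterval] = []
    for _ in range(n_prox):
        for _attempt in range(50):
            chrom, tss = coding_tss[rng.integers(len(coding_tss))]
            center = tss + int(rng.integers(-prox_jitter, prox_jitter + 1))
            w = int(rng.integers(wlo, whi + 1))
            s = max(0, center - w // 2)
            iv = GenomicInterval(chrom, s, min(cfg.chrom_length, s + w))
            if not overlaps_blacklist(iv):
                candidates.append(iv)
                break
    for _ in range(n_distal):
        for _attempt in range(200):
            chrom = chroms[rng.integers(len(chroms))]
            center = int(rng.integers(10_000, cfg.chrom_length - 10_000))
            w = int(rng.integers(wlo, whi + 1))
            iv = GenomicInterval(chrom, max(0, center - w // 2), center + w // 2 + 1)
            if min_tss_dist(chrom, center) > distal_gap + w and not overlaps_blacklist(iv):
                candidates.append(iv)
                break

    # enforce >= 500 bp separation so per-sample boundary jitter cannot
    # bridge adjacent consensus peaks
    candidates.sort()
    kept: list[GenomicInterval] = []
    for iv in candidates:
        if kept and iv.chrom == kept[-1].chrom and iv.start < kept[-1].end + 500:
            continue
        kept.append(iv)
    return kept


def _cn_multiplier(
    iv: GenomicInterval, sample: str, segments: Sequence[CNASegment]
) -> float:
    """Overlap-weighted copy multiplier: 1 outside segments, copy_ratio
    for fully contained features, linear in the overlap fraction."""
    m = 1.0
    for seg in segments:
        if seg.sample != sample or seg.chrom != iv.chrom:
            continue
        ov = min(iv.end, seg.end) - max(iv.start, seg.start)
        if ov > 0:
            m *= 1.0 + (seg.copy_ratio - 1.0) * ov / iv.length
    return m


def simulate_peaks_and_counts(
    cfg: SimConfig,
    genes: Sequence[GeneModel],
    blacklist: Sequence[GenomicInterval] = (),
) -> tuple[dict[str, MarkData], SimTruth]:
    """Per-sample peak calls plus IP/input count tables for both marks.

    Differential peaks get a symmetric group mean shift totalling
    ``2**effect_log2fc``; copy-number segments scale IP and input means
    identically.
    """
    truth = SimTruth(cna_segments=list(cfg.cna_segments))
    marks: dict[str, MarkData] = {}
    for mi, mark in enumerate(MARKS):
        rng = _rng(cfg, 2, mi)
        consensus = _place_peaks(rng, cfg, genes, blacklist, mark)
        n = len(consensus)
        peak_ids = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in consensus]

        n_diff = int(round(cfg.frac_diff_peaks * n))
        diff_idx = rng.choice(n, size=n_diff, replace=False)
        directions = rng.choice([UP_IN_TUMOR, UP_IN_NORMAL], size=n_diff)
        truth.diff_peaks[mark] = {
            peak_ids[i]: str(d) for i, d in zip(sorted(diff_idx), directions)
        }

        samples = cfg.samples
        ip_lib = pd.Series(
            rng.integers(cfg.lib_size_range[0], cfg.lib_size_range[1] + 1, len(samples)),
            index=samples, name="ip_lib_size")
        input_lib = pd.Series(
            rng.integers(cfg.lib_size_range[0], cfg.lib_size_range[1] + 1, len(samples)),
            index=samples, name="input_lib_size")

        base = np.exp(rng.normal(np.log(cfg.peak_mean_scale), 0.5, size=n))
        dir_by_idx = dict(zip(sorted(diff_idx), directions))

        ip = np.zeros((n, len(samples)), dtype=int)
        inp = np.zeros((n, len(samples)), dtype=int)
        widths_kb = np.array([iv.length / 1000 for iv in consensus])
        for si, s in enumerate(samples):
            is_tumor = cfg.groups[s] == "tumor"
            gshift = np.ones(n)
            for i, d in dir_by_idx.items():
                up_t = d == UP_IN_TUMOR
                half = cfg.effect_log2fc / 2
                gshift[i] = 2 ** (half if up_t == is_tumor else -half)
            cn = np.array([_cn_multiplier(iv, s, cfg.cna_segments) for iv in consensus])
            mu_ip = base * gshift * cn * (ip_lib[s] / 1e7)
            mu_in = cfg.input_density_per_kb * widths_kb * cn * (input_lib[s] / 1e7)
            ip[:, si] = _nb_sample(rng, mu_ip, cfg.dispersion)
            inp[:, si] = _nb_sample(rng, mu_in, cfg.dispersion)

        calls: dict[str, list[GenomicInterval]] = {}
        for s in samples:
            present = rng.random(n) < cfg.peak_presence_prob
            lst = []
            for i, iv in enumerate(consensus):
                if not present[i]:
                    continue
                js = int(rng.integers(-100, 101))
                je = int(rng.integers(-100, 101))
                s0 = max(0, iv.start + js)
                e0 = min(cfg.chrom_length, max(s0 + 200, iv.end + je))
                lst.append(GenomicInterval(iv.chrom, s0, e0))
            calls[s] = lst

        marks[mark] = MarkData(
            mark=mark,
            consensus=consensus,
            peak_calls=calls,
            ip_counts=pd.DataFrame(ip, index=peak_ids, columns=samples),
            input_counts=pd.DataFrame(inp, index=peak_ids, columns=samples),
            ip_lib_sizes=ip_lib,
            input_lib_sizes=input_lib,
        )
    return marks, truth


def simulate_expression(
    cfg: SimConfig,
    genes: Sequence[GeneModel],
    truth: SimTruth,
    marks: Mapping[str, MarkData] | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Gene count matrix, gene lengths and library sizes.

    A background ``frac_de_genes`` of genes is differentially expressed
    with random direction; with probability ``coupling`` the nearest gene
    of each differential peak is additionally forced into the DE set with
    the peak's direction (concordant coupling).
    """
    rng = _rng(cfg, 3)
    gene_ids = [g.gene_id for g in genes]
    n = len(genes)

    n_de = int(round(cfg.frac_de_genes * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    de_dirs = rng.choice([UP_IN_TUMOR, UP_IN_NORMAL], size=n_de)
    de: dict[str, str] = {
        gene_ids[i]: str(d) for i, d in zip(sorted(de_idx), de_dirs)
    }

    if marks is not None:
        gene_list = list(genes)
        for mark in sorted(marks):
            md = marks[mark]
            by_id = {f"{iv.chrom}:{iv.start}-{iv.end}": iv for iv in md.consensus}
            for pid in sorted(truth.diff_peaks.get(mark, {})):
                direction = truth.diff_peaks[mark][pid]
                if rng.random() >= cfg.coupling:
                    continue
                hit = nearest_gene(by_id[pid], gene_list)
                if hit.assigned:
                    de[hit.gene_id] = direction

    truth.de_genes = de

    samples = cfg.samples
    lib = pd.Series(
        rng.integers(cfg.lib_size_range[0], cfg.lib_size_range[1] + 1, len(samples)),
        index=samples, name="lib_size")
    base = np.exp(rng.normal(np.log(100), 1.0, size=n))
    lengths = pd.Series([g.interval.length for g in genes], index=gene_ids, name="length")

    counts = np.zeros((n, len(samples)), dtype=int)
    idx_of = {g: i for i, g in enumerate(gene_ids)}
    de_by_idx = {idx_of[g]: d for g, d in de.items()}
    for si, s in enumerate(samples):
        is_tumor = cfg.groups[s] == "tumor"
        gshift = np.ones(n)
        for i, d in de_by_idx.items():
            half = cfg.effect_log2fc / 2
            gshift[i] = 2 ** (half if (d == UP_IN_TUMOR) == is_tumor else -half)
        mu = base * gshift * (lib[s] / 1e7)
        counts[:, si] = _nb_sample(rng, mu, cfg.dispersion)

    return pd.DataFrame(counts, index=gene_ids, columns=samples), lengths, lib


def simulate_window_read_pairs(
    cfg: SimConfig,
    chrom_sizes: Mapping[str, int],
    width: int = 100_000,
    step: int = 10_000,
) -> tuple[list[GenomicInterval], pd.DataFrame, pd.Series]:
    """Pooled-input read pairs per sliding window per sample.

    Window means share a mild lognormal regional propensity across
    samples (mappability-like structure) and are multiplied by the
    overlap-weighted copy ratio of any CN segment of that sample.
    """
    rng = _rng(cfg, 4)
    windows = make_windows(chrom_sizes, width=width, step=step)
    samples = cfg.samples
    lib = pd.Series(
        rng.integers(cfg.lib_size_range[0], cfg.lib_size_range[1] + 1, len(samples)),
        index=samples, name="lib_size")
    propensity = np.exp(rng.normal(0.0, cfg.window_propensity_sd, size=len(windows)))
    counts = np.zeros((len(windows), len(samples)), dtype=int)
    for si, s in enumerate(samples):
        cn = np.array([_cn_multiplier(w, s, cfg.cna_segments) for w in windows])
        mu = cfg.window_read_mean * propensity * cn * (lib[s] / 1e7)
        counts[:, si] = _nb_sample(rng, mu, cfg.window_dispersion)
    ids = [f"{w.chrom}:{w.start}-{w.end}" for w in windows]
    return windows, pd.DataFrame(counts, index=ids, columns=samples), lib


def cna_truth_window_sets(
    windows: Sequence[GenomicInterval],
    segments: Sequence[CNASegment],
    min_abs_log2: float = 0.0,
) -> dict[str, dict[str, set[str]]]:
    """Truth window sets per sample for CNA recovery metrics.

    Because 100-kb windows slide with a 10-kb step, windows partially
    overlapping a segment carry intermediate signal.  ``full`` holds
    windows fully inside a segment (the sensitivity denominator);
    ``touched`` holds windows with any overlap (calls there are not
    false positives).
    """
    out: dict[str, dict[str, set[str]]] = {}
    for seg in segments:
        if abs(np.log2(seg.copy_ratio)) < min_abs_log2:
            continue
        d = out.setdefault(seg.sample, {"full": set(), "touched": set()})
        for w in windows:
            if w.chrom != seg.chrom:
                continue
            ov = min(w.end, seg.end) - max(w.start, seg.start)
            if ov <= 0:
                continue
            wid = f"{w.chrom}:{w.start}-{w.end}"
            d["touched"].add(wid)
            if w.start >= seg.start and w.end <= seg.end:
                d["full"].add(wid)
    return out


def write_simulation(cfg: SimConfig, outdir: str | Path) -> dict[str, str]:
    """Generate the full synthetic study and write every pipeline input.

    Returns a manifest of relative paths; all files are plain text
    (TSV/BED/JSON).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    chrom_sizes, genes, blacklist = simulate_genome(cfg)
    marks, truth = simulate_peaks_and_counts(cfg, genes, blacklist)
    expr, lengths, expr_lib = simulate_expression(cfg, genes, truth, marks)
    windows, win_counts, win_lib = simulate_window_read_pairs(cfg, chrom_sizes)

    paths: dict[str, str] = {}

    def _p(key: str, rel: str) -> Path:
        paths[key] = rel
        return out / rel

    eio.write_chrom_sizes(chrom_sizes, _p("chrom_sizes", "chrom.sizes"))
    eio.write_genes_tsv(genes, _p("genes", "genes.tsv"))
    eio.write_bed(blacklist, _p("blacklist", "blacklist.bed"))
    expr.to_csv(_p("expression_counts", "expression_counts.tsv"), sep="\t")
    lengths.to_frame().to_csv(_p("gene_lengths", "gene_lengths.tsv"), sep="\t")
    expr_lib.to_frame().to_csv(_p("expression_lib_sizes", "expression_lib_sizes.tsv"), sep="\t")
    win_counts.to_csv(_p("window_counts", "window_read_pairs.tsv"), sep="\t")
    win_lib.to_frame().to_csv(_p("window_lib_sizes", "window_lib_sizes.tsv"), sep="\t")

    for mark, md in marks.items():
        mdir = out / mark
        mdir.mkdir(exist_ok=True)
        for s, ivs in md.peak_calls.items():
            eio.write_bed(ivs, _p(f"{mark}_peaks_{s}", f"{mark}/peaks_{s}.bed"))
        md.ip_counts.to_csv(_p(f"{mark}_ip_counts", f"{mark}/ip_counts.tsv"), sep="\t")
        md.input_counts.to_csv(_p(f"{mark}_input_counts", f"{mark}/input_counts.tsv"), sep="\t")
        libdf = pd.DataFrame({"ip_lib_size": md.ip_lib_sizes,
                              "input_lib_size": md.input_lib_sizes})
        libdf.to_csv(_p(f"{mark}_lib_sizes", f"{mark}/lib_sizes.tsv"), sep="\t")

    eio.write_json(truth.to_json(), _p("truth", "truth.json"))
    eio.write_json({"groups": cfg.groups, "seed": cfg.seed}, _p("samples", "samples.json"))
    eio.write_json(paths, out / "inputs.json")
    return paths
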