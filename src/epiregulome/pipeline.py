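"""Stage orchestration: simulate -> matrix -> diff -> link -> cna -> report.

Each stage reads only files written by its prerequisites, writes its
artifacts under the run directory, and records a manifest (parameter
echo + sha256 of every output) so a rerun with the same config and seed
is hash-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import cna as cna_mod
from . import differential as diff_mod
from . import io as eio
from . import linkage as link_mod
from . import signal as sig_mod
from .intervals import GenomicInterval, MergedPeak, classify_region, make_windows, merge_intervals
from .simulate import MARKS, CNASegment, SimConfig, write_simulation

log = logging.getLogger("epiregulome")

STAGES = ("simulate", "matrix", "diff", "link", "cna", "report")
STAGE_DEPS = {
    "simulate": (),
    "matrix": ("simulate",),
    "diff": ("simulate",),
    "link": ("simulate", "diff"),
    "cna": ("simulate",),
    "report": ("link", "cna"),
}


@dataclass
class RunConfig:
    """All thresholds of the analysis, each defaulting to the study value."""

    outdir: str = "run"
    seed: int = 0
    cohort: str = "total_rna"  # single cohort per run; never pooled
    fdr_max: float = 0.05
    fc_expression: float = 3.0
    fc_peaks: float = 2.0
    z_thresh: float = 3.0
    top_n: int = 20_000
    min_support: int = 2
    min_reads: int = 100
    proximal_flank_k4: int = 2_000
    proximal_flank_k27: int = 2_500
    cna_norm_mode: str = "scalar"
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        for name in ("fdr_max", "fc_expression", "fc_peaks", "z_thresh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        segs = [CNASegment(**s) for s in sim_raw.pop("cna_segments", [])]
        lib = sim_raw.pop("lib_size_range", None)
        sim = SimConfig(
            cna_segments=segs,
            **({"lib_size_range": tuple(lib)} if lib else {}),
            **sim_raw,
        )
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, params: Mapping, outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "params": params,
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(outputs)
        },
    }
    (outdir / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def _check_deps(outdir: Path, stage: str) -> None:
    for dep in STAGE_DEPS[stage]:
        if not (outdir / f"manifest_{dep}.json").exists():
            raise RuntimeError(
                f"stage '{stage}' requires stage '{dep}' to have run first "
                f"(missing {outdir / f'manifest_{dep}.json'})"
            )


def _load_sim(outdir: Path):
    sim_dir = outdir / "inputs"
    chrom_sizes = eio.read_chrom_sizes(sim_dir / "chrom.sizes")
    genes = eio.read_genes_tsv(sim_dir / "genes.tsv")
    blacklist = eio.read_bed(sim_dir / "blacklist.bed")
    samples = eio.read_json(sim_dir / "samples.json")
    return sim_dir, chrom_sizes, genes, blacklist, samples["groups"]


def _merged_peaks(sim_dir: Path, mark: str, groups: Mapping[str, str]) -> list[MergedPeak]:
    calls = {}
    for sample in groups:
        p = sim_dir / mark / f"peaks_{sample}.bed"
        if p.exists():
            calls[sample] = eio.read_bed(p)
    return merge_intervals(calls)


def _parse_feature_id(fid: str) -> GenomicInterval:
    chrom, _, rng = fid.rpartition(":")
    s, _, e = rng.partition("-")
    return GenomicInterval(chrom, int(s), int(e))


def _feature_peaks(
    sim_dir: Path, mark: str, groups: Mapping[str, str], feature_ids
) -> list[MergedPeak]:
    """Count-table features as MergedPeak, with sample support taken from
    the merged per-sample peak calls they overlap.

    Per-sample calls carry boundary jitter, so support is matched by
    overlap rather than exact coordinates; features overlapped by no
    call in any sample get empty support (and fail any support filter).
    """
    merged = _merged_peaks(sim_dir, mark, groups)
    by_chrom: dict[str, list[MergedPeak]] = {}
    for m in merged:
        by_chrom.setdefault(m.interval.chrom, []).append(m)
    out = []
    for fid in feature_ids:
        iv = _parse_feature_id(fid)
        support: frozenset = frozenset()
        for m in by_chrom.get(iv.chrom, ()):
            if iv.overlaps(m.interval):
                support = support | m.support
        out.append(MergedPeak(iv, support))
    return out


def run_stage(stage: str, cfg: RunConfig) -> dict:
    """Run one pipeline stage; returns a small summary dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    _check_deps(outdir, stage)
    log.info("stage %s starting (seed=%d)", stage, cfg.seed)
    fn = {
        "simulate": _stage_simulate,
        "matrix": _stage_matrix,
        "diff": _stage_diff,
        "link": _stage_link,
        "cna": _stage_cna,
        "report": _stage_report,
    }[stage]
    summary = fn(outdir, cfg)
    log.info("stage %s done: %s", stage, summary)
    return summary


def run_all(cfg: RunConfig) -> dict:
    out = {}
    for stage in STAGES:
        out[stage] = run_stage(stage, cfg)
    return out


def _stage_simulate(outdir: Path, cfg: RunConfig) -> dict:
    sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
    if not sim.cna_segments:
        from .simulate import default_cna_segments
        sim = dataclasses.replace(sim, cna_segments=default_cna_segments(sim))
    paths = write_simulation(sim, outdir / "inputs")
    outputs = [outdir / "inputs" / p for p in paths.values()]
    _write_manifest(outdir, "simulate", {"sim": str(sim)}, outputs)
    return {"n_files": len(outputs)}


def _stage_matrix(outdir: Path, cfg: RunConfig) -> dict:
    sim_dir, chrom_sizes, genes, blacklist, groups = _load_sim(outdir)
    mdir = outdir / "matrix"
    mdir.mkdir(exist_ok=True)
    outputs = []
    summary = {}
    for mark in MARKS:
        ip = eio.read_counts_tsv(sim_dir / mark / "ip_counts.tsv")
        inp = eio.read_counts_tsv(sim_dir / mark / "input_counts.tsv")
        libs = pd.read_csv(sim_dir / mark / "lib_sizes.tsv", sep="\t", index_col=0)
        feats = _feature_peaks(sim_dir, mark, groups, ip.index)
        # blacklist-overlapping features are excluded up front
        keep = [
            i for i, p in enumerate(feats)
            if not any(p.interval.overlaps(b) for b in blacklist)
        ]
        feats = [feats[i] for i in keep]
        common = ip.index[keep]
        sm = sig_mod.build_signal_matrix(
            ip.loc[common], inp.loc[common],
            libs["ip_lib_size"], libs["input_lib_size"], features=feats,
        )
        keep_class = "proximal" if mark == "H3K4me3" else "distal"
        classes = {
            p.peak_id: classify_region(p.interval, genes, mark) for p in feats
        }
        sel = sig_mod.select_features(
            sm, min_support=cfg.min_support, region_class=classes,
            keep_class=keep_class, top_n=cfg.top_n,
        )
        corr = sig_mod.pairwise_correlation(sel)
        _z, leaves = sig_mod.hierarchical_cluster(sel)
        sel.values.to_csv(mdir / f"{mark}_signal.tsv", sep="\t")
        corr.to_csv(mdir / f"{mark}_correlation.tsv", sep="\t")
        (mdir / f"{mark}_leaf_order.tsv").write_text("\n".join(leaves) + "\n")
        eio.write_json(
            {"stage": sel.stage, "params": sel.params, "keep_class": keep_class},
            mdir / f"{mark}_signal_meta.json",
        )
        outputs += [mdir / f"{mark}_signal.tsv", mdir / f"{mark}_correlation.tsv",
                    mdir / f"{mark}_leaf_order.tsv", mdir / f"{mark}_signal_meta.json"]
        summary[mark] = {"n_features": sel.values.shape[0]}
    _write_manifest(outdir, "matrix", {"min_support": cfg.min_support,
                                       "top_n": cfg.top_n}, outputs)
    return summary


def _stage_diff(outdir: Path, cfg: RunConfig) -> dict:
    sim_dir, chrom_sizes, genes, blacklist, groups = _load_sim(outdir)
    ddir = outdir / "diff"
    ddir.mkdir(exist_ok=True)
    outputs = []
    summary = {}

    # expression
    expr = eio.read_counts_tsv(sim_dir / "expression_counts.tsv")
    lib = pd.read_csv(sim_dir / "expression_lib_sizes.tsv", sep="\t", index_col=0)["lib_size"]
    cm = diff_mod.CountMatrix(expr, groups, lib_sizes=lib.astype(float))
    res = diff_mod.run_differential(cm, fdr_max=cfg.fdr_max, min_fc=cfg.fc_expression)
    res.to_csv(ddir / "expression_diff.tsv", sep="\t")
    outputs.append(ddir / "expression_diff.tsv")
    summary["expression"] = {
        "n_tested": len(res),
        "n_up_tumor": int((res["direction"] == "up_in_tumor").sum()),
        "n_up_normal": int((res["direction"] == "up_in_normal").sum()),
        "common_dispersion": res.attrs["common_dispersion"],
    }

    # peak occupancy, per mark, on consensus peaks present in >= 2 samples
    for mark in MARKS:
        ip = eio.read_counts_tsv(sim_dir / mark / "ip_counts.tsv")
        feats = _feature_peaks(sim_dir, mark, groups, ip.index)
        keep = [
            fid for fid, p in zip(ip.index, feats) if p.n_support >= cfg.min_support
        ]
        libs = pd.read_csv(sim_dir / mark / "lib_sizes.tsv", sep="\t", index_col=0)
        cm = diff_mod.CountMatrix(
            ip.loc[keep], groups, lib_sizes=libs["ip_lib_size"].astype(float)
        )
        res = diff_mod.run_differential(cm, fdr_max=cfg.fdr_max, min_fc=cfg.fc_peaks)
        res.to_csv(ddir / f"{mark}_diff.tsv", sep="\t")
        outputs.append(ddir / f"{mark}_diff.tsv")
        summary[mark] = {
            "n_tested": len(res),
            "n_diff": int((res["direction"] != "ns").sum()),
        }
    _write_manifest(outdir, "diff", {"fdr_max": cfg.fdr_max,
                                     "fc_expression": cfg.fc_expression,
                                     "fc_peaks": cfg.fc_peaks}, outputs)
    return summary


def _stage_link(outdir: Path, cfg: RunConfig) -> dict:
    sim_dir, chrom_sizes, genes, blacklist, groups = _load_sim(outdir)
    ldir = outdir / "link"
    ldir.mkdir(exist_ok=True)
    expr = pd.read_csv(outdir / "diff" / "expression_diff.tsv", sep="\t", index_col=0)
    diff_genes = {
        g: d for g, d in expr["direction"].items() if d != "ns"
    }
    peaks_by_mark = {}
    calls_by_mark = {}
    for mark in MARKS:
        res = pd.read_csv(outdir / "diff" / f"{mark}_diff.tsv", sep="\t", index_col=0)
        peaks_by_mark[mark] = _feature_peaks(sim_dir, mark, groups, res.index)
        calls_by_mark[mark] = {
            pid: d for pid, d in res["direction"].items() if d != "ns"
        }
    table = link_mod.summarize_enrichment(peaks_by_mark, calls_by_mark, diff_genes, genes)
    table.to_csv(ldir / "enrichment.tsv", sep="\t", index=False)
    eio.write_json(json.loads(table.to_json(orient="records")), ldir / "enrichment.json")
    _write_manifest(outdir, "link", {"fdr_max": cfg.fdr_max},
                    [ldir / "enrichment.tsv", ldir / "enrichment.json"])
    return {"n_strata": len(table)}


def _stage_cna(outdir: Path, cfg: RunConfig) -> dict:
    sim_dir, chrom_sizes, genes, blacklist, groups = _load_sim(outdir)
    cdir = outdir / "cna"
    cdir.mkdir(exist_ok=True)
    windows = make_windows(chrom_sizes)
    reads = eio.read_counts_tsv(sim_dir / "window_read_pairs.tsv")
    lib = pd.read_csv(sim_dir / "window_lib_sizes.tsv", sep="\t", index_col=0)["lib_size"]
    all_peaks: list[GenomicInterval] = []
    for mark in MARKS:
        for p in _merged_peaks(sim_dir, mark, groups):
            all_peaks.append(p.interval)
    cov, eff = cna_mod.coverage_table(
        windows, reads, lib.astype(float), peaks=all_peaks,
        blacklist=blacklist, min_reads=cfg.min_reads,
    )
    normals = [s for s, g in groups.items() if g == "normal"]
    tumors = [s for s, g in groups.items() if g == "tumor"]
    log2r, z = cna_mod.normalize_and_zscore(cov, normals, tumors, mode=cfg.cna_norm_mode)
    calls = cna_mod.call_cna(z, z_thresh=cfg.z_thresh)

    rows = []
    for c in calls:
        chrom, s, e = c.window_id.rpartition(":")[0], *map(int, c.window_id.rpartition(":")[2].split("-"))
        rows.append({"chrom": chrom, "start": s, "end": e, "sample": c.sample,
                     "coverage": cov.loc[c.window_id, c.sample],
                     "log2_ratio": log2r.loc[c.window_id, c.sample],
                     "z": c.z, "state": c.state})
    pd.DataFrame(rows).to_csv(cdir / "window_calls.tsv", sep="\t", index=False)
    segs = cna_mod.merge_call_segments(calls)
    segs.to_csv(cdir / "segments.tsv", sep="\t", index=False)
    _write_manifest(outdir, "cna", {"z_thresh": cfg.z_thresh,
                                    "min_reads": cfg.min_reads,
                                    "mode": cfg.cna_norm_mode},
                    [cdir / "window_calls.tsv", cdir / "segments.tsv"])
    n_gain = int((pd.DataFrame(rows)["state"] == "gain").sum()) if rows else 0
    n_loss = int((pd.DataFrame(rows)["state"] == "loss").sum()) if rows else 0
    return {"n_windows_retained": len(cov), "n_gain_calls": n_gain, "n_loss_calls": n_loss}


def _stage_report(outdir: Path, cfg: RunConfig) -> dict:
    rdir = outdir / "report"
    rdir.mkdir(exist_ok=True)
    enrich = pd.read_csv(outdir / "link" / "enrichment.tsv", sep="\t")
    segs = pd.read_csv(outdir / "cna" / "segments.tsv", sep="\t")
    lines = ["# Run report", "", "## Peak-gene linkage enrichment", ""]
    for _, r in enrich.iterrows():
        enr = "undefined" if pd.isna(r["enrichment"]) else f"{r['enrichment']:.2f}"
        lines.append(
            f"- {r['mark']} {r['region_class']} {r['direction']}: "
            f"{r['k_diff']}/{r['n_diff']} vs {r['k_nondiff']}/{r['n_nondiff']}, "
            f"enrichment {enr}, chi2 p = {r['p']:.3g}"
        )
    lines += ["", "## CNA segments", ""]
    if len(segs):
        for _, r in segs.iterrows():
            lines.append(
                f"- {r['sample']}: {r['chrom']}:{r['start']}-{r['end']} "
                f"{r['state']} ({r['n_windows']} windows)"
            )
    else:
        lines.append("- none called")
    text = "\n".join(lines) + "\n"
    (rdir / "report.md").write_text(text)
    _write_manifest(outdir, "report", {}, [rdir / "report.md"])
    return {"report": str(rdir / "report.md")}
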