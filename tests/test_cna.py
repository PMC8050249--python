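"""Copy-number inference from input coverage windows."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import _oracles as oracle
from epiregulome.cna import (
    CNACall,
    assign_peak_cna,
    call_cna,
    cna_overlap_summary,
    coverage_table,
    effective_window_size,
    merge_call_segments,
    normalize_and_zscore,
    window_coverage,
)
from epiregulome.intervals import GenomicInterval, MergedPeak, make_windows
from epiregulome.simulate import (
    SimConfig,
    cna_truth_window_sets,
    default_cna_segments,
    simulate_window_read_pairs,
)
from conftest import random_intervals

W = GenomicInterval("chr1", 1_000_000, 1_100_000)


class TestEffectiveWindowSize:
    def test_no_exclusions_full_size(self):
        assert effective_window_size(W) == 100.0

    def test_fully_blacklisted_zero(self):
        assert effective_window_size(W, blacklist=[W]) == 0.0

    def test_shared_exclusions_counted_once(self):
        peaks = [GenomicInterval("chr1", 1_000_000, 1_010_000)]
        bl = [GenomicInterval("chr1", 1_005_000, 1_015_000)]
        assert effective_window_size(W, peaks, bl) == 85.0

    def test_matches_per_base_mask(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            excl = random_intervals(rng, 8, chroms=("chr1",),
                                    max_pos=1_150_000, max_len=30_000)
            got = effective_window_size(W, excl[:4], excl[4:])
            expected = oracle.effective_kb_per_base(
                ("chr1", W.start, W.end),
                [(e.chrom, e.start, e.end) for e in excl],
            )
            assert got == pytest.approx(expected, abs=1e-9)


class TestWindowCoverage:
    def test_formula_example(self):
        assert window_coverage(2_000, 20e6, 80.0) == pytest.approx(12.5)

    def test_lib_scaling(self):
        assert window_coverage(500, 2e7, 50.0) == pytest.approx(
            window_coverage(500, 1e7, 50.0) / 2
        )

    def test_zero_effective_size_rejected(self):
        with pytest.raises(ValueError):
            window_coverage(100, 1e7, 0.0)

    def test_low_read_windows_excluded(self):
        windows = make_windows({"chr1": 300_000}, 100_000, 100_000)
        ids = [f"{w.chrom}:{w.start}-{w.end}" for w in windows]
        reads = pd.DataFrame(
            {"s1": [0, 99, 500], "s2": [500, 500, 500]}, index=ids
        )
        lib = pd.Series({"s1": 1e7, "s2": 1e7})
        cov, eff = coverage_table(windows, reads, lib, min_reads=100)
        assert list(cov.index) == [ids[2]]


class TestNormalizeAndZscore:
    def _coverage(self, rng, n=500, tumor_shift=None):
        normals = {f"N{i}": rng.normal(10, 0.5, n).clip(1) for i in range(1, 4)}
        tumors = {}
        for i in range(1, 3):
            x = rng.normal(10, 0.5, n).clip(1)
            if tumor_shift is not None:
                x = x * tumor_shift[f"P{i}"]
            tumors[f"P{i}"] = x
        return pd.DataFrame({**normals, **tumors},
                            index=[f"chr1:{j}-{j+100000}" for j in range(n)])

    def test_null_tumor_z_small(self):
        rng = np.random.default_rng(1)
        cov = self._coverage(rng)
        _log2r, z = normalize_and_zscore(cov, ["N1", "N2", "N3"], ["P1", "P2"])
        assert abs(z.values.mean()) < 0.1

    def test_z_standardized_per_sample(self):
        rng = np.random.default_rng(2)
        cov = self._coverage(rng)
        _l, z = normalize_and_zscore(cov, ["N1", "N2", "N3"], ["P1", "P2"])
        np.testing.assert_allclose(z.mean(axis=0).values, 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=0, ddof=0).values, 1.0, atol=1e-10)

    def test_hand_worked_ten_window_example(self):
        """Scalar normalization checked step by step on 10 windows."""
        idx = [f"chr1:{j}-{j+100000}" for j in range(10)]
        cov = pd.DataFrame({
            "N1": np.linspace(8, 12, 10),
            "N2": np.linspace(9, 11, 10),
            "N3": np.full(10, 10.0),
            "P1": np.array([10, 10, 10, 40, 40, 10, 10, 10, 10, 10], float),
        }, index=idx)
        log2r, z = normalize_and_zscore(cov, ["N1", "N2", "N3"], ["P1"])
        denom = np.mean([np.median(cov["N1"]), np.median(cov["N2"]),
                         np.median(cov["N3"])])
        manual_l = np.log2(cov["P1"].values / denom)
        np.testing.assert_allclose(log2r["P1"].values, manual_l, atol=1e-12)
        manual_z = (manual_l - manual_l.mean()) / manual_l.std()
        np.testing.assert_allclose(z["P1"].values, manual_z, atol=1e-12)

    def test_zero_denominator_aborts(self):
        cov = pd.DataFrame({"N1": [0.0], "P1": [1.0]}, index=["chr1:0-100000"])
        with pytest.raises(ValueError):
            normalize_and_zscore(cov, ["N1"], ["P1"])

    def test_per_window_mode(self):
        rng = np.random.default_rng(3)
        cov = self._coverage(rng)
        _l, z = normalize_and_zscore(cov, ["N1", "N2", "N3"], ["P1", "P2"],
                                     mode="per_window")
        np.testing.assert_allclose(z.mean(axis=0).values, 0.0, atol=1e-10)

    def test_calls_invariant_under_uniform_lib_scaling(self):
        cfg = SimConfig(seed=6)
        cfg = dataclasses.replace(cfg, cna_segments=default_cna_segments(cfg))
        sizes = {f"chr{i+1}": cfg.chrom_length for i in range(cfg.n_chrom)}
        windows, reads, lib = simulate_window_read_pairs(cfg, sizes)
        cov1, _ = coverage_table(windows, reads, lib.astype(float), min_reads=10)
        cov2, _ = coverage_table(windows, reads, lib.astype(float) * 3, min_reads=10)
        n, t = cfg.normal_samples, cfg.tumor_samples
        _l1, z1 = normalize_and_zscore(cov1, n, t)
        _l2, z2 = normalize_and_zscore(cov2, n, t)
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-9)


class TestCallCna:
    def test_inclusive_thresholds(self):
        z = pd.DataFrame({"P1": [3.0, -3.0, 2.9, -2.5]},
                         index=[f"chr1:{j}-{j+100000}" for j in range(4)])
        states = {c.window_id: c.state for c in call_cna(z, 3.0)}
        assert states["chr1:0-100000"] == "gain"
        assert states["chr1:1-100001"] == "loss"
        assert states["chr1:2-100002"] == "neutral"
        assert states["chr1:3-100003"] == "neutral"
        relaxed = {c.window_id: c.state for c in call_cna(z, 2.0)}
        assert relaxed["chr1:3-100003"] == "loss"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        z = pd.DataFrame({"P1": rng.normal(0, 1.5, 50)},
                         index=[f"chr1:{j*10000}-{j*10000+100000}" for j in range(50)])
        a = set((c.window_id, c.state) for c in call_cna(z))
        b = set((c.window_id, c.state) for c in call_cna(z.iloc[::-1]))
        assert a == b


class TestAssignPeakCna:
    def _calls(self, states, start0=0):
        out = []
        for j, st in enumerate(states):
            s = start0 + j * 10_000
            out.append(CNACall(f"chr1:{s}-{s+100_000}", "P1", st, 0.0))
        return out

    def test_peak_on_window_midpoint(self):
        calls = self._calls(["neutral", "gain", "neutral"])
        # midpoint of window 1 ([10000,110000)) is 60000
        peak = GenomicInterval("chr1", 59_000, 61_000)
        assert assign_peak_cna(peak, calls, "P1") == "gain"

    def test_equidistant_tie_prefers_lower_window(self):
        calls = self._calls(["gain", "loss"])
        # midpoints 50000 and 60000; center 55000 is equidistant
        peak = GenomicInterval("chr1", 54_000, 56_000)
        assert assign_peak_cna(peak, calls, "P1") == "gain"

    def test_unassigned_without_windows_on_chrom(self):
        calls = self._calls(["gain"])
        assert assign_peak_cna(GenomicInterval("chr2", 0, 10), calls, "P1") == "unassigned"

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        states = [rng.choice(["gain", "loss", "neutral"]) for _ in range(80)]
        calls = self._calls(list(states))
        tuples = [(j * 10_000, j * 10_000 + 100_000, states[j]) for j in range(80)]
        for _ in range(100):
            s = int(rng.integers(0, 900_000))
            peak = GenomicInterval("chr1", s, s + int(rng.integers(200, 5_000)))
            expected = oracle.nearest_window_state(peak.center, tuples)
            assert assign_peak_cna(peak, calls, "P1") == expected


class TestOverlapSummary:
    def test_no_cna_zero_fractions(self):
        calls = [CNACall(f"chr1:{j*10000}-{j*10000+100000}", "P1", "neutral", 0.0)
                 for j in range(30)]
        peaks = [MergedPeak(GenomicInterval("chr1", 100_000 + i * 5_000,
                                            101_000 + i * 5_000), frozenset({"P1"}))
                 for i in range(10)]
        out = cna_overlap_summary({"all": peaks}, calls, ["P1"])
        assert out.loc[0, "frac_gain"] == 0.0
        assert out.loc[0, "frac_loss"] == 0.0

    def test_all_gain_fraction_one(self):
        calls = [CNACall(f"chr1:{j*10000}-{j*10000+100000}", "P1", "gain", 5.0)
                 for j in range(30)]
        peaks = [MergedPeak(GenomicInterval("chr1", 150_000, 151_000), frozenset({"P1"}))]
        out = cna_overlap_summary({"all": peaks}, calls, ["P1"])
        assert out.loc[0, "frac_gain"] == 1.0


class TestEndToEndRecovery:
    def test_injected_segments_recovered(self):
        """copy_ratio >= 2 segments of >= 5 windows give |z| >= 3
        throughout, and gain/loss directions match the injected ratio."""
        cfg = SimConfig(seed=17)
        cfg = dataclasses.replace(cfg, cna_segments=default_cna_segments(cfg))
        sizes = {f"chr{i+1}": cfg.chrom_length for i in range(cfg.n_chrom)}
        windows, reads, lib = simulate_window_read_pairs(cfg, sizes)
        cov, _ = coverage_table(windows, reads, lib.astype(float))
        _l, z = normalize_and_zscore(cov, cfg.normal_samples, cfg.tumor_samples)
        calls = call_cna(z)
        truth = cna_truth_window_sets(windows, cfg.cna_segments)
        states = {(c.sample, c.window_id): c.state for c in calls}
        for seg in cfg.cna_segments:
            want = "gain" if seg.copy_ratio > 1 else "loss"
            full = [
                w for w in windows
                if w.chrom == seg.chrom and w.start >= seg.start and w.end <= seg.end
            ]
            assert len(full) >= 5
            hit = sum(
                states.get((seg.sample, f"{w.chrom}:{w.start}-{w.end}")) == want
                for w in full
            )
            assert hit / len(full) >= 0.9

    def test_merge_call_segments_rebuilds_runs(self):
        calls = [
            CNACall("chr1:0-100000", "P1", "gain", 4.0),
            CNACall("chr1:10000-110000", "P1", "gain", 4.2),
            CNACall("chr1:20000-120000", "P1", "neutral", 0.1),
            CNACall("chr1:500000-600000", "P1", "loss", -3.5),
        ]
        segs = merge_call_segments(calls)
        assert len(segs) == 2
        gain = segs[segs.state == "gain"].iloc[0]
        assert (gain.start, gain.end, gain.n_windows) == (0, 110_000, 2)
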