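"""Signal matrices, quantile normalization, tracks and TSS profiles."""

import numpy as np
import pandas as pd
import pytest

import _oracles as oracle
from epiregulome.intervals import GeneModel, GenomicInterval, MergedPeak
from epiregulome.signal import (
    SignalMatrix,
    build_signal_matrix,
    hierarchical_cluster,
    make_track,
    pairwise_correlation,
    preprocess_expression,
    quantile_normalize,
    select_features,
    tss_profile,
)
from conftest import random_intervals


def _mk(vals, samples=None, ids=None):
    vals = np.asarray(vals, dtype=float)
    samples = samples or [f"s{j}" for j in range(vals.shape[1])]
    ids = ids or [f"f{i}" for i in range(vals.shape[0])]
    return pd.DataFrame(vals, index=ids, columns=samples)


class TestQuantileNormalize:
    def test_sorted_columns_identical_and_idempotent(self):
        rng = np.random.default_rng(0)
        df = _mk(rng.normal(size=(50, 4)))
        qn = quantile_normalize(df)
        ref = np.sort(qn.values[:, 0])
        for j in range(4):
            np.testing.assert_allclose(np.sort(qn.values[:, j]), ref, rtol=0, atol=0)
        pd.testing.assert_frame_equal(quantile_normalize(qn), qn)

    def test_identical_columns_fixed_point(self):
        col = np.arange(10.0)
        df = _mk(np.column_stack([col, col]))
        pd.testing.assert_frame_equal(quantile_normalize(df), df)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 5))
        got = quantile_normalize(_mk(x)).values
        np.testing.assert_allclose(got, oracle.quantile_normalize_naive(x), atol=1e-12)


class TestBuildSignalMatrix:
    def test_ip_equals_input_gives_constant_log_pseudocount(self):
        ip = _mk(np.full((4, 3), 10))
        lib = pd.Series(1e7, index=ip.columns)
        sm = build_signal_matrix(ip, ip.copy(), lib, lib, pseudocount=1.0)
        np.testing.assert_allclose(sm.values.values, 0.0, atol=1e-12)  # log2(1)
        assert sm.stage == "quantile_normalized"

    def test_hand_worked_example(self):
        """5x3 matrix checked against a step-by-step manual computation."""
        ip = _mk([[10, 0, 4], [0, 8, 2], [6, 6, 6], [2, 1, 9], [5, 5, 0]])
        inp = _mk([[1, 1, 1], [1, 1, 1], [2, 2, 2], [0, 0, 0], [5, 0, 5]])
        ip_lib = pd.Series([1e7, 2e7, 5e6], index=ip.columns)
        in_lib = pd.Series([1e7, 1e7, 1e7], index=ip.columns)
        sm = build_signal_matrix(ip, inp, ip_lib, in_lib, pseudocount=1.0)
        # manual: subtract scaled, clamp, log2(x+1), then quantile normalize
        scaled = ip.values * 1e7 / ip_lib.values - inp.values * 1e7 / in_lib.values
        manual = np.log2(np.clip(scaled, 0, None) + 1.0)
        expected = oracle.quantile_normalize_naive(manual)
        np.testing.assert_allclose(sm.values.values, expected, atol=1e-12)

    def test_mismatched_features_rejected(self):
        ip = _mk(np.ones((3, 2)), ids=["a", "b", "c"])
        inp = _mk(np.ones((3, 2)), ids=["a", "b", "X"])
        with pytest.raises(ValueError, match="X"):
            build_signal_matrix(ip, inp, pd.Series(1e7, index=ip.columns),
                                pd.Series(1e7, index=ip.columns))

    def test_monotone_in_ip_count(self):
        rng = np.random.default_rng(2)
        ip = _mk(rng.integers(0, 50, size=(10, 3)))
        inp = _mk(rng.integers(0, 10, size=(10, 3)))
        lib = pd.Series(1e7, index=ip.columns)
        base = build_signal_matrix(ip, inp, lib, lib)
        ip2 = ip.copy()
        ip2.iloc[4, 1] += 100
        bumped = build_signal_matrix(ip2, inp, lib, lib)
        assert bumped.values.iloc[4, 1] >= base.values.iloc[4, 1]


def _peaks_for(ids, support=2, chrom="chr1"):
    out = []
    for i, _ in enumerate(ids):
        iv = GenomicInterval(chrom, 1000 * (i + 1), 1000 * (i + 1) + 500)
        out.append(MergedPeak(iv, frozenset(f"s{k}" for k in range(support))))
    return out


class TestSelectFeatures:
    def test_top_n_exceeding_keeps_all_in_variance_order(self):
        vals = _mk([[0, 0, 10], [1, 1, 1], [0, 5, 5]])
        sm = SignalMatrix(vals, "quantile_normalized", _peaks_for(vals.index))
        out = select_features(sm, min_support=1, top_n=100)
        var = vals.var(axis=1, ddof=1)
        assert list(out.values.index) == list(var.sort_values(ascending=False).index)

    def test_low_support_dropped(self):
        vals = _mk(np.ones((3, 3)))
        feats = _peaks_for(vals.index, support=2)
        feats[1] = MergedPeak(feats[1].interval, frozenset({"s0"}))
        sm = SignalMatrix(vals, "quantile_normalized", feats)
        out = select_features(sm, min_support=2)
        assert len(out.values) == 2

    def test_sex_chromosome_dropped(self):
        vals = _mk(np.ones((2, 3)))
        feats = [
            MergedPeak(GenomicInterval("chr1", 0, 10), frozenset({"a", "b"})),
            MergedPeak(GenomicInterval("chrX", 0, 10), frozenset({"a", "b"})),
        ]
        sm = SignalMatrix(vals, "quantile_normalized", feats)
        out = select_features(sm)
        assert len(out.values) == 1

    def test_matches_variance_sort_oracle(self):
        rng = np.random.default_rng(4)
        vals = _mk(rng.normal(size=(40, 5)))
        sm = SignalMatrix(vals, "quantile_normalized", _peaks_for(vals.index))
        out = select_features(sm, min_support=1, top_n=10)
        var = vals.var(axis=1, ddof=1).values
        expected = [vals.index[i] for i in np.argsort(-var, kind="stable")[:10]]
        assert list(out.values.index) == expected


class TestCorrelationAndClustering:
    def test_duplicated_sample_correlates_one(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=30)
        df = _mk(np.column_stack([a, a, rng.normal(size=30)]))
        c = pairwise_correlation(df)
        assert c.iloc[0, 1] == pytest.approx(1.0)
        assert np.allclose(c.values, c.values.T)
        assert np.all(np.diag(c.values) == 1.0)

    def test_antiproportional_minus_one(self):
        a = np.arange(10.0)
        df = _mk(np.column_stack([a, -2 * a + 3]))
        assert pairwise_correlation(df).iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(100, 6))
        got = pairwise_correlation(_mk(x)).values
        for i in range(6):
            for j in range(6):
                xi, xj = x[:, i] - x[:, i].mean(), x[:, j] - x[:, j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert got[i, j] == pytest.approx(expected, abs=1e-12)

    def test_identical_samples_merge_first(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=30)
        df = _mk(np.column_stack([a, a + rng.normal(scale=1e-6, size=30),
                                  rng.normal(size=30), rng.normal(size=30)]),
                 samples=["dup1", "dup2", "o1", "o2"])
        z, _leaves = hierarchical_cluster(df)
        merged_pair = {int(z[0][0]), int(z[0][1])}
        names = sorted(df.columns)
        assert {names[i] for i in merged_pair} == {"dup1", "dup2"}

    def test_two_separated_groups_form_clades(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=50)
        cols, names = [], []
        for k in range(3):
            cols.append(base + rng.normal(scale=0.1, size=50))
            names.append(f"n{k}")
        for k in range(3):
            cols.append(-base + rng.normal(scale=0.1, size=50))
            names.append(f"t{k}")
        df = _mk(np.column_stack(cols), samples=names)
        _z, leaves = hierarchical_cluster(df)
        half = {s[0] for s in leaves[:3]}
        assert half in ({"n"}, {"t"})

    def test_permutation_invariant_topology(self):
        rng = np.random.default_rng(9)
        df = _mk(rng.normal(size=(30, 5)))
        z1, l1 = hierarchical_cluster(df)
        perm = df[["s3", "s0", "s4", "s1", "s2"]]
        z2, l2 = hierarchical_cluster(perm)
        np.testing.assert_allclose(z1, z2)
        assert l1 == l2


class TestMakeTrack:
    def test_no_reads_all_zero(self):
        tv = make_track([], "chr1", 10_000, 1e6)
        assert tv.values.shape == ((10_000 - 200) // 20 + 1,)
        assert not tv.values.any()

    def test_read_spanning_three_windows(self):
        # read [200, 221) overlaps windows starting 20..220 given width 200
        read = GenomicInterval("chr1", 200, 221)
        tv = make_track([read], "chr1", 2_000, 1e6)
        hit = np.nonzero(tv.values)[0]
        expected = oracle.track_counts_brute([(200, 221)], 2_000, 200, 20)
        np.testing.assert_allclose(tv.values, expected * 1e6 / 1e6)
        assert hit.size > 0

    def test_matches_brute_force_counts(self):
        rng = np.random.default_rng(10)
        reads = [(int(s), int(s + rng.integers(30, 150)))
                 for s in rng.integers(0, 4_800, size=200)]
        ivs = [GenomicInterval("chr1", s, e) for s, e in reads]
        tv = make_track(ivs, "chr1", 5_000, 2e6)
        expected = oracle.track_counts_brute(reads, 5_000, 200, 20) * 1e6 / 2e6
        np.testing.assert_allclose(tv.values, expected)


class TestTssProfile:
    GENE_P = GeneModel("gp", GenomicInterval("chr1", 10_000, 15_000), "+")
    GENE_M = GeneModel("gm", GenomicInterval("chr1", 30_000, 35_000), "-")

    def test_uniform_coverage_flat(self):
        reads = [GenomicInterval("chr1", s, s + 40) for s in range(7_000, 18_000, 40)]
        prof = tss_profile(reads, [self.GENE_P], 1e6)
        assert prof.std() / prof.mean() < 0.05

    def test_minus_strand_mirroring(self):
        """Signal genomically right of a minus-strand TSS is upstream."""
        tss = self.GENE_M.tss  # 34_999
        reads = [GenomicInterval("chr1", tss + 500, tss + 600)] * 5
        prof = tss_profile(reads, [self.GENE_M], 1e6)
        n = len(prof)
        assert prof[: n // 2].sum() > 0  # upstream half
        assert prof[n // 2:].sum() == 0

    def test_linearity(self):
        rng = np.random.default_rng(11)
        r1 = [GenomicInterval("chr1", int(s), int(s) + 80)
              for s in rng.integers(8_000, 12_000, 50)]
        r2 = [GenomicInterval("chr1", int(s), int(s) + 80)
              for s in rng.integers(9_000, 13_000, 50)]
        p1 = tss_profile(r1, [self.GENE_P], 1e6)
        p2 = tss_profile(r2, [self.GENE_P], 1e6)
        p12 = tss_profile(r1 + r2, [self.GENE_P], 1e6)
        np.testing.assert_allclose(p12, p1 + p2, atol=1e-9)

    def test_promoter_enriched_signal_peaks_at_tss(self):
        rng = np.random.default_rng(12)
        tss = self.GENE_P.tss
        centers = rng.normal(tss, 150, size=400).astype(int)
        reads = [GenomicInterval("chr1", c - 50, c + 50) for c in centers]
        prof = tss_profile(reads, [self.GENE_P], 1e6)
        peak_bin = int(np.argmax(prof))
        n = len(prof)
        assert abs(peak_bin - n // 2) <= 5  # within +/- 200 bp of TSS


def test_preprocess_expression_filters_and_normalizes():
    rng = np.random.default_rng(13)
    vals = _mk(np.abs(rng.normal(2, 1, size=(50, 4))))
    vals.iloc[0] = 0.01  # below RPKM floor everywhere
    chroms = {g: ("chrX" if i == 1 else "chr1") for i, g in enumerate(vals.index)}
    out = preprocess_expression(vals, gene_chroms=chroms, min_rpkm=0.5, top_n=10)
    assert "f0" not in out.index and "f1" not in out.index
    assert len(out) == 10
    assert np.isfinite(out.values).all()
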