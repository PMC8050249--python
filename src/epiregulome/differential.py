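"""Negative-binomial differential testing for expression and occupancy.

Implements the classic small-sample count workflow: TMM between-library
normalization, a single common NB dispersion estimated by conditional
maximum likelihood on library-size-equalized pseudocounts, and a
two-sided exact-style test on the conditional distribution of one
group's sum given the total.  The NB is parameterized mean-dispersion,
``var = mu + phi * mu**2``; ``phi = 0`` is the Poisson limit.

Thresholding follows the study design this pipeline reproduces:
features are called differential at FDR <= 0.05 (Benjamini-Hochberg)
and an absolute fold-change of at least 3 (expression) or 2 (peak
occupancy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "rpkm",
    "tmm_factors",
    "equalize_lib_sizes",
    "common_dispersion",
    "nb_exact_test",
    "call_differential",
    "run_differential",
]

UP_IN_TUMOR = "up_in_tumor"
UP_IN_NORMAL = "up_in_normal"
NS = "ns"


@dataclass
class CountMatrix:
    """Feature x sample counts with group labels and library sizes.

    ``lib_sizes`` defaults to column sums.  ``lengths`` (bp) is only
    needed for RPKM on genes.
    """

    counts: pd.DataFrame
    groups: Mapping[str, str]
    lib_sizes: pd.Series | None = None
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        labels = set(self.groups[s] for s in self.counts.columns)
        if len(labels) != 2:
            raise ValueError(f"need exactly 2 groups, got {sorted(labels)}")


def rpkm(
    counts: pd.DataFrame, lengths: pd.Series, lib_sizes: pd.Series
) -> pd.DataFrame:
    """Reads per kilobase of feature per million mapped reads:
    ``count * 1e9 / (length * lib_size)``."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing lengths for some features")
    lib = lib_sizes.reindex(counts.columns).astype(float)
    return counts.div(lengths, axis=0).div(lib, axis=1) * 1e9


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    logratio_trim: float = 0.30, abs_trim: float = 0.05,
) -> float:
    """Trimmed mean of M-values of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    if keep.sum() == 0:
        return 1.0
    o, r = obs[keep], ref[keep]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # delta-method asymptotic variance of M, used as inverse weight;
    # floored to keep weights finite when a feature exhausts its library
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    v = np.maximum(v, 1e-12)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[finite], a[finite], v[finite]
    if m.size == 0:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep2.sum() == 0 or np.sum(1.0 / v[keep2]) == 0:
        return 1.0
    w = 1.0 / v[keep2]
    f = np.sum(w * m[keep2]) / np.sum(w)
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame, lib_sizes: pd.Series | None = None
) -> pd.Series:
    """Per-sample TMM scaling factors, normalized to geometric mean 1.

    The reference sample is the one whose 75th count percentile (scaled
    by library size) is closest to the mean across samples.  Log-ratios
    are trimmed by 30% and absolute intensities by 5% before the
    precision-weighted mean.
    """
    x = counts.values.astype(float)
    if lib_sizes is None:
        lib = x.sum(axis=0)
    else:
        lib = lib_sizes.reindex(counts.columns).values.astype(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    uq = np.array([
        np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])
    ])
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array([
        1.0 if j == ref_j else _tmm_pair(x[:, j], x[:, ref_j], lib[j], lib[ref_j])
        for j in range(x.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _q2q_nbinom(
    x: np.ndarray, input_mean: np.ndarray, output_mean: np.ndarray, phi: float
) -> np.ndarray:
    """Quantile-to-quantile mapping of counts between NB distributions.

    Maps observed counts with per-sample means to the equivalent
    quantiles at a common library size, averaging a normal and a gamma
    continuous approximation of the NB.
    """
    eps = 1e-14
    input_mean = np.maximum(np.asarray(input_mean, float), eps)
    output_mean = np.maximum(np.asarray(output_mean, float), eps)
    ri = 1.0 + phi * input_mean
    ro = 1.0 + phi * output_mean
    # normal approximation: match mean and variance
    q1 = output_mean + np.sqrt(output_mean * ro / (input_mean * ri)) * (x - input_mean)
    # gamma approximation: match via shape = mean/(1+phi*mean)
    shape_i = input_mean / ri
    shape_o = output_mean / ro
    with np.errstate(invalid="ignore"):
        p = stats.gamma.cdf(x, a=shape_i, scale=ri)
        q2 = stats.gamma.ppf(p, a=shape_o, scale=ro)
    q2 = np.where(np.isfinite(q2), q2, q1)
    return np.maximum((q1 + q2) / 2.0, 0.0)


def equalize_lib_sizes(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    lib_sizes: pd.Series,
    factors: pd.Series,
    phi: float = 0.01,
) -> tuple[pd.DataFrame, float]:
    """Pseudocounts adjusted to a common (geometric-mean) library size.

    Effective library size = raw size x TMM factor; per-feature expected
    proportions are estimated within each group.
    """
    eff = lib_sizes.reindex(counts.columns).values * factors.reindex(counts.columns).values
    common = float(np.exp(np.mean(np.log(eff))))
    x = counts.values.astype(float)
    pseudo = np.zeros_like(x)
    cols = list(counts.columns)
    labels = np.array([groups[s] for s in cols])
    for g in np.unique(labels):
        j = np.where(labels == g)[0]
        prop = x[:, j].sum(axis=1) / eff[j].sum()  # feature proportion in group
        for jj in j:
            pseudo[:, jj] = _q2q_nbinom(
                x[:, jj], prop * eff[jj], prop * common, phi
            )
    return pd.DataFrame(pseudo, index=counts.index, columns=counts.columns), common


def _cond_loglik(
    pseudo: np.ndarray, group_cols: Sequence[np.ndarray], r: float
) -> float:
    """Summed conditional NB log-likelihood at size parameter r = 1/phi.

    For a feature with counts y_1..y_n in one group (equal library
    sizes) and total z, the conditional likelihood of the counts given z
    is free of the mean:
    sum_i lgamma(y_i + r) + lgamma(n r) - lgamma(z + n r) - n lgamma(r).
    """
    ll = 0.0
    for j in group_cols:
        y = pseudo[:, j]
        n = len(j)
        z = y.sum(axis=1)
        ll += float(
            np.sum(special.gammaln(y + r))
            + len(z) * special.gammaln(n * r)
            - np.sum(special.gammaln(z + n * r))
            - len(z) * n * special.gammaln(r)
        )
    return ll


def common_dispersion(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    lib_sizes: pd.Series | None = None,
    factors: pd.Series | None = None,
    tol: float = 1e-6,
) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    Counts are first equalized to a common library size (TMM-scaled
    pseudocounts); the conditional log-likelihood, summed over features
    and groups, is maximized over delta = phi/(1 + phi) by bounded
    scalar optimization.  Returns phi >= 0 (0 = Poisson limit).
    """
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0).astype(float)
    if factors is None:
        factors = tmm_factors(counts, lib_sizes)
    cols = list(counts.columns)
    labels = np.array([groups[s] for s in cols])
    group_cols = [np.where(labels == g)[0] for g in np.unique(labels)]

    phi_work = 0.01
    for _ in range(2):  # one refinement pass with the current estimate
        pseudo, _common = equalize_lib_sizes(counts, groups, lib_sizes, factors, phi_work)
        p = pseudo.values

        def neg_ll(delta: float) -> float:
            phi = delta / (1.0 - delta)
            r = 1.0 / max(phi, 1e-10)
            return -_cond_loglik(p, group_cols, r)

        res = optimize.minimize_scalar(
            neg_ll, bounds=(1e-6, 0.95), method="bounded",
            options={"xatol": tol},
        )
        delta = float(res.x)
        phi = delta / (1.0 - delta)
        # accept the boundary as (near-)Poisson
        if neg_ll(1e-6) <= res.fun:
            phi = 0.0
        phi_work = max(phi, 1e-4)
    return phi


def nb_exact_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    phi: float,
    factors: pd.Series | None = None,
    lib_sizes: pd.Series | None = None,
) -> pd.Series:
    """Two-sided exact-style NB p-values per feature.

    On library-size-equalized pseudocounts, each feature's group sums
    s1, s2 (rounded) are compared under the null that both groups share
    a common mean: the double-tail p-value sums, over the conditional
    support {0..s}, the probabilities of outcomes no more likely than
    the observed split, normalized by the total.  Sums of n iid NB with
    equal means are NB with size n/phi.  p in (0, 1].
    """
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0).astype(float)
    if factors is None:
        factors = tmm_factors(counts, lib_sizes)
    pseudo, _common = equalize_lib_sizes(
        counts, groups, lib_sizes, factors, max(phi, 1e-4)
    )
    cols = list(counts.columns)
    labels = np.array([groups[s] for s in cols])
    gnames = sorted(set(labels))
    j1 = np.where(labels == gnames[0])[0]
    j2 = np.where(labels == gnames[1])[0]
    n1, n2 = len(j1), len(j2)

    s1 = np.round(pseudo.values[:, j1].sum(axis=1)).astype(np.int64)
    s2 = np.round(pseudo.values[:, j2].sum(axis=1)).astype(np.int64)
    pvals = np.ones(len(s1))
    for i in range(len(s1)):
        pvals[i] = _double_tail_p(int(s1[i]), int(s2[i]), n1, n2, phi)
    return pd.Series(pvals, index=counts.index, name="pvalue")


def _double_tail_p(s1: int, s2: int, n1: int, n2: int, phi: float) -> float:
    s = s1 + s2
    if s == 0:
        return 1.0
    mu = s / (n1 + n2)
    mu1, mu2 = n1 * mu, n2 * mu
    x = np.arange(s + 1)
    if phi > 0:
        r1, r2 = n1 / phi, n2 / phi
        lp = (stats.nbinom.logpmf(x, r1, r1 / (r1 + mu1))
              + stats.nbinom.logpmf(s - x, r2, r2 / (r2 + mu2)))
    else:
        lp = stats.poisson.logpmf(x, mu1) + stats.poisson.logpmf(s - x, mu2)
    lp_obs = lp[s1]
    m = lp.max()
    p_all = np.exp(lp - m)
    keep = lp <= lp_obs + 1e-10
    p = p_all[keep].sum() / p_all.sum()
    return float(min(1.0, max(p, 1e-300)))


def _group_log2fc(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    lib_sizes: pd.Series,
    factors: pd.Series,
    tumor_label: str = "tumor",
) -> pd.Series:
    """log2 fold-change tumor vs normal from pseudocount-stabilized,
    effective-library-normalized group means (prior 0.5 per million)."""
    eff = lib_sizes.reindex(counts.columns) * factors.reindex(counts.columns)
    cpm = counts.div(eff, axis=1) * 1e6
    labels = pd.Series({s: groups[s] for s in counts.columns})
    tumor_cols = labels.index[labels == tumor_label]
    normal_cols = labels.index[labels != tumor_label]
    mt = cpm[tumor_cols].mean(axis=1) + 0.5
    mn = cpm[normal_cols].mean(axis=1) + 0.5
    return np.log2(mt / mn).rename("log2FC")


def call_differential(
    results: pd.DataFrame, fdr_max: float = 0.05, min_fc: float = 2.0
) -> pd.DataFrame:
    """Assign direction from FDR and fold-change thresholds.

    A feature is directional only when FDR <= fdr_max AND
    ``2**|log2FC| >= min_fc``; otherwise 'ns'.
    """
    out = results.copy()
    sig = (out["fdr"] <= fdr_max) & (2.0 ** out["log2FC"].abs() >= min_fc)
    out["direction"] = NS
    out.loc[sig & (out["log2FC"] > 0), "direction"] = UP_IN_TUMOR
    out.loc[sig & (out["log2FC"] < 0), "direction"] = UP_IN_NORMAL
    return out


def run_differential(
    cm: CountMatrix,
    fdr_max: float = 0.05,
    min_fc: float = 2.0,
    tumor_label: str = "tumor",
) -> pd.DataFrame:
    """Full pipeline: filter, TMM, common dispersion, exact test, BH, calls.

    Features with zero counts in all libraries are excluded before
    testing.  Returns a feature-indexed frame with log2FC (tumor vs
    normal), pvalue, fdr and direction; excluded features are absent.
    """
    counts = cm.counts.loc[cm.counts.sum(axis=1) > 0]
    factors = tmm_factors(counts, cm.lib_sizes)
    phi = common_dispersion(counts, cm.groups, cm.lib_sizes, factors)
    pvals = nb_exact_test(counts, cm.groups, phi, factors, cm.lib_sizes)
    fdr = pd.Series(
        multipletests(pvals.values, method="fdr_bh")[1],
        index=pvals.index, name="fdr",
    )
    lfc = _group_log2fc(counts, cm.groups, cm.lib_sizes, factors, tumor_label)
    res = pd.DataFrame({"log2FC": lfc, "pvalue": pvals, "fdr": fdr})
    res.attrs["common_dispersion"] = phi
    res.attrs["tmm_factors"] = factors.to_dict()
    return call_differential(res, fdr_max=fdr_max, min_fc=min_fc)
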