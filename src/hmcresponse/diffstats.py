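"""Normalization and differential testing for count matrices.

Covers median-of-ratios size factors, TPM, a regularized-log
approximation, a negative-binomial Wald test for two-group contrasts,
Benjamini-Hochberg adjustment, the inclusive DEG filter
(padj <= 0.1 and |log2FC| >= 0.5) and the strict per-patient DhMG filter
(raw p < 0.01 and |log2FC| >= 0.5), plus the basic two-sample tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix

__all__ = [
    "DifferentialResult",
    "size_factors",
    "tpm",
    "rlog_approx",
    "nb_wald_test",
    "bh_adjust",
    "filter_degs",
    "filter_dhmgs",
    "basic_tests",
]

DEG_PADJ_MAX = 0.1
DEG_LFC_MIN = 0.5
DHMG_P_MAX = 0.01          # strict inequality on raw p
DHMG_LFC_MIN = 0.5


@dataclass
class DifferentialResult:
    """Per-gene differential-test output.

    ``table`` has columns log2_fc, se, p, padj, mean_expr, passes_deg,
    passes_dhmg, indexed by gene id.  Fold changes are group B over
    group A.
    """

    table: pd.DataFrame
    group_a: list[str]
    group_b: list[str]

    @property
    def genes(self) -> pd.Index:
        return self.table.index


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    Uses genes with nonzero counts in every sample: factor_j is the
    median over those genes of count_gj divided by the gene's geometric
    mean across samples.
    """
    mat = counts.values.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; filter samples or "
            "use a pseudo-reference fallback")
    sub = mat[all_nonzero]
    geo_mean = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geo_mean[:, None], axis=0)
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def tpm(counts: CountMatrix, lengths_kb: pd.Series) -> CountMatrix:
    """Transcripts-per-million normalization from raw counts and lengths (kb)."""
    missing = counts.gene_ids.difference(lengths_kb.index)
    if len(missing):
        raise ValueError(f"missing gene length for: {', '.join(map(str, missing[:5]))}")
    lens = lengths_kb.loc[counts.gene_ids].to_numpy(dtype=float)
    rate = counts.values.to_numpy(dtype=float) / lens[:, None]
    col_sums = rate.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    out = 1e6 * rate / col_sums
    return CountMatrix(pd.DataFrame(out, index=counts.gene_ids,
                                    columns=counts.sample_ids), state="tpm")


def rlog_approx(counts: CountMatrix,
                factors: pd.Series | None = None) -> CountMatrix:
    """log2(count / size_factor + 1), a light stand-in for the regularized log.

    Unlike the full regularized-log transform it applies no shrinkage of
    low-count genes toward the fitted trend; at the sequencing depths the
    pipeline targets the two agree closely for moderately expressed genes.
    """
    if factors is None:
        factors = size_factors(counts)
    norm = counts.values.to_numpy(dtype=float) / factors.loc[counts.sample_ids].to_numpy()
    out = np.log2(norm + 1.0)
    return CountMatrix(pd.DataFrame(out, index=counts.gene_ids,
                                    columns=counts.sample_ids), state="rlog-approx")


def _dispersion_estimates(norm: np.ndarray, groups: list[np.ndarray],
                          inv_sf_mean: float) -> np.ndarray:
    """Gene-wise method-of-moments dispersion, shrunk toward a log-mean trend.

    The gene-wise estimate solves Var(y/s) ~= mu * mean(1/s) + d * mu^2 from
    the pooled within-group variance; it is then shrunk 50/50 (in log space)
    toward an ordinary least-squares trend of log dispersion on log mean.
    """
    n_total = sum(g.size for g in groups)
    pooled_ss = np.zeros(norm.shape[0])
    for g in groups:
        sub = norm[:, g]
        pooled_ss += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
    pooled_var = pooled_ss / (n_total - len(groups))
    mean_all = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_gene = (pooled_var - mean_all * inv_sf_mean) / mean_all**2
    d_gene = np.where(np.isfinite(d_gene), d_gene, 0.0)
    d_floor = 1e-8
    d_gene = np.maximum(d_gene, d_floor)

    usable = (mean_all > 0) & (d_gene > d_floor)
    if usable.sum() >= 10:
        x = np.log(mean_all[usable])
        y = np.log(d_gene[usable])
        slope, intercept = np.polyfit(x, y, 1)
        with np.errstate(divide="ignore"):
            d_trend = np.exp(intercept + slope * np.log(np.maximum(mean_all, 1e-8)))
    else:
        d_trend = np.full_like(d_gene, np.exp(np.mean(np.log(d_gene))))
    d_trend = np.maximum(d_trend, d_floor)
    return np.exp(0.5 * np.log(d_gene) + 0.5 * np.log(d_trend))


def nb_wald_test(counts: CountMatrix, group_a: Sequence[str],
                 group_b: Sequence[str]) -> DifferentialResult:
    """Negative-binomial Wald test of group B versus group A.

    Counts are normalized by median-of-ratios size factors; per-gene group
    means are compared on the log scale with a delta-method standard error
    combining Poisson and overdispersion variance, using a moment-based
    dispersion shrunk toward a mean-dispersion trend.  Genes with zero
    counts in every sample are dropped (logged).
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    for name, g in (("A", group_a), ("B", group_b)):
        if len(g) < 2:
            raise ValueError(f"group {name} has fewer than 2 samples")

    sub = counts.subset_samples(group_a + group_b)
    nonzero = (sub.values.to_numpy() > 0).any(axis=1)
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} all-zero genes before testing")
    mat = sub.values.loc[nonzero]
    sf = size_factors(CountMatrix(mat, state="raw"))
    norm = mat.to_numpy(dtype=float) / sf.to_numpy()

    na, nb = len(group_a), len(group_b)
    idx_a = np.arange(na)
    idx_b = np.arange(na, na + nb)
    sf_arr = sf.to_numpy()
    inv_sf_mean = float(np.mean(1.0 / sf_arr))

    disp = _dispersion_estimates(norm, [idx_a, idx_b], inv_sf_mean)

    # half-a-count continuity on the group mean scale keeps lfc/se finite
    pc_a = 0.5 * np.mean(1.0 / sf_arr[idx_a]) / na
    pc_b = 0.5 * np.mean(1.0 / sf_arr[idx_b]) / nb
    mean_a = norm[:, idx_a].mean(axis=1) + pc_a
    mean_b = norm[:, idx_b].mean(axis=1) + pc_b

    # Var(log mean) by the delta method: (1/n^2) sum_j (1/(m s_j) + d)
    inv_sf_sum_a = float((1.0 / sf_arr[idx_a]).sum())
    inv_sf_sum_b = float((1.0 / sf_arr[idx_b]).sum())
    var_log_a = (inv_sf_sum_a / mean_a + na * disp) / na**2
    var_log_b = (inv_sf_sum_b / mean_b + nb * disp) / nb**2
    se_ln = np.sqrt(var_log_a + var_log_b)

    lfc = np.log2(mean_b / mean_a)
    se_log2 = se_ln / np.log(2)
    z = np.log(mean_b / mean_a) / se_ln
    identical = np.array_equal(mat.to_numpy()[:, idx_a], mat.to_numpy()[:, idx_b]) \
        and na == nb
    df = na + nb - 2
    p = 2.0 * stats.t.sf(np.abs(z), df=df)

    table = pd.DataFrame({
        "log2_fc": lfc,
        "se": se_log2,
        "p": np.clip(p, 0.0, 1.0),
        "mean_expr": norm.mean(axis=1),
    }, index=mat.index)
    if identical:
        table["log2_fc"] = 0.0
        table["p"] = 1.0
    table["padj"] = bh_adjust(table["p"].to_numpy())
    table["passes_deg"] = ((table["padj"] <= DEG_PADJ_MAX)
                           & (table["log2_fc"].abs() >= DEG_LFC_MIN))
    table["passes_dhmg"] = ((table["p"] < DHMG_P_MAX)
                            & (table["log2_fc"].abs() >= DHMG_LFC_MIN))
    return DifferentialResult(table, group_a, group_b)


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def filter_degs(result: DifferentialResult) -> dict[str, list[str]]:
    """Differentially expressed genes: padj <= 0.1 and |log2FC| >= 0.5.

    Both thresholds inclusive.  Returns up/down/all gene lists (direction
    is the sign of the B-over-A fold change).
    """
    t = result.table
    mask = (t["padj"] <= DEG_PADJ_MAX) & (t["log2_fc"].abs() >= DEG_LFC_MIN)
    up = t.index[mask & (t["log2_fc"] > 0)].tolist()
    down = t.index[mask & (t["log2_fc"] < 0)].tolist()
    return {"up": up, "down": down, "all": t.index[mask].tolist()}


def filter_dhmgs(result: DifferentialResult) -> list[str]:
    """Differentially hydroxymethylated genes: raw p < 0.01 (strict) and
    |log2FC| >= 0.5."""
    t = result.table
    mask = (t["p"] < DHMG_P_MAX) & (t["log2_fc"].abs() >= DHMG_LFC_MIN)
    return t.index[mask].tolist()


def basic_tests(a: Sequence[float], b: Sequence[float],
                kind: str = "t_unpaired") -> tuple[float, float]:
    """Two-sided two-sample tests: unpaired t, paired t, or Wilcoxon rank-sum.

    The rank-sum test uses exact enumeration for group sizes <= 25 (no
    ties required), otherwise the tie-corrected normal approximation.
    Returns (statistic, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if kind == "t_unpaired":
        res = stats.ttest_ind(a, b)
        return float(res.statistic), float(res.pvalue)
    if kind == "t_paired":
        if a.size != b.size:
            raise ValueError("paired test requires equal-length vectors")
        if np.array_equal(a, b):
            return 0.0, 1.0
        res = stats.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue)
    if kind == "wilcoxon_ranksum":
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            return float(a.size * b.size / 2.0), 1.0
        has_ties = np.unique(pooled).size < pooled.size
        small = a.size <= 25 and b.size <= 25
        method = "exact" if (small and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test kind {kind!r}")
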