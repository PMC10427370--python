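"""Gene-set enrichment: preranked GSEA, per-sample set scores, and
coefficient-weighted signature scores.

The preranked statistic is the weighted Kolmogorov-Smirnov running sum:
hits increment in proportion to |stat|^weight_exponent, misses decrement
uniformly; the enrichment score (ES) is the maximum deviation from zero.
Significance comes from gene-label permutations; NES divides ES by the
mean |null ES| of matching sign.

The per-sample score is a rank statistic — (mean rank of set genes minus
mean rank of the complement) / N within each sample — a transparent
single-sample analogue of GSVA-style scoring that is invariant to any
monotone transform of a sample's expression values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "make_ranking",
    "preranked_gsea",
    "sample_set_score",
    "weighted_signature_score",
    "paired_day_comparison",
]


@dataclass
class RankedList:
    """Genes ordered by a ranking statistic, descending, ties broken by id."""

    stats: pd.Series

    def __post_init__(self) -> None:
        s = self.stats
        if s.index.duplicated().any():
            raise ValueError("ranking contains duplicate genes")
        order = sorted(range(len(s)), key=lambda i: (-s.iloc[i], s.index[i]))
        self.stats = s.iloc[order]

    @property
    def genes(self) -> pd.Index:
        return self.stats.index

    def __len__(self) -> int:
        return len(self.stats)


def make_ranking(table: pd.DataFrame, by: str = "log2_fc") -> RankedList:
    """Build a ranked list from a differential-result table column."""
    return RankedList(table[by].copy())


@dataclass
class EnrichmentResult:
    es: float
    nes: float
    p: float
    core_enrichment: list[str]
    n_perm: int

    @property
    def padj(self) -> float:  # single-set runs carry no family; caller adjusts
        return self.p


def _running_es(stat_values: np.ndarray, hit_mask: np.ndarray,
                weight_exponent: float) -> tuple[float, int]:
    """ES (signed max deviation) and the index where it is attained."""
    n = stat_values.size
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must hit a strict subset of the ranking")
    w = np.abs(stat_values) ** weight_exponent
    w_hit = np.where(hit_mask, w, 0.0)
    total = w_hit.sum()
    if total == 0:           # all hit weights zero: fall back to unweighted
        w_hit = hit_mask.astype(float)
        total = w_hit.sum()
    inc = w_hit / total
    dec = np.where(hit_mask, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(inc - dec)
    i_max = int(np.argmax(np.abs(running)))
    return float(running[i_max]), i_max


def preranked_gsea(ranking: RankedList, gene_set: list[str],
                   n_perm: int = 1000, weight_exponent: float = 1.0,
                   seed: int = 0) -> EnrichmentResult:
    """Preranked GSEA of one gene set against a ranked list.

    Null distribution from gene-label permutations (random sets of the
    same size); two-sided p from the sign-matched tail with resolution
    1/(n_perm + 1); NES = ES / mean(|null ES| of same sign).
    """
    genes = ranking.genes
    members = set(gene_set) & set(genes)
    if not members:
        raise ValueError("gene set does not intersect the ranking")
    values = ranking.stats.to_numpy(dtype=float)
    hit = np.asarray(genes.isin(members))
    es, i_max = _running_es(values, hit, weight_exponent)

    rng = np.random.default_rng(seed)
    n, k = len(genes), int(hit.sum())
    null_es = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        null_es[b], _ = _running_es(values, mask, weight_exponent)

    same_sign = null_es * np.sign(es) > 0
    if same_sign.any():
        denom = np.abs(null_es[same_sign]).mean()
        n_tail = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
        p = (n_tail + 1) / (int(same_sign.sum()) + 1)
    else:
        denom, p = np.nan, 1.0 / (n_perm + 1)
    nes = es / denom if denom and np.isfinite(denom) else np.sign(es) * np.inf

    if es >= 0:
        core = [g for g, h in zip(genes[:i_max + 1], hit[:i_max + 1]) if h]
    else:
        core = [g for g, h in zip(genes[i_max:], hit[i_max:]) if h]
    return EnrichmentResult(es=es, nes=float(nes), p=float(p),
                            core_enrichment=core, n_perm=n_perm)


def sample_set_score(expr: CountMatrix, gene_set: list[str]) -> pd.Series:
    """Per-sample rank-based set score on log-scale expression.

    score_s = (mean within-sample rank of set genes - mean rank of the
    complement) / N.  Higher means the set sits higher in that sample's
    expression ranking.
    """
    genes = expr.gene_ids
    members = np.asarray(genes.isin(set(gene_set)))
    if members.sum() == 0:
        raise ValueError("gene set shares no genes with the matrix")
    if members.all():
        raise ValueError("gene set covers every gene (no complement)")
    mat = expr.values.to_numpy(dtype=float)
    ranks = stats.rankdata(mat, axis=0)
    n = mat.shape[0]
    score = (ranks[members].mean(axis=0) - ranks[~members].mean(axis=0)) / n
    return pd.Series(score, index=expr.sample_ids, name="set_score")


def weighted_signature_score(tpm: CountMatrix, weights: pd.Series,
                             min_present: float = 0.8) -> pd.Series:
    """Coefficient-weighted sum of log2(TPM + 1), e.g. the LSC17 score."""
    present = weights.index.intersection(tpm.gene_ids)
    if len(present) == 0:
        raise ValueError("no weighted genes present in the matrix")
    if len(present) < min_present * len(weights):
        warnings.warn(
            f"only {len(present)}/{len(weights)} weighted genes present; "
            "missing genes contribute 0")
    log_expr = np.log2(tpm.values.loc[present].to_numpy(dtype=float) + 1.0)
    score = weights.loc[present].to_numpy() @ log_expr
    return pd.Series(score, index=tpm.sample_ids, name="signature_score")


def paired_day_comparison(scores_day0: pd.Series, scores_day5: pd.Series
                          ) -> tuple[float, float, int]:
    """Two-sided paired t-test of Day5 vs Day0 per-patient scores.

    Inputs are indexed by patient; unpaired entries are ignored with a
    logged count.  Returns (t statistic, p, n_pairs).
    """
    common = scores_day0.index.intersection(scores_day5.index)
    dropped = (len(scores_day0) - len(common)) + (len(scores_day5) - len(common))
    if dropped:
        warnings.warn(f"ignoring {dropped} unpaired score(s)")
    if len(common) < 3:
        raise ValueError(f"need >= 3 complete pairs, have {len(common)}")
    a = scores_day5.loc[common].to_numpy(dtype=float)
    b = scores_day0.loc[common].to_numpy(dtype=float)
    if np.array_equal(a, b):
        return 0.0, 1.0, len(common)
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), len(common)
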