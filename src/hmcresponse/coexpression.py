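"""Co-expression module detection among differential genes, plus network
extension with a user-supplied interaction edge list."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .io import CountMatrix

__all__ = [
    "ModuleAssignment",
    "pairwise_correlation",
    "cluster_modules",
    "extend_module",
    "read_edges",
]


@dataclass
class ModuleAssignment:
    """Gene -> module id (1..k) with per-module mean intra-correlation."""

    modules: pd.Series
    intra_correlation: pd.Series
    linkage_method: str = "average"

    @property
    def k(self) -> int:
        return int(self.modules.max())

    def genes_in(self, module_id: int) -> list[str]:
        return self.modules.index[self.modules == module_id].tolist()


def pairwise_correlation(expr: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between every pair of gene rows.

    Expression should be on a variance-stabilized log scale.  Genes with
    zero variance across samples are dropped with a warning (their
    correlation is undefined).
    """
    df = expr.values if isinstance(expr, CountMatrix) else expr
    if df.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlations")
    if df.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    var = df.to_numpy(dtype=float).var(axis=1)
    keep = var > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance gene(s)")
    sub = df.loc[keep]
    corr = np.corrcoef(sub.to_numpy(dtype=float))
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=sub.index, columns=sub.index)


def cluster_modules(corr: pd.DataFrame, k: int = 4,
                    method: str = "average") -> ModuleAssignment:
    """Agglomerative clustering of correlation-matrix rows into k modules.

    Euclidean distance between rows of the correlation matrix; the tree is
    cut at k clusters.  Deterministic.  Module ids are relabelled 1..k in
    order of first appearance.
    """
    n = corr.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} genes")
    if k == n:
        labels = np.arange(1, n + 1)
    else:
        Z = linkage(corr.to_numpy(dtype=float), method=method,
                    metric="euclidean")
        labels = fcluster(Z, t=k, criterion="maxclust")
    # stable relabelling by first appearance
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        out[i] = remap.setdefault(int(lab), len(remap) + 1)
    modules = pd.Series(out, index=corr.index, name="module")

    intra = {}
    arr = corr.to_numpy(dtype=float)
    for mod in sorted(set(out)):
        idx = np.where(out == mod)[0]
        if len(idx) == 1:
            intra[mod] = 1.0
        else:
            block = arr[np.ix_(idx, idx)]
            off = block[~np.eye(len(idx), dtype=bool)]
            intra[mod] = float(off.mean())
    return ModuleAssignment(modules, pd.Series(intra, name="intra_correlation"),
                            linkage_method=method)


def read_edges(path) -> pd.DataFrame:
    """Read an interaction edge list: two gene-id columns (extra cols ignored)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("edge list needs two gene-id columns")
    df = df.iloc[:, :2]
    df.columns = ["gene_a", "gene_b"]
    return df


def extend_module(module_genes: list[str], edges: pd.DataFrame | None,
                  expr_tpm: CountMatrix, tpm_floor: float = 3.0
                  ) -> dict[str, list[str]]:
    """Add first-order interaction neighbors with mean TPM strictly above
    the floor (default 3).

    Returns {"core": ..., "added": ..., "all": ...}; monotone in the edge
    list — adding edges can only add genes.
    """
    core = list(dict.fromkeys(module_genes))
    if edges is None or len(edges) == 0:
        if edges is None:
            warnings.warn("no edge list supplied; module returned unchanged")
        return {"core": core, "added": [], "all": core}
    if expr_tpm.state != "tpm":
        raise ValueError("expression must be TPM-normalized for the floor rule")
    in_module = set(core)
    neighbors: set[str] = set()
    for a, b in edges.itertuples(index=False):
        if a in in_module and b not in in_module:
            neighbors.add(b)
        if b in in_module and a not in in_module:
            neighbors.add(a)
    mean_tpm = expr_tpm.values.mean(axis=1)
    added = sorted(g for g in neighbors
                   if g in mean_tpm.index and mean_tpm[g] > tpm_floor)
    return {"core": core, "added": added, "all": core + added}
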