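"""Digital cytometry: signature building and bulk fraction estimation.

A signature matrix of marker genes is derived from per-cell-type reference
expression profiles; bulk TPM profiles are then decomposed by non-negative
least squares (linear mixing in TPM space, no log transform), and the
inferred weights are rescaled to proportions.  Malignant and immune
compartments are additionally renormalized to sum to 1 each, matching how
relative-mode fractions are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io import CountMatrix, SampleSheet
from .synthetic import IMMUNE_TYPES, MALIGNANT_TYPES

__all__ = [
    "SignatureMatrix",
    "FractionEstimate",
    "build_signature",
    "estimate_fractions",
    "compartment_normalize",
    "average_tissues",
]


@dataclass
class SignatureMatrix:
    """Signature genes x cell types, with a compartment map."""

    values: pd.DataFrame
    compartments: dict[str, str] = field(default_factory=dict)
    condition_number: float = float("nan")

    def __post_init__(self) -> None:
        if not self.compartments:
            self.compartments = {
                t: ("malignant" if t in MALIGNANT_TYPES else "immune")
                for t in self.values.columns}

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    def types_in(self, compartment: str) -> list[str]:
        return [t for t in self.cell_types
                if self.compartments.get(t) == compartment]


@dataclass
class FractionEstimate:
    """Per-sample cell-type proportions plus fit residuals."""

    fractions: pd.DataFrame          # samples x cell types, rows sum to 1
    residual_norm: pd.Series
    malignant: pd.DataFrame | None = None
    immune: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> pd.Index:
        return self.fractions.index


def build_signature(reference: pd.DataFrame, markers_per_type: int = 50,
                    compartments: dict[str, str] | None = None
                    ) -> SignatureMatrix:
    """Select per-type marker genes by fold over the max of the other types.

    For each cell type the ``markers_per_type`` genes with the largest
    ratio of that type's expression to the maximum across all other types
    are chosen; the union of the selections forms the signature rows.
    """
    types = list(reference.columns)
    arr = reference.to_numpy(dtype=float)
    chosen: set[str] = set()
    for i, t in enumerate(types):
        others = np.delete(arr, i, axis=1).max(axis=1)
        fold = arr[:, i] / np.maximum(others, 1e-12)
        if (fold <= 1.0).all():
            raise ValueError(f"cell type {t!r} has no discriminating genes")
        order = np.argsort(-fold, kind="mergesort")
        top = order[:markers_per_type]
        top = top[fold[top] > 1.0]
        chosen.update(reference.index[top])
    rows = [g for g in reference.index if g in chosen]
    sig = reference.loc[rows]
    cond = float(np.linalg.cond(sig.to_numpy()))
    return SignatureMatrix(sig, compartments or {}, condition_number=cond)


def estimate_fractions(bulk: CountMatrix, signature: SignatureMatrix
                       ) -> FractionEstimate:
    """Non-negative least-squares decomposition of bulk profiles.

    Requires at least 50% of signature genes in the bulk matrix.  Raw NNLS
    weights are renormalized to proportions, making the estimate invariant
    to the overall scale of each bulk column.
    """
    sig_genes = signature.values.index
    present = sig_genes.intersection(bulk.gene_ids)
    if len(present) < 0.5 * len(sig_genes):
        raise ValueError(
            f"only {len(present)}/{len(sig_genes)} signature genes present "
            "in bulk matrix (need >= 50%)")
    A = signature.values.loc[present].to_numpy(dtype=float)
    B = bulk.values.loc[present].to_numpy(dtype=float)
    weights = np.zeros((B.shape[1], A.shape[1]))
    resid = np.zeros(B.shape[1])
    for j in range(B.shape[1]):
        weights[j], resid[j] = nnls(A, B[:, j])
    sums = weights.sum(axis=1)
    ok = sums > 0
    fractions = np.zeros_like(weights)
    fractions[ok] = weights[ok] / sums[ok, None]
    est = FractionEstimate(
        fractions=pd.DataFrame(fractions, index=bulk.sample_ids,
                               columns=signature.cell_types),
        residual_norm=pd.Series(resid, index=bulk.sample_ids))
    return compartment_normalize(est, signature)


def compartment_normalize(est: FractionEstimate,
                          signature: SignatureMatrix | None = None
                          ) -> FractionEstimate:
    """Rescale malignant and immune fractions to sum to 1 within compartment.

    A compartment with zero total mass yields all-NaN rows with a warning.
    Idempotent: renormalizing an already-normalized view is a no-op.
    """
    if signature is not None:
        mal = signature.types_in("malignant")
        imm = signature.types_in("immune")
    else:
        mal = [t for t in est.fractions.columns if t in MALIGNANT_TYPES]
        imm = [t for t in est.fractions.columns if t in IMMUNE_TYPES]

    def _norm(cols: list[str]) -> pd.DataFrame:
        sub = est.fractions[cols]
        totals = sub.sum(axis=1)
        zero = totals <= 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} sample(s) have zero mass in a compartment; "
                "returning NaN fractions for them")
        out = sub.div(totals.where(~zero), axis=0)
        return out

    est.malignant = _norm(mal) if mal else None
    est.immune = _norm(imm) if imm else None
    return est


def average_tissues(est: FractionEstimate, sheet: SampleSheet,
                    view: str = "fractions") -> pd.DataFrame:
    """Patient-level fractions: arithmetic mean across available tissues.

    Means of points on the simplex stay on the simplex, so no
    renormalization is reapplied.  Patients with no estimated samples are
    excluded with a warning.
    """
    table = {"fractions": est.fractions, "malignant": est.malignant,
             "immune": est.immune}[view]
    if table is None:
        raise ValueError(f"view {view!r} not computed")
    meta = sheet.data.set_index("sample_id")
    common = table.index.intersection(meta.index)
    skipped = set(sheet.patients) - set(meta.loc[common, "patient_id"])
    if skipped:
        warnings.warn(f"patients without estimates excluded: {sorted(skipped)}")
    grouped = table.loc[common].groupby(meta.loc[common, "patient_id"])
    return grouped.mean()
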