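"""Response classifiers: composition scores with ROC analysis, and the
grouped-CV gradient-boosting 5hmC signature workflow.

The signature workflow mirrors a patient-based design: folds partition
patients (never splitting one patient's samples), a gradient-boosted tree
ensemble is trained per fold, out-of-fold probabilities are pooled into a
cross-validation AUC, per-gene importance is the split count ("F score")
of an all-train fit, and a top-k refit sweep picks the smallest k
maximizing the cross-validation AUC.  A shuffled-label control provides
the chance-level baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .io import SampleSheet

__all__ = [
    "BoostingConfig",
    "SignatureModel",
    "composition_score",
    "roc_auc",
    "grouped_kfold",
    "train_signature_model",
    "select_top_k_refit",
    "evaluate_test",
    "shuffled_label_control",
]

COMPOSITION_MODES = {"gmp", "hsc", "gmp_minus_hsc", "nk", "nk_plus_gmp"}


def composition_score(fractions: pd.DataFrame, mode: str) -> pd.Series:
    """Patient-level composition score.

    ``gmp_minus_hsc`` is f(GMP-like) - f(HSC-like); ``nk_plus_gmp`` is
    f(NK) + f(GMP-like); single-type modes return the fraction itself.
    ``fractions`` rows are patients, columns cell types.
    """
    need = {"gmp": ["GMP-like"], "hsc": ["HSC-like"],
            "gmp_minus_hsc": ["GMP-like", "HSC-like"],
            "nk": ["NK"], "nk_plus_gmp": ["NK", "GMP-like"]}
    if mode not in need:
        raise ValueError(f"unknown mode {mode!r}; choose from {sorted(need)}")
    missing = [c for c in need[mode] if c not in fractions.columns]
    if missing:
        raise ValueError(f"missing cell type column(s): {missing}")
    if mode == "gmp_minus_hsc":
        s = fractions["GMP-like"] - fractions["HSC-like"]
    elif mode == "nk_plus_gmp":
        s = fractions["NK"] + fractions["GMP-like"]
    else:
        s = fractions[need[mode][0]]
    return s.rename(mode)


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC as the Mann-Whitney U statistic over n+ x n- pairs (ties 0.5),
    plus ROC curve points at every distinct threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    from scipy.stats import rankdata
    ranks = rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="mergesort")
    s_sorted, y_sorted = scores[order], labels[order]
    distinct = np.r_[np.where(np.diff(s_sorted))[0], s_sorted.size - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(~y_sorted)[distinct]
    curve = pd.DataFrame({
        "threshold": np.r_[np.inf, s_sorted[distinct]],
        "fpr": np.r_[0.0, fps / n_neg],
        "tpr": np.r_[0.0, tps / n_pos],
    })
    return float(auc), curve


def grouped_kfold(patients, k: int = 5, seed: int = 0) -> dict[str, int]:
    """Partition patients into k folds balanced in size (+-1 patient).

    Returns patient -> fold index (0..k-1); every sample of a patient
    inherits its patient's fold.
    """
    patients = list(dict.fromkeys(patients))
    if k > len(patients):
        raise ValueError(f"k={k} exceeds {len(patients)} patients")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    folds: dict[str, int] = {}
    for f, chunk in enumerate(np.array_split(order, k)):
        for i in chunk:
            folds[patients[i]] = f
    return folds


@dataclass
class BoostingConfig:
    """Gradient-boosting hyperparameters (recorded in every model output).

    ``colsample_bytree`` defaults to 0.1 and engages only for wide
    matrices (more features than ``colsample_min_features``): with
    thousands of correlated 5hmC features and a few dozen patients,
    full-column trees concentrate every split on one member of each
    correlated block, making the split-count importance ranking unstable;
    per-tree column subsampling spreads split credit across the block.
    Narrow refits (e.g. a selected top-11 signature) use all columns.
    """

    n_estimators: int = 100
    max_depth: int = 3
    learning_rate: float = 0.1
    colsample_bytree: float = 0.1
    colsample_min_features: int = 200
    objective: str = "binary:logistic"

    def make(self, seed: int, n_features: int | None = None) -> XGBClassifier:
        colsample = 1.0
        if n_features is None or n_features > self.colsample_min_features:
            colsample = self.colsample_bytree
        return XGBClassifier(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            learning_rate=self.learning_rate, objective=self.objective,
            colsample_bytree=colsample,
            eval_metric="logloss", random_state=seed, n_jobs=1,
            tree_method="hist", verbosity=0)


@dataclass
class SignatureModel:
    """Fitted 5hmC signature classifier with provenance."""

    selected_genes: list[str]
    importance: pd.Series                  # F score = split count
    fold_map: dict[str, int]
    cv_auc: float
    oof_probabilities: pd.Series
    model: XGBClassifier
    config: BoostingConfig
    seed: int
    test_auc: float | None = None
    control_aucs: list[float] = field(default_factory=list)


def _check_no_leakage(train_patients, val_patients) -> None:
    overlap = set(train_patients) & set(val_patients)
    if overlap:
        raise ValueError(
            f"patient leakage between train and validation/test sets: "
            f"{sorted(overlap)[:5]}")


def _fold_average_auc(probs: pd.Series, labels: pd.Series,
                      sample_patients: pd.Series,
                      fold_map: dict[str, int]) -> float:
    """Mean of per-fold AUCs (folds lacking a class are skipped).

    Unlike pooling out-of-fold probabilities, this is unbiased under the
    null: pooled probabilities carry fold-specific calibration offsets
    that anti-correlate with validation class balance in small cohorts,
    depressing the pooled AUC below chance.
    """
    per = []
    valid = probs.notna()
    k = max(fold_map.values()) + 1
    for f in range(k):
        val_pat = {p for p, ff in fold_map.items() if ff == f}
        mask = sample_patients.isin(val_pat).to_numpy() & valid.to_numpy()
        if mask.sum() and labels[mask].nunique() == 2:
            auc, _ = roc_auc(probs[mask], labels[mask])
            per.append(auc)
    if not per:
        raise ValueError("no fold had both classes present")
    return float(np.mean(per))


def _cv_auc(probs: pd.Series, labels: pd.Series, sample_patients: pd.Series,
            fold_map: dict[str, int], cv_metric: str) -> float:
    if cv_metric == "fold_average":
        return _fold_average_auc(probs, labels, sample_patients, fold_map)
    if cv_metric == "pooled":
        valid = probs.notna()
        auc, _ = roc_auc(probs[valid], labels[valid])
        return float(auc)
    raise ValueError(f"unknown cv_metric {cv_metric!r}")


def _cv_oof_probs(features: pd.DataFrame, labels: pd.Series,
                  sample_patients: pd.Series, fold_map: dict[str, int],
                  config: BoostingConfig, seed: int) -> pd.Series:
    probs = pd.Series(np.nan, index=features.index)
    k = max(fold_map.values()) + 1
    for f in range(k):
        val_pat = {p for p, ff in fold_map.items() if ff == f}
        train_pat = {p for p, ff in fold_map.items() if ff != f}
        _check_no_leakage(train_pat, val_pat)
        tr = sample_patients.isin(train_pat).to_numpy()
        va = sample_patients.isin(val_pat).to_numpy()
        if va.sum() == 0:
            continue
        y_tr = labels.to_numpy()[tr].astype(int)
        if y_tr.min() == y_tr.max():
            # degenerate single-class training fold: constant probability
            probs.iloc[np.where(va)[0]] = float(y_tr[0])
            continue
        clf = config.make(seed, n_features=features.shape[1])
        clf.fit(features.to_numpy()[tr], y_tr)
        probs.iloc[np.where(va)[0]] = clf.predict_proba(
            features.to_numpy()[va])[:, 1]
    return probs


def train_signature_model(features: pd.DataFrame, labels: pd.Series,
                          sample_patients: pd.Series,
                          fold_map: dict[str, int] | None = None,
                          config: BoostingConfig | None = None,
                          k: int = 5, seed: int = 0,
                          cv_metric: str = "fold_average") -> SignatureModel:
    """Patient-based k-fold CV of a gradient-boosted classifier.

    ``features``: samples x genes (regularized-log 5hmC levels);
    ``labels``: responder flag per sample (responders are the positive
    class); ``sample_patients``: patient id per sample.  The CV AUC is
    the mean of per-fold out-of-fold AUCs by default (``cv_metric =
    "pooled"`` pools the probabilities instead); importance is the split
    count from a final fit on all training samples.
    """
    config = config or BoostingConfig()
    if not features.index.equals(labels.index):
        raise ValueError("features and labels must share the sample index")
    if fold_map is None:
        fold_map = grouped_kfold(list(sample_patients), k=k, seed=seed)

    probs = _cv_oof_probs(features, labels, sample_patients, fold_map,
                          config, seed)
    cv_auc = _cv_auc(probs, labels, sample_patients, fold_map, cv_metric)
    if features.to_numpy().std(axis=0).max() == 0:
        warnings.warn("all features constant; CV AUC is chance level")

    final = config.make(seed, n_features=features.shape[1])
    final.fit(features.to_numpy(), labels.to_numpy().astype(int))
    booster = final.get_booster()
    fscore = booster.get_score(importance_type="weight")
    imp = pd.Series(0.0, index=features.columns)
    for fname, v in fscore.items():
        # default feature names are f0, f1, ... in column order
        idx = int(fname[1:]) if fname.startswith("f") and fname[1:].isdigit() \
            else features.columns.get_loc(fname)
        imp.iloc[idx] = v
    imp = imp.sort_values(ascending=False, kind="mergesort")

    return SignatureModel(
        selected_genes=list(features.columns), importance=imp,
        fold_map=dict(fold_map), cv_auc=float(cv_auc),
        oof_probabilities=probs, model=final, config=config, seed=seed)


def select_top_k_refit(features: pd.DataFrame, labels: pd.Series,
                       sample_patients: pd.Series, base: SignatureModel,
                       k_grid=(5, 11, 25, 50), seed: int = 0,
                       cv_metric: str = "fold_average"
                       ) -> tuple[SignatureModel, pd.DataFrame]:
    """Refit on the top-k genes by F score for each k; keep the best.

    Ties in CV AUC go to the smaller k.  Returns the winning model (refit
    on the full training set with the chosen genes) and the k-sweep table.
    """
    n_feat = len(base.importance)
    grid = sorted({min(int(k), n_feat) for k in k_grid})
    if max(k_grid) > n_feat:
        warnings.warn(f"k grid truncated to feature count {n_feat}")
    records = []
    best: tuple[float, int, SignatureModel] | None = None
    for k in grid:
        genes = base.importance.index[:k].tolist()
        model = train_signature_model(
            features[genes], labels, sample_patients,
            fold_map=base.fold_map, config=base.config, seed=seed,
            cv_metric=cv_metric)
        model.selected_genes = genes
        records.append({"k": k, "cv_auc": model.cv_auc})
        if best is None or model.cv_auc > best[0] + 1e-12:
            best = (model.cv_auc, k, model)
    assert best is not None
    return best[2], pd.DataFrame(records)


def evaluate_test(model: SignatureModel, test_features: pd.DataFrame,
                  test_labels: pd.Series, test_sheet: SampleSheet
                  ) -> dict[str, float]:
    """Held-out evaluation with a patient-leakage guard.

    Returns the overall AUC plus per-day (Day0/Day5) and per-tissue
    (BM/PB) AUCs where both classes are present in the subgroup.
    """
    train_patients = set(model.fold_map)
    meta = test_sheet.data.set_index("sample_id").loc[test_features.index]
    _check_no_leakage(train_patients, set(meta["patient_id"]))
    genes = model.selected_genes
    probs = model.model.predict_proba(test_features[genes].to_numpy())[:, 1]
    probs = pd.Series(probs, index=test_features.index)
    out: dict[str, float] = {}
    out["auc"], _ = roc_auc(probs, test_labels)
    for name, mask in [("day0", meta["day"].astype(float) == 0),
                       ("day5", meta["day"].astype(float) == 5),
                       ("bm", meta["tissue"] == "BM"),
                       ("pb", meta["tissue"] == "PB")]:
        sub = probs[mask.to_numpy()]
        lab = test_labels[mask.to_numpy()]
        if len(sub) and lab.nunique() == 2:
            out[f"auc_{name}"], _ = roc_auc(sub, lab)
    return out


def shuffled_label_control(features: pd.DataFrame, labels: pd.Series,
                           sample_patients: pd.Series,
                           fold_map: dict[str, int],
                           n_shuffles: int = 20,
                           config: BoostingConfig | None = None,
                           seed: int = 0,
                           cv_metric: str = "fold_average") -> list[float]:
    """Chance-level baseline: shuffle responder status across patients,
    keeping all samples of a patient consistent, and redo the CV."""
    config = config or BoostingConfig()
    rng = np.random.default_rng(seed)
    patient_label = labels.groupby(sample_patients.to_numpy()).first()
    aucs = []
    for b in range(n_shuffles):
        shuffled = pd.Series(
            rng.permutation(patient_label.to_numpy()),
            index=patient_label.index)
        y = sample_patients.map(shuffled).astype(bool)
        y.index = features.index
        probs = _cv_oof_probs(features, y, sample_patients, fold_map,
                              config, seed=seed + b + 1)
        aucs.append(_cv_auc(probs, y, sample_patients, fold_map, cv_metric))
    return aucs
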