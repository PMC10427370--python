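"""Epigenetic-responsiveness statistics and survival analysis.

Per patient, 5hmC responsiveness to azacitidine is summarized either as
the number of differentially hydroxymethylated genes between Day 5 and
Day 0 (DhMG count, tissues pooled as replicates) or as the Spearman
correlation between the Day 0 and Day 5 profiles (lower correlation =
larger global change).  Patients are median-split on the statistic and
compared by Kaplan-Meier / log-rank; multivariable Cox models adjust for
age and sex.  The Cox partial likelihood uses Breslow tie handling and
Newton-Raphson maximization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import basic_tests, filter_dhmgs, nb_wald_test, size_factors
from .io import CountMatrix, SampleSheet

__all__ = [
    "patient_dhmg_count",
    "day_correlation",
    "cohort_responsiveness",
    "median_split",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "dose_trend",
    "CoxResult",
]


def _paired_day_samples(sheet: SampleSheet, patient: str,
                        tissues=("BM", "PB")) -> tuple[list[str], list[str]]:
    day0, day5 = [], []
    for tissue in tissues:
        day0 += sheet.samples_for(patient, tissue=tissue, day=0)
        day5 += sheet.samples_for(patient, tissue=tissue, day=5)
    if not day0 or not day5:
        raise ValueError(f"patient {patient} lacks Day 0 or Day 5 samples")
    return day0, day5


def patient_dhmg_count(counts: CountMatrix, sheet: SampleSheet, patient: str,
                       tissues=("BM", "PB")) -> int:
    """Number of DhMGs (Day5 vs Day0) for one patient.

    Both tissues are pooled as replicates (2 vs 2 with the full BM+PB
    pairing), the NB Wald test is run Day5 versus Day0, and the strict
    DhMG filter (p < 0.01, |log2FC| >= 0.5) is applied.
    """
    day0, day5 = _paired_day_samples(sheet, patient, tissues)
    res = nb_wald_test(counts, day0, day5)
    return len(filter_dhmgs(res))


def day_correlation(counts: CountMatrix, sheet: SampleSheet, patient: str,
                    tissue: str = "BM") -> float:
    """Spearman correlation between a patient's Day 0 and Day 5 profiles.

    Computed on size-factor-normalized counts; BM-only by default
    (mirroring the paired bone-marrow design), averaging tissue replicates
    within a day when more than one sample is present.
    """
    tissues = ("BM", "PB") if tissue == "both" else (tissue,)
    day0, day5 = _paired_day_samples(sheet, patient, tissues)
    sub = counts.subset_samples(day0 + day5)
    sf = size_factors(sub)
    norm = sub.values / sf
    v0 = norm[day0].mean(axis=1).to_numpy()
    v5 = norm[day5].mean(axis=1).to_numpy()
    rho, _ = stats.spearmanr(v0, v5)
    return float(rho)


def cohort_responsiveness(counts: CountMatrix, sheet: SampleSheet,
                          stat: str = "dhmg", tissues=("BM", "PB")
                          ) -> pd.DataFrame:
    """Per-patient responsiveness table: dhmg_count or day_correlation,
    with dose, over all patients that have the required paired samples."""
    rows = []
    for patient in sheet.patients:
        try:
            if stat == "dhmg":
                value = patient_dhmg_count(counts, sheet, patient, tissues)
            elif stat == "spearman":
                value = day_correlation(counts, sheet, patient,
                                        tissue=tissues[0] if len(tissues) == 1
                                        else "both")
            else:
                raise ValueError(f"unknown stat {stat!r}")
        except ValueError as exc:
            if "lacks Day" in str(exc):
                continue
            raise
        info = sheet.patient_table().loc[patient]
        rows.append({"patient_id": patient, "value": value,
                     "dose_mg_m2": info["dose_mg_m2"],
                     "os_time": info["os_time"], "os_event": info["os_event"],
                     "age": info["age"], "sex": info["sex"]})
    return pd.DataFrame(rows).set_index("patient_id")


def median_split(values: pd.Series) -> pd.Series:
    """Split patients at the median: above -> 'high', at or below -> 'low'.

    Ties at the median are assigned to the low group (documented rule).
    Constant input is an error (no split exists).
    """
    values = values.dropna()
    if len(values) < 2:
        raise ValueError("need >= 2 patients to split")
    if values.nunique() == 1:
        raise ValueError("constant values cannot be median-split")
    med = float(values.median())
    labels = pd.Series(np.where(values > med, "high", "low"),
                       index=values.index, name="group")
    return labels


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimator.

    Returns a step table (time, n_at_risk, n_events, survival); censored
    observations reduce the risk set without a step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if times.size == 0:
        raise ValueError("need >= 1 record")
    if (times < 0).any():
        raise ValueError("negative survival time")
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    rows = []
    surv = 1.0
    n = times.size
    for t in np.unique(times):
        at_risk = int((times >= t).sum())
        d = int(events[times == t].sum())
        if d > 0:
            surv *= 1.0 - d / at_risk
        rows.append({"time": float(t), "n_at_risk": at_risk,
                     "n_events": d, "survival": surv})
    return pd.DataFrame(rows)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic and two-tailed p (1 df).

    Observed-minus-expected events in group A summed over event times,
    with the hypergeometric variance.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a).astype(int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b).astype(int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events observed")
    all_event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in all_event_times:
        na = int((ta >= t).sum())
        nb = int((tb >= t).sum())
        n = na + nb
        da = int(ea[ta == t].sum())
        db = int(eb[tb == t].sum())
        d = da + db
        if n <= 1:
            continue
        e_a = d * na / n
        v = d * (na / n) * (nb / n) * (n - d) / (n - 1)
        o_minus_e += da - e_a
        var += v
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


@dataclass
class CoxResult:
    """Cox proportional-hazards fit summary."""

    table: pd.DataFrame        # coef, se, z, p, hr per covariate
    loglik: float
    n_iter: int
    converged: bool


def cox_fit(times, events, covariates: pd.DataFrame,
            max_iter: int = 50, tol: float = 1e-8) -> CoxResult:
    """Cox proportional-hazards regression (Breslow ties, Newton-Raphson).

    Maximizes the partial likelihood; convergence when the gradient norm
    drops below ``tol``.  Monotone likelihood (perfect separation) is
    detected via diverging coefficients and reported as an error.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    X = covariates.to_numpy(dtype=float)
    names = list(covariates.columns)
    n, p = X.shape
    if e.sum() == 0:
        raise ValueError("no events observed")
    # center covariates for numerical stability (does not change beta)
    X = X - X.mean(axis=0)

    beta = np.zeros(p)
    event_times = np.unique(t[e == 1])
    loglik = -np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        w = np.exp(eta)
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        ll = 0.0
        for et in event_times:
            risk = t >= et
            dead = (t == et) & (e == 1)
            d = int(dead.sum())
            s0 = w[risk].sum()
            s1 = X[risk].T @ w[risk]
            s2 = (X[risk].T * w[risk]) @ X[risk]
            ll += eta[dead].sum() - d * np.log(s0)
            grad += X[dead].sum(axis=0) - d * s1 / s0
            hess += d * (s2 / s0 - np.outer(s1, s1) / s0**2)
        if np.linalg.norm(grad) < tol:
            loglik = ll
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix "
                             "(collinear covariates?)") from exc
        beta = beta + step
        loglik = ll
        if np.abs(beta).max() > 50:
            raise ValueError(
                "divergence detected (monotone likelihood / perfect "
                "separation); coefficients unbounded")
    else:
        it = max_iter
    converged = np.linalg.norm(grad) < tol
    # monotone likelihood: fitted log-hazard spread implies infinite MLE
    if np.abs(X @ beta).max() > 15:
        raise ValueError(
            "divergence detected (monotone likelihood / perfect "
            "separation); a coefficient is unbounded")
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame({"coef": beta, "se": se, "z": z, "p": pvals,
                          "hr": np.exp(beta)}, index=names)
    return CoxResult(table=table, loglik=float(loglik), n_iter=it,
                     converged=bool(converged))


def dose_trend(stat_table: pd.DataFrame) -> dict:
    """Pairwise Wilcoxon rank-sum tests of the responsiveness statistic
    across dose groups, plus per-dose medians.

    ``stat_table`` is the output of :func:`cohort_responsiveness` (needs
    ``value`` and ``dose_mg_m2`` columns).
    """
    groups = {float(d): g["value"].to_numpy()
              for d, g in stat_table.groupby("dose_mg_m2") if len(g) >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 dose groups with >= 2 patients each")
    doses = sorted(groups)
    pairwise = {}
    for i, a in enumerate(doses):
        for b in doses[i + 1:]:
            _, pval = basic_tests(groups[a], groups[b], "wilcoxon_ranksum")
            pairwise[f"{a:g}_vs_{b:g}"] = pval
    medians = {f"{d:g}": float(np.median(groups[d])) for d in doses}
    ordered = [medians[f"{d:g}"] for d in doses]
    return {"pairwise_p": pairwise, "median_by_dose": medians,
            "monotone_increasing": all(b >= a for a, b in zip(ordered,
                                                              ordered[1:]))}
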