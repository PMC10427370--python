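"""End-to-end orchestration of the analysis stages on a cohort.

Runs differential testing, co-expression modules, enrichment,
deconvolution, composition/signature classifiers and survival analysis in
dependency order, writing per-stage TSV/JSON outputs, a provenance
manifest and a summary JSON.  Stage toggles allow partial runs; a stage
failure halts with a stage-named error while earlier outputs are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifiers import (composition_score, grouped_kfold, roc_auc,
                          select_top_k_refit, train_signature_model)
from .coexpression import cluster_modules, pairwise_correlation
from .deconvolution import (average_tissues, build_signature,
                            estimate_fractions)
from .diffstats import (filter_degs, nb_wald_test, rlog_approx, tpm)
from .enrichment import sample_set_score
from .io import CountMatrix, SampleSheet, write_json
from .survival import (cohort_responsiveness, cox_fit, km_estimate,
                       logrank_test, median_split)
from .synthetic import (SimulationConfig, gene_lengths_kb,
                        generate_bulk_cohort, generate_hmc_cohort,
                        generate_reference_profiles)

__all__ = ["PipelineConfig", "run_full", "concordance_check"]


@dataclass
class PipelineConfig:
    """Stage toggles and parameters for a full synthetic-cohort run."""

    seed: int = 0
    out_dir: str | Path = "pipeline_out"
    n_patients_bulk: int = 46
    n_patients_hmc: int = 20
    n_genes: int = 2000
    stages: dict = field(default_factory=lambda: {
        "diff": True, "coexpression": True, "enrichment": True,
        "deconvolution": True, "classifiers": True, "survival": True})
    markers_per_type: int = 50
    module_k: int = 4
    k_grid: tuple[int, ...] = (5, 11, 25)
    cv_folds: int = 5


def run_full(config: PipelineConfig) -> dict:
    """Run the whole pipeline on generated cohorts and write a report bundle.

    Returns the summary dictionary (also written to summary.json).  With a
    fixed config the summary is byte-identical across runs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stage_seeds": {}, "parameters": {
                          "n_patients_bulk": config.n_patients_bulk,
                          "n_patients_hmc": config.n_patients_hmc,
                          "n_genes": config.n_genes,
                          "markers_per_type": config.markers_per_type,
                          "module_k": config.module_k,
                          "k_grid": list(config.k_grid),
                          "cv_folds": config.cv_folds},
                      "stages_enabled": dict(config.stages)}

    sim = SimulationConfig(n_patients=config.n_patients_bulk,
                           n_genes=config.n_genes, seed=config.seed)
    reference, ref_truth = generate_reference_profiles(sim)
    bulk, sheet, truth = generate_bulk_cohort(sim, reference)
    lengths = gene_lengths_kb(sim)
    manifest["stage_seeds"]["simulate_bulk"] = config.seed

    responder = sheet.responder_map()
    sample_resp = sheet.data.set_index("sample_id")["patient_id"].map(responder)

    if config.stages.get("diff", True):
        resp_samples = sample_resp.index[sample_resp].tolist()
        nonresp_samples = sample_resp.index[~sample_resp].tolist()
        if len(resp_samples) >= 2 and len(nonresp_samples) >= 2:
            diff = nb_wald_test(bulk, nonresp_samples, resp_samples)
            degs = filter_degs(diff)
            diff.table.to_csv(out / "diff_deg.tsv", sep="\t")
            summary["n_deg"] = len(degs["all"])
            summary["n_deg_up"] = len(degs["up"])
            summary["n_deg_down"] = len(degs["down"])
        else:
            warnings.warn("skipping diff: a response group has <2 samples")
            degs = {"all": []}
    else:
        degs = {"all": []}

    if config.stages.get("coexpression", True) and len(degs["all"]) >= config.module_k:
        log_expr = rlog_approx(bulk)
        corr = pairwise_correlation(log_expr.values.loc[degs["all"]])
        modules = cluster_modules(corr, k=min(config.module_k, corr.shape[0]))
        modules.modules.to_csv(out / "modules.tsv", sep="\t")
        summary["module_sizes"] = (
            modules.modules.value_counts().sort_index().tolist())
    elif config.stages.get("coexpression", True):
        warnings.warn("skipping coexpression: too few differential genes")

    tpm_mat = tpm(bulk, lengths)

    if config.stages.get("deconvolution", True):
        signature = build_signature(reference, config.markers_per_type)
        est = estimate_fractions(tpm_mat, signature)
        est.fractions.to_csv(out / "fractions.tsv", sep="\t")
        patient_frac = average_tissues(est, sheet)
        patient_frac.to_csv(out / "fractions_patient.tsv", sep="\t")
        summary["deconv_mae_gmp"] = float(
            (est.fractions["GMP-like"]
             - truth.true_fractions["GMP-like"]).abs().mean())
    else:
        patient_frac = None

    if config.stages.get("enrichment", True):
        log_expr = rlog_approx(bulk)
        nk_score = sample_set_score(log_expr, ref_truth.marker_genes["NK"])
        nk_score.to_csv(out / "nk_score.tsv", sep="\t")
        summary["nk_score_mean"] = float(nk_score.mean())

    if config.stages.get("classifiers", True):
        if patient_frac is not None:
            labels = responder.loc[patient_frac.index]
            for mode in ("gmp", "gmp_minus_hsc", "nk", "nk_plus_gmp"):
                score = composition_score(patient_frac, mode)
                auc, _ = roc_auc(score, labels)
                summary[f"auc_{mode}"] = float(auc)
        else:
            summary["classifier_composition_skipped"] = (
                "deconvolution disabled; composition modes unavailable")
            warnings.warn("composition classifiers skipped: "
                          "deconvolution stage is disabled")

        hmc_cfg = SimulationConfig(n_patients=config.n_patients_hmc,
                                   n_genes=config.n_genes,
                                   seed=config.seed + 1000)
        hmc, hmc_sheet, hmc_truth = generate_hmc_cohort(hmc_cfg)
        manifest["stage_seeds"]["simulate_hmc"] = config.seed + 1000
        features = rlog_approx(hmc).values.T
        meta = hmc_sheet.data.set_index("sample_id")
        patients = meta.loc[features.index, "patient_id"]
        labels_s = patients.map(hmc_truth.true_labels).astype(bool)
        folds = grouped_kfold(list(patients), k=config.cv_folds,
                              seed=config.seed)
        manifest["stage_seeds"]["grouped_kfold"] = config.seed
        base = train_signature_model(features, labels_s, patients,
                                     fold_map=folds, seed=config.seed)
        best, sweep = select_top_k_refit(features, labels_s, patients, base,
                                         k_grid=config.k_grid,
                                         seed=config.seed)
        sweep.to_csv(out / "k_sweep.tsv", sep="\t", index=False)
        summary["signature_cv_auc"] = float(base.cv_auc)
        summary["signature_best_k"] = int(len(best.selected_genes))
        summary["signature_best_cv_auc"] = float(best.cv_auc)

        if config.stages.get("survival", True):
            stat = cohort_responsiveness(hmc, hmc_sheet, stat="dhmg")
            stat.to_csv(out / "responsiveness.tsv", sep="\t")
            groups = median_split(stat["value"])
            hi = stat.loc[groups == "high"]
            lo = stat.loc[groups == "low"]
            chi2, p = logrank_test(hi["os_time"], hi["os_event"],
                                   lo["os_time"], lo["os_event"])
            km_estimate(stat["os_time"], stat["os_event"]).to_csv(
                out / "km_all.tsv", sep="\t", index=False)
            summary["survival_logrank_chi2"] = float(chi2)
            summary["survival_logrank_p"] = float(p)
            cov = pd.DataFrame({
                "high_dhmg": (groups == "high").astype(float),
                "age": stat["age"].astype(float),
                "sex_male": (stat["sex"] == "M").astype(float)})
            cox = cox_fit(stat["os_time"], stat["os_event"], cov)
            cox.table.to_csv(out / "cox.tsv", sep="\t")
            summary["cox_high_dhmg_hr"] = float(cox.table.loc["high_dhmg", "hr"])

    write_json(manifest, out / "manifest.json")
    write_json(summary, out / "summary.json")
    return summary


def concordance_check(values: pd.DataFrame, sheet: SampleSheet,
                      day: int | None = None) -> pd.Series:
    """Per-patient Pearson correlation between BM and PB feature vectors.

    ``values``: samples x features.  Patients lacking one of the tissues
    are skipped; if no patient has both tissues, an error is raised.
    """
    meta = sheet.data.set_index("sample_id")
    out = {}
    for patient in sheet.patients:
        bm = sheet.samples_for(patient, tissue="BM", day=day)
        pb = sheet.samples_for(patient, tissue="PB", day=day)
        bm = [s for s in bm if s in values.index]
        pb = [s for s in pb if s in values.index]
        if not bm or not pb:
            continue
        v_bm = values.loc[bm].mean(axis=0).to_numpy(dtype=float)
        v_pb = values.loc[pb].mean(axis=0).to_numpy(dtype=float)
        out[patient] = float(np.corrcoef(v_bm, v_pb)[0, 1])
    if not out:
        raise ValueError("no patient has both BM and PB samples")
    return pd.Series(out, name="bm_pb_correlation")
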