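"""Synthetic cohort generator with full ground truth.

Emulates the statistical structure the downstream analysis assumes:

* a 13-cell-type reference (6 malignant AML subsets named for the normal
  hematopoietic state they resemble, 7 immune populations) with disjoint
  planted marker genes;
* bulk RNA samples as negative-binomial draws around mixtures of the
  reference columns, with Dirichlet cell fractions and responder labels
  whose log-odds load on the (GMP-like - HSC-like) and NK fractions;
* paired Day0/Day5 5hmC matrices in which azacitidine exposure shifts a
  dose-dependent random gene subset by a fixed log2 amount, plus a set of
  response-informative genes for classifier benchmarks;
* exponential survival times whose log-hazard decreases with the number
  of shifted genes (stronger epigenetic responsiveness -> longer survival),
  with uniform right-censoring.

Every planted quantity is returned in a ``CohortTruth`` so downstream
stages can be tested without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (CountMatrix, SampleSheet, write_counts, write_sample_sheet,
                 write_json)

__all__ = [
    "MALIGNANT_TYPES",
    "IMMUNE_TYPES",
    "CELL_TYPES",
    "SimulationConfig",
    "CohortTruth",
    "generate_reference_profiles",
    "generate_bulk_cohort",
    "generate_hmc_cohort",
    "write_cohort",
]

MALIGNANT_TYPES = ["HSC-like", "Prog-like", "GMP-like", "ProMono-like",
                   "Mono-like", "cDC-like"]
IMMUNE_TYPES = ["B", "cDC", "CTL", "Monocyte", "Plasma", "T", "NK"]
CELL_TYPES = MALIGNANT_TYPES + IMMUNE_TYPES


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the trial design: 46 patients for the transcriptome
    cohort, bone marrow + peripheral blood per patient, azacitidine dose
    levels of 37.5/50/75 mg/m2, and a Day5-vs-Day0 5hmC shift applied to a
    dose-increasing fraction of genes.
    """

    n_patients: int = 46
    tissues: tuple[str, ...] = ("BM", "PB")
    days: tuple[int, ...] = (0, 5)
    n_genes: int = 2000
    cell_types: tuple[str, ...] = tuple(CELL_TYPES)
    n_markers_per_type: int = 50
    marker_fold: float = 10.0
    sequencing_depth: float = 2e6
    nb_dispersion: float = 0.05
    response_effect: float = 3.0
    dose_levels: tuple[float, ...] = (37.5, 50.0, 75.0)
    dhmg_fraction_per_dose: Mapping[float, float] = field(
        default_factory=lambda: {37.5: 0.01, 50.0: 0.03, 75.0: 0.08})
    dhmg_log2_shift: float = 1.5
    survival_hazard_coef: float = 0.01
    censoring_rate: float = 0.3
    # 5hmC response signal: genes whose baseline level differs by response
    n_informative_genes: int = 30
    informative_log2_effect: float = 1.5
    # shared patient effect across tissues (log-normal sd) vs tissue noise
    patient_effect_sd: float = 0.4
    tissue_effect_sd: float = 0.1
    patient_prefix: str = "P"   # distinguishes independent cohorts
    # when set, the 5hmC gene architecture (baseline means, informative
    # gene identities) is drawn from this seed so that independently
    # generated cohorts (e.g. train and held-out test) share it
    architecture_seed: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_genes < 1 or self.n_markers_per_type < 1:
            raise ValueError("counts must be >= 1")
        if self.n_markers_per_type * len(self.cell_types) > self.n_genes:
            raise ValueError(
                f"{self.n_markers_per_type} markers x {len(self.cell_types)} "
                f"types exceeds {self.n_genes} genes")
        if not set(self.tissues) <= {"BM", "PB"}:
            raise ValueError("tissues must be a subset of {BM, PB}")
        if not set(self.days) <= {0, 5}:
            raise ValueError("days must be a subset of {0, 5}")
        if not set(self.dose_levels) <= {37.5, 50.0, 75.0}:
            raise ValueError("dose levels must be a subset of {37.5, 50, 75}")
        fracs = [self.dhmg_fraction_per_dose.get(d, 0.0)
                 for d in sorted(self.dose_levels)]
        if any(b < a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("dhmg_fraction_per_dose must be non-decreasing in dose")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]


@dataclass
class CohortTruth:
    """Planted ground truth for a generated cohort."""

    true_fractions: pd.DataFrame | None = None      # samples x cell types
    true_labels: pd.Series | None = None            # patient -> bool responder
    true_shifted_genes: dict[str, list[str]] = field(default_factory=dict)
    true_informative_genes: list[str] = field(default_factory=list)
    true_hazard: pd.Series | None = None            # patient -> positive real
    marker_genes: dict[str, list[str]] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        out: dict = {"true_shifted_genes": self.true_shifted_genes,
                     "true_informative_genes": self.true_informative_genes,
                     "marker_genes": self.marker_genes}
        if self.true_fractions is not None:
            out["true_fractions"] = self.true_fractions.round(6).to_dict("index")
        if self.true_labels is not None:
            out["true_labels"] = self.true_labels.astype(bool).to_dict()
        if self.true_hazard is not None:
            out["true_hazard"] = self.true_hazard.to_dict()
        return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB draw with Var = m + dispersion * m^2 (Poisson when dispersion ~ 0)."""
    mean = np.maximum(mean, 1e-12)
    if dispersion < 1e-8:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_reference_profiles(config: SimulationConfig) -> tuple[pd.DataFrame,
                                                                   CohortTruth]:
    """Genes x 13 matrix of positive mean expressions with planted markers.

    Each cell type owns a disjoint block of ``n_markers_per_type`` genes
    elevated ``marker_fold`` over that gene's baseline; baselines are
    log-normal around a mean of ~5.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = config.gene_ids
    types = list(config.cell_types)
    baseline = rng.lognormal(mean=np.log(5.0), sigma=0.6, size=config.n_genes)
    # mild type-specific wiggle so columns are not collinear off-marker
    wiggle = rng.lognormal(mean=0.0, sigma=0.1,
                           size=(config.n_genes, len(types)))
    ref = baseline[:, None] * wiggle

    marker_genes: dict[str, list[str]] = {}
    perm = rng.permutation(config.n_genes)
    for i, t in enumerate(types):
        block = perm[i * config.n_markers_per_type:(i + 1) * config.n_markers_per_type]
        ref[block, i] *= config.marker_fold
        marker_genes[t] = [genes[j] for j in sorted(block)]

    df = pd.DataFrame(ref, index=genes, columns=types)
    return df, CohortTruth(marker_genes=marker_genes)


def _dirichlet_alpha(types: Sequence[str]) -> np.ndarray:
    """Concentrations giving GMP-like and HSC-like mean fractions of ~0.2."""
    alpha = np.full(len(types), 6.0 / (len(types) - 2))
    for i, t in enumerate(types):
        if t in ("GMP-like", "HSC-like"):
            alpha[i] = 2.0
    return alpha


def generate_bulk_cohort(config: SimulationConfig,
                         reference: pd.DataFrame
                         ) -> tuple[CountMatrix, SampleSheet, CohortTruth]:
    """Day-0 bulk RNA cohort: NB counts around cell-type mixtures.

    Per sample, fractions are Dirichlet; the patient's responder label is
    Bernoulli with log-odds ``response_effect * ((GMP - HSC) + NK)``
    computed from the patient's mean fractions; counts are NB with mean
    ``depth x mixture profile x gene length`` (reads scale with transcript
    abundance times length, so TPM normalization recovers the mixture).
    """
    if list(reference.index) != config.gene_ids:
        raise ValueError("reference generated with a different gene universe")
    rng = np.random.default_rng(config.seed + 2)
    types = list(config.cell_types)
    alpha = _dirichlet_alpha(types)
    ref = reference.to_numpy()
    lengths = gene_lengths_kb(config).to_numpy()
    i_gmp = types.index("GMP-like")
    i_hsc = types.index("HSC-like")
    i_nk = types.index("NK")

    rows, counts_cols, frac_rows, sample_ids = [], [], [], []
    labels = {}
    doses = rng.choice(list(config.dose_levels), size=config.n_patients)
    for p in range(config.n_patients):
        pid = f"{config.patient_prefix}{p:03d}"
        frac_p = rng.dirichlet(alpha)
        score = (frac_p[i_gmp] - frac_p[i_hsc]) + frac_p[i_nk]
        prob = 1.0 / (1.0 + np.exp(-config.response_effect * score))
        responder = bool(rng.random() < prob)
        labels[pid] = responder
        for tissue in config.tissues:
            # per-sample jitter around the patient's composition
            frac_s = rng.dirichlet(100.0 * np.maximum(frac_p, 1e-4))
            profile = (ref @ frac_s) * lengths
            profile = profile / profile.sum()
            mean = config.sequencing_depth * profile
            counts = _nb_draw(rng, mean, config.nb_dispersion)
            sid = f"{pid}_{tissue}_D0"
            sample_ids.append(sid)
            counts_cols.append(counts)
            frac_rows.append(frac_s)
            resp_code = "TF"
            if responder:
                resp_code = "CR" if rng.random() < 19 / 28 else "CRi"
            rows.append(dict(sample_id=sid, patient_id=pid, tissue=tissue,
                             day=0, dose_mg_m2=doses[p], response=resp_code,
                             os_time=np.nan, os_event=0,
                             age=float(np.round(rng.uniform(25, 75), 1)),
                             sex=rng.choice(["M", "F"])))

    mat = pd.DataFrame(np.column_stack(counts_cols), index=config.gene_ids,
                       columns=sample_ids)
    sheet_df = pd.DataFrame(rows)
    # one response category per patient (CR vs CRi drawn once above per sample;
    # enforce consistency by taking the first)
    first = sheet_df.drop_duplicates("patient_id").set_index("patient_id")["response"]
    sheet_df["response"] = sheet_df["patient_id"].map(first)
    truth = CohortTruth(
        true_fractions=pd.DataFrame(frac_rows, index=sample_ids, columns=types),
        true_labels=pd.Series(labels, name="responder"))
    return (CountMatrix(mat, state="raw"), SampleSheet(sheet_df), truth)


def generate_hmc_cohort(config: SimulationConfig
                        ) -> tuple[CountMatrix, SampleSheet, CohortTruth]:
    """Paired Day0/Day5 5hmC cohort with dose-dependent shifts and survival.

    Day5 negative-binomial means equal Day0 means with ``dhmg_log2_shift``
    applied to a per-patient random gene subset whose size is
    ``dhmg_fraction_per_dose[dose] * n_genes``.  A fixed set of
    ``n_informative_genes`` has baseline 5hmC separated by responder
    status.  Survival is exponential with log-hazard
    ``log(h0) - survival_hazard_coef * |shifted set|`` and uniform
    right-censoring at rate ``censoring_rate``.
    """
    if not {0, 5} <= set(config.days):
        raise ValueError("5hmC cohort requires both Day 0 and Day 5")
    if not config.dose_levels:
        raise ValueError("at least one dose level required")
    rng = np.random.default_rng(config.seed + 3)
    arch_rng = (np.random.default_rng(config.architecture_seed)
                if config.architecture_seed is not None else rng)
    genes = config.gene_ids
    n_genes = config.n_genes

    base_mean = arch_rng.lognormal(mean=np.log(5.0), sigma=0.7, size=n_genes)
    informative = sorted(arch_rng.choice(
        n_genes, size=config.n_informative_genes, replace=False))
    informative_ids = [genes[i] for i in informative]

    rows, cols, sample_ids = [], [], []
    labels, shifted_sets, hazards = {}, {}, {}
    base_hazard = 1.0 / 365.0   # days; median survival ~ 8 months untreated
    doses = rng.choice(list(config.dose_levels), size=config.n_patients)
    for p in range(config.n_patients):
        pid = f"{config.patient_prefix}{p:03d}"
        dose = float(doses[p])
        responder = bool(rng.random() < 0.5)
        labels[pid] = responder

        patient_effect = rng.lognormal(0.0, config.patient_effect_sd, n_genes)
        mean_p = base_mean * patient_effect
        if responder:
            mean_p[informative] *= 2.0 ** config.informative_log2_effect

        frac = config.dhmg_fraction_per_dose.get(dose, 0.0)
        n_shift = int(round(frac * n_genes))
        shift_idx = rng.choice(n_genes, size=n_shift, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_shift)
        shifted_sets[pid] = [genes[i] for i in sorted(shift_idx)]

        hazard = base_hazard * np.exp(-config.survival_hazard_coef * n_shift)
        hazards[pid] = hazard
        t_event = rng.exponential(1.0 / hazard)
        if rng.random() < config.censoring_rate:
            os_time, os_event = rng.uniform(0, t_event), 0
        else:
            os_time, os_event = t_event, 1
        age = float(np.round(rng.uniform(25, 75), 1))
        sex = rng.choice(["M", "F"])
        resp_code = "TF"
        if responder:
            resp_code = "CR" if rng.random() < 19 / 28 else "CRi"

        depth_scale = config.sequencing_depth / (base_mean.sum())
        for tissue in config.tissues:
            tissue_effect = rng.lognormal(0.0, config.tissue_effect_sd, n_genes)
            for day in sorted(config.days):
                mean_s = mean_p * tissue_effect
                if day == 5:
                    mean_s = mean_s.copy()
                    mean_s[shift_idx] *= 2.0 ** (config.dhmg_log2_shift * signs)
                mean_s = mean_s * depth_scale
                counts = _nb_draw(rng, mean_s, config.nb_dispersion)
                sid = f"{pid}_{tissue}_D{day}"
                sample_ids.append(sid)
                cols.append(counts)
                rows.append(dict(sample_id=sid, patient_id=pid, tissue=tissue,
                                 day=day, dose_mg_m2=dose, response=resp_code,
                                 os_time=float(np.round(os_time, 2)),
                                 os_event=os_event, age=age, sex=sex))

    mat = pd.DataFrame(np.column_stack(cols), index=genes, columns=sample_ids)
    truth = CohortTruth(
        true_labels=pd.Series(labels, name="responder"),
        true_shifted_genes=shifted_sets,
        true_informative_genes=informative_ids,
        true_hazard=pd.Series(hazards, name="hazard"))
    return (CountMatrix(mat, state="raw"), SampleSheet(pd.DataFrame(rows)), truth)


def gene_lengths_kb(config: SimulationConfig) -> pd.Series:
    """Log-uniform gene lengths in 0.5-10 kb, for TPM normalization."""
    rng = np.random.default_rng(config.seed + 4)
    lens = np.exp(rng.uniform(np.log(0.5), np.log(10.0), size=config.n_genes))
    return pd.Series(lens, index=config.gene_ids, name="length_kb")


def write_cohort(counts: CountMatrix, sheet: SampleSheet, truth: CohortTruth,
                 out_dir: str | Path, lengths: pd.Series | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts(counts, out / "counts.tsv")
    write_sample_sheet(sheet, out / "samples.tsv")
    write_json(truth.to_jsonable(), out / "truth.json")
    if lengths is not None:
        lengths.rename_axis("gene_id").to_frame().to_csv(
            out / "gene_lengths.tsv", sep="\t")
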