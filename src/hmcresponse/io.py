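"""Readers and writers for on-disk artifacts.

Everything is plain TSV/GMT/JSON: gene x sample count matrices, sample
sheets binding samples to patients and clinical annotations, gene-set
collections, and per-gene weight tables.  Gene identifiers are opaque
strings; TSV is used throughout to avoid locale/quoting ambiguity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "GeneSetCollection",
    "FormatError",
    "ValidationError",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_lengths",
    "read_gene_weights",
    "responder_rate",
]

VALID_TISSUES = {"BM", "PB"}
VALID_DAYS = {0, 5}
VALID_RESPONSES = {"CR", "CRi", "TF"}
VALID_DOSES = {37.5, 50.0, 75.0}
RESPONDER_CLASSES = {"CR", "CRi"}


class FormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(ValueError):
    """Parsed content violates a semantic invariant."""


@dataclass
class CountMatrix:
    """Genes x samples matrix with a normalization-state tag.

    ``state`` is one of ``raw`` (non-negative integers), ``normalized``
    (size-factor divided), ``tpm`` or ``rlog-approx``.
    """

    values: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in {"raw", "normalized", "tpm", "rlog-approx"}:
            raise ValidationError(f"unknown state tag {self.state!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene ids: {', '.join(map(str, dups[:5]))}")
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            raise FormatError("matrix contains missing values")
        if (arr < 0).any():
            raise FormatError("matrix contains negative entries")
        if self.state == "raw" and not np.allclose(arr, np.round(arr)):
            raise FormatError("raw count matrix contains non-integer entries")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, samples: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.values.loc[:, list(samples)].copy(), state=self.state)


SHEET_COLUMNS = [
    "sample_id",
    "patient_id",
    "tissue",
    "day",
    "dose_mg_m2",
    "response",
    "os_time",
    "os_event",
    "age",
    "sex",
]


@dataclass
class SampleSheet:
    """Per-sample clinical metadata.

    One row per sample; ``sample_id`` unique and ``(patient_id, tissue,
    day)`` unique.  ``response`` uses the trial's categories: complete
    remission (CR), CR with incomplete count recovery (CRi) and treatment
    failure (TF); responders are CR + CRi.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")
        key = df[["patient_id", "tissue", "day"]].astype(str).agg("|".join, axis=1)
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValidationError(f"duplicated (patient, tissue, day): {dup}")
        bad_tissue = set(df["tissue"].dropna()) - VALID_TISSUES
        if bad_tissue:
            raise ValidationError(f"unknown tissue token(s): {sorted(bad_tissue)}")
        bad_day = set(df["day"].dropna().astype(int)) - VALID_DAYS
        if bad_day:
            raise ValidationError(f"unknown day token(s): {sorted(bad_day)}")
        bad_resp = set(df["response"].dropna()) - VALID_RESPONSES
        if bad_resp:
            raise ValidationError(f"unknown response token(s): {sorted(bad_resp)}")
        doses = df["dose_mg_m2"].dropna().astype(float)
        bad_dose = set(doses) - VALID_DOSES
        if bad_dose:
            raise ValidationError(f"unknown dose level(s): {sorted(bad_dose)}")
        ev = df["os_event"].dropna()
        if not set(ev.astype(int)) <= {0, 1}:
            raise ValidationError("os_event must be 0/1")
        has_event = df["os_event"].fillna(0).astype(float) == 1
        if (has_event & df["os_time"].isna()).any():
            raise ValidationError("os_event=1 requires os_time")
        if (df["os_time"].dropna() < 0).any():
            raise ValidationError("negative os_time")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.data["sample_id"])

    @property
    def patients(self) -> list[str]:
        return list(pd.unique(self.data["patient_id"]))

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def samples_for(self, patient: str, tissue: str | None = None,
                    day: int | None = None) -> list[str]:
        df = self.data
        mask = df["patient_id"] == patient
        if tissue is not None:
            mask &= df["tissue"] == tissue
        if day is not None:
            mask &= df["day"].astype(float) == day
        return list(df.loc[mask, "sample_id"])

    def responder_map(self) -> pd.Series:
        """Per-patient responder flag: CR or CRi -> True, TF -> False."""
        per_patient = (
            self.data.dropna(subset=["response"])
            .drop_duplicates("patient_id")
            .set_index("patient_id")["response"]
        )
        return per_patient.isin(RESPONDER_CLASSES)

    def patient_table(self) -> pd.DataFrame:
        """One row per patient with patient-level fields."""
        cols = ["patient_id", "dose_mg_m2", "response", "os_time", "os_event",
                "age", "sex"]
        return (self.data[cols].drop_duplicates("patient_id")
                .set_index("patient_id"))


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-gene weights.

    Membership order is preserved as read; weights (when present) support
    coefficient-weighted signature scores such as LSC17.
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    weights: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {name!r} has duplicate members")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def read_counts(path: str | Path, state: str = "raw") -> CountMatrix:
    """Read a TSV count matrix (first column gene id, one column per sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = df.index[coerced.isna().argmax()]
            raise FormatError(
                f"non-numeric entry at gene {row!r}, column {col!r} in {path}")
        df[col] = coerced
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df, state=state)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    out = cm.values.copy()
    if cm.state == "raw":
        out = out.astype(int)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT: name, description, then tab-separated members."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member (got {len(fields)} fields)")
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, sep="\t", index=False)


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Read a two-column TSV gene_id -> length in kilobases."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0].astype(float)
    if (s <= 0).any():
        raise FormatError("gene lengths must be positive")
    s.index = s.index.astype(str)
    return s


def read_gene_weights(path: str | Path) -> pd.Series:
    """Read a two-column TSV gene_id -> real-valued weight."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0].astype(float)
    s.index = s.index.astype(str)
    return s


def responder_rate(sheet: SampleSheet) -> tuple[int, int, float]:
    """Overall response rate (CR + CRi) / all patients with a response label.

    Returns ``(n_responders, n_total, rate)``; the rate is a proportion in
    [0, 1].  Percentages elsewhere round half-up to the whole percent.
    """
    table = sheet.patient_table().dropna(subset=["response"])
    n_total = len(table)
    if n_total == 0:
        raise ValidationError("no patients with a response label")
    n_resp = int(table["response"].isin(RESPONDER_CLASSES).sum())
    return n_resp, n_total, n_resp / n_total


def percent(x: float) -> int:
    """Round a proportion to a whole percent, half away from zero."""
    return int(np.floor(100.0 * x + 0.5))


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
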