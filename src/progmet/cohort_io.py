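"""Data model and I/O for expression matrices, clinical tables and probe maps.

Expression matrices are probes x samples of log2 signal intensities stored
as plain TSV (first column: probe id; header row: sample ids).  Clinical
tables carry distant-metastasis-free survival (DMFS) and standard breast
cancer covariates.  Missing expression values are rejected at load time --
imputation is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CLINICAL_COLUMNS",
    "ER_LEVELS",
    "LN_LEVELS",
    "SIZE_LEVELS",
    "GRADE_LEVELS",
    "TREATMENT_LEVELS",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "validate_clinical",
    "read_probe_map",
    "write_probe_map",
    "intersect_probes",
    "delimit_followup",
]

#: Required columns of a clinical table, in canonical order.
CLINICAL_COLUMNS = [
    "sample_id",
    "dmfs_time",
    "dmfs_event",
    "er_status",
    "ln_status",
    "tumor_size_class",
    "grade",
    "age_years",
    "treatment",
    "study",
]

ER_LEVELS = {"positive", "negative", "unknown"}
LN_LEVELS = {"negative", "positive", "unknown"}
SIZE_LEVELS = {"T1", "T2", "T3", "unknown"}
GRADE_LEVELS = {"1", "2", "3", "unknown"}
TREATMENT_LEVELS = {"none", "tamoxifen", "chemotherapy", "unknown"}


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of log2 intensities.

    Attributes
    ----------
    probe_ids : list of str
        Unique probe (row) identifiers.
    sample_ids : list of str
        Unique sample (column) identifiers.
    values : ndarray of shape (n_probes, n_samples)
        Finite log2 signal intensities.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        dup = _duplicates(self.probe_ids)
        if dup:
            raise ValueError(f"duplicate probe ids: {sorted(dup)}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValueError(f"duplicate sample ids: {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite value at probe "
                f"{self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self, probes: Sequence[str]) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probes if p not in lookup]
        if missing:
            raise KeyError(f"probes not in matrix: {missing[:10]}")
        return np.array([lookup[p] for p in probes], dtype=int)

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.probe_index(probes)
        return ExpressionMatrix(list(probes), list(self.sample_ids), self.values[idx])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:10]}")
        idx = np.array([lookup[s] for s in samples], dtype=int)
        return ExpressionMatrix(list(self.probe_ids), list(samples), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.probe_ids == other.probe_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a probes x samples TSV; hard error on duplicates or missing cells."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    probe_ids = [str(p) for p in df.index]
    dup = _duplicates(probe_ids)
    if dup:
        raise ValueError(f"{path}: duplicate probe ids: {sorted(dup)}")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(raw[:, j], errors="raise")
        except (ValueError, TypeError):
            for i, cell in enumerate(raw[:, j]):
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at probe "
                        f"{probe_ids[i]!r}, sample {col!r}"
                    ) from None
            raise
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path}: missing/non-finite value at probe {probe_ids[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    return ExpressionMatrix(probe_ids, list(df.columns), values)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write TSV with 12 significant digits (round-trip safe)."""
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.12g", index_label="probe_id")


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a clinical table.

    Categorical fields are restricted to their documented levels, with
    ``unknown`` retained as a distinct level (excluded listwise per-analysis
    downstream).  ``age_years`` may be NaN for unknown.
    """
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    dup = _duplicates(df["sample_id"])
    if dup:
        raise ValueError(f"duplicate sample ids: {sorted(dup)}")
    df["dmfs_time"] = pd.to_numeric(df["dmfs_time"], errors="raise").astype(float)
    df["dmfs_event"] = pd.to_numeric(df["dmfs_event"], errors="raise").astype(int)
    if (df["dmfs_time"] < 0).any():
        raise ValueError("negative dmfs_time")
    if not df["dmfs_event"].isin([0, 1]).all():
        raise ValueError("dmfs_event must be 0 or 1")
    if ((df["dmfs_event"] == 1) & (df["dmfs_time"] <= 0)).any():
        raise ValueError("dmfs_event=1 requires dmfs_time > 0")
    for col, levels in [
        ("er_status", ER_LEVELS),
        ("ln_status", LN_LEVELS),
        ("tumor_size_class", SIZE_LEVELS),
        ("treatment", TREATMENT_LEVELS),
    ]:
        df[col] = df[col].astype(str)
        bad = set(df[col]) - levels
        if bad:
            raise ValueError(f"invalid {col} values: {sorted(bad)}")
    df["grade"] = df["grade"].astype(str)
    bad = set(df["grade"]) - GRADE_LEVELS
    if bad:
        raise ValueError(f"invalid grade values: {sorted(bad)}")
    df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce").astype(float)
    df["study"] = df["study"].astype(str)
    if "subtype" in df.columns:
        df["subtype"] = df["subtype"].astype(str)
    return df.reset_index(drop=True)


def read_clinical(path: str | Path, time_unit: str = "years") -> pd.DataFrame:
    """Read a clinical TSV. ``time_unit='months'`` converts times by /12."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["age_years"] = df["age_years"].replace({"unknown": "", "NA": ""})
    df = validate_clinical(df)
    if time_unit == "months":
        df["dmfs_time"] = df["dmfs_time"] / 12.0
    elif time_unit != "years":
        raise ValueError(f"unknown time_unit {time_unit!r}")
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    cols = CLINICAL_COLUMNS + [c for c in out.columns if c not in CLINICAL_COLUMNS]
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_probe_map(path: str | Path) -> pd.Series:
    """Two-column TSV (probe_id, gene_symbol) -> Series probe -> gene."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: probe map needs 2 columns")
    probes, genes = df.iloc[:, 0], df.iloc[:, 1]
    dup = _duplicates(probes)
    if dup:
        raise ValueError(f"{path}: probe mapped more than once: {sorted(dup)}")
    return pd.Series(genes.to_numpy(), index=probes.to_numpy(), name="gene_symbol")


def write_probe_map(probe_map: pd.Series, path: str | Path) -> None:
    probe_map.rename_axis("probe_id").to_frame().to_csv(path, sep="\t")


def intersect_probes(matrices: Sequence[ExpressionMatrix]) -> list[str]:
    """Sorted intersection of probe id sets across matrices.

    Mirrors the multi-platform harmonization step where only probe sets
    common to all chip types are retained.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    common = set(matrices[0].probe_ids)
    for m in matrices[1:]:
        common &= set(m.probe_ids)
    if not common:
        raise ValueError("no probes common to all matrices")
    return sorted(common)


def delimit_followup(clinical: pd.DataFrame, horizon_years: float = 10.0) -> pd.DataFrame:
    """Administratively censor follow-up beyond ``horizon_years``.

    Samples with ``dmfs_time > horizon`` become (horizon, censored); events
    exactly at the horizon are kept as events (closed interval).  Idempotent.
    """
    if horizon_years <= 0:
        raise ValueError("horizon must be > 0")
    if (clinical["dmfs_time"] < 0).any():
        raise ValueError("negative dmfs_time")
    out = clinical.copy()
    late = out["dmfs_time"] > horizon_years
    out.loc[late, "dmfs_time"] = horizon_years
    out.loc[late, "dmfs_event"] = 0
    return out
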