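"""Cohort container, CSV input/output and the fibrinogen gating rule.

A cohort is a per-patient table of the 15 coagulation/fibrinolysis factors
(APTT, D-dimer, FDP, fibrinogen, Hct, Hgb, Plt, PT-sec, PT-INR, AP, AT, FMC,
PIC, TAT and the derived Hgb/fibrinogen ratio), a binary hematuria label
marking organ dysfunction, and optional blood-loss/transfusion metadata.
Analysis is restricted to records with fibrinogen < 170 mg/dL — the
previously established failure point of the coagulation system in massive
delivery hemorrhage — via :func:`filter_coagulation_failure`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .reference import ASSAY_CEILINGS, FACTORS, GATE_FBG_FAILURE, HGB_FBG_SCALE

__all__ = [
    "FACTOR_COLUMNS",
    "PatientRecord",
    "Cohort",
    "read_cohort_csv",
    "write_cohort_csv",
    "filter_coagulation_failure",
    "derive_hgb_fbg",
]

logger = logging.getLogger(__name__)

#: factor columns required on every analysable record
FACTOR_COLUMNS: tuple[str, ...] = tuple(FACTORS)

#: optional metadata columns (kept when present, never required)
META_COLUMNS: tuple[str, ...] = ("blood_loss_ml", "rcc", "ffp")

CSV_COLUMNS: tuple[str, ...] = (
    ("patient_id",) + FACTOR_COLUMNS + ("hematuria",) + META_COLUMNS
)

# case-insensitive header aliases -> canonical column names
_ALIASES = {
    "fibrinogen": "fbg",
    "d-dimer": "dd",
    "d_dimer": "dd",
    "ddimer": "dd",
    "hgb/fbg": "hgb_fbg",
    "hgb_fibrinogen": "hgb_fbg",
    "pt": "pt_sec",
    "pt-sec": "pt_sec",
    "pt-inr": "pt_inr",
    "inr": "pt_inr",
    "platelet": "plt",
    "hemoglobin": "hgb",
    "hematocrit": "hct",
    "id": "patient_id",
    "label": "hematuria",
    "organ_dysfunction": "hematuria",
}


def derive_hgb_fbg(hgb, fbg):
    """Hgb/fibrinogen ratio on the documented x1000 scale."""
    return np.asarray(hgb, dtype=float) / np.asarray(fbg, dtype=float) * HGB_FBG_SCALE


@dataclass(frozen=True)
class PatientRecord:
    """One patient's factor vector plus label and optional metadata.

    Units follow clinical reporting: fibrinogen and FDP in mg/dL, Hgb in
    g/dL, Hct in %, Plt in 10^3/uL, times in seconds; TAT and FMC are
    censored at their assay ceilings (120 and 250).
    """

    patient_id: str
    fbg: float
    fdp: float
    dd: float
    tat: float
    pic: float
    fmc: float
    ap: float
    at: float
    aptt: float
    pt_sec: float
    pt_inr: float
    hgb: float
    hct: float
    plt: float
    hgb_fbg: float
    hematuria: bool
    blood_loss_ml: Optional[float] = None
    rcc: Optional[bool] = None
    ffp: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in FACTOR_COLUMNS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.tat > ASSAY_CEILINGS["tat"] + 1e-9:
            raise ValueError(f"TAT exceeds assay ceiling: {self.tat}")
        if self.fmc > ASSAY_CEILINGS["fmc"] + 1e-9:
            raise ValueError(f"FMC exceeds assay ceiling: {self.fmc}")


@dataclass
class Cohort:
    """Ordered per-patient factor table with a binary hematuria label.

    Thin wrapper over a :class:`pandas.DataFrame` whose columns follow the
    documented dictionary.  ``n_excluded`` counts input rows dropped for
    missing required factors.
    """

    df: pd.DataFrame
    provenance: str = "unspecified"
    n_excluded: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in FACTOR_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort is missing factor columns: {missing}")
        if "hematuria" not in self.df.columns:
            raise ValueError("cohort is missing the hematuria label column")
        if "patient_id" not in self.df.columns:
            self.df = self.df.copy()
            self.df.insert(0, "patient_id", [f"p{i:04d}" for i in range(len(self.df))])
        if self.df["patient_id"].duplicated().any():
            raise ValueError("patient_id values must be unique")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> np.ndarray:
        return self.df["hematuria"].to_numpy(dtype=bool)

    @property
    def n_hematuria(self) -> int:
        return int(self.labels.sum())

    def factor_matrix(self, columns: Optional[list[str]] = None) -> np.ndarray:
        cols = list(columns) if columns is not None else list(FACTOR_COLUMNS)
        return self.df[cols].to_numpy(dtype=float)

    def records(self) -> Iterator[PatientRecord]:
        for _, row in self.df.iterrows():
            kwargs = {c: row[c] for c in ("patient_id",) + FACTOR_COLUMNS}
            kwargs["patient_id"] = str(kwargs["patient_id"])
            kwargs["hematuria"] = bool(row["hematuria"])
            for c in META_COLUMNS:
                if c in row.index and pd.notna(row[c]):
                    kwargs[c] = bool(row[c]) if c in ("rcc", "ffp") else float(row[c])
            yield PatientRecord(**kwargs)

    def group(self, hematuria: bool) -> pd.DataFrame:
        return self.df[self.df["hematuria"].astype(bool) == hematuria]


def read_cohort_csv(path: str | Path) -> Cohort:
    """Read a cohort from CSV (comma-separated, UTF-8, header required).

    Header names are matched case-insensitively with a small alias
    dictionary.  Rows with any required factor missing are excluded and
    counted in ``n_excluded``.  A missing Hgb/fibrinogen column is derived
    from Hgb and fibrinogen.  Missing values are empty strings.
    """
    path = Path(path)
    raw = pd.read_csv(path, float_precision="round_trip")
    raw.columns = [
        _ALIASES.get(str(c).strip().lower(), str(c).strip().lower()) for c in raw.columns
    ]
    if "hematuria" not in raw.columns:
        raise ValueError(f"{path}: no hematuria label column")
    if "hgb_fbg" not in raw.columns and {"hgb", "fbg"} <= set(raw.columns):
        raw["hgb_fbg"] = derive_hgb_fbg(raw["hgb"], raw["fbg"])
    required = [c for c in FACTOR_COLUMNS] + ["hematuria"]
    missing_cols = [c for c in required if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")

    complete = raw[required].notna().all(axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.info("%s: excluded %d rows with missing required data", path, n_excluded)
    df = raw.loc[complete].copy()
    for c in FACTOR_COLUMNS:
        df[c] = df[c].astype(float)
    df["hematuria"] = df["hematuria"].astype(int).astype(bool)
    if "patient_id" in df.columns:
        df["patient_id"] = df["patient_id"].astype(str)
    if (df["fbg"] > 1000).any():
        logger.warning(
            "%s: fibrinogen values > 1000 mg/dL present; check units", path
        )
    keep = [c for c in CSV_COLUMNS if c in df.columns]
    return Cohort(df=df[keep], provenance=str(path), n_excluded=n_excluded)


def write_cohort_csv(cohort: Cohort, path: str | Path) -> Path:
    """Write the cohort in the documented CSV dialect; returns the path."""
    path = Path(path)
    df = cohort.df.copy()
    df["hematuria"] = df["hematuria"].astype(int)
    for c in ("rcc", "ffp"):
        if c in df.columns:
            df[c] = df[c].astype("Int64")
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def filter_coagulation_failure(
    cohort: Cohort, threshold: float = GATE_FBG_FAILURE
) -> Cohort:
    """Keep records with fibrinogen strictly below ``threshold`` (mg/dL).

    The strict inequality mirrors the coagulation-failure gate at
    170 mg/dL; original record order is preserved.
    """
    mask = cohort.df["fbg"].to_numpy(dtype=float) < threshold
    out = cohort.df.loc[mask].copy()
    if out.empty:
        logger.warning("fibrinogen gate at %g left no records", threshold)
    return Cohort(
        df=out,
        provenance=f"{cohort.provenance} | fbg<{threshold:g}",
        n_excluded=cohort.n_excluded,
    )
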