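"""Long-format concentration-time dataset container, validation and CSV I/O.

One row per observation (NONMEM-style): subject ID, study label, clock time
in decimal hours, the observed concentration (DV, ng/dL), and the subject's
covariates repeated on every row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structural import classify_season, semesters_from_season, wrap24

REQUIRED_COLUMNS = ["ID", "CLOCKTIME", "DV"]
COVARIATE_COLUMNS = ["AGE", "SEM1", "SEM2", "SEASON", "WT", "BMI", "HT", "ETHN"]
ALL_COLUMNS = ["ID", "STUDY", "CLOCKTIME", "DV"] + COVARIATE_COLUMNS


class DatasetError(ValueError):
    """Raised for schema or row-level validation failures."""


@dataclass
class Dataset:
    """Validated long-format observations plus provenance metadata."""

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)
        validate_dataframe(self.df)

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self):
        return self.df["ID"].unique()

    def covariate_table(self) -> pd.DataFrame:
        """One row per subject with its (constant) covariates."""
        cols = [c for c in ["ID", "STUDY"] + COVARIATE_COLUMNS if c in self.df.columns]
        return self.df[cols].groupby("ID", sort=False).first().reset_index()

    def subject_groups(self):
        return self.df.groupby("ID", sort=False)


def validate_dataframe(df: pd.DataFrame, allow_duplicates: bool = True) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise DatasetError("dataset has no observations")
    dv = pd.to_numeric(df["DV"], errors="coerce")
    bad = df.index[~(dv > 0)]
    if len(bad):
        raise DatasetError(f"non-positive or unparseable DV at rows {list(bad[:5])}")
    t = pd.to_numeric(df["CLOCKTIME"], errors="coerce")
    if t.isna().any():
        raise DatasetError("unparseable CLOCKTIME values")
    if ((t < 0) | (t >= 24)).any():
        raise DatasetError("CLOCKTIME must lie in [0, 24); wrap on read")
    for col in COVARIATE_COLUMNS:
        if col in df.columns:
            nun = df.groupby("ID", sort=False)[col].nunique(dropna=False)
            varying = nun[nun > 1]
            if len(varying):
                raise DatasetError(
                    f"covariate {col} varies within subject(s) {list(varying.index[:5])}"
                )
    if not allow_duplicates:
        if df.duplicated(subset=["ID", "CLOCKTIME"]).any():
            raise DatasetError("duplicate (ID, CLOCKTIME) pairs present")


def _parse_clock(value) -> float:
    """Accept decimal hours or 'HH:MM' strings."""
    if isinstance(value, str) and ":" in value:
        hh, mm = value.split(":")
        return float(int(hh)) + float(mm) / 60.0
    return float(value)


def read_dataset(path, dose_clock: float = 8.0, drop_nonpositive: bool = False) -> Dataset:
    """Read and validate a CSV dataset.

    Accepts either a ``CLOCKTIME`` column (decimal hours or HH:MM) or a
    ``TIME`` column of hours-from-reference that is anchored via
    ``DOSECLOCK`` (a column or the ``dose_clock`` argument; clock time =
    ``(DOSECLOCK + TIME) mod 24``).  A ``DATE`` column (ISO) is converted
    to SEASON/SEM1/SEM2.  ``DV <= 0`` rows raise unless
    ``drop_nonpositive`` is set, in which case they are dropped and the
    count recorded in provenance.
    """
    df = pd.read_csv(path)
    report = {"source": str(path), "n_rows_read": len(df)}
    if "CLOCKTIME" in df.columns:
        df["CLOCKTIME"] = wrap24(df["CLOCKTIME"].map(_parse_clock))
    elif "TIME" in df.columns:
        anchor = df["DOSECLOCK"].map(_parse_clock) if "DOSECLOCK" in df.columns else dose_clock
        df["CLOCKTIME"] = wrap24(anchor + pd.to_numeric(df["TIME"], errors="raise"))
    else:
        raise DatasetError("need a CLOCKTIME column, or TIME (+ optional DOSECLOCK)")
    if "DATE" in df.columns and "SEASON" not in df.columns:
        seasons = df["DATE"].map(lambda d: classify_season(d)[0])
        df["SEASON"] = seasons
    if "SEASON" in df.columns:
        sems = df["SEASON"].map(semesters_from_season)
        if "SEM1" not in df.columns:
            df["SEM1"] = [s[0] for s in sems]
        if "SEM2" not in df.columns:
            df["SEM2"] = [s[1] for s in sems]
    if drop_nonpositive and "DV" in df.columns:
        keep = pd.to_numeric(df["DV"], errors="coerce") > 0
        report["n_dropped_nonpositive"] = int((~keep).sum())
        df = df[keep]
    keep_cols = [c for c in df.columns if c in ALL_COLUMNS or c in ("DATE",)]
    return Dataset(df[keep_cols].copy(), provenance=report)


def write_dataset(dataset: Dataset, path) -> None:
    """Write the dataset as CSV (header, empty fields for missing values)."""
    cols = [c for c in ALL_COLUMNS if c in dataset.df.columns]
    dataset.df[cols].to_csv(path, index=False)
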