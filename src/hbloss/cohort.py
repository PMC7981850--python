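"""Cohort tables: reading, validating, writing and complete-case filtering.

A cohort is a table of donor records, one row per donor, with the canonical
CSV dialect (comma-separated, UTF-8, header row):

    donor_id,sex,height_cm,weight_kg,age,hb_pre,hb_post,hct_pre,hct_post,
    plt_pre,leuco_pre,hb_loss_g

Heights are stored in centimetres in files (mirroring clinical charts) and
converted to metres at the API boundary.  Missing optional values are empty
cells.  The only missing-data policy offered is listwise deletion
(complete-case analysis): records lacking any required field are dropped,
never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .formulas import DonorProfile, PeriProcedureLabs, Sex

#: canonical column order for the CSV dialect
COLUMNS = [
    "donor_id",
    "sex",
    "height_cm",
    "weight_kg",
    "age",
    "hb_pre",
    "hb_post",
    "hct_pre",
    "hct_post",
    "plt_pre",
    "leuco_pre",
    "hb_loss_g",
]

#: mandatory columns a file must at least name in its header
MANDATORY = ["sex", "height_cm", "weight_kg", "hb_pre", "hb_post"]

_NUMERIC = [c for c in COLUMNS if c not in ("donor_id", "sex")]

#: logical field names accepted by complete_case_filter, mapped to columns
FIELD_TO_COLUMN = {
    "sex": "sex",
    "height": "height_cm",
    "weight": "weight_kg",
    "age": "age",
    "hb_pre": "hb_pre",
    "hb_post": "hb_post",
    "hct_pre": "hct_pre",
    "hct_post": "hct_post",
    "plt_pre": "plt_pre",
    "leuco_pre": "leuco_pre",
    "observed_hb_loss": "hb_loss_g",
}

DEFAULT_REQUIRED = ("sex", "height", "weight", "hb_pre", "hb_post", "observed_hb_loss")


@dataclass(frozen=True)
class CohortRecord:
    donor_id: str
    profile: DonorProfile
    labs: PeriProcedureLabs
    observed_hb_loss: Optional[float] = None

    def __post_init__(self):
        if self.observed_hb_loss is not None and self.observed_hb_loss < 0:
            raise ValueError("observed_hb_loss must be >= 0 g")


@dataclass(frozen=True)
class FilterReport:
    n_in: int
    n_dropped: int
    n_out: int
    required: tuple

    def __post_init__(self):
        assert self.n_in == self.n_dropped + self.n_out


class CohortTable:
    """Ordered collection of donor records backed by a pandas DataFrame.

    Iteration order is the row order of the underlying frame and is stable
    across filtering.  ``provenance`` records where the table came from
    (file path, or generator parameters + seed).
    """

    def __init__(self, df: pd.DataFrame, provenance: str = "", issues: Optional[list] = None):
        df = df.copy()
        for col in COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        self.df = df[COLUMNS].reset_index(drop=True)
        if self.df["donor_id"].isna().any():
            missing = self.df["donor_id"].isna()
            self.df.loc[missing, "donor_id"] = [f"D{i:05d}" for i in np.flatnonzero(missing)]
        self.df["donor_id"] = self.df["donor_id"].astype(str)
        if self.df["donor_id"].duplicated().any():
            dup = self.df.loc[self.df["donor_id"].duplicated(), "donor_id"].iloc[0]
            raise ValueError(f"duplicate donor_id {dup!r}")
        self.provenance = provenance
        self.issues = list(issues or [])

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[CohortRecord]:
        for _, row in self.df.iterrows():
            yield self._to_record(row)

    @staticmethod
    def _opt(row, col):
        v = row[col]
        return None if pd.isna(v) else float(v)

    def _to_record(self, row) -> CohortRecord:
        profile = DonorProfile(
            sex=Sex.parse(row["sex"]),
            height=float(row["height_cm"]) / 100.0,
            weight=float(row["weight_kg"]),
            age=self._opt(row, "age"),
        )
        labs = PeriProcedureLabs(
            hb_pre=float(row["hb_pre"]),
            hb_post=self._opt(row, "hb_post"),
            hct_pre=self._opt(row, "hct_pre"),
            hct_post=self._opt(row, "hct_post"),
            plt_pre=self._opt(row, "plt_pre"),
            leuco_pre=self._opt(row, "leuco_pre"),
        )
        return CohortRecord(
            donor_id=str(row["donor_id"]),
            profile=profile,
            labs=labs,
            observed_hb_loss=self._opt(row, "hb_loss_g"),
        )

    def record(self, i: int) -> CohortRecord:
        return self._to_record(self.df.iloc[i])


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV in the canonical dialect.

    Empty cells become missing optional fields.  Cells that fail numeric
    parsing are collected into the table's per-row ``issues`` list (and the
    cell treated as missing) rather than silently becoming NaN.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    for col in MANDATORY:
        if col not in raw.columns:
            raise ValueError(f"missing mandatory column {col!r} in {path}")
    issues = []
    df = pd.DataFrame(index=raw.index)
    df["donor_id"] = raw["donor_id"].str.strip() if "donor_id" in raw.columns else np.nan
    sex = raw["sex"].str.strip()
    parsed_sex = []
    for i, s in sex.items():
        if pd.isna(s) or s == "":
            parsed_sex.append(np.nan)
        else:
            parsed_sex.append(Sex.parse(s).value)  # raises on unrecognised codes
    df["sex"] = parsed_sex
    for col in _NUMERIC:
        if col not in raw.columns:
            df[col] = np.nan
            continue
        parsed = np.full(len(raw), np.nan)
        for i, cell in enumerate(raw[col]):
            if pd.isna(cell) or str(cell).strip() == "":
                continue
            try:
                # python float() round-trips repr output exactly
                parsed[i] = float(cell)
            except ValueError:
                issues.append((int(i), col, cell))
        df[col] = parsed
    if len(df) == 0:
        warnings.warn(f"{path}: header only, returning empty cohort", UserWarning)
    return CohortTable(df, provenance=str(path), issues=issues)


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort in the canonical CSV dialect (round-trips with read_cohort)."""
    table.df.to_csv(path, index=False)


def complete_case_filter(
    table: CohortTable, required: Sequence[str] = DEFAULT_REQUIRED
) -> tuple[CohortTable, FilterReport]:
    """Keep exactly the records with every required field present.

    Mirrors the complete-case rule used to define the analysis cohort
    (e.g. 478 donors, 77 missing post-collection CBC, 401 analysed).
    Idempotent: filtering a filtered table changes nothing.
    """
    cols = []
    for f in required:
        if f not in FIELD_TO_COLUMN:
            raise ValueError(f"unknown required field {f!r}; known: {sorted(FIELD_TO_COLUMN)}")
        cols.append(FIELD_TO_COLUMN[f])
    mask = table.df[cols].notna().all(axis=1)
    out = CohortTable(
        table.df.loc[mask],
        provenance=f"{table.provenance} | complete-case on {','.join(required)}",
    )
    report = FilterReport(
        n_in=len(table), n_dropped=int((~mask).sum()), n_out=len(out), required=tuple(required)
    )
    return out, report


def to_dataframe(table: CohortTable) -> pd.DataFrame:
    """Copy of the underlying canonical DataFrame (height in cm, as stored)."""
    return table.df.copy()
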