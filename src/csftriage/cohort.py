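"""Cohort container and CSV I/O.

A cohort is a table with one row per patient: identifier, age, sex,
optional clinical diagnosis, and the cataloged feature values with explicit
missingness (blank CSV cells, NaN in memory). Validation is strict: values
outside a feature's plausible range are rejected, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import (
    DEFAULT_CATALOG,
    GROUPS,
    META_COLUMNS,
    SCHEMA_COLUMNS,
    FeatureSpec,
    catalog_by_name,
)

SEX_CODES = {"F": 1.0, "M": 0.0}  # model coding: 0=male, 1=female


@dataclass
class Cohort:
    """A validated patient table.

    Attributes
    ----------
    data : pandas.DataFrame
        One row per patient with columns ``patient_id`` (str), ``age``
        (float, years), ``sex`` ("F"/"M"), ``diagnosis`` (group label or
        NaN) and one float column per cataloged feature (NaN = missing).
    catalog : tuple of FeatureSpec
        The feature inventory the columns refer to.
    corrected : bool
        True once age/sex covariate correction has been applied.
    """

    data: pd.DataFrame
    catalog: tuple[FeatureSpec, ...] = field(default=DEFAULT_CATALOG)
    corrected: bool = False

    def __post_init__(self) -> None:
        validate_cohort(self)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.catalog)

    @property
    def n(self) -> int:
        return len(self.data)

    def groups(self) -> dict[str, pd.DataFrame]:
        """Rows split by diagnosis label (unlabeled rows excluded)."""
        lab = self.data["diagnosis"]
        return {g: self.data.loc[lab == g] for g in GROUPS if (lab == g).any()}

    def subset(self, mask) -> "Cohort":
        """A new cohort restricted to rows selected by ``mask``."""
        return replace(self, data=self.data.loc[mask].reset_index(drop=True))

    def sex_numeric(self) -> np.ndarray:
        """Sex coded 0=male, 1=female."""
        return self.data["sex"].map(SEX_CODES).to_numpy(float)


def validate_cohort(cohort: Cohort) -> None:
    df = cohort.data
    specs = catalog_by_name(cohort.catalog)
    expected = set(META_COLUMNS) | set(specs)
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise ValueError(f"unknown column(s): {', '.join(unknown)}")
    missing_cols = [c for c in META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing column(s): {', '.join(missing_cols)}")

    ids = df["patient_id"]
    if ids.isna().any():
        raise ValueError("patient_id may not be missing")
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate patient_id: {dup.iloc[0]!r}")

    age = df["age"]
    if age.isna().any() or (age <= 0).any():
        raise ValueError("age must be present and positive for every patient")
    bad_sex = ~df["sex"].isin(SEX_CODES)
    if bad_sex.any():
        raise ValueError(
            f"sex must be F or M (patient {df.loc[bad_sex, 'patient_id'].iloc[0]!r})"
        )
    diag = df["diagnosis"]
    bad_diag = diag.notna() & ~diag.isin(GROUPS)
    if bad_diag.any():
        raise ValueError(
            f"unknown diagnosis {diag[bad_diag].iloc[0]!r} "
            f"(patient {df.loc[bad_diag, 'patient_id'].iloc[0]!r})"
        )

    for name, spec in specs.items():
        if name not in df.columns:
            continue
        col = pd.to_numeric(df[name], errors="coerce")
        bad_parse = col.isna() & df[name].notna()
        if bad_parse.any():
            pid = df.loc[bad_parse, "patient_id"].iloc[0]
            raise ValueError(f"non-numeric value in column {name} (patient {pid!r})")
        if cohort.corrected and spec.kind == "continuous":
            # residualization may shift values slightly off the raw scale
            continue
        present = col.notna()
        ok = col[present].map(spec.in_range)
        if not ok.all():
            row = ok[~ok].index[0]
            raise ValueError(
                f"value {col[row]} out of range for {name} "
                f"[{spec.lower}, {spec.upper}] (patient {df.loc[row, 'patient_id']!r})"
            )


def read_cohort(path, catalog: tuple[FeatureSpec, ...] = DEFAULT_CATALOG) -> Cohort:
    """Read a cohort CSV (header row, one row per patient, blanks = missing)."""
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "sex": str, "diagnosis": str},
        keep_default_na=True,
        na_values=[""],
    )
    specs = catalog_by_name(catalog)
    for name in specs:
        if name in df.columns:
            df[name] = pd.to_numeric(df[name], errors="coerce").astype(float)
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce").astype(float)
    return Cohort(data=df.reset_index(drop=True), catalog=catalog)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort CSV with blanks for missing values.

    ``read_cohort(write_cohort(c))`` is the identity (text fields exact,
    numerics via repr round-trip).
    """
    cols = [c for c in SCHEMA_COLUMNS if c in cohort.data.columns]
    extra = [c for c in cohort.data.columns if c not in cols]
    out = cohort.data[cols + extra].copy()
    out.to_csv(path, index=False, float_format="%.17g", na_rep="")
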