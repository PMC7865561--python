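"""Reading, validation, joining and writing of the pipeline's tabular inputs.

Two table kinds flow through the pipeline:

* a *feature table* — one row per subject, one numeric column per
  MRI-derived measure (T1 morphometry or DTI tract metrics); feature
  identity is opaque to the pipeline, and
* a *cohort table* — one row per subject with chronological age, sex,
  head coil, APOE-e4 carrier status and optional clinical scores.

Both are plain CSV/TSV files with a header row whose first column is
``subject_id``.  Values are written back with full ``repr`` precision so
that a write/read round trip is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "CohortTable",
    "AnalysisDataset",
    "read_feature_table",
    "write_feature_table",
    "read_cohort_table",
    "write_cohort_table",
    "assemble_dataset",
    "TableFormatError",
]

MODALITIES = ("T1", "DTI")
SEX_LEVELS = ("male", "female")
COIL_LEVELS = ("HNS", "8HRBRAIN")

#: cohort columns with a fixed meaning; anything else is carried as an
#: opaque clinical/covariate field.
_COHORT_REQUIRED = ("subject_id", "age")
_COHORT_KNOWN = ("subject_id", "age", "sex", "head_coil", "apoe_e4", "icv")


class TableFormatError(ValueError):
    """Raised when an input table violates the declared schema."""


def _infer_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


@dataclass
class FeatureTable:
    """Subject-by-feature numeric matrix for one modality.

    ``values`` is dense float64 with shape ``(len(subject_ids),
    len(feature_names))``; all entries are finite after validation.
    """

    modality: str
    subject_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise TableFormatError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        self.values = np.asarray(self.values, dtype=float)
        dup = _duplicates(self.subject_ids)
        if dup:
            raise TableFormatError(f"duplicate subject ids: {sorted(dup)}")
        dup = _duplicates(self.feature_names)
        if dup:
            raise TableFormatError(f"duplicate feature names: {sorted(dup)}")
        if self.values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise TableFormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.feature_names)} features"
            )
        if self.values.size == 0:
            raise TableFormatError("empty feature table")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise TableFormatError(
                f"non-finite value at subject {self.subject_ids[bad[0]]!r}, "
                f"feature {self.feature_names[bad[1]]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def subset(self, subject_ids: list[str]) -> "FeatureTable":
        """Restrict to ``subject_ids`` in the given order."""
        index = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in index]
        if missing:
            raise KeyError(f"subjects not in {self.modality} table: {missing}")
        rows = [index[s] for s in subject_ids]
        return FeatureTable(
            modality=self.modality,
            subject_ids=list(subject_ids),
            feature_names=list(self.feature_names),
            values=self.values[rows],
        )


def _duplicates(items) -> set:
    seen, dup = set(), set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


def read_feature_table(
    path: str | Path, modality: str, sep: str | None = None
) -> FeatureTable:
    """Read a CSV/TSV feature table (first column ``subject_id``).

    The delimiter is inferred from the extension (``.tsv``/``.txt`` →
    tab, otherwise comma) unless ``sep`` is given.  Column order is
    preserved.  Duplicate subject ids, non-numeric cells and empty
    tables raise :class:`TableFormatError` naming the offender.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_infer_sep(path, sep), dtype={0: str})
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise TableFormatError(f"{path}: empty feature table")
    subject_ids = df.iloc[:, 0].astype(str).tolist()
    feature_names = [str(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:]
    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(np.isnan(values) & ~raw.isna().to_numpy())
    if len(bad):
        r, c = bad[0]
        raise TableFormatError(
            f"{path}: non-numeric cell at subject {subject_ids[r]!r}, "
            f"column {feature_names[c]!r}: {raw.iat[r, c]!r}"
        )
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise TableFormatError(
            f"{path}: missing value at subject {subject_ids[r]!r}, "
            f"column {feature_names[c]!r}"
        )
    return FeatureTable(modality, subject_ids, feature_names, values)


def write_feature_table(table: FeatureTable, path: str | Path, sep: str | None = None) -> None:
    """Write a feature table; values serialized at repr precision."""
    path = Path(path)
    df = table.to_frame()
    df.to_csv(path, sep=_infer_sep(path, sep), index=False, float_format=None)


@dataclass
class CohortTable:
    """Per-subject demographics, covariates and optional clinical scores.

    Backed by a DataFrame with at least ``subject_id`` and ``age``;
    ``sex``, ``head_coil``, ``apoe_e4`` and ``icv`` are validated when
    present, every other column rides along as an opaque numeric
    clinical field.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        for col in _COHORT_REQUIRED:
            if col not in df.columns:
                raise TableFormatError(f"cohort table missing required column {col!r}")
        df = df.copy()
        df["subject_id"] = df["subject_id"].astype(str)
        dup = _duplicates(df["subject_id"].tolist())
        if dup:
            raise TableFormatError(f"duplicate subject ids: {sorted(dup)}")
        age = pd.to_numeric(df["age"], errors="coerce")
        if age.isna().any():
            who = df.loc[age.isna(), "subject_id"].tolist()
            raise TableFormatError(f"missing or non-numeric age for subjects: {who}")
        if (age <= 0).any():
            who = df.loc[age <= 0, "subject_id"].tolist()
            raise TableFormatError(f"non-positive age for subjects: {who}")
        df["age"] = age.astype(float)
        if "sex" in df.columns:
            bad = set(df["sex"].dropna()) - set(SEX_LEVELS)
            if bad:
                raise TableFormatError(
                    f"unrecognized sex codes {sorted(bad)}; expected {SEX_LEVELS}"
                )
        if "head_coil" in df.columns:
            bad = set(df["head_coil"].dropna()) - set(COIL_LEVELS)
            if bad:
                raise TableFormatError(
                    f"unrecognized head_coil codes {sorted(bad)}; expected {COIL_LEVELS}"
                )
        if "apoe_e4" in df.columns:
            e4 = pd.to_numeric(df["apoe_e4"], errors="coerce")
            bad = ~e4.isin([0, 1]) & df["apoe_e4"].notna()
            if bad.any():
                raise TableFormatError(
                    "apoe_e4 must be coded 0 (non-carrier) / 1 (carrier); got "
                    f"{df.loc[bad, 'apoe_e4'].tolist()}"
                )
            df["apoe_e4"] = e4
        self.data = df.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return self.data["subject_id"].tolist()

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def clinical_fields(self) -> list[str]:
        return [c for c in self.data.columns if c not in _COHORT_KNOWN]

    def require_apoe(self) -> None:
        if "apoe_e4" not in self.data.columns or self.data["apoe_e4"].isna().any():
            raise TableFormatError(
                "apoe_e4 carrier status required for every subject in a group comparison"
            )


def read_cohort_table(path: str | Path, sep: str | None = None) -> CohortTable:
    """Read and validate a cohort table (see :class:`CohortTable`)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_infer_sep(path, sep))
    return CohortTable(df)


def write_cohort_table(cohort: CohortTable, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    cohort.data.to_csv(path, sep=_infer_sep(path, sep), index=False)


@dataclass
class AnalysisDataset:
    """Cohort rows joined with one or more feature tables on the common
    subject set, with a provenance log of listwise-dropped subjects."""

    cohort: CohortTable
    features: dict[str, FeatureTable]
    drop_log: list[tuple[str, str]]  # (subject_id, reason)

    @property
    def subject_ids(self) -> list[str]:
        return self.cohort.subject_ids

    @property
    def n_subjects(self) -> int:
        return self.cohort.n_subjects


def assemble_dataset(cohort: CohortTable, *features: FeatureTable) -> AnalysisDataset:
    """Inner-join cohort and feature tables on ``subject_id``.

    Subjects missing from any table are dropped listwise; each drop is
    logged with the table it was missing from.  Retained subject order
    follows the cohort table.  An empty intersection is an error.
    """
    if not features:
        raise ValueError("assemble_dataset requires at least one feature table")
    drop_log: list[tuple[str, str]] = []
    cohort_ids = cohort.subject_ids
    keep = list(cohort_ids)
    for ft in features:
        present = set(ft.subject_ids)
        for sid in keep:
            if sid not in present:
                drop_log.append((sid, f"missing {ft.modality}"))
        keep = [s for s in keep if s in present]
    cohort_set = set(cohort_ids)
    for ft in features:
        for sid in ft.subject_ids:
            if sid not in cohort_set:
                drop_log.append((sid, "missing cohort row"))
    if not keep:
        raise TableFormatError("no subjects common to the cohort and all feature tables")
    sub_cohort = CohortTable(
        cohort.data[cohort.data["subject_id"].isin(keep)].reset_index(drop=True)
    )
    return AnalysisDataset(
        cohort=sub_cohort,
        features={ft.modality: ft.subset(keep) for ft in features},
        drop_log=drop_log,
    )
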