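"""Cohort feature tables: containers, CSV I/O, validation and split primitives.

The data model mirrors how internal-calibration studies organise their
inputs: a *radiome* matrix of target-ROI features (patients x features), a
*surrogate* matrix of control-region (CR) features (patients x surrogates,
each surrogate tagged with the CR it was extracted from), a binary label
vector, and optional patient grouping identifiers for lesion-level rows.

CSV dialect: comma-separated, UTF-8, ``.`` decimal point.  The identifier
column is named ``id``, labels live in a ``label`` column and the patient
grouping in ``group_id`` (defaulting to ``id``).  Surrogate columns encode
their control region as ``CR::feature``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RadiomeMatrix",
    "SurrogateMatrix",
    "CohortLabels",
    "Cohort",
    "SeriesRecord",
    "SeriesTable",
    "ValidationReport",
    "load_cohort",
    "validate_cohort",
    "split_train_test",
]


class AlignmentError(ValueError):
    """Rows of paired tables could not be matched by identifier."""


def _as_2d_float(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {arr.shape}")
    return arr


@dataclass
class RadiomeMatrix:
    """Patients x target-ROI features, the quantity being calibrated."""

    values: np.ndarray
    patient_ids: list[str]
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values)
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        n, m = self.values.shape
        if n != len(self.patient_ids):
            raise ValueError("row count does not match patient_ids")
        if m != len(self.feature_names):
            raise ValueError("column count does not match feature_names")
        if len(set(self.feature_names)) != m:
            raise ValueError("feature names must be unique")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, idx) -> "RadiomeMatrix":
        idx = np.asarray(idx)
        return RadiomeMatrix(
            self.values[idx], [self.patient_ids[i] for i in idx], list(self.feature_names)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "id", self.patient_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RadiomeMatrix":
        ids, values = _split_id_column(df, "radiome")
        return cls(values.to_numpy(dtype=float), ids, list(values.columns))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "RadiomeMatrix":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


@dataclass
class SurrogateMatrix:
    """Patients x CR-derived candidate surrogates with CR provenance."""

    values: np.ndarray
    patient_ids: list[str]
    surrogate_names: list[str]
    cr_of: dict[str, str]

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values)
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.surrogate_names = [str(s) for s in self.surrogate_names]
        missing = [s for s in self.surrogate_names if s not in self.cr_of]
        if missing:
            raise ValueError(f"cr_of missing for surrogates: {missing[:5]}")
        if len(set(self.surrogate_names)) != len(self.surrogate_names):
            raise ValueError("surrogate names must be unique")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_surrogates(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, idx) -> "SurrogateMatrix":
        idx = np.asarray(idx)
        return SurrogateMatrix(
            self.values[idx],
            [self.patient_ids[i] for i in idx],
            list(self.surrogate_names),
            dict(self.cr_of),
        )

    def columns_encoded(self) -> list[str]:
        return [f"{self.cr_of[s]}::{s}" for s in self.surrogate_names]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns_encoded())
        df.insert(0, "id", self.patient_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurrogateMatrix":
        ids, values = _split_id_column(df, "surrogate")
        names, cr_of = [], {}
        for col in values.columns:
            if "::" in col:
                cr, name = col.split("::", 1)
            else:
                cr, name = "unknown", col
            # keep the full encoded name unique even if two CRs share a feature name
            key = name if name not in cr_of else col
            names.append(key)
            cr_of[key] = cr
        return cls(values.to_numpy(dtype=float), ids, names, cr_of)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "SurrogateMatrix":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


@dataclass
class CohortLabels:
    """Binary annotation per row plus patient-level grouping for lesion rows."""

    b: np.ndarray
    patient_ids: list[str]
    group_ids: list[str] = field(default=None)

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b).astype(int)
        if not np.isin(self.b, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        self.patient_ids = [str(p) for p in self.patient_ids]
        if self.group_ids is None:
            self.group_ids = list(self.patient_ids)
        else:
            self.group_ids = [str(g) for g in self.group_ids]
        if len(self.b) != len(self.patient_ids) or len(self.b) != len(self.group_ids):
            raise ValueError("labels, ids and groups must have equal length")

    def subset_rows(self, idx) -> "CohortLabels":
        idx = np.asarray(idx)
        return CohortLabels(
            self.b[idx],
            [self.patient_ids[i] for i in idx],
            [self.group_ids[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.patient_ids, "label": self.b, "group_id": self.group_ids}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class Cohort:
    """Aligned (radiome, surrogates, labels) triple."""

    radiome: RadiomeMatrix
    surrogates: SurrogateMatrix
    labels: CohortLabels

    def __post_init__(self) -> None:
        if self.radiome.patient_ids != self.surrogates.patient_ids:
            raise AlignmentError("radiome and surrogate patient_ids differ")
        if self.radiome.patient_ids != self.labels.patient_ids:
            raise AlignmentError("radiome and label patient_ids differ")

    @property
    def n(self) -> int:
        return self.radiome.n_patients

    def subset(self, idx) -> "Cohort":
        return Cohort(
            self.radiome.subset_rows(idx),
            self.surrogates.subset_rows(idx),
            self.labels.subset_rows(idx),
        )

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.radiome.to_csv(directory / "radiome.csv")
        self.surrogates.to_csv(directory / "surrogates.csv")
        self.labels.to_csv(directory / "labels.csv")

    @classmethod
    def load(cls, directory) -> "Cohort":
        directory = Path(directory)
        return load_cohort(
            directory / "radiome.csv",
            directory / "surrogates.csv",
            directory / "labels.csv",
        )


@dataclass
class SeriesRecord:
    """One acquisition condition of a perturbation or phantom series."""

    condition: str
    radiome: RadiomeMatrix
    surrogates: SurrogateMatrix
    family: str | None = None
    level: int | None = None


@dataclass
class SeriesTable:
    """Ordered records of in-silico noise variants or phantom protocol scans.

    ``kind="perturbation"``: one baseline record (``level=0``) plus
    families x monotone noise levels, rows aligned with the cohort.
    ``kind="phantom"``: >= 2 protocol conditions of a fixed object, no
    biological variation; rows are acquisitions, not patients.
    """

    kind: str
    records: list[SeriesRecord]

    def __post_init__(self) -> None:
        if self.kind not in ("perturbation", "phantom"):
            raise ValueError(f"unknown series kind: {self.kind}")

    @property
    def families(self) -> list[str]:
        return sorted({r.family for r in self.records if r.family is not None})

    def baseline(self) -> SeriesRecord:
        for r in self.records:
            if r.family is None or r.level == 0:
                return r
        raise ValueError("perturbation series has no baseline record")

    def family_levels(self, family: str) -> list[SeriesRecord]:
        recs = [r for r in self.records if r.family == family and r.level]
        return sorted(recs, key=lambda r: r.level)

    def subset_rows(self, idx) -> "SeriesTable":
        if self.kind != "perturbation":
            return self
        return SeriesTable(
            self.kind,
            [
                SeriesRecord(
                    r.condition,
                    r.radiome.subset_rows(idx),
                    r.surrogates.subset_rows(idx),
                    r.family,
                    r.level,
                )
                for r in self.records
            ],
        )

    def to_frames(self) -> pd.DataFrame:
        """Long-format table with condition metadata columns, for CSV export."""
        parts = []
        for r in self.records:
            df = pd.concat(
                [r.radiome.to_frame(), r.surrogates.to_frame().drop(columns="id")],
                axis=1,
            )
            df.insert(0, "condition", r.condition)
            df.insert(1, "family", r.family if r.family is not None else "")
            df.insert(2, "level", r.level if r.level is not None else -1)
            parts.append(df)
        return pd.concat(parts, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frames().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, kind: str, n_radiome_features: int) -> "SeriesTable":
        df = pd.read_csv(path, keep_default_na=False, na_values=[], float_precision="round_trip")
        records = []
        meta = ["condition", "family", "level", "id"]
        rad_cols = [c for c in df.columns if c not in meta][:n_radiome_features]
        sur_cols = [c for c in df.columns if c not in meta][n_radiome_features:]
        for cond, grp in df.groupby("condition", sort=False):
            family = grp["family"].iloc[0] or None
            level = int(grp["level"].iloc[0])
            records.append(
                SeriesRecord(
                    str(cond),
                    RadiomeMatrix.from_frame(grp[["id"] + rad_cols].astype({c: float for c in rad_cols})),
                    SurrogateMatrix.from_frame(grp[["id"] + sur_cols].astype({c: float for c in sur_cols})),
                    family,
                    None if level < 0 else level,
                )
            )
        return cls(kind, records)


def _split_id_column(df: pd.DataFrame, what: str) -> tuple[list[str], pd.DataFrame]:
    if df.columns[0] != "id":
        raise ValueError(f"{what} table must have 'id' as its first column")
    ids = df["id"].astype(str).tolist()
    values = df.drop(columns="id")
    bad = values.columns[~values.apply(lambda c: pd.to_numeric(c, errors="coerce").notna() | c.isna()).all()]
    if len(bad):
        for col in bad:
            coerced = pd.to_numeric(values[col], errors="coerce")
            row = coerced[coerced.isna() & values[col].notna()].index[0]
            raise ValueError(f"non-numeric cell in {what} table: column {col!r}, row {row}")
    return ids, values.astype(float)


def load_cohort(radiome_path, surrogate_path, labels_path) -> Cohort:
    """Read and align the three cohort tables by the ``id`` column.

    Rows are matched by identifier; the radiome file fixes the row order.
    Mismatched identifier sets raise :class:`AlignmentError` naming the
    orphan identifiers.
    """
    radiome = RadiomeMatrix.read_csv(radiome_path)
    surrogates = SurrogateMatrix.read_csv(surrogate_path)
    lab = pd.read_csv(labels_path)
    if "id" not in lab.columns or "label" not in lab.columns:
        raise ValueError("labels table needs 'id' and 'label' columns")
    if lab["label"].isna().any():
        missing = lab.loc[lab["label"].isna(), "id"].tolist()
        raise ValueError(f"missing label for ids: {missing}")

    order = radiome.patient_ids
    for name, ids in (("surrogate", surrogates.patient_ids), ("label", lab["id"].astype(str))):
        orphans = sorted(set(order).symmetric_difference(ids))
        if orphans:
            raise AlignmentError(f"{name} table ids do not match radiome ids: {orphans}")

    pos = {p: i for i, p in enumerate(surrogates.patient_ids)}
    surrogates = surrogates.subset_rows([pos[p] for p in order])
    lab = lab.set_index(lab["id"].astype(str)).loc[order]
    group = lab["group_id"].astype(str).tolist() if "group_id" in lab.columns else None
    labels = CohortLabels(lab["label"].to_numpy(), order, group)
    return Cohort(radiome, surrogates, labels)


@dataclass
class ValidationReport:
    """Report-only diagnostics; an empty issue list means a clean cohort."""

    issues: list[tuple[str, str]]

    @property
    def ok(self) -> bool:
        return not self.issues

    def constant_columns(self) -> list[str]:
        return [d for k, d in self.issues if k == "zero-variance"]


def validate_cohort(radiome: RadiomeMatrix, surrogates: SurrogateMatrix, labels: CohortLabels) -> ValidationReport:
    issues: list[tuple[str, str]] = []
    for mat, names in ((radiome, radiome.feature_names), (surrogates, surrogates.surrogate_names)):
        bad = ~np.isfinite(mat.values)
        if bad.any():
            for j in np.unique(np.nonzero(bad)[1]):
                issues.append(("missing", names[j]))
        with np.errstate(invalid="ignore"):
            var = np.nanvar(mat.values, axis=0)
        for j in np.nonzero(var == 0)[0]:
            issues.append(("zero-variance", names[j]))
    classes = np.unique(labels.b)
    if classes.size < 2:
        issues.append(("single class", f"labels all {classes[0]}"))
    return ValidationReport(issues)


def _group_table(n: int, group_ids, labels) -> tuple[list[str], dict[str, np.ndarray], dict[str, int]]:
    if group_ids is None:
        group_ids = [str(i) for i in range(n)]
    group_ids = [str(g) for g in group_ids]
    if len(group_ids) != n:
        raise ValueError("group_ids length must equal n")
    rows: dict[str, list[int]] = {}
    for i, g in enumerate(group_ids):
        rows.setdefault(g, []).append(i)
    members = {g: np.asarray(ix) for g, ix in rows.items()}
    order = list(rows)  # order of first appearance
    if labels is not None:
        labels = np.asarray(labels)
        strat = {g: int(np.round(labels[ix].mean())) for g, ix in members.items()}
    else:
        strat = {g: 0 for g in order}
    return order, members, strat


def split_train_test(n: int, scheme: str, group_ids=None, seed: int = 0, labels=None):
    """Group-aware, optionally label-stratified train/test partitions.

    ``cv10`` yields 10 folds with a 9:1 group split; ``ssd`` (small sample
    detectability) yields a single split with 1/5 of the groups in the
    training set and 4/5 held out.  All rows of one group always land on
    the same side.  Deterministic given ``seed``.
    """
    if scheme not in ("cv10", "ssd"):
        raise ValueError(f"unknown scheme: {scheme}")
    order, members, strat = _group_table(n, group_ids, labels)
    rng = np.random.default_rng(seed)
    strata: dict[int, list[str]] = {}
    for g in order:
        strata.setdefault(strat[g], []).append(g)
    for s in strata:
        strata[s] = list(np.array(strata[s])[rng.permutation(len(strata[s]))])

    if scheme == "cv10":
        k = 10
        if len(order) < k:
            raise ValueError(f"cv10 needs at least {k} groups, got {len(order)}")
        fold_of: dict[str, int] = {}
        offset = 0
        for s in sorted(strata):
            for i, g in enumerate(strata[s]):
                fold_of[g] = (i + offset) % k
            offset += len(strata[s])
        splits = []
        for f in range(k):
            test = np.concatenate([members[g] for g in order if fold_of[g] == f])
            train = np.concatenate([members[g] for g in order if fold_of[g] != f])
            splits.append((np.sort(train), np.sort(test)))
        return splits

    # ssd: 1/5 of the groups train, 4/5 test, stratified where possible
    train_groups: list[str] = []
    for s in sorted(strata):
        gs = strata[s]
        n_train = max(1, int(round(len(gs) / 5)))
        train_groups.extend(gs[:n_train])
    train = np.concatenate([members[g] for g in train_groups])
    test = np.concatenate([members[g] for g in order if g not in set(train_groups)])
    if labels is not None:
        if np.unique(np.asarray(labels)[train]).size < 2:
            warnings.warn("ssd training split contains a single class")
    return [(np.sort(train), np.sort(test))]
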