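"""Tabular inputs for measurement-variability analysis.

Two tables drive everything downstream:

* a *repeated-readings* table — one row per (lesion, reader, session, phase)
  diameter measurement, used to fit the measurement-error model;
* a *trial* table — one row per target lesion of a trial patient with its
  baseline and post-treatment size, used to evaluate how reproducible the
  trial's response rates are under reassessment.

Both are plain UTF-8 comma-separated files with a header row and decimal
points.  Per-patient tumor burdens (RECIST sums of target-lesion diameters)
are summarised by :func:`summarize_burden`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import pandas as pd

PHASES = ("baseline", "post")
ORGANS = ("solid", "lymph")
AXES = ("long", "short")

READING_COLUMNS = [
    "lesion_id",
    "patient_id",
    "reader_id",
    "session",
    "phase",
    "axis",
    "organ",
    "diameter_mm",
]
TRIAL_COLUMNS = ["patient_id", "organ", "baseline_mm", "post_mm"]


class TableParseError(ValueError):
    """A tabular input violated the expected schema or invariants."""


@dataclass(frozen=True)
class ReadingRecord:
    """One diameter measurement of one lesion by one reader in one session."""

    lesion_id: str
    patient_id: str
    reader_id: str
    session: int
    phase: str
    axis: str
    organ: str
    diameter_mm: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        if self.organ not in ORGANS:
            raise ValueError(f"organ must be one of {ORGANS}, got {self.organ!r}")
        if self.organ == "solid" and self.axis == "short":
            raise ValueError("solid lesions are measured on the long axis only")
        if not self.diameter_mm > 0:
            raise ValueError(f"diameter_mm must be > 0, got {self.diameter_mm}")

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.lesion_id, self.reader_id, self.session, self.phase)


@dataclass
class RepeatedReadingDataset:
    """Repeated diameter readings for one measurement axis.

    The error model is fitted separately for long-axis (solid lesions, and
    historically lymph nodes too) and short-axis (lymph nodes) data, so a
    dataset carries a single ``axis_kind``.
    """

    records: list[ReadingRecord]
    axis_kind: str

    def __post_init__(self) -> None:
        if self.axis_kind not in AXES:
            raise ValueError(f"axis_kind must be one of {AXES}")
        seen: set[tuple[str, str, int, str]] = set()
        for rec in self.records:
            if rec.axis != self.axis_kind:
                raise ValueError(
                    f"record {rec.key} has axis {rec.axis!r}, dataset is {self.axis_kind!r}"
                )
            if rec.key in seen:
                raise ValueError(f"duplicate (lesion, reader, session, phase) key {rec.key}")
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lesion_ids(self) -> list[str]:
        return sorted({r.lesion_id for r in self.records})

    @property
    def reader_ids(self) -> list[str]:
        return sorted({r.reader_id for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records], columns=READING_COLUMNS)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, axis_kind: str | None = None) -> "RepeatedReadingDataset":
        records = [
            ReadingRecord(
                lesion_id=str(row.lesion_id),
                patient_id=str(row.patient_id),
                reader_id=str(row.reader_id),
                session=int(row.session),
                phase=str(row.phase),
                axis=str(row.axis),
                organ=str(row.organ),
                diameter_mm=float(row.diameter_mm),
            )
            for row in frame.itertuples()
        ]
        if axis_kind is None:
            axes = {r.axis for r in records}
            if len(axes) != 1:
                raise ValueError(f"cannot infer axis_kind from mixed axes {sorted(axes)}")
            axis_kind = axes.pop()
        return cls(records=records, axis_kind=axis_kind)


class Lesion(NamedTuple):
    """One target lesion of a trial patient (sizes on its RECIST axis)."""

    organ: str
    baseline_mm: float
    post_mm: float


@dataclass
class TrialRecord:
    """All target lesions of one trial patient."""

    patient_id: str
    lesions: list[Lesion]

    def __post_init__(self) -> None:
        if not self.lesions:
            raise ValueError(f"patient {self.patient_id}: at least one lesion required")
        for les in self.lesions:
            if les.organ not in ORGANS:
                raise ValueError(
                    f"patient {self.patient_id}: organ must be one of {ORGANS}, got {les.organ!r}"
                )
            if not les.baseline_mm > 0:
                raise ValueError(f"patient {self.patient_id}: baseline_mm must be > 0")
            if les.post_mm < 0:
                raise ValueError(f"patient {self.patient_id}: post_mm must be >= 0")


@dataclass
class TrialDataset:
    """Trial lesion table plus the count of definitive-progression patients.

    Patients with unequivocal radiologic progression, symptomatic progression
    or death carry no lesion rows: they are unaffected by measurement
    variability and enter the evaluation with progression probability 1.
    They are counted in both rate denominators.
    """

    records: list[TrialRecord]
    n_definitive_progression: int = 0

    def __post_init__(self) -> None:
        if self.n_definitive_progression < 0:
            raise ValueError("n_definitive_progression must be >= 0")
        ids = [r.patient_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("patient_ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_patients_total(self) -> int:
        return len(self.records) + self.n_definitive_progression

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": rec.patient_id,
                "organ": les.organ,
                "baseline_mm": les.baseline_mm,
                "post_mm": les.post_mm,
            }
            for rec in self.records
            for les in rec.lesions
        ]
        return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


@dataclass(frozen=True)
class BurdenSummary:
    """Per-patient tumor-burden summary (RECIST sum of target-lesion sizes)."""

    patient_id: str
    n_solid: int
    n_lymph: int
    burden_baseline_mm: float
    burden_post_mm: float
    percent_change: float  # percent units; fraction scale used internally


def summarize_burden(record: TrialRecord) -> BurdenSummary:
    """Sum lesion sizes into the tumor burden and its percent change.

    The percent change is reported in percent units here; response cut-offs
    downstream operate on the fractional scale (e.g. -0.30), and this is the
    single place where the conversion happens.
    """
    base = sum(les.baseline_mm for les in record.lesions)
    post = sum(les.post_mm for les in record.lesions)
    return BurdenSummary(
        patient_id=record.patient_id,
        n_solid=sum(1 for les in record.lesions if les.organ == "solid"),
        n_lymph=sum(1 for les in record.lesions if les.organ == "lymph"),
        burden_baseline_mm=base,
        burden_post_mm=post,
        percent_change=100.0 * (post - base) / base,
    )


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TableParseError(f"{path}: missing column(s) {missing}; expected {list(required)}")


def read_readings_csv(path) -> RepeatedReadingDataset:
    """Read a repeated-readings table; the axis kind is inferred and must be uniform."""
    frame = pd.read_csv(path, float_precision="round_trip")
    _require_columns(frame, READING_COLUMNS, path)
    if len(frame) == 0:
        raise TableParseError(f"{path}: file contains a header but no data rows")
    records = []
    for pos, row in enumerate(frame.itertuples(), start=2):  # header is line 1
        try:
            records.append(
                ReadingRecord(
                    lesion_id=str(row.lesion_id),
                    patient_id=str(row.patient_id),
                    reader_id=str(row.reader_id),
                    session=int(row.session),
                    phase=str(row.phase),
                    axis=str(row.axis),
                    organ=str(row.organ),
                    diameter_mm=float(row.diameter_mm),
                )
            )
        except (ValueError, TypeError) as exc:
            raise TableParseError(f"{path}, line {pos}: {exc}") from exc
    try:
        return RepeatedReadingDataset.from_frame(pd.DataFrame([r.__dict__ for r in records]))
    except ValueError as exc:
        raise TableParseError(f"{path}: {exc}") from exc


def write_readings_csv(dataset: RepeatedReadingDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def read_trial_csv(path, n_definitive_progression: int = 0) -> TrialDataset:
    """Read a trial lesion table, grouping rows into per-patient records.

    ``n_definitive_progression`` is supplied out-of-band (CLI flag or call
    argument), mirroring the "further information" a trialist adds alongside
    the lesion table.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    _require_columns(frame, TRIAL_COLUMNS, path)
    records: list[TrialRecord] = []
    if len(frame) > 0:
        lesions_by_patient: dict[str, list[Lesion]] = {}
        for pos, row in enumerate(frame.itertuples(), start=2):
            organ = str(row.organ)
            if organ not in ORGANS:
                raise TableParseError(
                    f"{path}, line {pos}: unknown organ {organ!r}; allowed labels: {list(ORGANS)}"
                )
            try:
                les = Lesion(organ=organ, baseline_mm=float(row.baseline_mm), post_mm=float(row.post_mm))
            except (ValueError, TypeError) as exc:
                raise TableParseError(f"{path}, line {pos}: {exc}") from exc
            if not les.baseline_mm > 0:
                raise TableParseError(f"{path}, line {pos}: baseline_mm must be > 0")
            if les.post_mm < 0:
                raise TableParseError(f"{path}, line {pos}: post_mm must be >= 0")
            lesions_by_patient.setdefault(str(row.patient_id), []).append(les)
        records = [TrialRecord(pid, lesions) for pid, lesions in lesions_by_patient.items()]
    try:
        return TrialDataset(records=records, n_definitive_progression=n_definitive_progression)
    except ValueError as exc:
        raise TableParseError(f"{path}: {exc}") from exc


def write_trial_csv(trial: TrialDataset, path) -> None:
    trial.to_frame().to_csv(path, index=False)
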