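"""Stroke cohort table: loading, validation, dataset A/B resolution, summaries.

The cohort mixes two clinical designs: 19 patients measured once (their one
recording session feeds both longitudinal datasets, session label
``single``) and 6 patients measured twice at least ten days apart (sessions
``A`` and ``B``). Dataset A is all ``single`` records plus the A
measurements; dataset B is all ``single`` records plus the B measurements,
so each dataset contains every patient exactly once.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

COLUMNS = ["patient_id", "session", "age", "sex", "stroke_type",
           "onset_days", "fma_ue", "paretic_side"]

_SESSIONS = {"single", "A", "B"}
_SEXES = {"M", "F"}
_STROKE_TYPES = {"CI", "ICH"}
_SIDES = {"L", "R"}

#: Packaged transcription of the study cohort table.
DEFAULT_COHORT_PATH = Path(__file__).parent / "data" / "table1_cohort.csv"


class CohortValidationError(ValueError):
    """A cohort row failed validation; message names the row and field."""


@dataclass(frozen=True)
class PatientRecord:
    """One measurement session of one patient."""

    patient_id: str
    session: str          # 'single', 'A' or 'B'
    age: int              # years; inclusion criterion requires > 18
    sex: str              # 'M' / 'F'
    stroke_type: str      # 'CI' (cerebral infarction) / 'ICH' (hemorrhage)
    onset_days: int       # days since the cerebrovascular event, >= 1
    fma_ue: int           # Fugl-Meyer upper-extremity score, 0..66
    paretic_side: str     # 'L' / 'R'

    def __post_init__(self):
        def err(fieldname, msg):
            raise CohortValidationError(
                f"patient {self.patient_id!r} session {self.session!r}: {fieldname} {msg}")
        if self.session not in _SESSIONS:
            err("session", f"must be one of {sorted(_SESSIONS)}, got {self.session!r}")
        if self.sex not in _SEXES:
            err("sex", f"must be one of {sorted(_SEXES)}, got {self.sex!r}")
        if self.stroke_type not in _STROKE_TYPES:
            err("stroke_type", f"must be one of {sorted(_STROKE_TYPES)}, got {self.stroke_type!r}")
        if self.paretic_side not in _SIDES:
            err("paretic_side", f"must be one of {sorted(_SIDES)}, got {self.paretic_side!r}")
        if not self.age > 18:
            err("age", f"must exceed 18 (adult inclusion criterion), got {self.age}")
        if not (0 <= self.fma_ue <= 66):
            err("fma_ue", f"must be in [0, 66], got {self.fma_ue}")
        if not self.onset_days >= 1:
            err("onset_days", f"must be >= 1, got {self.onset_days}")


@dataclass
class Cohort:
    """A validated collection of patient records."""

    records: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self):
        keys = [(r.patient_id, r.session) for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise CohortValidationError(f"duplicate (patient_id, session) pairs: {dupes}")
        by_patient: dict[str, set[str]] = {}
        for r in self.records:
            by_patient.setdefault(r.patient_id, set()).add(r.session)
        # a patient is either measured once ('single') or holds A/B session
        # records; a dataset selected from a full cohort may carry only one
        # of the two sessions
        for pid, sessions in by_patient.items():
            if "single" in sessions and len(sessions) > 1:
                raise CohortValidationError(
                    f"patient {pid!r} mixes a 'single' record with session records "
                    f"{sorted(sessions - {'single'})}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def patient_ids(self) -> list[str]:
        """Unique patient ids, in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.patient_id)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=COLUMNS)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class DemographicSummary:
    n_patients: int
    sex_counts: dict[str, int]
    stroke_type_counts: dict[str, int]
    paretic_side_counts: dict[str, int]
    age: dict[str, float]          # mean / sd / median
    onset_days: dict[str, float]
    fma_ue: dict[str, float]


def load_cohort(path: str | Path | None = None) -> Cohort:
    """Load and validate a cohort table.

    Exact duplicate rows (identical in every field) are collapsed to one
    record with a warning; any other duplication of a (patient, session)
    key is an error.
    """
    path = Path(path) if path is not None else DEFAULT_COHORT_PATH
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"cohort table {path} is missing columns {missing}")
    n_before = len(df)
    df = df.drop_duplicates()
    if len(df) < n_before:
        msg = f"collapsed {n_before - len(df)} exact duplicate row(s) in {path.name}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(PatientRecord(
                patient_id=str(row["patient_id"]),
                session=str(row["session"]),
                age=int(row["age"]),
                sex=str(row["sex"]),
                stroke_type=str(row["stroke_type"]),
                onset_days=int(row["onset_days"]),
                fma_ue=int(row["fma_ue"]),
                paretic_side=str(row["paretic_side"]),
            ))
        except (ValueError, TypeError) as exc:
            if isinstance(exc, CohortValidationError):
                raise
            raise CohortValidationError(f"row {i}: {exc}") from exc
    return Cohort(records)


def select_dataset(cohort: Cohort, which: str) -> Cohort:
    """Resolve longitudinal dataset membership: 'A' or 'B'.

    Returns every ``single`` record plus the records of the requested
    session, so each patient appears exactly once.
    """
    if which not in {"A", "B"}:
        raise ValueError(f"dataset must be 'A' or 'B', got {which!r}")
    return Cohort([r for r in cohort.records if r.session in ("single", which)])


def _moments(values: pd.Series) -> dict[str, float]:
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        "median": float(values.median()),
    }


def summarize(cohort: Cohort) -> DemographicSummary:
    """Demographic and clinical summary over the cohort's records.

    SDs use the sample (n-1) convention. For a cohort containing A/B
    session pairs each record counts once; summarize a single dataset
    (via :func:`select_dataset`) for per-patient statistics.
    """
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    df = cohort.to_frame()
    for col in ("age", "onset_days", "fma_ue"):
        df[col] = df[col].astype(int)
    return DemographicSummary(
        n_patients=len(df["patient_id"].unique()),
        sex_counts=df.drop_duplicates("patient_id")["sex"].value_counts().to_dict(),
        stroke_type_counts=df.drop_duplicates("patient_id")["stroke_type"].value_counts().to_dict(),
        paretic_side_counts=df.drop_duplicates("patient_id")["paretic_side"].value_counts().to_dict(),
        age=_moments(df.drop_duplicates("patient_id")["age"]),
        onset_days=_moments(df["onset_days"]),
        fma_ue=_moments(df["fma_ue"]),
    )
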