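"""Encounter records, cohort CSV I/O, and age banding.

An :class:`Encounter` is one outpatient clinic visit for first-time chest-pain
evaluation: demographic fields, binary clinical-feature flags, the subset of
the four cardiac tests performed, the provider seen, and (where applicable)
the provider's stated reason for ordering an echocardiogram against the
recommendation.

Cohorts are exchanged as UTF-8, comma-delimited CSV with a mandatory header
whose column names are exactly the :class:`Encounter` field names.  Flags are
serialized as literal ``"0"``/``"1"`` — no truthy coercion — so that audit
data stay unambiguous.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, fields as _dc_fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "AGE_MAX",
    "AGE_MIN",
    "AgeBand",
    "CohortWarning",
    "DeviationCategory",
    "Encounter",
    "Era",
    "RowError",
    "SchemaError",
    "Sex",
    "age_band",
    "read_cohort",
    "write_cohort",
]

AGE_MIN = 7.0
AGE_MAX = 21.0


class Era(str, Enum):
    """Cohort era: pre-standardization chart review vs. SCAMP enrollment."""

    HISTORICAL = "historical"
    SCAMP = "scamp"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class DeviationCategory(str, Enum):
    """Stated reason for an echocardiogram ordered against the recommendation."""

    PARENTAL_CONCERN = "parental_concern"
    UNDERLYING_MEDICAL_ILLNESS = "underlying_medical_illness"
    ABNORMAL_EXAM_UNRELATED = "abnormal_exam_unrelated"
    OTHER = "other"


class AgeBand(str, Enum):
    """Reporting age bands partitioning [7, 21]."""

    YEARS_7_11 = "7-11"
    YEARS_12_16 = "12-16"
    YEARS_17_21 = "17-21"


class SchemaError(ValueError):
    """A cohort file is missing a required column."""


class RowError(ValueError):
    """A cohort row failed validation.

    ``row_index`` is the 0-based index of the data row (header excluded).
    """

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class CohortWarning(UserWarning):
    """Non-fatal irregularity in cohort data."""


#: Flag fields, in schema order.
FLAG_FIELDS = (
    "exertional_pain",
    "palpitations",
    "positive_pmh",
    "positive_fh",
    "abnormal_exam",
    "abnormal_ecg",
    "echo_done",
    "est_done",
    "holter_done",
    "event_monitor_done",
)

#: Clinical flags that trigger an echocardiogram indication (see scampqi.rules).
TRIGGER_FLAGS = (
    "exertional_pain",
    "positive_pmh",
    "positive_fh",
    "abnormal_exam",
    "abnormal_ecg",
)


@dataclass(frozen=True)
class Encounter:
    """One validated clinic visit."""

    patient_id: str
    era: Era
    sex: Sex
    age_years: float
    exertional_pain: bool
    palpitations: bool
    positive_pmh: bool
    positive_fh: bool
    abnormal_exam: bool
    abnormal_ecg: bool
    echo_done: bool
    est_done: bool
    holter_done: bool
    event_monitor_done: bool
    provider_id: str
    deviation_reason: Optional[DeviationCategory] = None

    def __post_init__(self) -> None:
        if not isinstance(self.era, Era):
            object.__setattr__(self, "era", Era(self.era))
        if not isinstance(self.sex, Sex):
            object.__setattr__(self, "sex", Sex(self.sex))
        if self.deviation_reason is not None and not isinstance(
            self.deviation_reason, DeviationCategory
        ):
            object.__setattr__(
                self, "deviation_reason", DeviationCategory(self.deviation_reason)
            )
        age = float(self.age_years)
        object.__setattr__(self, "age_years", age)
        if not (AGE_MIN <= age <= AGE_MAX):
            raise ValueError(
                f"age_years must be within [{AGE_MIN:g}, {AGE_MAX:g}], got {age!r}"
            )
        for name in FLAG_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, bool):
                raise ValueError(f"flag {name!r} must be a bool, got {value!r}")


#: Column order of the CSV dialect == Encounter field order.
COLUMNS = tuple(f.name for f in _dc_fields(Encounter))


def age_band(age_years: float) -> AgeBand:
    """Assign an age to its reporting band.

    Bands are the half-open real intervals [7, 12), [12, 17) and the closed
    [17, 21], so fractional ages are always assignable and the bands partition
    the admissible range.
    """
    age = float(age_years)
    if not (AGE_MIN <= age <= AGE_MAX):
        raise ValueError(f"age {age!r} outside [{AGE_MIN:g}, {AGE_MAX:g}]")
    if age < 12.0:
        return AgeBand.YEARS_7_11
    if age < 17.0:
        return AgeBand.YEARS_12_16
    return AgeBand.YEARS_17_21


def _parse_flag(raw: str, column: str) -> bool:
    if raw == "0":
        return False
    if raw == "1":
        return True
    raise ValueError(f"column {column!r}: expected '0' or '1', got {raw!r}")


def _in_deviation_universe(e: Encounter) -> bool:
    # mirrors rules.echo_indicated without importing it (no circular dep)
    return e.echo_done and not any(getattr(e, f) for f in TRIGGER_FLAGS)


def _parse_row(row: dict, index: int) -> Encounter:
    try:
        raw_reason = (row.get("deviation_reason") or "").strip()
        reason = DeviationCategory(raw_reason) if raw_reason else None
        enc = Encounter(
            patient_id=row["patient_id"],
            era=Era(row["era"]),
            sex=Sex(row["sex"]),
            age_years=float(row["age_years"]),
            provider_id=row["provider_id"],
            deviation_reason=reason,
            **{name: _parse_flag(row[name], name) for name in FLAG_FIELDS},
        )
    except (ValueError, KeyError) as exc:
        raise RowError(index, str(exc)) from exc
    if enc.deviation_reason is not None and not _in_deviation_universe(enc):
        warnings.warn(
            f"row {index}: deviation_reason set but echocardiogram was either "
            "not performed or was indicated",
            CohortWarning,
            stacklevel=3,
        )
    return enc


def read_cohort(path: Union[str, Path]) -> list[Encounter]:
    """Read and validate a cohort CSV; row order is preserved.

    Raises :class:`SchemaError` when a required column is absent and
    :class:`RowError` (carrying the 0-based data-row index) when a row fails
    validation.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError("empty file: no header row")
        missing = [c for c in COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        return [_parse_row(row, i) for i, row in enumerate(reader)]


def _serialize(e: Encounter) -> list[str]:
    out = []
    for name in COLUMNS:
        value = getattr(e, name)
        if name in FLAG_FIELDS:
            out.append("1" if value else "0")
        elif name == "age_years":
            out.append(repr(value))  # repr round-trips floats exactly
        elif name == "deviation_reason":
            out.append("" if value is None else value.value)
        elif isinstance(value, Enum):
            out.append(value.value)
        else:
            out.append(str(value))
    return out


def write_cohort(encounters: Iterable[Encounter], path: Union[str, Path]) -> None:
    """Write encounters to CSV such that ``read_cohort`` restores them exactly."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(COLUMNS)
        for e in encounters:
            writer.writerow(_serialize(e))
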