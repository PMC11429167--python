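"""Individual age/size records, CSV I/O and age-class aggregation.

The unit of observation is one frog: its sex, life stage, age in
LAG-years (lines of arrested growth counted in a phalangeal
cross-section, one per year of life) and snout--vent length (SVL, mm).
Ages arrive here as final integer LAG counts; reading and interpreting
the sections (double lines, metamorphosis line, endosteal resorption)
happens upstream.

The module also ships :func:`table1_fixture`, a reconstruction of the
published Çakıroluk *Rana tavasensis* sample (10 adult males, 17 adult
females, 2 subadult males, 2 juveniles) from the per-age-class summary
table, since no individual-level data file was deposited.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Sex",
    "LifeStage",
    "AgeRecord",
    "StudyDataset",
    "AgeClassCounts",
    "RecordValidationError",
    "SchemaError",
    "read_records",
    "write_records",
    "table1_fixture",
    "aggregate_age_classes",
    "CSV_COLUMNS",
]

CSV_COLUMNS = ("id", "sex", "life_stage", "age_years", "svl_mm")


class SchemaError(ValueError):
    """The CSV header does not name the required columns."""


class RecordValidationError(ValueError):
    """A record (or CSV row) violates an invariant; carries line context."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class Sex(enum.Enum):
    MALE = "M"
    FEMALE = "F"
    UNKNOWN = "U"


class LifeStage(enum.Enum):
    NEWLY_METAMORPHOSED = "NM"
    JUVENILE = "J"
    SUBADULT = "SA"
    ADULT = "A"


@dataclass(frozen=True)
class AgeRecord:
    """One measured individual.

    ``approximate`` marks records whose SVL is a class mean rather than
    an individually measured value (used where a published age class
    cannot be reconstructed individual-by-individual).
    """

    id: str
    sex: Sex
    life_stage: LifeStage
    age_years: int
    svl_mm: float
    approximate: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.age_years, int) or isinstance(self.age_years, bool):
            raise RecordValidationError(f"age_years must be an integer, got {self.age_years!r}")
        if self.age_years < 0:
            raise RecordValidationError(f"age_years must be >= 0, got {self.age_years}")
        if not self.svl_mm > 0:
            raise RecordValidationError(f"svl_mm must be > 0, got {self.svl_mm}")


@dataclass(frozen=True)
class StudyDataset:
    """An ordered collection of :class:`AgeRecord` with unique ids."""

    records: tuple[AgeRecord, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise RecordValidationError(f"duplicate record ids: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def filter(self, sex: Sex | None = None, life_stage: LifeStage | None = None) -> "StudyDataset":
        recs = [
            r
            for r in self.records
            if (sex is None or r.sex == sex) and (life_stage is None or r.life_stage == life_stage)
        ]
        return StudyDataset(tuple(recs), label=self.label)

    def ages(self) -> list[int]:
        return [r.age_years for r in self.records]

    def svls(self) -> list[float]:
        return [r.svl_mm for r in self.records]


@dataclass(frozen=True)
class AgeClassCounts:
    """Counts of individuals per integer age for one group.

    ``counts[a]`` is N_a, the number of individuals aged ``a`` LAG-years;
    R = sum of counts is the group total used by the survival estimator.
    """

    counts: Mapping[int, int]
    group_label: str = ""

    def __post_init__(self) -> None:
        cleaned = {int(a): int(n) for a, n in self.counts.items() if n != 0}
        for a, n in cleaned.items():
            if a < 0:
                raise ValueError(f"age {a} < 0")
            if n < 0:
                raise ValueError(f"count for age {a} is negative")
        object.__setattr__(self, "counts", dict(sorted(cleaned.items())))

    @property
    def total(self) -> int:
        """R, the number of contributing individuals."""
        return sum(self.counts.values())

    @property
    def is_empty(self) -> bool:
        return self.total == 0


def _parse_row(row: Mapping[str, str], line: int) -> AgeRecord:
    try:
        sex = Sex(row["sex"].strip())
    except ValueError:
        raise RecordValidationError(f"unknown sex code {row['sex']!r} (expected M/F/U)", line)
    try:
        stage = LifeStage(row["life_stage"].strip())
    except ValueError:
        raise RecordValidationError(
            f"unknown life_stage code {row['life_stage']!r} (expected NM/J/SA/A)", line
        )
    raw_age = row["age_years"].strip()
    try:
        age = int(raw_age)
    except ValueError:
        raise RecordValidationError(f"age_years {raw_age!r} is not an integer", line)
    raw_svl = row["svl_mm"].strip()
    try:
        svl = float(raw_svl)
    except ValueError:
        raise RecordValidationError(f"svl_mm {raw_svl!r} is not a number", line)
    approx = row.get("approximate", "").strip() in {"1", "true", "True"}
    try:
        return AgeRecord(row["id"].strip(), sex, stage, age, svl, approximate=approx)
    except RecordValidationError as exc:
        raise RecordValidationError(str(exc), line) from None


def read_records(path: str | Path, *, delimiter: str = ",", label: str | None = None) -> StudyDataset:
    """Read a records CSV (columns ``id,sex,life_stage,age_years,svl_mm``).

    Raises :class:`SchemaError` for missing columns and
    :class:`RecordValidationError` (with line number) for malformed rows.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing required column(s) {missing} in {path}")
        records = [_parse_row(row, line) for line, row in enumerate(reader, start=2)]
    return StudyDataset(tuple(records), label=label if label is not None else str(path))


def write_records(dataset: StudyDataset, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a dataset to CSV, re-readable by :func:`read_records`.

    SVL is written at 2 decimal places (caliper precision)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(CSV_COLUMNS + ("approximate",))
        for r in dataset:
            writer.writerow(
                [r.id, r.sex.value, r.life_stage.value, r.age_years, f"{r.svl_mm:.2f}", int(r.approximate)]
            )


# ---------------------------------------------------------------------------
# Published-table reconstruction
# ---------------------------------------------------------------------------

# (age, [svl...]) per class. Classes with n=1 are the printed value; n=2 are
# the printed min and max (both attained); n=3 add 3*mean - min - max.
_MALE_ADULTS: list[tuple[int, list[float]]] = [
    (3, [51.13]),
    (4, [51.97]),
    (5, [54.80, 71.69]),
    (6, [58.02, 64.98]),
    (7, [66.16]),
    (8, [68.21]),
    (11, [69.14]),
    (12, [71.47]),
]

# Female age-3: third value = 3*46.12 - 42.33 - 49.02 = 47.01
# Female age-7: third value = 3*61.71 - 54.71 - 66.46 = 63.96
# Female age-6 (n=5) is not reconstructable from mean/min/max alone; the five
# individuals are stored at the class mean 58.12 and flagged approximate.
_FEMALE_ADULTS: list[tuple[int, list[float], bool]] = [
    (3, [42.33, 47.01, 49.02], False),
    (4, [49.87], False),
    (5, [55.48, 59.51], False),
    (6, [58.12] * 5, True),
    (7, [54.71, 63.96, 66.46], False),
    (8, [65.23], False),
    (11, [73.97], False),
    (12, [70.84], False),
]

_SUBADULT_MALES = [(2, [42.73, 50.40])]
_JUVENILES = [(1, [16.95, 29.89])]

#: Summary rows exactly as printed, kept for provenance; two are internally
#: inconsistent with their own min–max (female age-5 mean, juvenile mean) and
#: are never used as exact targets.
TABLE1_PRINTED_SUMMARIES = {
    ("male", "adult", "total"): {"n": 10, "mean": 62.75, "sd": 8.02, "min": 51.13, "max": 71.69},
    ("female", "adult", "total"): {"n": 17, "mean": 58.04, "sd": 8.37, "min": 42.33, "max": 73.97},
    ("female", "adult", 5): {"n": 2, "mean": 56.92, "sd": 1.29, "min": 55.48, "max": 59.51},
    ("female", "adult", 6): {"n": 5, "mean": 58.12, "sd": 0.69, "min": 56.81, "max": 59.79},
    ("unknown", "juvenile", 1): {"n": 2, "mean": 23.07, "sd": 9.64, "min": 16.95, "max": 29.89},
}


def table1_fixture() -> StudyDataset:
    """Reconstructed individual records of the published Çakıroluk sample.

    Singleton age classes carry the printed value; two-individual classes
    the printed min and max; three-individual classes additionally
    3·mean − min − max. The only class not reconstructable this way (the
    five females aged 6) is stored at its class mean with
    ``approximate=True`` so downstream exact-SVL checks can exclude it.
    """
    records: list[AgeRecord] = []

    def add(prefix: str, sex: Sex, stage: LifeStage, age: int, svls: Iterable[float], approx: bool = False):
        for j, svl in enumerate(svls, start=1):
            records.append(
                AgeRecord(f"{prefix}{age:02d}_{j}", sex, stage, age, svl, approximate=approx)
            )

    for age, svls in _MALE_ADULTS:
        add("M", Sex.MALE, LifeStage.ADULT, age, svls)
    for age, svls, approx in _FEMALE_ADULTS:
        add("F", Sex.FEMALE, LifeStage.ADULT, age, svls, approx)
    for age, svls in _SUBADULT_MALES:
        add("SAM", Sex.MALE, LifeStage.SUBADULT, age, svls)
    for age, svls in _JUVENILES:
        add("J", Sex.UNKNOWN, LifeStage.JUVENILE, age, svls)
    return StudyDataset(tuple(records), label="cakiroluk-2019-reconstruction")


def aggregate_age_classes(
    dataset: StudyDataset,
    sex: Sex | None = None,
    life_stage: LifeStage | None = None,
) -> AgeClassCounts:
    """Count individuals per integer age after optional sex/stage filtering.

    An empty selection yields valid empty counts (``is_empty``), which the
    estimators reject explicitly.
    """
    sub = dataset.filter(sex=sex, life_stage=life_stage)
    counts: dict[int, int] = {}
    for r in sub:
        counts[r.age_years] = counts.get(r.age_years, 0) + 1
    parts = [p for p in (sex.name.lower() if sex else None,
                         life_stage.name.lower() if life_stage else None) if p]
    return AgeClassCounts(counts, group_label="/".join(parts) or "all")
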