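"""File formats: person-level record files and surname lists.

Two record shapes are supported, both as headered CSV in UTF-8:

* vital records (death-file style): surname, father's surname, optional
  demographics, birthplace, birth/death years;
* registry records (cancer-registry style): surname, maiden name, father's
  surname, country of birth, and a tri-state flag for reference-list
  membership.

Column layouts vary between data providers and between file years, so both
readers accept a *dialect*: a mapping from the column names present in the
file to the canonical field names used here.

Surname lists travel either as plain text (one name per line) or as CSV
with provenance columns (surname, source, truncated, evidence).  Writers
sort lexicographically by uppercased surname so output files are
deterministic and diff-able.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import pandas as pd

__all__ = [
    "DialectError",
    "VitalRecord",
    "RegistryRecord",
    "SurnameEntry",
    "SurnameList",
    "LoadSummary",
    "SOURCES",
    "read_vital_records",
    "read_registry_records",
    "read_surname_list",
    "write_surname_list",
]

#: Provenance categories for a surname entry.
SOURCES = ("reference_linked", "birthplace_added", "reference_retained", "external")

#: Sources whose entries may carry a truncated spelling (truncation happens
#: in the reference extract; birthplace-derived names are always full).
_TRUNCATABLE_SOURCES = frozenset({"reference_linked", "reference_retained", "external"})

_LIST_CSV_HEADER = ["surname", "source", "truncated", "evidence"]


class DialectError(ValueError):
    """A required column is absent from the file under the given dialect."""


@dataclass(frozen=True)
class VitalRecord:
    """One death-file row: the decedent's surname plus linkage-relevant fields."""

    surname: str
    father_surname: Optional[str] = None
    first_name: Optional[str] = None
    sex: Optional[str] = None
    birthplace: Optional[str] = None
    birth_year: Optional[int] = None
    death_year: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "surname", self.surname.strip())
        if not self.surname:
            raise ValueError("VitalRecord surname must be non-empty")
        if (
            self.birth_year is not None
            and self.death_year is not None
            and self.birth_year > self.death_year
        ):
            raise ValueError(
                f"birth_year {self.birth_year} exceeds death_year {self.death_year}"
            )


@dataclass(frozen=True)
class RegistryRecord:
    """One registry row: patient surnames, country of birth, reference-list flag.

    ``on_reference_list`` is tri-state: True, False, or None (not recorded).
    """

    surname: str
    maiden_name: Optional[str] = None
    father_surname: Optional[str] = None
    country_of_birth: Optional[str] = None
    on_reference_list: Optional[bool] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "surname", self.surname.strip())
        if not self.surname:
            raise ValueError("RegistryRecord surname must be non-empty")


@dataclass(frozen=True)
class SurnameEntry:
    """A surname with provenance.

    ``surname`` is kept as spelled (punctuation preserved); ``truncated``
    marks spellings cut at the reference list's fixed character length.
    """

    surname: str
    source: str = "external"
    truncated: bool = False
    evidence: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "surname", self.surname.strip())
        if not self.surname:
            raise ValueError("SurnameEntry surname must be non-empty")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {SOURCES}")
        if self.truncated and self.source not in _TRUNCATABLE_SOURCES:
            raise ValueError(f"source {self.source!r} entries cannot be truncated")

    @property
    def key(self) -> str:
        """Uppercased exact spelling — the uniqueness key throughout."""
        return self.surname.upper()


@dataclass
class LoadSummary:
    """Bookkeeping from a record-file read: rows kept, rows skipped."""

    n_read: int = 0
    n_skipped: int = 0

    @property
    def n_rows(self) -> int:
        return self.n_read + self.n_skipped


class SurnameList:
    """A named, ordered, deduplicated collection of :class:`SurnameEntry`.

    Deduplication is by uppercased exact spelling: the first entry with a
    given key wins, later duplicates increment ``duplicate_count``.
    Insertion order is preserved for iteration; writers sort on output.
    """

    def __init__(self, name: str = "", entries: Iterable[SurnameEntry] = ()) -> None:
        self.name = name
        self._entries: dict[str, SurnameEntry] = {}
        self.duplicate_count = 0
        for entry in entries:
            self.add(entry)

    @classmethod
    def from_names(
        cls, names: Iterable[str], name: str = "", source: str = "external"
    ) -> "SurnameList":
        return cls(name=name, entries=(SurnameEntry(n, source=source) for n in names))

    def add(self, entry: SurnameEntry) -> bool:
        """Add an entry; return False (and count a duplicate) if its key exists."""
        if entry.key in self._entries:
            self.duplicate_count += 1
            return False
        self._entries[entry.key] = entry
        return True

    def __iter__(self) -> Iterator[SurnameEntry]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, surname: str) -> bool:
        return surname.strip().upper() in self._entries

    def get(self, surname: str) -> Optional[SurnameEntry]:
        return self._entries.get(surname.strip().upper())

    def keys(self) -> set[str]:
        """The set of uppercased spellings."""
        return set(self._entries)

    def surnames(self) -> list[str]:
        """Spellings as stored, in insertion order."""
        return [e.surname for e in self]

    def sorted_entries(self) -> list[SurnameEntry]:
        return sorted(self._entries.values(), key=lambda e: e.key)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SurnameList(name={self.name!r}, n={len(self)})"


def _clean(value: object) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return text or None


def _clean_year(value: object) -> Optional[int]:
    text = _clean(value)
    return int(float(text)) if text is not None else None


def read_vital_records(
    path: str | Path, dialect: Optional[Mapping[str, str]] = None
) -> tuple[list[VitalRecord], LoadSummary]:
    """Read a vital-records CSV into :class:`VitalRecord` rows.

    ``dialect`` maps file column names to canonical field names.  Rows with
    an empty surname are skipped and counted in the returned summary.

    Raises
    ------
    DialectError
        If no column maps to the required ``surname`` field.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame = frame.rename(columns=dict(dialect or {}))
    if "surname" not in frame.columns:
        raise DialectError(
            f"required column 'surname' not found in {path} (columns: {list(frame.columns)})"
        )
    records: list[VitalRecord] = []
    summary = LoadSummary()
    for row in frame.to_dict("records"):
        surname = _clean(row.get("surname"))
        if surname is None:
            summary.n_skipped += 1
            continue
        records.append(
            VitalRecord(
                surname=surname,
                father_surname=_clean(row.get("father_surname")),
                first_name=_clean(row.get("first_name")),
                sex=_clean(row.get("sex")),
                birthplace=_clean(row.get("birthplace")),
                birth_year=_clean_year(row.get("birth_year")),
                death_year=_clean_year(row.get("death_year")),
            )
        )
        summary.n_read += 1
    return records, summary


_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


def _clean_flag(value: object) -> Optional[bool]:
    text = _clean(value)
    if text is None:
        return None
    low = text.lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"unparseable boolean flag {text!r}")


def read_registry_records(
    path: str | Path, dialect: Optional[Mapping[str, str]] = None
) -> tuple[list[RegistryRecord], LoadSummary]:
    """Read a registry CSV into :class:`RegistryRecord` rows (see read_vital_records)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame = frame.rename(columns=dict(dialect or {}))
    if "surname" not in frame.columns:
        raise DialectError(
            f"required column 'surname' not found in {path} (columns: {list(frame.columns)})"
        )
    records: list[RegistryRecord] = []
    summary = LoadSummary()
    for row in frame.to_dict("records"):
        surname = _clean(row.get("surname"))
        if surname is None:
            summary.n_skipped += 1
            continue
        records.append(
            RegistryRecord(
                surname=surname,
                maiden_name=_clean(row.get("maiden_name")),
                father_surname=_clean(row.get("father_surname")),
                country_of_birth=_clean(row.get("country_of_birth")),
                on_reference_list=_clean_flag(row.get("on_reference_list")),
            )
        )
        summary.n_read += 1
    return records, summary


def read_surname_list(path: str | Path, name: str = "") -> SurnameList:
    """Read a surname list from plain text (one name/line) or provenance CSV.

    A file whose first line is the provenance header
    ``surname,source,truncated,evidence`` is parsed as CSV; anything else is
    treated as plain text.  Duplicate spellings (after uppercasing and
    trimming) collapse with a warning; an empty file yields an empty list
    with a warning, not an error.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    result = SurnameList(name=name or path.stem)
    lines = [line for line in text.splitlines() if line.strip()]
    if not lines:
        warnings.warn(f"surname list file {path} is empty", stacklevel=2)
        return result
    if lines[0].strip().lower() == ",".join(_LIST_CSV_HEADER):
        for row in csv.DictReader(lines):
            result.add(
                SurnameEntry(
                    surname=row["surname"],
                    source=row.get("source") or "external",
                    truncated=(row.get("truncated", "") or "").lower() in _TRUE,
                    evidence=row.get("evidence", "") or "",
                )
            )
    else:
        for line in lines:
            result.add(SurnameEntry(line.strip()))
    if result.duplicate_count:
        warnings.warn(
            f"{result.duplicate_count} duplicate surname(s) collapsed reading {path}",
            stacklevel=2,
        )
    return result


def write_surname_list(
    surname_list: SurnameList, path: str | Path, format: str = "plain"
) -> None:
    """Write a surname list, lexicographically sorted by uppercased spelling.

    ``plain`` writes one surname per line; ``csv`` adds the provenance
    columns.  Reading a written file back preserves the set of
    (surname, source) pairs, and write-read-write is byte-stable.
    """
    path = Path(path)
    entries = surname_list.sorted_entries()
    if format == "plain":
        path.write_text("".join(e.surname + "\n" for e in entries), encoding="utf-8")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(_LIST_CSV_HEADER)
            for e in entries:
                writer.writerow([e.surname, e.source, str(e.truncated).lower(), e.evidence])
    else:
        raise ValueError(f"unknown surname list format {format!r}")
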