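"""Evaluation of a surname list against registry-style records.

Operations: pairwise overlap (with Jaccard and coverage percentages),
three-set Venn region counts, coverage gain of a new list over a baseline
within a proxy-truth reference set, a list-membership x birthplace-stratum
contingency table with column percentages, and suffix-convention
distributions (optionally by birthplace stratum).

All set arithmetic is on uppercased exact spellings.  The optional
``truncation_aware`` membership mode additionally counts a list entry as
matching a record surname when one is a prefix of the other and the
shorter side is at least the truncation length — needed when retained
reference entries are truncated spellings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Protocol, Sequence, Union

from .filters import suffix_class
from .io_formats import RegistryRecord, SurnameList, VitalRecord

__all__ = [
    "OverlapReport",
    "VennThree",
    "ContingencyTable",
    "overlap",
    "venn3",
    "coverage_gain",
    "contingency",
    "suffix_distribution",
    "ListMembership",
    "OriginRanker",
    "SuffixHeuristicRanker",
]

STRATA = ("target", "other", "unknown")


def _keys(surname_list: SurnameList | Iterable[str]) -> set[str]:
    if isinstance(surname_list, SurnameList):
        return surname_list.keys()
    return {str(s).strip().upper() for s in surname_list}


@dataclass(frozen=True)
class OverlapReport:
    """Two-list overlap: exclusive counts, intersection, Jaccard, coverage of b."""

    only_a: int
    only_b: int
    both: int
    jaccard: Optional[float]  # None when both lists are empty
    pct_of_b_in_a: Optional[float]  # None when b is empty


def overlap(a: SurnameList | Iterable[str], b: SurnameList | Iterable[str]) -> OverlapReport:
    """Count surnames in both versus only one of two deduplicated lists."""
    set_a, set_b = _keys(a), _keys(b)
    both = len(set_a & set_b)
    only_a = len(set_a - set_b)
    only_b = len(set_b - set_a)
    union = only_a + only_b + both
    return OverlapReport(
        only_a=only_a,
        only_b=only_b,
        both=both,
        jaccard=(both / union) if union else None,
        pct_of_b_in_a=(100.0 * both / (only_b + both)) if (only_b + both) else None,
    )


@dataclass(frozen=True)
class VennThree:
    """Counts for the seven disjoint regions of three sets A, B, C."""

    a_only: int
    b_only: int
    c_only: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int

    @property
    def union_size(self) -> int:
        return (
            self.a_only + self.b_only + self.c_only
            + self.ab_only + self.ac_only + self.bc_only + self.abc
        )

    def marginal(self, which: str) -> int:
        """Total size of one input set (sum of its four regions)."""
        if which == "a":
            return self.a_only + self.ab_only + self.ac_only + self.abc
        if which == "b":
            return self.b_only + self.ab_only + self.bc_only + self.abc
        if which == "c":
            return self.c_only + self.ac_only + self.bc_only + self.abc
        raise ValueError(f"which must be 'a', 'b' or 'c', got {which!r}")

    def as_dict(self) -> dict[str, int]:
        return {
            "a_only": self.a_only, "b_only": self.b_only, "c_only": self.c_only,
            "ab_only": self.ab_only, "ac_only": self.ac_only, "bc_only": self.bc_only,
            "abc": self.abc,
        }


def venn3(
    a: SurnameList | Iterable[str],
    b: SurnameList | Iterable[str],
    c: SurnameList | Iterable[str],
) -> VennThree:
    """Region counts for the three-set Venn decomposition."""
    set_a, set_b, set_c = _keys(a), _keys(b), _keys(c)
    abc = set_a & set_b & set_c
    ab = (set_a & set_b) - abc
    ac = (set_a & set_c) - abc
    bc = (set_b & set_c) - abc
    return VennThree(
        a_only=len(set_a - set_b - set_c),
        b_only=len(set_b - set_a - set_c),
        c_only=len(set_c - set_a - set_b),
        ab_only=len(ab),
        ac_only=len(ac),
        bc_only=len(bc),
        abc=len(abc),
    )


def coverage_gain(
    new_list: SurnameList | Iterable[str],
    baseline: SurnameList | Iterable[str],
    reference: SurnameList | Iterable[str],
) -> tuple[int, Optional[float]]:
    """Reference surnames captured by the new list but missed by the baseline.

    Returns ``(gain_count, gain_pct)`` where gain_pct is the percentage of
    reference-and-new surnames absent from the baseline; None when the new
    list captures no reference surname at all.
    """
    new_keys, base_keys, ref_keys = _keys(new_list), _keys(baseline), _keys(reference)
    captured = ref_keys & new_keys
    gained = captured - base_keys
    pct = (100.0 * len(gained) / len(captured)) if captured else None
    return len(gained), pct


class ListMembership:
    """Membership test for a surname list, exact or truncation-aware.

    In ``truncation_aware`` mode a query also matches when it extends (or
    is extended by) a list entry of at least ``truncation_length`` letters
    sharing that prefix — the situation created by fixed-width truncation
    in the reference extract.
    """

    def __init__(
        self,
        surname_list: SurnameList | Iterable[str],
        match_mode: str = "exact",
        truncation_length: int = 10,
    ) -> None:
        if match_mode not in ("exact", "truncation_aware"):
            raise ValueError(f"unknown match_mode {match_mode!r}")
        self._keys = _keys(surname_list)
        self.match_mode = match_mode
        self.truncation_length = truncation_length
        self._prefixes = (
            {k[:truncation_length] for k in self._keys if len(k) >= truncation_length}
            if match_mode == "truncation_aware"
            else set()
        )

    def __contains__(self, surname: str) -> bool:
        key = str(surname).strip().upper()
        if key in self._keys:
            return True
        if self.match_mode != "truncation_aware" or len(key) < self.truncation_length:
            return False
        # query is a truncated form of a listed full name, or extends a
        # truncated listed form
        if key[: self.truncation_length] in self._prefixes and any(
            k.startswith(key) or key.startswith(k)
            for k in self._keys
            if len(k) >= self.truncation_length
        ):
            return True
        return False


@dataclass(frozen=True)
class ContingencyTable:
    """2x3 cross-tab: list membership (yes/no) x birthplace stratum.

    Units are unique (surname, stratum) pairs: a surname seen with two
    different birthplaces counts once in each stratum.  Percentages are
    within columns.
    """

    counts: dict[str, dict[str, int]]  # counts[row][column]
    column_pct: dict[str, dict[str, float]]

    @property
    def grand_total(self) -> int:
        return sum(sum(row.values()) for row in self.counts.values())

    def column_total(self, column: str) -> int:
        return self.counts["yes"][column] + self.counts["no"][column]


Record = Union[VitalRecord, RegistryRecord]


def _record_stratum(record: Record, target: str) -> str:
    birthplace = (
        record.birthplace if isinstance(record, VitalRecord) else record.country_of_birth
    )
    if birthplace is None or not birthplace.strip():
        return "unknown"
    return "target" if birthplace.strip().upper() == target.strip().upper() else "other"


def contingency(
    records: Sequence[Record],
    surname_list: SurnameList | Iterable[str],
    target_birthplace: str,
    match_mode: str = "exact",
    truncation_length: int = 10,
) -> ContingencyTable:
    """Cross-tabulate harvested unique surnames by list membership and stratum."""
    membership = ListMembership(surname_list, match_mode, truncation_length)
    units: set[tuple[str, str]] = set()
    for record in records:
        units.add((record.surname.strip().upper(), _record_stratum(record, target_birthplace)))
    counts = {row: {col: 0 for col in STRATA} for row in ("yes", "no")}
    for surname, stratum in units:
        row = "yes" if surname in membership else "no"
        counts[row][stratum] += 1
    column_pct = {row: {} for row in ("yes", "no")}
    for col in STRATA:
        total = counts["yes"][col] + counts["no"][col]
        for row in ("yes", "no"):
            column_pct[row][col] = (100.0 * counts[row][col] / total) if total else math.nan
    return ContingencyTable(counts=counts, column_pct=column_pct)


def suffix_distribution(
    surname_list: SurnameList | Iterable[str],
    strata: Optional[Mapping[str, str]] = None,
) -> dict[str, dict[str, float]]:
    """Proportions of suffix-convention classes, overall or per stratum.

    ``strata`` maps uppercased surname -> stratum label; names without a
    mapping fall into an "unassigned" stratum.  Empty strata are omitted.
    Proportions within each stratum sum to 1.
    """
    names = _keys(surname_list)
    groups: dict[str, list[str]] = {}
    if strata is None:
        groups["all"] = list(names)
    else:
        upper_strata = {k.strip().upper(): v for k, v in strata.items()}
        for name in names:
            groups.setdefault(upper_strata.get(name, "unassigned"), []).append(name)
    out: dict[str, dict[str, float]] = {}
    for stratum, members in groups.items():
        if not members:
            continue
        tally = {"I_convention": 0, "Y_convention": 0, "russian": 0, "other": 0}
        for name in members:
            tally[suffix_class(name)] += 1
        out[stratum] = {cls: count / len(members) for cls, count in tally.items()}
    return out


class OriginRanker(Protocol):
    """Adapter contract for an external country-of-origin ranking service.

    Implementations return up to 10 (country, rank) pairs ordered from most
    to least likely origin of the surname.  No production implementation is
    bundled; external classification services fill this slot.
    """

    def rank(self, surname: str) -> list[tuple[str, int]]: ...


class SuffixHeuristicRanker:
    """Toy ranker for pipeline plumbing tests ONLY — not a scientific classifier.

    Ranks a fixed country guess from the suffix-convention class.  It exists
    so the evaluation pipeline can be exercised end to end without an
    external service; its output has no validity for research use.
    """

    _GUESS = {
        "I_convention": ["Armenia", "Iran"],
        "Y_convention": ["Armenia", "Georgia"],
        "russian": ["Russia", "Armenia"],
        "other": ["Unknown"],
    }

    def rank(self, surname: str) -> list[tuple[str, int]]:
        return [(country, i + 1) for i, country in enumerate(self._GUESS[suffix_class(surname)])]
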