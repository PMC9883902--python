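"""Orchestration of the full surname-list build with an audit trail.

The build mirrors a two-step construction:

* Step 1 — link the reference extract against surnames harvested from the
  vital records (Soundex-blocked linkage).  Every spelling on either side
  of a match pair enters the output as ``reference_linked``; spelling
  variants ("Mahtesyan" / "Mahtesian") are therefore both retained as
  distinct entries.
* Step 2 — surnames on target-birthplace records that did not link in
  Step 1 become candidates, the deletion rules prune them, and survivors
  enter as ``birthplace_added``.
* Reference surnames that neither linked nor resurfaced through the
  birthplace query are kept verbatim as ``reference_retained`` (these are
  the only entries that may carry a truncated spelling).

The three source sets are disjoint by construction, and a
:class:`BuildAudit` records every box of the flow so list releases can be
reconciled count by count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .filters import FilterConfig, FilterDecision, apply_filter
from .io_formats import SurnameEntry, SurnameList, VitalRecord
from .linkage import LinkageConfig, LinkageResult, link

__all__ = [
    "BuildConfig",
    "BuildAudit",
    "harvest_surnames",
    "birthplace_candidates",
    "build_list",
]


@dataclass(frozen=True)
class BuildConfig:
    """Knobs for the full build.

    ``target_birthplace`` selects the records whose surnames are candidates
    in Step 2 (compared case-insensitively).  ``harvest_father_surname``
    additionally harvests the father's surname from each record, which
    catches inherited spellings hidden behind a changed family name
    (a record "Danielson" with father "Danielian" contributes both).
    ``emit_truncated_reference`` controls whether the (possibly truncated)
    reference spelling of a linked pair is emitted alongside the full form.
    """

    target_birthplace: str = "Armenia"
    linkage: LinkageConfig = field(default_factory=LinkageConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    harvest_father_surname: bool = True
    emit_truncated_reference: bool = True
    collapse_punctuation_variants: bool = False

    def __post_init__(self) -> None:
        if not self.target_birthplace.strip():
            raise ValueError("target_birthplace must be non-empty")


@dataclass(frozen=True)
class BuildAudit:
    """Counts for each box of the construction flow."""

    n_reference_input: int
    n_linked: int
    n_birthplace_candidates: int
    n_removed_by_filter: int
    n_birthplace_added: int
    n_reference_retained: int
    n_total_unique: int

    def as_dict(self) -> dict[str, int]:
        return {
            "n_reference_input": self.n_reference_input,
            "n_linked": self.n_linked,
            "n_birthplace_candidates": self.n_birthplace_candidates,
            "n_removed_by_filter": self.n_removed_by_filter,
            "n_birthplace_added": self.n_birthplace_added,
            "n_reference_retained": self.n_reference_retained,
            "n_total_unique": self.n_total_unique,
        }


def harvest_surnames(
    records: Iterable[VitalRecord], config: BuildConfig = BuildConfig()
) -> SurnameList:
    """Unique surnames from the surname (and optionally father-surname) fields.

    Uniqueness is by uppercased exact spelling; each entry's evidence notes
    the field it first appeared in.
    """
    harvested = SurnameList(name="harvested")
    for record in records:
        harvested.add(SurnameEntry(record.surname, source="external", evidence="surname"))
        if config.harvest_father_surname and record.father_surname:
            harvested.add(
                SurnameEntry(record.father_surname, source="external", evidence="father_surname")
            )
    return harvested


def _is_target(birthplace: Optional[str], target: str) -> bool:
    return birthplace is not None and birthplace.strip().upper() == target.strip().upper()


def birthplace_candidates(
    records: Iterable[VitalRecord],
    linked: set[str],
    config: BuildConfig = BuildConfig(),
) -> SurnameList:
    """Surnames on target-birthplace records that Step 1 did not link.

    ``linked`` is the set of uppercased spellings already captured by the
    linkage; records with missing or other birthplace contribute nothing.
    """
    linked_keys = {name.strip().upper() for name in linked}
    candidates = SurnameList(name="birthplace_candidates")
    for record in records:
        if not _is_target(record.birthplace, config.target_birthplace):
            continue
        names = [record.surname]
        if config.harvest_father_surname and record.father_surname:
            names.append(record.father_surname)
        for name in names:
            if name.strip().upper() not in linked_keys:
                candidates.add(
                    SurnameEntry(name, source="external", evidence="birthplace_query")
                )
    return candidates


def build_list(
    reference: SurnameList,
    records: Iterable[VitalRecord],
    config: BuildConfig = BuildConfig(),
) -> tuple[SurnameList, BuildAudit, LinkageResult, list[FilterDecision]]:
    """Run the full two-step build and return (list, audit, linkage, decisions).

    Deterministic for fixed inputs and config.  Empty reference or records
    are tolerated: the build proceeds and the audit shows zeros.
    """
    records = list(records)
    harvested = harvest_surnames(records, config)

    # Step 1: blocked linkage of reference spellings vs harvested spellings.
    if len(reference) and len(harvested):
        linkage_result = link(reference, harvested, config.linkage)
    else:
        linkage_result = LinkageResult(
            matches=[],
            reviews=[],
            left_names=reference.surnames(),
            right_names=harvested.surnames(),
        )

    output = SurnameList(name="built")
    linked_keys: set[str] = set()
    for result in linkage_result.matches:
        left_entry = reference.get(result.pair.left)
        truncated_left = bool(left_entry and left_entry.truncated)
        linked_keys.add(result.pair.left.strip().upper())
        linked_keys.add(result.pair.right.strip().upper())
        if config.emit_truncated_reference or result.basis != "truncation_prefix":
            output.add(
                SurnameEntry(
                    result.pair.left,
                    source="reference_linked",
                    truncated=truncated_left,
                    evidence=f"linked:{result.basis}",
                )
            )
        output.add(
            SurnameEntry(
                result.pair.right, source="reference_linked",
                evidence=f"linked:{result.basis}",
            )
        )
    n_linked = sum(1 for e in output if e.source == "reference_linked")

    # Step 2: birthplace-derived candidates, pruned by the deletion rules.
    candidates = birthplace_candidates(records, linked_keys, config)
    kept, removed, decisions = apply_filter(candidates, config.filter)
    for entry in kept:
        output.add(
            SurnameEntry(entry.surname, source="birthplace_added", evidence=entry.evidence)
        )

    # Retained reference surnames: neither linked nor re-found by birthplace.
    n_retained = 0
    for entry in reference:
        if entry.key in linked_keys or entry.key in kept.keys():
            continue
        added = output.add(
            SurnameEntry(
                entry.surname,
                source="reference_retained",
                truncated=entry.truncated,
                evidence="retained_unlinked",
            )
        )
        if added:
            n_retained += 1

    audit = BuildAudit(
        n_reference_input=len(reference),
        n_linked=n_linked,
        n_birthplace_candidates=len(candidates),
        n_removed_by_filter=len(removed),
        n_birthplace_added=len(kept),
        n_reference_retained=n_retained,
        n_total_unique=len(output),
    )
    return output, audit, linkage_result, decisions
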