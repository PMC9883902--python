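"""Deletion rules for birthplace-derived surname candidates.

Names harvested purely because they appear on a record with the target
birthplace include plenty of non-target surnames (clerical coincidence,
mixed households).  Two rules prune them:

1. delete names shorter than ``min_length`` letters;
2. delete names that carry neither a recognized patronymic suffix
   (Armenian -ian/-yan family, Russian -ov/-ova) nor enough length
   (``long_name_exempt_length``) to be kept on length alone.

Everything else is kept.  The rules are evaluated in that order, which is
observable in the reason codes: a four-letter "-yan" name ("Ryan") is
deleted as too short, not rescued by its suffix.  Lengths count letters
only (via phonetics.normalize), so hyphens and spaces are neutral.

The suffix-convention classifier used by the evaluation stage also lives
here: I-convention (-ian/-ians/-iants), Y-convention (-yan/-yans/-yants),
Russian (-ov/-ova), other.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .io_formats import SurnameList
from .phonetics import normalize

__all__ = [
    "FilterConfig",
    "FilterDecision",
    "suffix_match",
    "decide",
    "apply_filter",
    "suffix_class",
    "ARMENIAN_SUFFIXES",
    "RUSSIAN_SUFFIXES",
]

ARMENIAN_SUFFIXES = ("ian", "yan", "ians", "yans", "iants", "yants")
RUSSIAN_SUFFIXES = ("ov", "ova")

_I_CONVENTION = frozenset({"ian", "ians", "iants"})
_Y_CONVENTION = frozenset({"yan", "yans", "yants"})


@dataclass(frozen=True)
class FilterConfig:
    """Suffix inventories and length thresholds for the deletion rules.

    Defaults follow common usage for the target population: the Armenian
    -ian/-yan suffix family plus the Russian patronymic -ov/-ova (kept
    because of Soviet-era suffix changes), a 5-letter minimum, and a
    12-letter exemption above which a name is kept without any suffix.
    """

    armenian_suffixes: tuple[str, ...] = ARMENIAN_SUFFIXES
    russian_suffixes: tuple[str, ...] = RUSSIAN_SUFFIXES
    min_length: int = 5
    long_name_exempt_length: int = 12

    def __post_init__(self) -> None:
        for suffix in self.armenian_suffixes + self.russian_suffixes:
            if not suffix or not suffix.isalpha() or suffix != suffix.lower():
                raise ValueError(f"suffixes must be non-empty lowercase letters: {suffix!r}")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.long_name_exempt_length <= self.min_length:
            raise ValueError("long_name_exempt_length must exceed min_length")

    @property
    def all_suffixes(self) -> tuple[str, ...]:
        return self.armenian_suffixes + self.russian_suffixes


@dataclass(frozen=True)
class FilterDecision:
    """Keep/delete verdict for one candidate, with the rule that fired."""

    surname: str
    keep: bool
    reason: str  # too_short | no_suffix_and_short | kept_suffix | kept_long
    matched_suffix: Optional[str] = None


def _final_token_letters(surname: str) -> str:
    """Lowercase letters of the text after the last hyphen/space.

    Suffix tests apply to the inheritable stem of a compound name:
    'Ter-Prakhourany' is tested on "prakhourany", so a prefix particle
    never supplies or masks a suffix.
    """
    token = re.split(r"[-\s]+", surname.strip())[-1]
    return normalize(token).normalized.lower() if re.search(r"[^\W\d_]", token) else ""


def suffix_match(surname: str, config: FilterConfig = FilterConfig()) -> Optional[str]:
    """Longest configured suffix carried by the final token, or None."""
    token = _final_token_letters(surname)
    best = None
    for suffix in config.all_suffixes:
        if token.endswith(suffix) and (best is None or len(suffix) > len(best)):
            best = suffix
    return best


def decide(surname: str, config: FilterConfig = FilterConfig()) -> FilterDecision:
    """Apply the two deletion rules to one candidate surname.

    Delete when letters_count < min_length, or when no configured suffix
    matches and letters_count < long_name_exempt_length; keep otherwise.
    """
    letters = normalize(surname).letters_count
    suffix = suffix_match(surname, config)
    if letters < config.min_length:
        return FilterDecision(surname, keep=False, reason="too_short", matched_suffix=suffix)
    if suffix is None:
        if letters < config.long_name_exempt_length:
            return FilterDecision(surname, keep=False, reason="no_suffix_and_short")
        return FilterDecision(surname, keep=True, reason="kept_long")
    return FilterDecision(surname, keep=True, reason="kept_suffix", matched_suffix=suffix)


def apply_filter(
    candidates: SurnameList, config: FilterConfig = FilterConfig()
) -> tuple[SurnameList, SurnameList, list[FilterDecision]]:
    """Partition a candidate list into kept and removed, with per-name decisions."""
    kept = SurnameList(name=f"{candidates.name}:kept")
    removed = SurnameList(name=f"{candidates.name}:removed")
    decisions: list[FilterDecision] = []
    for entry in candidates:
        decision = decide(entry.surname, config)
        decisions.append(decision)
        (kept if decision.keep else removed).add(entry)
    return kept, removed, decisions


def suffix_class(surname: str) -> str:
    """Suffix-convention class: I_convention, Y_convention, russian, or other."""
    token = _final_token_letters(surname)
    best = None
    for suffix in ARMENIAN_SUFFIXES + RUSSIAN_SUFFIXES:
        if token.endswith(suffix) and (best is None or len(suffix) > len(best)):
            best = suffix
    if best in _I_CONVENTION:
        return "I_convention"
    if best in _Y_CONVENTION:
        return "Y_convention"
    if best in RUSSIAN_SUFFIXES:
        return "russian"
    return "other"
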