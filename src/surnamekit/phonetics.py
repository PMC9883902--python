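"""Surname normalization and American Soundex phonetic coding.

Soundex is the blocking key for the whole linkage stage: two surnames are
compared at all only if their codes agree.  The variant implemented here is
standard American Soundex, including the rule that letters separated only by
H or W collapse as if adjacent (so ASHCRAFT -> A261, not A226).

Normalization strips everything that is not a letter before coding, so
hyphen, space and case variants of a surname ("Ter-Minasyan",
"Ter Minasyan", "TER MINASYAN") land in the same block and compare as
identical strings downstream.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass

__all__ = [
    "DegenerateNameError",
    "NormalizedSurname",
    "normalize",
    "soundex",
    "same_block",
]


class DegenerateNameError(ValueError):
    """Raised when an input contains no letters after normalization."""


@dataclass(frozen=True)
class NormalizedSurname:
    """A surname reduced to uppercase ASCII letters.

    Attributes
    ----------
    original : str
        The input exactly as supplied.
    normalized : str
        Uppercase A-Z only: diacritics folded, punctuation, spaces and
        digits removed.
    letters_count : int
        ``len(normalized)``; the canonical length used by the filter rules,
        so punctuation never rescues or dooms a name under a length
        threshold.
    """

    original: str
    normalized: str
    letters_count: int


# Soundex digit classes.  Vowels and Y reset the "previous digit" state;
# H and W are transparent (the previous digit survives across them).
_SOUNDEX_DIGITS = {
    **dict.fromkeys("BFPV", "1"),
    **dict.fromkeys("CGJKQSXZ", "2"),
    **dict.fromkeys("DT", "3"),
    "L": "4",
    **dict.fromkeys("MN", "5"),
    "R": "6",
}
_VOWELS = frozenset("AEIOUY")


def _fold_ascii(text: str) -> str:
    """Transliterate diacritics to plain ASCII letters (é -> E, ü -> U)."""
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def normalize(raw: str) -> NormalizedSurname:
    """Normalize a raw surname to uppercase letters only.

    Spaces, hyphens, apostrophes, periods and digits are removed and
    diacritics are folded to ASCII, so spelling variants that differ only in
    punctuation or case normalize identically.  Idempotent.

    Raises
    ------
    DegenerateNameError
        If no letters remain (empty input, or punctuation/digits only).
    """
    folded = _fold_ascii(str(raw)).upper()
    letters = "".join(ch for ch in folded if "A" <= ch <= "Z")
    if not letters:
        raise DegenerateNameError(f"no letters in surname input {raw!r}")
    return NormalizedSurname(original=raw, normalized=letters, letters_count=len(letters))


def soundex(name: NormalizedSurname | str) -> str:
    """American Soundex code: one letter followed by three digits.

    Rules: keep the first letter; map the remaining letters to digit
    classes; drop vowels and Y (resetting adjacency); treat H and W as
    transparent; collapse runs of the same digit, including a run that
    starts at the first letter; pad with zeros / truncate to 4 characters.
    """
    if isinstance(name, str):
        name = normalize(name)
    letters = name.normalized
    first = letters[0]
    prev = _SOUNDEX_DIGITS.get(first)  # first letter participates in collapsing
    digits: list[str] = []
    for ch in letters[1:]:
        if ch in ("H", "W"):
            continue  # transparent: prev digit survives
        if ch in _VOWELS:
            prev = None
            continue
        digit = _SOUNDEX_DIGITS[ch]
        if digit != prev:
            digits.append(digit)
        prev = digit
        if len(digits) == 3:
            break
    return first + "".join(digits).ljust(3, "0")


def same_block(a: str, b: str) -> bool:
    """True iff the two surnames share a Soundex block.

    Symmetric and reflexive; an equivalence relation on normalizable
    strings.  Degenerate inputs raise :class:`DegenerateNameError`.
    """
    return soundex(normalize(a)) == soundex(normalize(b))
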