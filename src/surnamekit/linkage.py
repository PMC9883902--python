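"""Soundex-blocked surname linkage with a manual-review round-trip.

Candidate pairs are generated only within shared Soundex blocks, then each
pair is scored on a three-tier basis:

1. ``exact_normalized`` — the punctuation-stripped uppercase forms are equal
   (score 1.0, always a match; this is how "Ter-Minasyan" and
   "Ter Minasyan" score as a perfect match);
2. ``truncation_prefix`` — one form is a proper prefix of the other and the
   shorter form is at least ``truncation_length`` letters, matching a
   reference spelling cut at a fixed width against its full form
   ("Haroutunia" / "Haroutunian");
3. ``similarity`` — Jaro-Winkler on the normalized forms, thresholded into
   match / review / non-match.

Review pairs can be exported to CSV, decided by hand, and imported back;
undecided pairs resolve to a configurable default (non-match by default,
the conservative choice).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .io_formats import SurnameList
from .phonetics import normalize, soundex

__all__ = [
    "LinkageConfig",
    "CandidatePair",
    "MatchResult",
    "LinkageResult",
    "ReviewImportError",
    "jaro_winkler",
    "generate_candidates",
    "score_pair",
    "link",
    "export_review",
    "import_review",
]


class ReviewImportError(ValueError):
    """A review file row refers to a pair that is not under review."""


@dataclass(frozen=True)
class LinkageConfig:
    """Scoring thresholds and truncation behaviour for the linkage stage.

    ``match_threshold`` and ``review_low`` partition the similarity scale
    into non-match / review / match; ``truncation_length`` is the fixed
    width reference spellings were cut at.  With ``asymmetric_truncation``
    the truncated (shorter) form must be the left (reference) name.
    """

    match_threshold: float = 0.95
    review_low: float = 0.85
    truncation_length: int = 10
    asymmetric_truncation: bool = False
    default_review_decision: str = "non_match"

    def __post_init__(self) -> None:
        if not 0.0 <= self.review_low <= self.match_threshold <= 1.0:
            raise ValueError("need 0 <= review_low <= match_threshold <= 1")
        if self.default_review_decision not in ("match", "non_match"):
            raise ValueError("default_review_decision must be 'match' or 'non_match'")


@dataclass(frozen=True)
class CandidatePair:
    """A same-block (left, right) surname pair; ``block_code`` is the shared Soundex."""

    left: str
    right: str
    block_code: str


@dataclass(frozen=True)
class MatchResult:
    """A scored candidate pair with its basis and category."""

    pair: CandidatePair
    score: float
    basis: str  # exact_normalized | truncation_prefix | similarity
    category: str  # match | review | non_match


@dataclass
class LinkageResult:
    """Outcome of linking two lists: matches, pending reviews, unmatched names.

    A surname is unmatched when it appears in no match pair and no pending
    review pair.  ``left_names`` / ``right_names`` retain the input
    inventories so review decisions can be re-applied consistently.
    """

    matches: list[MatchResult]
    reviews: list[MatchResult]
    left_names: list[str]
    right_names: list[str]

    @property
    def left_unmatched(self) -> set[str]:
        seen = {r.pair.left for r in self.matches} | {r.pair.left for r in self.reviews}
        return {n for n in self.left_names if n not in seen}

    @property
    def right_unmatched(self) -> set[str]:
        seen = {r.pair.right for r in self.matches} | {r.pair.right for r in self.reviews}
        return {n for n in self.right_names if n not in seen}

    def linked_left(self) -> set[str]:
        """Left surnames appearing in at least one match pair."""
        return {r.pair.left for r in self.matches}

    def linked_right(self) -> set[str]:
        return {r.pair.right for r in self.matches}


def _jaro(s1: str, s2: str) -> float:
    if s1 == s2:
        return 1.0
    len1, len2 = len(s1), len(s2)
    if not len1 or not len2:
        return 0.0
    window = max(len1, len2) // 2 - 1
    flags1 = [False] * len1
    flags2 = [False] * len2
    matches = 0
    for i, ch in enumerate(s1):
        lo = max(0, i - window)
        hi = min(len2, i + window + 1)
        for j in range(lo, hi):
            if not flags2[j] and s2[j] == ch:
                flags1[i] = flags2[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    transpositions = 0
    j = 0
    for i in range(len1):
        if flags1[i]:
            while not flags2[j]:
                j += 1
            if s1[i] != s2[j]:
                transpositions += 1
            j += 1
    transpositions //= 2
    return (
        matches / len1 + matches / len2 + (matches - transpositions) / matches
    ) / 3.0


def jaro_winkler(s1: str, s2: str, prefix_scale: float = 0.1) -> float:
    """Jaro-Winkler similarity in [0, 1].

    The Winkler common-prefix boost (up to 4 characters, scale 0.1) is
    applied only when the base Jaro score exceeds 0.7, the conventional
    boost threshold.
    """
    jaro = _jaro(s1, s2)
    if jaro <= 0.7:
        return jaro
    prefix = 0
    for a, b in zip(s1[:4], s2[:4]):
        if a != b:
            break
        prefix += 1
    return jaro + prefix * prefix_scale * (1.0 - jaro)


def _blocks(names: Iterable[str]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for name in names:
        out.setdefault(soundex(normalize(name)), []).append(name)
    return out


def _list_names(surname_list: SurnameList | Iterable[str]) -> list[str]:
    if isinstance(surname_list, SurnameList):
        return surname_list.surnames()
    return list(surname_list)


def generate_candidates(
    left_list: SurnameList | Iterable[str], right_list: SurnameList | Iterable[str]
) -> list[CandidatePair]:
    """All cross-pairs within shared Soundex blocks, sorted by (block, left, right)."""
    left_blocks = _blocks(_list_names(left_list))
    right_blocks = _blocks(_list_names(right_list))
    pairs = [
        CandidatePair(left=l, right=r, block_code=code)
        for code in left_blocks.keys() & right_blocks.keys()
        for l in left_blocks[code]
        for r in right_blocks[code]
    ]
    pairs.sort(key=lambda p: (p.block_code, p.left.upper(), p.right.upper()))
    return pairs


def score_pair(pair: CandidatePair, config: LinkageConfig = LinkageConfig()) -> MatchResult:
    """Score one candidate pair on the three-tier basis."""
    left = normalize(pair.left).normalized
    right = normalize(pair.right).normalized
    if left == right:
        return MatchResult(pair, 1.0, "exact_normalized", "match")
    shorter, longer = (left, right) if len(left) <= len(right) else (right, left)
    prefix_ok = len(shorter) >= config.truncation_length and longer.startswith(shorter)
    if config.asymmetric_truncation:
        prefix_ok = prefix_ok and shorter == left
    if prefix_ok:
        return MatchResult(pair, 1.0, "truncation_prefix", "match")
    score = jaro_winkler(left, right)
    if score >= config.match_threshold:
        category = "match"
    elif score >= config.review_low:
        category = "review"
    else:
        category = "non_match"
    return MatchResult(pair, score, "similarity", category)


def link(
    left_list: SurnameList | Iterable[str],
    right_list: SurnameList | Iterable[str],
    config: LinkageConfig = LinkageConfig(),
) -> LinkageResult:
    """Block, score and categorize every candidate pair between two lists."""
    left_names = _list_names(left_list)
    right_names = _list_names(right_list)
    matches: list[MatchResult] = []
    reviews: list[MatchResult] = []
    for pair in generate_candidates(left_names, right_names):
        result = score_pair(pair, config)
        if result.category == "match":
            matches.append(result)
        elif result.category == "review":
            reviews.append(result)
    return LinkageResult(
        matches=matches, reviews=reviews, left_names=left_names, right_names=right_names
    )


_REVIEW_HEADER = ["left", "right", "score", "basis", "decision"]


def export_review(result: LinkageResult, path: str | Path) -> None:
    """Write all pending review pairs to CSV with an empty decision column."""
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(_REVIEW_HEADER)
        for r in result.reviews:
            writer.writerow([r.pair.left, r.pair.right, f"{r.score:.6f}", r.basis, ""])


def import_review(
    result: LinkageResult, path: str | Path, config: LinkageConfig = LinkageConfig()
) -> LinkageResult:
    """Apply decisions from a review CSV; undecided pairs resolve per config.

    Raises :class:`ReviewImportError` listing any rows whose (left, right)
    pair is not among the pending review pairs.
    """
    decisions: dict[tuple[str, str], str] = {}
    bad_rows: list[str] = []
    known = {(r.pair.left, r.pair.right) for r in result.reviews}
    with Path(path).open(encoding="utf-8", newline="") as handle:
        for row in csv.DictReader(handle):
            decision = (row.get("decision") or "").strip().lower()
            if not decision:
                continue
            key = (row["left"], row["right"])
            if key not in known or decision not in ("match", "non_match"):
                bad_rows.append(f"{row['left']},{row['right']},{decision}")
                continue
            decisions[key] = decision
    if bad_rows:
        raise ReviewImportError(
            "review rows do not correspond to pending review pairs: " + "; ".join(bad_rows)
        )
    matches = list(result.matches)
    for r in result.reviews:
        decided = decisions.get((r.pair.left, r.pair.right), config.default_review_decision)
        if decided == "match":
            matches.append(MatchResult(r.pair, r.score, r.basis, "match"))
    return LinkageResult(
        matches=matches,
        reviews=[],
        left_names=result.left_names,
        right_names=result.right_names,
    )
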