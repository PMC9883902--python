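"""Ground-truth-labelled synthetic fixtures for every pipeline stage.

Real death-file, registry and reference-list data are access-restricted,
so this module fabricates a small world with the same *structure*: a
reference surname extract (possibly truncated at a fixed width), a vital
records file (surname, father's surname, birthplace, years) and a registry
file (surname, country of birth, reference-list flag) — every generated
surname carrying a target / non-target truth label.

Design choices that make recovery properties structural rather than lucky:

* Target surnames are built from CV-alternating syllable stems (consonant
  inventory excludes H, W and Y so every consonant contributes a Soundex
  digit, making fixed-width truncation Soundex-stable) plus a suffix drawn
  from the configured convention mix (Y-convention -yan family,
  I-convention -ian family, Russian -ov/-ova, or no suffix with >= 12
  letters).
* Non-target surnames are rejection-sampled so none shares a Soundex block
  with any target spelling: in a noise-free world nothing non-target can
  link, so false inclusions can only enter through the birthplace query —
  where the deletion rules remove them.
* Trap names emulate the classic false-positive shapes: very short names,
  medium-length suffix-less names, and short names with a coincidental
  "-yan" ending.  Traps are placed on target-birthplace records so that
  only the deletion rules stand between them and the output list.

Stems are synthetic syllable strings, not a real-name dictionary; no
personal data ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .evaluation import ListMembership
from .filters import suffix_match
from .io_formats import (
    RegistryRecord,
    SurnameEntry,
    SurnameList,
    VitalRecord,
    write_surname_list,
)
from .phonetics import normalize, soundex

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "make_surname",
    "generate_world",
    "score_against_truth",
    "write_world",
]

CONVENTIONS = ("Y_convention", "I_convention", "russian", "no_suffix_long")
PLACEMENTS = ("reference_only", "records_only", "both")

_CONSONANTS = "BDGKLMNRSTVZ"  # no H/W (Soundex-transparent), no Y (vowel-like)
_VOWELS = "AEIOU"

_SUFFIX_POOL = {
    "Y_convention": (("yan", "yans", "yants"), (0.8, 0.1, 0.1)),
    "I_convention": (("ian", "ians", "iants"), (0.8, 0.1, 0.1)),
    "russian": (("ov", "ova"), (0.6, 0.4)),
}


def _default_convention_mix() -> dict[str, float]:
    return {"Y_convention": 0.55, "I_convention": 0.25, "russian": 0.10, "no_suffix_long": 0.10}


def _default_placement_mix() -> dict[str, float]:
    return {"reference_only": 0.2, "records_only": 0.4, "both": 0.4}


def _default_birthplace_mix() -> dict[str, float]:
    return {"United States": 0.6, "Mexico": 0.2, "Philippines": 0.1, "unknown": 0.1}


@dataclass
class WorldConfig:
    """Parameters of the synthetic world.

    Defaults emulate the study conditions at desk scale: a few hundred
    target stems, a Y-dominant suffix-convention mix, 10% truncation in the
    reference extract, 10% spelling-variant noise between the extract and
    the records, a small realistic rate of missing birthplace on
    target-name records, and a dozen filter-removable trap names riding on
    target-birthplace records.
    """

    n_target_stems: int = 300
    n_other_surnames: int = 300
    n_traps: int = 12
    convention_mix: dict[str, float] = field(default_factory=_default_convention_mix)
    placement_mix: dict[str, float] = field(default_factory=_default_placement_mix)
    p_variant_spelling: float = 0.10
    p_truncated_in_reference: float = 0.10
    p_target_birthplace_missing: float = 0.05
    p_father_only: float = 0.05
    p_particle: float = 0.08
    birthplace_mix: dict[str, float] = field(default_factory=_default_birthplace_mix)
    target_birthplace: str = "Armenia"
    truncation_length: int = 10
    p_registry_target: float = 0.5
    p_registry_other: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name, mix in (
            ("convention_mix", self.convention_mix),
            ("placement_mix", self.placement_mix),
            ("birthplace_mix", self.birthplace_mix),
        ):
            if any(p < 0 for p in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must be >= 0 and sum to 1")
        if set(self.convention_mix) != set(CONVENTIONS):
            raise ValueError(f"convention_mix must cover exactly {CONVENTIONS}")
        if set(self.placement_mix) != set(PLACEMENTS):
            raise ValueError(f"placement_mix must cover exactly {PLACEMENTS}")
        for p in (
            self.p_variant_spelling,
            self.p_truncated_in_reference,
            self.p_target_birthplace_missing,
            self.p_father_only,
            self.p_particle,
            self.p_registry_target,
            self.p_registry_other,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_target_stems < 1:
            raise ValueError("need at least one target stem")
        if self.n_other_surnames < 0 or self.n_traps < 0:
            raise ValueError("counts must be non-negative")
        target_key = self.target_birthplace.strip().upper()
        if any(k.strip().upper() == target_key for k in self.birthplace_mix):
            raise ValueError("birthplace_mix must not include the target birthplace")


@dataclass
class SyntheticWorld:
    """A generated world: labelled truth plus the three input artifacts."""

    config: WorldConfig
    truth: dict[str, str]  # uppercased spelling -> "target" | "non_target"
    reference_extract: SurnameList
    vital_records: list[VitalRecord]
    registry_records: list[RegistryRecord]
    trap_surnames: set[str]

    def target_spellings_in_sources(self) -> set[str]:
        """Uppercased target spellings present in the extract or the records."""
        present: set[str] = set(self.reference_extract.keys())
        for record in self.vital_records:
            present.add(record.surname.upper())
            if record.father_surname:
                present.add(record.father_surname.upper())
        return {s for s in present if self.truth.get(s) == "target"}


def _syllable(rng: np.random.Generator) -> str:
    return rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))


def _stem(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(_syllable(rng) for _ in range(n_syllables))


def make_surname(
    stem: str,
    convention: str,
    rng: Optional[np.random.Generator] = None,
    particle_prob: float = 0.0,
) -> str:
    """Compose a surname from a stem and a suffix convention.

    Suffixed conventions append one suffix from their family; the
    ``no_suffix_long`` convention instead pads the stem with syllables
    until it has at least 12 letters and carries no recognized suffix.
    With ``particle_prob`` a "Ter-" particle is prepended.
    """
    if len(stem) < 3:
        raise ValueError("stem must have at least 3 letters")
    rng = rng or np.random.default_rng(0)
    stem = stem.upper()
    if convention == "no_suffix_long":
        body = stem
        while len(body) < 12 or suffix_match(body.title()) is not None:
            body += _syllable(rng)
    elif convention in _SUFFIX_POOL:
        suffixes, weights = _SUFFIX_POOL[convention]
        body = stem + str(rng.choice(suffixes, p=weights)).upper()
    else:
        raise ValueError(f"unknown convention {convention!r}")
    name = body.title()
    if particle_prob and rng.random() < particle_prob:
        name = "Ter-" + name
    return name


def _variant_spelling(name: str, rng: np.random.Generator) -> str:
    """A same-block spelling variant: ian<->yan swap, or hyphen<->space."""
    if "-" in name:
        return name.replace("-", " ", 1)
    if " " in name:
        return name.replace(" ", "-", 1)
    low = name.lower()
    for a, b in (("ian", "yan"), ("yan", "ian")):
        if low.endswith(a + "s") or low.endswith(a + "ts") or low.endswith(a):
            idx = low.rfind(a)
            swapped = name[:idx] + b + name[idx + len(a):]
            return swapped
    return name  # no applicable variant; caller treats as unchanged


def _truncate(name: str, length: int) -> str:
    return name if len(name) <= length else name[:length]


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a reproducible labelled world from the config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth: dict[str, str] = {}
    used_spellings: set[str] = set()
    target_codes: set[str] = set()

    def register(name: str, label: str) -> None:
        truth[name.upper()] = label
        used_spellings.add(name.upper())
        if label == "target":
            target_codes.add(soundex(normalize(name)))

    # --- target inventory -------------------------------------------------
    conventions = list(config.convention_mix)
    conv_probs = [config.convention_mix[c] for c in conventions]
    placements = list(config.placement_mix)
    place_probs = [config.placement_mix[c] for c in placements]

    target_names: list[tuple[str, str, str]] = []  # (spelling, convention, placement)
    while len(target_names) < config.n_target_stems:
        stem = _stem(rng, int(rng.integers(2, 5)))
        convention = str(rng.choice(conventions, p=conv_probs))
        name = make_surname(stem, convention, rng, particle_prob=config.p_particle)
        if name.upper() in used_spellings:
            continue
        placement = str(rng.choice(placements, p=place_probs))
        register(name, "target")
        target_names.append((name, convention, placement))

    reference = SurnameList(name="reference_extract")
    vital_records: list[VitalRecord] = []
    father_only_queue: list[str] = []

    for name, convention, placement in target_names:
        in_reference = placement in ("reference_only", "both")
        in_records = placement in ("records_only", "both")
        record_spelling = name
        if in_records and rng.random() < config.p_variant_spelling:
            variant = _variant_spelling(name, rng)
            if variant.upper() != name.upper():
                record_spelling = variant
                register(variant, "target")
        if in_reference:
            ref_spelling = name
            truncated = False
            if (
                rng.random() < config.p_truncated_in_reference
                and len(ref_spelling) > config.truncation_length
            ):
                ref_spelling = _truncate(ref_spelling, config.truncation_length)
                truncated = True
                register(ref_spelling, "target")
            reference.add(
                SurnameEntry(ref_spelling, source="external", truncated=truncated)
            )
        if in_records:
            if rng.random() < config.p_father_only:
                father_only_queue.append(record_spelling)
                continue
            birthplace: Optional[str] = config.target_birthplace
            if rng.random() < config.p_target_birthplace_missing:
                birthplace = None
            for _ in range(int(rng.integers(1, 3))):
                birth = int(rng.integers(1910, 1990))
                vital_records.append(
                    VitalRecord(
                        surname=record_spelling,
                        birthplace=birthplace,
                        birth_year=birth,
                        death_year=birth + int(rng.integers(20, 90)),
                    )
                )

    # --- non-target inventory (Soundex-disjoint from targets) -------------
    def sample_disjoint(builder, label: str, max_tries: int = 2000) -> str:
        for _ in range(max_tries):
            name = builder()
            key = name.upper()
            if key in used_spellings:
                continue
            if soundex(normalize(name)) in target_codes:
                continue
            register(name, label)
            return name
        raise RuntimeError("could not sample a Soundex-disjoint surname; relax config")

    countries = list(config.birthplace_mix)
    country_probs = [config.birthplace_mix[c] for c in countries]
    other_names: list[str] = []
    for _ in range(config.n_other_surnames):
        name = sample_disjoint(
            lambda: _stem(rng, int(rng.integers(3, 6)))[: int(rng.integers(6, 12))].title(),
            "non_target",
        )
        other_names.append(name)
        country = str(rng.choice(countries, p=country_probs))
        birthplace = None if country == "unknown" else country
        birth = int(rng.integers(1900, 1995))
        vital_records.append(
            VitalRecord(
                surname=name,
                birthplace=birthplace,
                birth_year=birth,
                death_year=birth + int(rng.integers(10, 90)),
            )
        )

    # Traps ride on target-birthplace records; each shape must fall to one
    # of the deletion rules (too_short / no_suffix_and_short).
    def _medium_no_suffix() -> str:
        # 5-8 letters, resampled until no recognized suffix (a random slice
        # can end in "-ov"/"-ova" by chance, which the filter would keep)
        while True:
            name = _stem(rng, 3)[: int(rng.integers(5, 9))].title()
            if suffix_match(name) is None:
                return name

    trap_builders = [
        lambda: _stem(rng, 2)[: int(rng.integers(3, 5))].title(),  # too_short
        _medium_no_suffix,  # no_suffix_and_short
        lambda: (_stem(rng, 1)[0] + "YAN").title(),  # 'Ryan'-style: short despite suffix
    ]
    traps: set[str] = set()
    for i in range(config.n_traps):
        name = sample_disjoint(trap_builders[i % len(trap_builders)], "non_target")
        traps.add(name)
        birth = int(rng.integers(1900, 1995))
        vital_records.append(
            VitalRecord(
                surname=name,
                birthplace=config.target_birthplace,
                birth_year=birth,
                death_year=birth + int(rng.integers(10, 90)),
            )
        )

    # Father-only target names: the record's own surname follows another
    # convention (and is filter-removable); the target spelling appears in
    # the father field only.
    for target_spelling in father_only_queue:
        # host stays under 12 letters and suffix-less so the deletion rules
        # remove it when it surfaces as a birthplace candidate
        host = sample_disjoint(
            lambda: _stem(rng, 3)[: int(rng.integers(6, 9))].title() + "son", "non_target"
        )
        birthplace = config.target_birthplace
        if rng.random() < config.p_target_birthplace_missing:
            birthplace = None
        birth = int(rng.integers(1910, 1990))
        vital_records.append(
            VitalRecord(
                surname=host,
                father_surname=target_spelling,
                birthplace=birthplace,
                birth_year=birth,
                death_year=birth + int(rng.integers(20, 90)),
            )
        )

    # --- registry ----------------------------------------------------------
    membership = ListMembership(
        reference, match_mode="truncation_aware", truncation_length=config.truncation_length
    )
    registry_records: list[RegistryRecord] = []
    for name, _, _ in target_names:
        if rng.random() >= config.p_registry_target:
            continue
        country = config.target_birthplace
        if rng.random() < config.p_target_birthplace_missing:
            country = None
        registry_records.append(
            RegistryRecord(
                surname=name,
                country_of_birth=country,
                on_reference_list=(name in membership),
            )
        )
    for name in other_names:
        if rng.random() >= config.p_registry_other:
            continue
        country = str(rng.choice(countries, p=country_probs))
        registry_records.append(
            RegistryRecord(
                surname=name,
                country_of_birth=None if country == "unknown" else country,
                on_reference_list=(name in membership),
            )
        )

    return SyntheticWorld(
        config=config,
        truth=truth,
        reference_extract=reference,
        vital_records=vital_records,
        registry_records=registry_records,
        trap_surnames=traps,
    )


def score_against_truth(
    built: SurnameList, world: SyntheticWorld
) -> tuple[float, int]:
    """Sensitivity and false-inclusion count of a built list vs world truth.

    Sensitivity is the fraction of target spellings present in any input
    source that the built list captures (truncation-aware, since reference
    spellings may be truncated).  False inclusions are built entries whose
    truth label is not target.
    """
    membership = ListMembership(
        built,
        match_mode="truncation_aware",
        truncation_length=world.config.truncation_length,
    )
    denominator = world.target_spellings_in_sources()
    recovered = sum(1 for name in denominator if name in membership)
    sensitivity = recovered / len(denominator) if denominator else 1.0
    false_inclusions = sum(
        1 for key in built.keys() if world.truth.get(key) != "target"
    )
    return sensitivity, false_inclusions


def write_world(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    """Write reference.txt, deaths.csv, registry.csv and truth.csv to a directory."""
    import csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "reference.txt",
        "deaths": out / "deaths.csv",
        "registry": out / "registry.csv",
        "truth": out / "truth.csv",
    }
    write_surname_list(world.reference_extract, paths["reference"], format="plain")
    with paths["deaths"].open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["surname", "father_surname", "first_name", "sex", "birthplace", "birth_year", "death_year"]
        )
        for r in world.vital_records:
            writer.writerow(
                [
                    r.surname, r.father_surname or "", r.first_name or "", r.sex or "",
                    r.birthplace or "", r.birth_year or "", r.death_year or "",
                ]
            )
    with paths["registry"].open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["surname", "maiden_name", "father_surname", "country_of_birth", "on_reference_list"]
        )
        for r in world.registry_records:
            flag = "" if r.on_reference_list is None else str(r.on_reference_list).lower()
            writer.writerow(
                [r.surname, r.maiden_name or "", r.father_surname or "", r.country_of_birth or "", flag]
            )
    with paths["truth"].open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["surname", "label"])
        for surname in sorted(world.truth):
            writer.writerow([surname, world.truth[surname]])
    return paths
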