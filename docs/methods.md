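# Methods

## Problem setting

Surname lists are a standard identification tool in epidemiology when a
population of interest (here, modelled on Armenian-Americans) is folded
into broader census race categories and self-reported ethnicity is not
available. A list is built from two complementary signals: a pre-existing
reference extract of known surnames, and birthplace recorded on
vital-records files — birthplace in the target country being a strong
proxy for ancestry. Neither signal is complete: the reference extract is
truncated at a fixed character width and frozen in time; birthplace is
missing on some records and absent for descendants born elsewhere. The
toolkit combines both, with explicit provenance on every output entry.

## Normalization and blocking

Surnames are uppercased, diacritics are folded to ASCII (NFKD
decomposition, combining marks dropped), and spaces, hyphens, apostrophes,
periods and digits are removed before any comparison. The letters-only
length (`letters_count`) is the canonical length everywhere, so
punctuation can neither rescue nor doom a name under a length threshold;
the hyphenated worked examples are consistent with either counting
convention, so the simpler rule is used.

Blocking uses **American Soundex** with the rule that letters separated
only by H or W collapse as if adjacent, and with the first letter
participating in digit collapsing (Pfister → P236). The implementation is
verified against published reference vectors (the Robert/R163 family,
Ashcraft/A261, Tymczak/T522, Honeyman/H555, and the classic
Euler/Gauss/Hilbert/Knuth/Lloyd/Lukasiewicz pairs) before anything else
runs. Coding the punctuation-stripped form is a deliberate choice: it
forces hyphen/space/case variants into one block, which the perfect-match
behaviour of `Ter-Minasyan` / `Ter Minasyan` requires.

Soundex reads at most the prefix needed for three digits, so a name
truncated at 10 characters keeps its code whenever the first 10 letters
contain enough codable consonants — this is what lets truncated reference
spellings block together with their full forms.

## Linkage scoring

Industrial probabilistic-linkage tools keep their internal weights
unpublished, so scoring is specified here as an explicit three-tier basis:
exact on normalized forms; truncation-prefix (shorter side ≥ the
10-character truncation width); otherwise Jaro–Winkler similarity
(standard definition; Winkler prefix boost up to 4 characters at scale
0.1, applied above the conventional 0.7 threshold, verified against the
published MARTHA/MARHTA = 0.9611 family of values). Defaults
`match_threshold = 0.95`, `review_low = 0.85`: the band between them is a
review queue exported to CSV for human decisions, and undecided pairs
resolve to non-match — the conservative mirror of a manual-review step
that discards false hits. Truncation matching is symmetric by default
(`asymmetric_truncation` restricts the truncated side to the reference
list). Matching is at the surname-type level, never the person level.
Candidate pairs are ordered by (block code, left, right), which fixes
every downstream ordering.

## Deletion rules for birthplace candidates

Candidates are surnames harvested from target-birthplace records
(including the father-surname field by default — it catches inherited
spellings hidden behind an anglicized family name, e.g. a record
"Danielson" with father "Danielian") minus surnames already linked.
Two rules delete a candidate:

1. fewer than 5 letters (`min_length`);
2. no recognized suffix **and** fewer than 12 letters
   (`long_name_exempt_length`).

Rule 2 is a conjunction over both suffix families: Armenian
(-ian, -yan, -ians, -yans, -iants, -yants) and Russian patronymic
(-ov, -ova), the latter kept because Soviet-era name policy pushed many
families to Russian suffixes. The rules are evaluated in order, visible in
the reason codes: `Ryan` dies as `too_short`, not by suffix. The suffix
test applies to the final token of a compound name, because particles such
as `Ter-` precede the inheritable stem — `Ter-Prakhourany` is tested on
"Prakhourany" (no suffix, but ≥ 12 letters, hence kept). The filter
applies only to birthplace candidates, never to linked or retained
reference surnames.

## Merging and audit

Uniqueness is by uppercased exact spelling with punctuation preserved;
spelling variants are deliberately distinct entries
(`collapse_punctuation_variants` exists as a switch but defaults to off,
consistent with variant retention). Sources partition the output: every
spelling on either side of a match pair is `reference_linked` (the
truncated reference form is emitted alongside the full form by default,
controllable via `emit_truncated_reference`); filter survivors are
`birthplace_added`; unlinked, un-resurfaced reference names are
`reference_retained` and are the only entries that may carry a truncated
spelling. The audit counts satisfy
`n_birthplace_added = n_birthplace_candidates − n_removed_by_filter` and
`n_total_unique = |union|` by construction, and the whole build is
deterministic: fixed inputs and config give byte-identical output files
(writers sort lexicographically by uppercased spelling).

## Evaluation conventions

Contingency tables count unique (surname, stratum) units — a surname
observed under two birthplaces counts once in each stratum — with
percentages within columns. Missing birthplace is an explicit "unknown"
stratum. Membership tests default to exact spelling; `truncation_aware`
mode also accepts a ≥ 10-letter prefix relationship, needed when retained
reference entries are truncated. Country-of-origin ranking is exposed only
as the `OriginRanker` adapter protocol (up to 10 ranked countries per
surname); the bundled `SuffixHeuristicRanker` is plumbing for pipeline
tests and explicitly non-scientific. Venn plotting is out of scope; the
region counts are the deliverable.

## Synthetic worlds

The generator emulates the *structure* of the restricted source files, not
their content. Stems are CV-alternating syllable strings (consonants
`BDGKLMNRSTVZ` — no H/W, which are Soundex-transparent, and no Y — so
every consonant contributes a digit and 10-character truncation is
Soundex-stable by construction); no real-name dictionary ships, and the
handful of real printed surnames appear only inside unit tests.

Defaults, chosen once as the study conditions at desk scale:

| parameter | default | rationale |
|---|---|---|
| `n_target_stems` | 300 | hundreds of names exercise blocking without slowing tests |
| `n_other_surnames` | 300 | comparable background population |
| `n_traps` | 12 | ≥ 4 per trap shape (see below) |
| `convention_mix` | 0.55 Y / 0.25 I / 0.10 russian / 0.10 no-suffix-long | Y-convention dominance among target-birthplace names, a documented default rather than an estimate |
| `placement_mix` | 0.2 reference-only / 0.4 records-only / 0.4 both | all three recovery paths (retained / birthplace-added / linked) get mass |
| `p_truncated_in_reference` | 0.10 | truncation noise level |
| `p_variant_spelling` | 0.10 | ian↔yan and hyphen↔space variants |
| `p_target_birthplace_missing` | 0.05 | realistic low missingness for birthplace on death records |
| `p_father_only` | 0.05 | names reachable only through the father-surname field |
| `truncation_length` | 10 | reference-extract truncation width |

Two structural guarantees replace luck: (a) non-target names are
rejection-sampled to share no Soundex block with any target spelling, so
in the noise-free limit nothing non-target can link and false inclusions
can only arrive through the birthplace query; (b) trap names placed on
target-birthplace records come in exactly the shapes the deletion rules
exist for — 3–4 letter names, 5–8 letter suffix-less names (resampled if a
random slice happens to end in a recognized suffix), and 4-letter "-yan"
coincidences — so only the filter stands between them and the output.
Consequently a noise-free world yields sensitivity 1.0 with zero false
inclusions as a theorem of the construction, and under default noise the
only loss channel is missing birthplace on records-only names
(sensitivity ≈ 0.97–0.99 across seeds, always with zero false
inclusions). These recovery figures are engineering targets of the
generator design, not estimates about any real population.

What the generator does **not** model: demographic realism (ages, causes
of death), marriage-driven surname change beyond the father field,
frequency-weighted name distributions, transliteration drift beyond the
ian/yan swap, and real-world Soundex collisions between target and
non-target names. Passing recovery tests therefore demonstrate the
pipeline's internal correctness, not field performance on real registry
data.

## Numerical and degenerate-input choices

Inputs with no letters raise a degenerate-input error rather than coding
to a dummy block. Empty lists and empty record files build successfully
with zeroed audits and a warning. Jaccard and percentage denominators of
zero are reported as undefined (`None`/NaN) instead of zero, so a missing
denominator is never mistaken for a measured zero. All randomness flows
from one integer seed through a single `numpy` generator; no iteration
order depends on hashing.

## Known limitations

Scoring is single-field (surname only) with fixed thresholds — no
EM-estimated agreement weights and no multi-field comparators; the
review-band policy is a configurable stand-in for an unpublished manual
rule set. The suffix inventory is fixed at the two families above, so
target names with rarer suffixes below 12 letters are deleted, exactly as
the rules dictate. Evaluation treats birthplace as proxy truth; the
toolkit cannot assess ancestry misclassification that a gold standard
would reveal.
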