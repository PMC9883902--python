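# surnamekit

A toolkit for constructing and evaluating **ethnicity surname lists** from
administrative data: a reference surname extract is linked against
vital-records surnames with Soundex-blocked matching, additional surnames
are harvested from records with a target birthplace and pruned by
suffix/length deletion rules, and the merged list — every entry carrying
its provenance — is evaluated against registry-style records.

It is aimed at epidemiologists and registry analysts who identify study
populations (for example, Armenian-Americans in cancer-registry data) by
surname when self-reported ethnicity is not collected. The real source
files such lists are built from are access-restricted, so the package also
ships a ground-truth-labelled synthetic data generator that emulates their
structure — surname morphology (stems plus the -ian/-yan/-ians/-yans/
-iants/-yants and -ov/-ova suffix conventions), fixed-width truncation,
hyphen/space/case spelling variants, and missing birthplace — making every
stage testable at desk scale.

## Method

**Step 1 — phonetically blocked linkage.** Surnames are normalized
(uppercased, punctuation and diacritics stripped) and blocked by American
Soundex, the classic letter-plus-three-digits phonetic code. Candidate
pairs within a block are scored on three tiers:

* *exact_normalized* — normalized forms are equal (score 1; this is how
  `Ter-Minasyan` / `Ter Minasyan` is a perfect match);
* *truncation_prefix* — one form is a proper prefix of the other and the
  shorter has at least 10 letters, the width reference extracts are
  truncated at (`Haroutunia` / `Haroutunian`);
* *similarity* — Jaro–Winkler on the normalized forms, thresholded into
  match (≥ 0.95), review (≥ 0.85) or non-match. Review pairs round-trip
  through a CSV for manual decisions; undecided pairs default to
  non-match.

Both spellings of a matched variant pair (`Mahtesyan` / `Mahtesian`) enter
the output list as distinct entries.

**Step 2 — birthplace-derived additions.** Surnames appearing on records
with the target birthplace that did not link in Step 1 become candidates.
A candidate is **deleted** when it (1) has fewer than 5 letters, or
(2) carries none of the recognized patronymic suffixes (-ian/-yan families
or Russian -ov/-ova) *and* has fewer than 12 letters. Everything else is
kept; reference surnames that neither linked nor resurfaced are retained
verbatim. An audit object records the count at every box of the flow.

**Evaluation.** Set overlaps (pairwise and three-way Venn regions),
coverage gain over a baseline list within a proxy-truth surname set, a
list-membership × birthplace-stratum contingency table with column
percentages, and suffix-convention distributions (I-convention /
Y-convention / Russian / other).

## Worked example

```python
from surnamekit import SurnameList, VitalRecord, build_list, decide

for name in ["Smith", "Abad", "Ryan", "Weatherford", "Hambartsumanz", "Ter-Prakhourany"]:
    d = decide(name)
    print(f"{name:16s} keep={d.keep!s:5s} reason={d.reason}")

reference = SurnameList.from_names(["Mahtesyan", "Haroutunia", "Ter-Galoustian"])
records = [
    VitalRecord("Mahtesian", birthplace="United States"),
    VitalRecord("Haroutunian", birthplace="Armenia"),
    VitalRecord("Karapetyan", birthplace="Armenia"),
    VitalRecord("Ryan", birthplace="Armenia"),
]
built, audit, _, _ = build_list(reference, records)
for e in built.sorted_entries():
    print(f"{e.surname:14s} {e.source}")
print(audit.as_dict())
```

prints

```
Smith            keep=False reason=no_suffix_and_short
Abad             keep=False reason=too_short
Ryan             keep=False reason=too_short
Weatherford      keep=False reason=no_suffix_and_short
Hambartsumanz    keep=True  reason=kept_long
Ter-Prakhourany  keep=True  reason=kept_long
Haroutunia     reference_linked
Haroutunian    reference_linked
Karapetyan     birthplace_added
Mahtesian      reference_linked
Mahtesyan      reference_linked
Ter-Galoustian reference_retained
{'n_reference_input': 3, 'n_linked': 4, 'n_birthplace_candidates': 2, 'n_removed_by_filter': 1, 'n_birthplace_added': 1, 'n_reference_retained': 1, 'n_total_unique': 6}
```

Note `Ryan` is deleted by the length rule despite its "-yan" ending, the
truncated `Haroutunia` links to its full form with both spellings
retained, and `Ter-Galoustian` — absent from the records — is retained
from the reference list.

The same pipeline is available from the shell:

```
surnamekit simulate --config cfg.yaml --out-dir fixtures/
surnamekit build    --config cfg.yaml --reference fixtures/reference.txt \
                    --records fixtures/deaths.csv --out asl.csv --audit audit.json
surnamekit evaluate --config cfg.yaml --list asl.csv --baseline fixtures/reference.txt \
                    --records fixtures/registry.csv --out report.json
```

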