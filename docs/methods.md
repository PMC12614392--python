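# Methods

## The harmonization model

A raw record is one child's survey response: a set of checked boxes drawn
from the base categories plus "other race" and (in some instruments) a
multiracial checkbox; zero or more free-text "please specify" write-ins; and,
for separate-question instruments, a Hispanic/Latino yes/no item. The engine
produces one `Allocation` per record with two classifications:

**Original category** (checkboxes only, write-ins ignored):

| rule | condition | outcome |
|------|-----------|---------|
| O1 | nothing checked, no affirmative Hispanic flag | Missing |
| O2 | multiracial box, or ≥2 base boxes, or Hispanic flag + base box | Multiracial |
| O3 | exactly one base box | that category |
| O4 | Hispanic flag, no base box (race blank or "other race" only) | Hispanic |
| O5 | "other race" checked alone | Other race |

This split matters: the original classification is what conventional
checkbox-only processing would report, so the original-vs-reallocated
cross-tabulation isolates exactly the information carried by write-ins.

**Reallocated category**: the indicator pool is
P = (checked base categories) ∪ (crosswalked write-in codes) ∪ ({Hispanic}
when the flag or checkbox is affirmative). Hispanic/Latino is an indicator on
equal footing with the race codes, which unifies combined-question checkboxes
with separate-question flags; a "no" answer to the ethnicity item asserts no
identity and contributes nothing.

| rule | condition | outcome |
|------|-----------|---------|
| R1 | no boxes, no write-ins, no Hispanic assertion | Missing |
| R2 | multiracial box, P = ∅ | Other race |
| R3 | P = ∅ but something was answered ("other race" box and/or unmappable write-ins) | Other race |
| R4 | \|P\| ≥ 2 | Multiracial, indicators P |
| R5 | \|P\| = 1 | that category |

Consequences worth spelling out: "other race" + "German" → White; the
multiracial checkbox without written detail → Other race (no indicators are
constructible); a base checkbox plus a distinct-category write-in →
Multiracial; a write-in that duplicates the checked box is absorbed (the pool
is a set), so such records never move. An unmapped write-in next to a valid
checkbox leaves the checkbox category intact and is logged — no response
pattern demotes a classified child to Other race. Rule identifiers are stable
strings in each allocation's `rule_trace`.

The invariant enforced on every output: Multiracial ⇔ |indicators| ≥ 2; a
single-category outcome carries exactly its own indicator; Other/Missing
carry none.

### Design choices that were genuinely open

- **Multiracial box + exactly one mapped write-in collapses to that single
  category (R5).** This loses the child's asserted multiracial identity,
  which is a real drawback; `preserve_multiracial_checkbox=True` (CLI
  `--preserve-multiracial-checkbox`) instead keeps such records Multiracial
  via rule `R5M`, retaining the one known indicator. The strict cardinality
  invariant is relaxed only for R5M-traced records, and only under the flag.
- **No-box records whose write-ins are all unmappable** are routed to Other
  race by R3, not Missing: an unmappable written response is still a
  response. (Such records do not occur in the packaged worked example.)
- **Exact-match crosswalk only.** Normalization is lowercasing, NFKD
  diacritic stripping, punctuation removal, and whitespace collapsing —
  idempotent by construction. Tokenization splits on the word-bounded
  connectors "and", "&", "/", ",", ";" and treats parenthetical annotations
  ("French (White)") as additional terms. No edit-distance matching: the
  dictionary is a consensus artifact and fuzzy hits would be unauditable.
- **Tribe names.** Any federally recognized tribe maps to AIAN; the shipped
  dictionary carries a small illustrative tribe list (Cherokee, Navajo,
  Sioux, Chippewa, Choctaw, Apache). Deployments should extend the mapping
  file (`term,code[,provenance]` CSV) with an authoritative list; `mapping
  lint` checks normalization-closure and code validity.
- **"Asian or Pacific Islander" as a single checkbox** (some instruments):
  the schema's `checkbox_map` may bind such a label to either pooled member;
  since the two codes pool into one reporting group, the 7-level analysis is
  unaffected. The packaged schemas use distinct Asian and NHPI boxes.
- **MENA** is registrable as a base category (`Taxonomy.with_mena()`) but
  absent from the default: the pooled data predate the 2024 revision, so
  MENA write-ins ("Lebanese", "Egyptian") map to White per the pre-2024
  federal definition.

## Reporting

The cross-tabulation, flows, and chi-square use the pooled 7-level outcome
set (White, Black, Hispanic, Asian or NHPI, AIAN, Multiracial, Other race).
Missing records are excluded from the table and the test — the published
margins total 7530 classified children, not 8087 — and are reported
separately; nonresponse is never folded into a category, because blanks are
plausibly nonrandom.

Chi-square is Pearson's Σ(O−E)²/E with expected counts from the margins,
df = (r−1)(c−1), no continuity correction and no small-cell simulation; the
p-value is a chi-square survival function displayed with a "<.001" cap. The
summary reports the statistic both at full precision (37044.05 on the worked
example) and rounded to two significant figures (37000), matching how such
statistics are conventionally printed. Percent changes are
100·(after−before)/before rounded half-up to two decimals. Combination
counts within the reallocated-multiracial group sort count-descending with
ties broken by canonical identity order (White, Black, Hispanic, Asian,
NHPI, AIAN), alongside a boolean membership matrix ready for UpSet
rendering; graphics themselves are out of scope.

Two published percentages are arithmetically inconsistent with their own
counts (+7.42% for 1482→1594, −9.5% for 732→665; the definitions give +7.56%
and −9.15%), and a printed "7277 remained" disagrees with the table diagonal
(7227). The package implements the arithmetic definitions and anchors to the
table.

## The worked-example fixture

`build_pooled_fixture` reconstructs the pooled eight-study dataset (8087
children, studies A–H with the published per-study sizes) as *raw survey
responses*, not allocations: every cell of the published cross-tabulation is
realized by a checkbox/write-in pattern licensed by the study narrative
(other→Black cells use the "other race" box plus a Black-mapped term;
multiracial→Other cells use the multiracial box with no write-in;
Hispanic→Multiracial cells pair the Hispanic box with a distinct-category
write-in; and so on — `fixture_manifest()` lists every pattern choice with
counts). The engine must therefore route each pattern correctly for the
table to emerge; the fixture tests logic, not bookkeeping.

Studies A and B are separate-question instruments carrying the published
structure: 1431 children, 735 identified Hispanic/Latino, 491 of those with
no usable race response. Studies G and H (the earliest) offer the
multiracial checkbox. Cell patterns the narrative leaves open use the
simplest licensed realization (e.g. the single White→Multiracial child is a
White box plus a written tribe name). Within the 665 multiracial children,
the three published combination counts (269, 169, 86) are pinned; the
remaining 141 children are spread over a fixed list of further combinations
chosen to realize the published structure — 22 distinct combinations in all,
AIAN present in 13 of them and held by 81 children. The spread is fixed
rather than randomized so that structure is exact; the build seed shuffles
record order only. Per-study composition beyond the printed constraints is
synthetic and documented in the manifest.

## The simulator

`simulate_survey` draws independent records under explicit parameters:
single-category weights (default: White plurality, substantial Black and
Hispanic groups), other-box rate 0.04, multiracial-box rate 0.09, write-in
probability 0.30 over a small term vocabulary, missingness 0.07, and an 18%
share of separate-question records — defaults mirroring a pooled
community-based child sample. It emulates checkbox/write-in/flag mechanics
only: no within-family correlation, no study-level clustering, no response
drift over time, and a vocabulary far smaller than a real deployment's
(real pooled data produced 101 distinct written responses). Passing tests on
simulated data therefore demonstrate the engine's routing and bookkeeping,
not population realism.

## Numerical and degenerate-input choices

- Zero margins raise a degenerate-table error before the chi-square; an
  all-missing batch raises an empty-input error at cross-tabulation.
- Percent change from a zero baseline is an error, not ±inf.
- Rounding is decimal half-up (two decimals for percents; significant-figure
  rounding for the headline statistic), so printed values are
  platform-independent.
- All text I/O is UTF-8; write-ins may contain any letters, and diacritics
  are stripped only inside the normalizer.

## Limitations

- The crosswalk inherits the federal definitions' politics: Brazilians,
  and other groups the definitions exclude, remain unmappable by design and
  are surfaced in the unmapped-term log rather than forced into a category.
- No imputation of missing race/ethnicity and no probabilistic
  (surname/geocode) classification; the package harmonizes what parents
  reported, only.
- The default R5 collapse of multiracial-box + single write-in erases a
  multiracial self-identification; see the preserve flag above.
- The fixture reproduces the published tables exactly but is still a
  reconstruction: within-cell pattern choices and per-study composition
  beyond the printed constraints are synthetic.
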