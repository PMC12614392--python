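# ombcrosswalk

Harmonization of parent-reported child race and ethnicity survey data into
US federal (OMB Directive 15) categories.

Pediatric health studies collect child race/ethnicity through heterogeneous
demographic surveys: closed-ended checkboxes, an ambiguous "other race"
option, sometimes a dedicated multiracial checkbox, a separate Hispanic/Latino
ethnicity item in some instruments, and open-ended "please specify" write-in
fields. Pooling such studies — and tracking outcomes across racial and ethnic
groups at all — requires a *replicable* procedure for mapping every response
pattern onto the federal minimum categories. Ad hoc recoding systematically
misclassifies exactly the groups most affected by racism: children written in
as "Haitian" or "Cape Verdean" under an "other race" checkbox, multiracial
children collapsed into a residual category, Hispanic children whose race
item was left blank.

`ombcrosswalk` implements that procedure as an auditable library and CLI for
epidemiologists and survey methodologists:

- **Taxonomy** — the six federal base identities (White; Black or African
  American; Hispanic or Latino; Asian; NHPI; AIAN) plus three derived
  outcomes (Multiracial, Other race, Missing), with Asian/NHPI pooled only at
  the reporting layer and a MENA extension point for the 2024 revision.
- **Write-in crosswalk** — exact-match lookup of normalized ethnonyms against
  a curated dictionary (no fuzzy matching; unknown terms are logged for
  curator review, never silently guessed).
- **Two-stage decision cascade** — an *original* classification from
  categorical responses alone, then a *reallocation* that builds an indicator
  set I ⊆ {W, B, H, A, N, AI} per child from checkboxes, crosswalked
  write-ins, and the Hispanic item, and routes on its cardinality:
  |I| ≥ 2 → Multiracial, |I| = 1 → that category, |I| = 0 → Other race (if
  anything was answered) or Missing. Every allocation carries a stable rule
  trace (`O1`–`O5`, `R1`–`R5`) for audit diffs.
- **Reporting** — original-vs-reallocated cross-tabulation with margins, flow
  counts between categories, signed percent changes, Pearson chi-square
  (χ² = Σ(O−E)²/E, df = (r−1)(c−1), no continuity correction), and
  disaggregation of the multiracial group into identity combinations with an
  UpSet-ready membership matrix.
- **Fixtures** — a deterministic reconstruction of a pooled eight-study
  worked example (8087 children) from its published cross-tabulation, plus a
  randomized survey simulator for property testing.

## Worked example

```
ombcrosswalk fixture   --out fix --seed 1
ombcrosswalk harmonize --input fix/records.csv --schema fix/schemas.yaml --out out
ombcrosswalk report    --input out
```

prints

```
wrote 8087 records to fix/records.csv
303 of 7530 non-missing records reallocated (4.02%)
records: 8087 (missing 557)
reallocated: 303/7530 (4.02%)
chi-square: 37044.05 (2 s.f. 37000), df=36, p <.001
multiracial combination WHITE+HISPANIC: 269
multiracial combination WHITE+BLACK: 169
multiracial combination BLACK+HISPANIC: 86
```

Of 8087 pooled records, 557 children have no usable response; of the 7530
classified children, 303 (4.02%) end up in a different category than their
parent's checkbox behavior alone would give — e.g. an "other race" checkbox
with "Haitian" written moves to Black, and a Hispanic checkbox with "White
and Black" written becomes Multiracial with indicators {Hispanic, White,
Black}. The chi-square tests association between original and reallocated
categories on the 7×7 pooled table. Within the 665 reallocated-multiracial
children, the three most common identity combinations are White+Hispanic
(269), White+Black (169), and Black+Hispanic (86).

The same pipeline is available as a library:

```python
from ombcrosswalk import (build_pooled_fixture, pooled_schemas,
                          default_mapping_table, batch_harmonize, crosstab)

allocs = batch_harmonize(build_pooled_fixture(seed=1), pooled_schemas(),
                         default_mapping_table())
print(crosstab(allocs).to_frame())
```

Per-record audit output lands in `out/allocations.csv` and `out/audit.log`
(every moved record's rule trace, greppable); `out/summary.json` holds all
counts, flows, percent changes, chi-square and combination counts in one
machine-readable object.

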