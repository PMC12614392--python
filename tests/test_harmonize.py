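"""The two-stage decision cascade, including brute-force oracle equivalence."""

import itertools

import pytest

from ombcrosswalk import (
    AIAN,
    ASIAN,
    BLACK,
    HISPANIC,
    MISSING,
    MULTIRACIAL,
    NHPI,
    OTHER,
    UNMAPPED,
    WHITE,
    RawRecord,
    SurveySchema,
    batch_harmonize,
    default_taxonomy,
    derive_original,
    reallocate,
)
from ombcrosswalk.harmonize import BatchError
from ombcrosswalk.taxonomy import FLAG_MISSING, FLAG_NO, FLAG_YES, validate_allocation
from ombcrosswalk.writeins import MappingTable

BASES = (WHITE, BLACK, HISPANIC, ASIAN, NHPI, AIAN)

COMBINED = SurveySchema(
    schema_id="C",
    ethnicity_mode="combined",
    has_multiracial_checkbox=True,
    checkbox_map={c: c for c in BASES + (OTHER, MULTIRACIAL)},
)
SEPARATE = SurveySchema(
    schema_id="S",
    ethnicity_mode="separate",
    has_multiracial_checkbox=False,
    checkbox_map={c: c for c in (WHITE, BLACK, ASIAN, NHPI, AIAN, OTHER)},
)

# Ten-term vocabulary used for the exhaustive oracle sweep.
VOCAB = {
    "haitian": BLACK,
    "german": WHITE,
    "cherokee": AIAN,
    "japanese": ASIAN,
    "hawaiian": NHPI,
    "mexican": HISPANIC,
    "white": WHITE,
    "black": BLACK,
    "brazilian": UNMAPPED,
    "mixed": UNMAPPED,
}
TABLE = MappingTable(entries=VOCAB)


def rec(checked=(), writeins=(), flag=FLAG_MISSING, schema=COMBINED, rid="r"):
    return RawRecord(rid, schema.schema_id, frozenset(checked), tuple(writeins), flag)


# ---------------------------------------------------------------------------
# Original (checkbox-only) classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "checked, flag, schema, expected",
    [
        ((WHITE,), FLAG_MISSING, COMBINED, WHITE),
        ((MULTIRACIAL,), FLAG_MISSING, COMBINED, MULTIRACIAL),
        ((WHITE, BLACK), FLAG_MISSING, COMBINED, MULTIRACIAL),
        ((), FLAG_YES, SEPARATE, HISPANIC),          # ethnicity yes, race blank
        ((OTHER,), FLAG_YES, SEPARATE, HISPANIC),    # ethnicity yes, other box
        ((WHITE,), FLAG_YES, SEPARATE, MULTIRACIAL), # ethnicity yes + race box
        ((OTHER,), FLAG_MISSING, COMBINED, OTHER),
        ((), FLAG_MISSING, COMBINED, MISSING),
        ((), FLAG_NO, SEPARATE, MISSING),
        ((HISPANIC,), FLAG_MISSING, COMBINED, HISPANIC),
    ],
)
def test_derive_original(checked, flag, schema, expected):
    assert derive_original(rec(checked, flag=flag, schema=schema), schema) == expected


def test_derive_original_ignores_writeins():
    """Write-ins never affect the original categorical classification."""
    r = rec((OTHER,), ("German",))
    assert derive_original(r, COMBINED) == OTHER


# ---------------------------------------------------------------------------
# Reallocation cascade
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "checked, writeins, flag, schema, expected_cat, expected_inds",
    [
        # other box + one mapped term -> that category
        ((OTHER,), ("german",), FLAG_MISSING, COMBINED, WHITE, {WHITE}),
        # multiracial box, no detail -> no indicators constructible -> other
        ((MULTIRACIAL,), (), FLAG_MISSING, COMBINED, OTHER, set()),
        # Hispanic box + "white and black" -> three indicators
        ((HISPANIC,), ("white and black",), FLAG_MISSING, COMBINED,
         MULTIRACIAL, {HISPANIC, WHITE, BLACK}),
        # other box + two distinct mapped terms -> multiracial
        ((OTHER,), ("german", "japanese"), FLAG_MISSING, COMBINED,
         MULTIRACIAL, {WHITE, ASIAN}),
        # base box + distinct-category term -> multiracial
        ((BLACK,), ("cherokee",), FLAG_MISSING, COMBINED, MULTIRACIAL, {BLACK, AIAN}),
        # multiracial box + single term collapses to that category
        ((MULTIRACIAL,), ("german",), FLAG_MISSING, COMBINED, WHITE, {WHITE}),
        # identity: single box, no write-in
        ((WHITE,), (), FLAG_MISSING, COMBINED, WHITE, {WHITE}),
        # write-in duplicating the box is deduplicated, record stays put
        ((WHITE,), ("german",), FLAG_MISSING, COMBINED, WHITE, {WHITE}),
        # unmapped write-in leaves the checkbox category intact
        ((WHITE,), ("brazilian",), FLAG_MISSING, COMBINED, WHITE, {WHITE}),
        # other box + unmapped write-in stays other
        ((OTHER,), ("brazilian",), FLAG_MISSING, COMBINED, OTHER, set()),
        # separate-question Hispanic alone
        ((), (), FLAG_YES, SEPARATE, HISPANIC, {HISPANIC}),
        # ethnicity yes + race box -> multiracial
        ((WHITE,), (), FLAG_YES, SEPARATE, MULTIRACIAL, {WHITE, HISPANIC}),
        # fully blank -> missing
        ((), (), FLAG_MISSING, COMBINED, MISSING, set()),
    ],
)
def test_reallocate_cases(checked, writeins, flag, schema, expected_cat, expected_inds):
    alloc = reallocate(rec(checked, writeins, flag, schema), schema, TABLE)
    assert alloc.reallocated_category == expected_cat
    assert set(alloc.indicators) == expected_inds
    assert alloc.rule_trace  # audit trail always populated


def test_unmapped_terms_recorded():
    alloc = reallocate(rec((OTHER,), ("Brazilian", "German")), COMBINED, TABLE)
    assert alloc.reallocated_category == WHITE
    assert alloc.unmapped_terms == ("brazilian",)


def test_hispanic_flag_no_contributes_nothing():
    alloc = reallocate(rec((WHITE,), flag=FLAG_NO, schema=SEPARATE), SEPARATE, TABLE)
    assert alloc.reallocated_category == WHITE
    assert HISPANIC not in alloc.indicators


def test_preserve_multiracial_checkbox_flag():
    r = rec((MULTIRACIAL,), ("german",))
    default = reallocate(r, COMBINED, TABLE)
    preserved = reallocate(r, COMBINED, TABLE, preserve_multiracial_checkbox=True)
    assert default.reallocated_category == WHITE
    assert preserved.reallocated_category == MULTIRACIAL
    assert "R5M" in preserved.rule_trace


def test_order_invariance_of_inputs():
    a = reallocate(rec((WHITE, BLACK), ("cherokee", "japanese")), COMBINED, TABLE)
    b = reallocate(rec((BLACK, WHITE), ("japanese", "cherokee")), COMBINED, TABLE)
    assert a.reallocated_category == b.reallocated_category
    assert a.indicators == b.indicators


def test_stability_of_unambiguous_records():
    """A single-category record whose write-ins agree is never moved."""
    for writeins in ((), ("german",)):
        alloc = reallocate(rec((WHITE,), writeins), COMBINED, TABLE)
        assert alloc.original_category == alloc.reallocated_category == WHITE


def test_batch_preserves_order_and_purity():
    recs = [rec((WHITE,), rid="a"), rec((OTHER,), ("haitian",), rid="b")]
    out = batch_harmonize(recs, {"C": COMBINED}, TABLE)
    assert [a.record_id for a in out] == ["a", "b"]
    twins = batch_harmonize(
        [rec((WHITE,), rid="x"), rec((WHITE,), rid="y")], {"C": COMBINED}, TABLE
    )
    assert twins[0].reallocated_category == twins[1].reallocated_category
    assert twins[0].indicators == twins[1].indicators


def test_batch_empty():
    assert batch_harmonize([], {}, TABLE) == []


def test_batch_rejects_duplicate_ids():
    with pytest.raises(BatchError, match="duplicate"):
        batch_harmonize([rec(rid="a"), rec(rid="a")], {"C": COMBINED}, TABLE)


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence
# ---------------------------------------------------------------------------

def oracle_outcome(checked, writeins, flag, mode):
    """Independent reference: classify by explicit case enumeration.

    Works from counted features (number of base identities asserted, whether
    any response at all was given), not from the rule cascade.
    """
    asserted = set()
    for box in checked:
        if box in BASES:
            asserted.add(box)
    for text in writeins:
        for raw in text.replace(",", " , ").split(" , "):
            code = VOCAB.get(raw.strip().lower(), UNMAPPED)
            if code != UNMAPPED:
                asserted.add(code)
    if HISPANIC in checked or (mode == "separate" and flag == FLAG_YES):
        asserted.add(HISPANIC)

    responded = bool(checked) or bool(writeins) or (
        mode == "separate" and flag == FLAG_YES
    )
    if not responded:
        return MISSING, frozenset()
    if len(asserted) == 0:
        return OTHER, frozenset()
    if len(asserted) == 1:
        only = next(iter(asserted))
        return only, frozenset({only})
    return MULTIRACIAL, frozenset(asserted)


def test_cascade_matches_bruteforce_oracle_exhaustively():
    """Exhaustive sweep: every record with <=2 checkboxes and <=2 write-in
    terms from a 10-term vocabulary routes identically under the rule cascade
    and the case-enumeration oracle."""
    boxes = BASES + (OTHER, MULTIRACIAL)
    box_subsets = [()] + [(b,) for b in boxes] + list(itertools.combinations(boxes, 2))
    terms = list(VOCAB)
    writein_lists = [()] + [(t,) for t in terms] + list(itertools.product(terms, repeat=2))
    taxonomy = default_taxonomy()
    checked_count = 0
    for checked in box_subsets:
        for writeins in writein_lists:
            for schema in (COMBINED, SEPARATE):
                flags = (FLAG_MISSING,) if schema is COMBINED else (FLAG_YES, FLAG_NO, FLAG_MISSING)
                for flag in flags:
                    if schema is SEPARATE and (
                        HISPANIC in checked or MULTIRACIAL in checked
                    ):
                        continue  # not expressible on a separate-question survey
                    r = rec(checked, writeins, flag, schema)
                    alloc = reallocate(r, schema, TABLE)
                    expect_cat, expect_inds = oracle_outcome(
                        checked, writeins, flag, schema.ethnicity_mode
                    )
                    assert alloc.reallocated_category == expect_cat, (checked, writeins, flag)
                    assert alloc.indicators == expect_inds, (checked, writeins, flag)
                    validate_allocation(alloc, taxonomy)
                    checked_count += 1
    # 37 checkbox subsets x 111 write-in lists x schema/flag states, minus
    # states inexpressible on a separate-question survey
    assert checked_count == 11433
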