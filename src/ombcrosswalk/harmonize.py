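"""The two-stage decision cascade that harmonizes raw survey responses.

Stage 1 (:func:`derive_original`) classifies a record from its *categorical*
responses alone — checkboxes plus, for separate-question schemas, the
Hispanic-ethnicity yes/no item.  Write-ins are ignored at this stage; this is
the category the parent's checkbox behavior puts the child in.

Stage 2 (:func:`reallocate`) builds the child's indicator set by combining
checked base categories, crosswalked write-in terms, and the Hispanic flag,
and routes the record through ordered rules R1–R5.  Hispanic/Latino is an
indicator on equal footing with the race codes, so a Hispanic flag plus one
race checkbox yields a multiracial outcome.

Rule identifiers (O1–O5, R1–R5, plus R5M for the optional
preserve-multiracial-checkbox behavior) are stable strings recorded in each
allocation's ``rule_trace`` so audit logs diff cleanly across runs.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .taxonomy import (
    FLAG_YES,
    HISPANIC,
    MISSING,
    MULTIRACIAL,
    OTHER,
    Allocation,
    RawRecord,
    SurveySchema,
    Taxonomy,
    default_taxonomy,
    validate_allocation,
    validate_record,
)
from .writeins import MappingTable, resolve_writeins


class RecordValidationError(ValueError):
    """A record violated its schema's invariants."""


class BatchError(ValueError):
    """A batch-level problem (duplicate ids, unknown schemas)."""


def _base_checked(record: RawRecord, taxonomy: Taxonomy) -> set[str]:
    return {c for c in record.checked if taxonomy.is_base(c)}


def derive_original(
    record: RawRecord, schema: SurveySchema, taxonomy: Taxonomy | None = None
) -> str:
    """Original categorical classification; uses checkboxes (and the Hispanic
    flag in separate mode) only, never write-ins.

    Rules, in order:

    * O1 — nothing checked and no affirmative Hispanic flag: MISSING.
    * O2 — multiracial checkbox, or two or more base checkboxes, or
      (separate mode) Hispanic flag plus at least one base checkbox:
      MULTIRACIAL.
    * O3 — exactly one base checkbox: that category.
    * O4 — separate mode, Hispanic flag, no base checkbox (the race question
      was left blank or only "other race" was checked): HISPANIC.
    * O5 — "other race" checked alone: OTHER.
    """
    taxonomy = taxonomy or default_taxonomy()
    bases = _base_checked(record, taxonomy)
    separate = schema.ethnicity_mode == "separate"
    flag_yes = separate and record.hispanic_flag == FLAG_YES

    if not record.checked and not flag_yes:
        return MISSING  # O1
    if MULTIRACIAL in record.checked or len(bases) >= 2 or (flag_yes and bases):
        return MULTIRACIAL  # O2
    if len(bases) == 1:
        return next(iter(bases))  # O3
    if flag_yes and not bases:
        return HISPANIC  # O4
    return OTHER  # O5: OTHER checked alone


def _original_rule_id(record: RawRecord, schema: SurveySchema, taxonomy: Taxonomy) -> str:
    bases = _base_checked(record, taxonomy)
    separate = schema.ethnicity_mode == "separate"
    flag_yes = separate and record.hispanic_flag == FLAG_YES
    if not record.checked and not flag_yes:
        return "O1"
    if MULTIRACIAL in record.checked or len(bases) >= 2 or (flag_yes and bases):
        return "O2"
    if len(bases) == 1:
        return "O3"
    if flag_yes and not bases:
        return "O4"
    return "O5"


def reallocate(
    record: RawRecord,
    schema: SurveySchema,
    table: MappingTable,
    taxonomy: Taxonomy | None = None,
    *,
    preserve_multiracial_checkbox: bool = False,
    validate: bool = True,
) -> Allocation:
    """Run the full cascade on one record and return a traced Allocation.

    The indicator pool P is the union of checked base categories, base codes
    resolved from write-ins, and {Hispanic} when the Hispanic flag or checkbox
    is affirmative.  Routing:

    * R1 — no checkboxes, no write-ins, no Hispanic assertion: MISSING.
    * R2 — multiracial checkbox but P is empty (no written detail from which
      to build indicators): OTHER.
    * R3 — "other race" checked (or only unmappable write-ins provided) and P
      empty: OTHER.
    * R4 — |P| >= 2: MULTIRACIAL with indicators P.
    * R5 — |P| = 1: that single base category.  With
      ``preserve_multiracial_checkbox=True``, a checked multiracial box keeps
      the record MULTIRACIAL instead (rule R5M), retaining the one known
      indicator.

    Unmapped write-in terms are recorded on the allocation and never affect
    routing except by leaving P empty (R2/R3).
    """
    taxonomy = taxonomy or default_taxonomy()
    if validate:
        problems = validate_record(record, schema, taxonomy)
        if problems:
            raise RecordValidationError("; ".join(problems))

    codes, unmapped = resolve_writeins(record.writeins, table)
    bases = _base_checked(record, taxonomy)
    separate = schema.ethnicity_mode == "separate"
    hisp = {HISPANIC} if (separate and record.hispanic_flag == FLAG_YES) or HISPANIC in record.checked else set()
    pool = bases | codes | hisp

    original = derive_original(record, schema, taxonomy)
    trace = [_original_rule_id(record, schema, taxonomy)]

    if not record.checked and not record.writeins and not hisp:
        outcome, indicators = MISSING, frozenset()
        trace.append("R1")
    elif MULTIRACIAL in record.checked and not pool:
        outcome, indicators = OTHER, frozenset()
        trace.append("R2")
    elif not pool and (OTHER in record.checked or record.writeins):
        outcome, indicators = OTHER, frozenset()
        trace.append("R3")
    elif len(pool) >= 2:
        outcome, indicators = MULTIRACIAL, frozenset(pool)
        trace.append("R4")
    elif preserve_multiracial_checkbox and MULTIRACIAL in record.checked:
        outcome, indicators = MULTIRACIAL, frozenset(pool)
        trace.append("R5M")
    else:
        outcome, indicators = next(iter(pool)), frozenset(pool)
        trace.append("R5")

    alloc = Allocation(
        record_id=record.record_id,
        original_category=original,
        reallocated_category=outcome,
        indicators=indicators,
        rule_trace=tuple(trace),
        unmapped_terms=tuple(unmapped),
    )
    validate_allocation(alloc, taxonomy, preserve_multiracial=preserve_multiracial_checkbox)
    return alloc


def batch_harmonize(
    records: Sequence[RawRecord],
    schemas: Mapping[str, SurveySchema],
    table: MappingTable,
    taxonomy: Taxonomy | None = None,
    *,
    preserve_multiracial_checkbox: bool = False,
) -> list[Allocation]:
    """Harmonize a batch; one Allocation per record, input order preserved."""
    taxonomy = taxonomy or default_taxonomy()
    seen: set[str] = set()
    dupes = []
    for rec in records:
        if rec.record_id in seen:
            dupes.append(rec.record_id)
        seen.add(rec.record_id)
    if dupes:
        raise BatchError(f"duplicate record_ids: {sorted(set(dupes))}")
    missing_schemas = sorted({r.schema_id for r in records} - set(schemas))
    if missing_schemas:
        raise BatchError(f"unknown schema_ids: {missing_schemas}")
    return [
        reallocate(
            rec,
            schemas[rec.schema_id],
            table,
            taxonomy,
            preserve_multiracial_checkbox=preserve_multiracial_checkbox,
        )
        for rec in records
    ]
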