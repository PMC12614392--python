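"""Tabular readers/writers and the end-to-end pipeline.

Two input dialects are supported.  The *canonical* dialect is what
:func:`write_records` emits: one row per child with ``record_id``,
``schema_id``, pipe-joined ``checked`` codes, pipe-joined ``writeins`` and
``hispanic_flag``.  The *mapped* dialect ingests a study's own export: a
layout config declares, per schema, which columns are checkboxes (and which
cell values count as checked), which hold write-ins, and which holds the
Hispanic-ethnicity item.  Encoding is UTF-8 throughout; input files are never
mutated.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .harmonize import batch_harmonize
from .report import combinations, crosstab, flows, summarize
from .taxonomy import (
    FLAG_MISSING,
    FLAG_NO,
    FLAG_YES,
    Allocation,
    RawRecord,
    SurveySchema,
    Taxonomy,
    default_taxonomy,
)
from .writeins import MappingTable

logger = logging.getLogger("ombcrosswalk")

_SEP = "|"
DEFAULT_TRUTHY = ("1", "yes", "y", "true", "checked", "x")


class MalformedRowError(ValueError):
    """A row could not be parsed under the active layout."""


def write_records(records: Sequence[RawRecord], path: str | Path) -> None:
    """Write records in the canonical dialect (CSV, UTF-8)."""
    df = pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "schema_id": [r.schema_id for r in records],
            "checked": [_SEP.join(sorted(r.checked)) for r in records],
            "writeins": [_SEP.join(r.writeins) for r in records],
            "hispanic_flag": [r.hispanic_flag for r in records],
        }
    )
    df.to_csv(path, index=False, encoding="utf-8")


def _split(value) -> list[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return []
    return [p for p in str(value).split(_SEP) if p]


def _canonical_row_to_record(row: Mapping) -> RawRecord:
    flag = row.get("hispanic_flag", FLAG_MISSING)
    if flag is None or (isinstance(flag, float) and pd.isna(flag)) or flag == "":
        flag = FLAG_MISSING
    return RawRecord(
        record_id=str(row["record_id"]),
        schema_id=str(row["schema_id"]),
        checked=frozenset(_split(row.get("checked"))),
        writeins=tuple(_split(row.get("writeins"))),
        hispanic_flag=str(flag),
    )


def _mapped_row_to_record(row: Mapping, rid: str, sid: str, layout: Mapping) -> RawRecord:
    truthy = {t.lower() for t in layout.get("truthy", DEFAULT_TRUTHY)}
    checked = set()
    for col, code in layout.get("checkbox_columns", {}).items():
        if col not in row:
            raise MalformedRowError(f"missing mapped column {col!r}")
        val = row[col]
        if val is not None and not (isinstance(val, float) and pd.isna(val)):
            if str(val).strip().lower() in truthy:
                checked.add(code)
    writeins = []
    for col in layout.get("writein_columns", []):
        val = row.get(col)
        if val is not None and not (isinstance(val, float) and pd.isna(val)) and str(val).strip():
            writeins.append(str(val).strip())
    flag = FLAG_MISSING
    eth_col = layout.get("ethnicity_column")
    if eth_col:
        val = row.get(eth_col)
        if val is not None and not (isinstance(val, float) and pd.isna(val)) and str(val).strip():
            v = str(val).strip().lower()
            flag = FLAG_YES if v in truthy else FLAG_NO
    return RawRecord(rid, sid, frozenset(checked), tuple(writeins), flag)


def read_records(
    path: str | Path,
    schema_config: Mapping[str, Mapping] | None = None,
    *,
    strict: bool = False,
) -> tuple[list[RawRecord], list[str]]:
    """Read records from a delimited file.

    With ``schema_config=None`` the canonical dialect is assumed.  Otherwise
    ``schema_config`` maps schema_id -> column layout (``checkbox_columns``,
    ``writein_columns``, ``ethnicity_column``, ``truthy``); each row's schema
    comes from its ``schema_id`` column.  Blank rows become fully missing
    records.  Malformed rows are collected into the returned error report; in
    strict mode the first malformed row aborts.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    records: list[RawRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        try:
            if "record_id" not in row or "schema_id" not in row:
                raise MalformedRowError("missing record_id/schema_id column")
            rid, sid = str(row["record_id"]), str(row["schema_id"])
            if schema_config is None:
                records.append(_canonical_row_to_record(row))
            else:
                if sid not in schema_config:
                    raise MalformedRowError(f"unknown schema_id {sid!r}")
                records.append(_mapped_row_to_record(row, rid, sid, schema_config[sid]))
        except (MalformedRowError, ValueError, KeyError) as exc:
            msg = f"row {i + 2}: {exc}"
            if strict:
                raise MalformedRowError(msg) from exc
            errors.append(msg)
    return records, errors


def write_allocations(
    allocations: Sequence[Allocation], path: str | Path, taxonomy: Taxonomy | None = None
) -> None:
    """Write the allocations table with canonical-order indicator strings."""
    taxonomy = taxonomy or default_taxonomy()
    df = pd.DataFrame(
        {
            "record_id": [a.record_id for a in allocations],
            "original": [a.original_category for a in allocations],
            "reallocated": [a.reallocated_category for a in allocations],
            "indicators": [
                _SEP.join(taxonomy.sort_identities(a.indicators)) for a in allocations
            ],
            "rule_trace": [_SEP.join(a.rule_trace) for a in allocations],
            "unmapped_terms": [_SEP.join(a.unmapped_terms) for a in allocations],
        }
    )
    df.to_csv(path, index=False, encoding="utf-8")


def run_pipeline(
    records: Sequence[RawRecord],
    schemas: Mapping[str, SurveySchema],
    table: MappingTable,
    output_dir: str | Path,
    *,
    taxonomy: Taxonomy | None = None,
    preserve_multiracial_checkbox: bool = False,
    upset_matrix: bool = False,
) -> dict:
    """Harmonize, report, and write all artifacts; returns the summary dict.

    Artifacts: ``allocations.csv``, ``crosstab.csv`` (with margins),
    ``flows.csv``, ``combinations.csv``, ``summary.json``, ``audit.log``
    (every reallocated record's rule trace, greppable), and optionally
    ``upset_matrix.csv``.
    """
    taxonomy = taxonomy or default_taxonomy()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("harmonizing %d records", len(records))
    allocations = batch_harmonize(
        records, schemas, table, taxonomy,
        preserve_multiracial_checkbox=preserve_multiracial_checkbox,
    )
    write_allocations(allocations, out / "allocations.csv", taxonomy)

    ct = crosstab(allocations, taxonomy)
    ct.to_frame(margins=True).to_csv(out / "crosstab.csv", encoding="utf-8")
    logger.info("cross-tabulated %d non-missing records", ct.grand_total)

    fl = flows(allocations, taxonomy)
    pd.DataFrame(
        {"from": [f.from_category for f in fl], "to": [f.to_category for f in fl],
         "count": [f.count for f in fl]}
    ).to_csv(out / "flows.csv", index=False, encoding="utf-8")

    combos, matrix = combinations(allocations, taxonomy)
    pd.DataFrame(
        {"identities": ["+".join(c.identities) for c in combos],
         "count": [c.count for c in combos]}
    ).to_csv(out / "combinations.csv", index=False, encoding="utf-8")
    if upset_matrix:
        matrix.to_csv(out / "upset_matrix.csv", encoding="utf-8")

    summary = summarize(allocations, taxonomy)
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2), encoding="utf-8"
    )

    with open(out / "audit.log", "w", encoding="utf-8") as fh:
        for a in allocations:
            if a.moved or a.unmapped_terms:
                fh.write(
                    f"{a.record_id}\t{a.original_category}->{a.reallocated_category}"
                    f"\ttrace={','.join(a.rule_trace)}"
                    f"\tunmapped={','.join(a.unmapped_terms)}\n"
                )
    logger.info(
        "reallocated %d of %d non-missing records",
        summary["reallocated"], summary["non_missing"],
    )
    return summary
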