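"""Category taxonomy, survey schemas, and core record types.

The OMB Directive 15 minimum reporting categories are the backbone of every
stage: six *base* identities (White; Black or African American; Hispanic or
Latino; Asian; Native Hawaiian or Other Pacific Islander; American Indian or
Alaska Native) plus three *derived* outcomes a harmonized record can land in
(MULTIRACIAL, OTHER, MISSING).  Asian and NHPI are distinct base codes
internally; pooling into a single "Asian or NHPI" reporting group happens only
at the reporting layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

# Base category codes
WHITE = "WHITE"
BLACK = "BLACK"
HISPANIC = "HISPANIC"
ASIAN = "ASIAN"
NHPI = "NHPI"
AIAN = "AIAN"
MENA = "MENA"  # 2024-revision extension point; not in the default taxonomy

# Derived outcome codes
MULTIRACIAL = "MULTIRACIAL"
OTHER = "OTHER"
MISSING = "MISSING"

DERIVED_CODES = (MULTIRACIAL, OTHER, MISSING)

# Hispanic-ethnicity item states (separate-question schemas only)
FLAG_YES = "yes"
FLAG_NO = "no"
FLAG_MISSING = "missing"
FLAG_VALUES = (FLAG_YES, FLAG_NO, FLAG_MISSING)

# Federal Register definitions of the minimum reporting categories.
_FEDERAL_DEFINITIONS = {
    AIAN: (
        "A person having origins in any of the original peoples of North and "
        "South America (including Central America) and who maintains tribal "
        "affiliation or community attachment."
    ),
    ASIAN: (
        "A person having origins in any of the original peoples of the Far "
        "East, Southeast Asia, or the Indian subcontinent, including, for "
        "example, Cambodia, China, India, Japan, Korea, Malaysia, Pakistan, "
        "the Philippine Islands, Thailand, and Vietnam."
    ),
    BLACK: (
        "A person having origins in any of the Black racial groups of Africa."
    ),
    HISPANIC: (
        "A person of Cuban, Mexican, Puerto Rican, South or Central American, "
        "or other Spanish culture or origin, regardless of race."
    ),
    NHPI: (
        "A person having origins in any of the original peoples of Hawaii, "
        "Guam, Samoa, or other Pacific Islands."
    ),
    WHITE: (
        "A person having origins in any of the original peoples of Europe, "
        "the Middle East, or North Africa."
    ),
}

_LABELS = {
    WHITE: "White",
    BLACK: "Black",
    HISPANIC: "Hispanic",
    ASIAN: "Asian",
    NHPI: "NHPI",
    AIAN: "AIAN",
    MENA: "MENA",
    MULTIRACIAL: "Multiracial",
    OTHER: "Other race",
    MISSING: "Missing",
}


@dataclass(frozen=True)
class BaseCategory:
    """One federally defined single-identity group."""

    code: str
    label: str
    definition: str = ""
    notes: str = ""


@dataclass(frozen=True)
class Taxonomy:
    """The active category system: base identities plus derived outcomes.

    Parameters
    ----------
    base_categories
        Ordered base identities.
    derived_codes
        The non-base outcomes (MULTIRACIAL, OTHER, MISSING).
    pooling_map
        Base code -> reporting-group label.  The default pools Asian and NHPI
        into "Asian or NHPI"; every other base code reports under its own
        label.
    canonical_order
        Ordering of base codes used for combination labels and tie-breaks.
    """

    base_categories: tuple[BaseCategory, ...]
    derived_codes: tuple[str, ...] = DERIVED_CODES
    pooling_map: Mapping[str, str] = field(default_factory=dict)
    canonical_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        codes = [c.code for c in self.base_categories]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate base category codes")
        if set(self.derived_codes) & set(codes):
            raise ValueError("derived codes must be disjoint from base codes")
        if not set(self.pooling_map) <= set(codes):
            raise ValueError("pooling_map keys must be base codes")
        if sorted(self.canonical_order) != sorted(codes):
            raise ValueError("canonical_order must be a permutation of base codes")

    @property
    def base_codes(self) -> tuple[str, ...]:
        return tuple(c.code for c in self.base_categories)

    def is_base(self, code: str) -> bool:
        return code in self.base_codes

    def reporting_label(self, code: str) -> str:
        """Pooled display label for a base or derived outcome code."""
        if code in self.pooling_map:
            return self.pooling_map[code]
        if self.is_base(code) or code in self.derived_codes:
            return _LABELS.get(code, code)
        raise KeyError(f"unknown outcome code: {code!r}")

    def reporting_levels(self, include_missing: bool = False) -> list[str]:
        """Ordered pooled reporting labels (base groups, then Multiracial, Other)."""
        levels: list[str] = []
        for code in self.canonical_order:
            lab = self.reporting_label(code)
            if lab not in levels:
                levels.append(lab)
        levels.append(self.reporting_label(MULTIRACIAL))
        levels.append(self.reporting_label(OTHER))
        if include_missing:
            levels.append(self.reporting_label(MISSING))
        return levels

    def sort_identities(self, codes: Iterable[str]) -> tuple[str, ...]:
        """Return identity codes as a tuple in canonical order."""
        order = {c: i for i, c in enumerate(self.canonical_order)}
        return tuple(sorted(codes, key=lambda c: order[c]))

    def to_dict(self) -> dict:
        return {
            "base_categories": [
                {
                    "code": c.code,
                    "label": c.label,
                    "definition": c.definition,
                    "notes": c.notes,
                }
                for c in self.base_categories
            ],
            "derived_codes": list(self.derived_codes),
            "pooling_map": dict(self.pooling_map),
            "canonical_order": list(self.canonical_order),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Taxonomy":
        return cls(
            base_categories=tuple(
                BaseCategory(
                    code=b["code"],
                    label=b.get("label", b["code"]),
                    definition=b.get("definition", ""),
                    notes=b.get("notes", ""),
                )
                for b in d["base_categories"]
            ),
            derived_codes=tuple(d.get("derived_codes", DERIVED_CODES)),
            pooling_map=dict(d.get("pooling_map", {})),
            canonical_order=tuple(d["canonical_order"]),
        )

    def with_mena(self) -> "Taxonomy":
        """Register the 2024-revision MENA base category (extension point)."""
        mena = BaseCategory(
            code=MENA,
            label=_LABELS[MENA],
            definition=(
                "A person having origins in any of the original peoples of the "
                "Middle East or North Africa."
            ),
        )
        return replace(
            self,
            base_categories=self.base_categories + (mena,),
            canonical_order=self.canonical_order + (MENA,),
        )


def default_taxonomy() -> Taxonomy:
    """The 6 base + 3 derived outcome taxonomy with Asian/NHPI pooled reporting.

    Canonical order: White, Black, Hispanic, Asian, NHPI, AIAN.
    """
    bases = tuple(
        BaseCategory(code=code, label=_LABELS[code], definition=_FEDERAL_DEFINITIONS[code])
        for code in (WHITE, BLACK, HISPANIC, ASIAN, NHPI, AIAN)
    )
    return Taxonomy(
        base_categories=bases,
        derived_codes=DERIVED_CODES,
        pooling_map={ASIAN: "Asian or NHPI", NHPI: "Asian or NHPI"},
        canonical_order=(WHITE, BLACK, HISPANIC, ASIAN, NHPI, AIAN),
    )


@dataclass(frozen=True)
class SurveySchema:
    """Description of one study's demographic instrument.

    ``ethnicity_mode`` is ``"combined"`` when Hispanic/Latino is a checkbox in
    the single race-and-ethnicity question, and ``"separate"`` when the survey
    asks a dedicated Hispanic-ethnicity yes/no item alongside a race question.
    """

    schema_id: str
    ethnicity_mode: str  # "combined" | "separate"
    has_multiracial_checkbox: bool = False
    checkbox_map: Mapping[str, str] = field(default_factory=dict)
    writein_fields: tuple[str, ...] = ("please_specify",)

    def __post_init__(self) -> None:
        if self.ethnicity_mode not in ("combined", "separate"):
            raise ValueError(f"unknown ethnicity_mode: {self.ethnicity_mode!r}")

    @property
    def checkbox_codes(self) -> set[str]:
        return set(self.checkbox_map.values())

    def to_dict(self) -> dict:
        return {
            "schema_id": self.schema_id,
            "ethnicity_mode": self.ethnicity_mode,
            "has_multiracial_checkbox": self.has_multiracial_checkbox,
            "checkbox_map": dict(self.checkbox_map),
            "writein_fields": list(self.writein_fields),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SurveySchema":
        return cls(
            schema_id=d["schema_id"],
            ethnicity_mode=d["ethnicity_mode"],
            has_multiracial_checkbox=bool(d.get("has_multiracial_checkbox", False)),
            checkbox_map=dict(d.get("checkbox_map", {})),
            writein_fields=tuple(d.get("writein_fields", ("please_specify",))),
        )


@dataclass(frozen=True)
class RawRecord:
    """One child's unharmonized survey responses."""

    record_id: str
    schema_id: str
    checked: frozenset[str] = frozenset()
    writeins: tuple[str, ...] = ()
    hispanic_flag: str = FLAG_MISSING

    def __post_init__(self) -> None:
        object.__setattr__(self, "checked", frozenset(self.checked))
        object.__setattr__(self, "writeins", tuple(self.writeins))
        if self.hispanic_flag not in FLAG_VALUES:
            raise ValueError(f"invalid hispanic_flag: {self.hispanic_flag!r}")


@dataclass(frozen=True)
class Allocation:
    """Fully traced harmonization outcome for one record.

    ``indicators`` is the set of base identities constructed for the child
    (Hispanic counts as one); its cardinality determines single-category vs
    multiracial outcomes.  ``rule_trace`` lists the decision rules fired, in
    order, for audit.
    """

    record_id: str
    original_category: str
    reallocated_category: str
    indicators: frozenset[str] = frozenset()
    rule_trace: tuple[str, ...] = ()
    unmapped_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "indicators", frozenset(self.indicators))
        object.__setattr__(self, "rule_trace", tuple(self.rule_trace))
        object.__setattr__(self, "unmapped_terms", tuple(self.unmapped_terms))

    @property
    def moved(self) -> bool:
        return self.original_category != self.reallocated_category


class SchemaNotFoundError(KeyError):
    """Raised when a record references an unregistered survey schema."""


def validate_allocation(alloc: Allocation, taxonomy: Taxonomy, *, preserve_multiracial: bool = False) -> None:
    """Assert the indicator-cardinality invariant on one allocation.

    MULTIRACIAL iff |indicators| >= 2; a single base outcome carries exactly
    its own indicator; OTHER/MISSING carry none.  With
    ``preserve_multiracial=True`` a MULTIRACIAL outcome with one indicator is
    tolerated when the trace shows the multiracial checkbox was honored (R5M).
    """
    cat = alloc.reallocated_category
    n = len(alloc.indicators)
    if cat == MULTIRACIAL:
        if n < 2 and not (preserve_multiracial and "R5M" in alloc.rule_trace and n == 1):
            raise AssertionError(f"{alloc.record_id}: MULTIRACIAL with {n} indicators")
    elif taxonomy.is_base(cat):
        if alloc.indicators != frozenset({cat}):
            raise AssertionError(
                f"{alloc.record_id}: base outcome {cat} with indicators {set(alloc.indicators)}"
            )
    elif cat in (OTHER, MISSING):
        if n != 0:
            raise AssertionError(f"{alloc.record_id}: {cat} with nonempty indicators")
    else:
        raise AssertionError(f"{alloc.record_id}: unknown outcome {cat!r}")
    if cat != MISSING and not alloc.rule_trace:
        raise AssertionError(f"{alloc.record_id}: empty rule_trace on non-missing record")


def validate_record(
    record: RawRecord,
    schema: SurveySchema,
    taxonomy: Taxonomy | None = None,
) -> list[str]:
    """Check one record against its schema; return human-readable violations."""
    taxonomy = taxonomy or default_taxonomy()
    violations: list[str] = []
    valid_codes = set(taxonomy.base_codes) | {OTHER, MULTIRACIAL}
    for code in record.checked:
        if code not in valid_codes:
            violations.append(f"{record.record_id}: unknown checked code {code!r}")
    if schema.ethnicity_mode == "combined" and record.hispanic_flag != FLAG_MISSING:
        violations.append(
            f"{record.record_id}: hispanic_flag={record.hispanic_flag!r} under combined mode"
        )
    if schema.ethnicity_mode == "separate" and HISPANIC in record.checked:
        violations.append(
            f"{record.record_id}: Hispanic checkbox under separate mode (use hispanic_flag)"
        )
    if MULTIRACIAL in record.checked and not schema.has_multiracial_checkbox:
        violations.append(
            f"{record.record_id}: multiracial checkbox not offered by schema "
            f"{schema.schema_id!r}"
        )
    if record.schema_id != schema.schema_id:
        violations.append(
            f"{record.record_id}: schema_id {record.schema_id!r} != {schema.schema_id!r}"
        )
    return violations


def validate_batch(
    records: Sequence[RawRecord],
    schemas: Mapping[str, SurveySchema],
    taxonomy: Taxonomy | None = None,
) -> list[str]:
    """Validate a batch; flags duplicate record_ids and unknown schemas."""
    violations: list[str] = []
    seen: set[str] = set()
    for rec in records:
        if rec.record_id in seen:
            violations.append(f"duplicate record_id: {rec.record_id}")
        seen.add(rec.record_id)
        schema = schemas.get(rec.schema_id)
        if schema is None:
            violations.append(f"{rec.record_id}: unknown schema_id {rec.schema_id!r}")
            continue
        violations.extend(validate_record(rec, schema, taxonomy))
    return violations


def load_taxonomy(path: str | Path) -> Taxonomy:
    """Load a Taxonomy from a YAML or JSON config file."""
    return Taxonomy.from_dict(_load_structured(path))


def load_schemas(path: str | Path) -> dict[str, SurveySchema]:
    """Load survey schemas from a YAML/JSON config file (list or mapping)."""
    data = _load_structured(path)
    if isinstance(data, Mapping) and "schemas" in data:
        data = data["schemas"]
    if isinstance(data, Mapping):
        items = [dict(v, schema_id=v.get("schema_id", k)) for k, v in data.items()]
    else:
        items = list(data)
    schemas = {s["schema_id"]: SurveySchema.from_dict(s) for s in items}
    return schemas


def _load_structured(path: str | Path):
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
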