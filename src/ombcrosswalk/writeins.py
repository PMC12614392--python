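"""Normalization and crosswalking of free-text "please specify" responses.

Survey respondents who check "other race" (or any category) may write an
ethnonym — "Haitian", "Cape Verdean", "German" — in the accompanying
open-ended field.  This module resolves such terms to base OMB categories
through a curated, exact-match dictionary.  There is deliberately no fuzzy
matching: the crosswalk is a consensus-audited artifact, and silent
edit-distance matches would break its auditability.  Terms absent from the
dictionary come back as :data:`UNMAPPED` and are logged for curator review.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .taxonomy import DERIVED_CODES, Taxonomy, default_taxonomy

UNMAPPED = "UNMAPPED"

# Connectors separating multiple identities in one write-in, word-bounded.
_CONNECTOR_RE = re.compile(r"(?:\band\b|&|/|,|;)", re.IGNORECASE)
_PUNCT_RE = re.compile(r"[^\w\s]|_")
_WS_RE = re.compile(r"\s+")


def normalize_term(text: str) -> str:
    """Canonicalize one term: lowercase, strip diacritics and punctuation,
    collapse whitespace.  Idempotent; empty input yields the empty string."""
    text = unicodedata.normalize("NFKD", text)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    text = text.lower()
    text = _PUNCT_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


def tokenize_writein(text: str) -> list[str]:
    """Split one raw write-in into individual terms.

    Splits on the connectors "and", "&", "/", ",", ";" (word-bounded,
    case-insensitive).  Parenthetical annotations such as "French (White)"
    are treated as separate terms: the parenthesis content is tokenized too.
    Order is preserved; empty tokens are dropped.
    """
    text = re.sub(r"[()]", ",", text)
    parts = _CONNECTOR_RE.split(text)
    return [p.strip() for p in parts if p.strip()]


class MappingTableError(ValueError):
    """Raised when a mapping table violates its invariants."""


@dataclass(frozen=True)
class MappingTable:
    """Normalized ethnonym -> base OMB code (or UNMAPPED) crosswalk.

    Keys must be normalization-closed (``normalize_term(key) == key``) and may
    only map to base codes of the active taxonomy or the UNMAPPED sentinel —
    never to a derived outcome.
    """

    entries: Mapping[str, str]
    provenance: Mapping[str, str] = field(default_factory=dict)
    taxonomy: Taxonomy = field(default_factory=default_taxonomy)

    def __post_init__(self) -> None:
        problems = self.lint()
        if problems:
            raise MappingTableError("; ".join(problems))

    def lint(self) -> list[str]:
        """Return invariant violations (empty list means the table is clean)."""
        problems = []
        valid = set(self.taxonomy.base_codes) | {UNMAPPED}
        for key, code in self.entries.items():
            if normalize_term(key) != key:
                problems.append(f"key not normalization-closed: {key!r}")
            if code in DERIVED_CODES:
                problems.append(f"key {key!r} maps to derived code {code}")
            elif code not in valid:
                problems.append(f"key {key!r} maps to unknown code {code!r}")
        return problems

    def lookup(self, term: str) -> str:
        """Exact lookup after normalization; absent keys return UNMAPPED."""
        return self.entries.get(normalize_term(term), UNMAPPED)


def map_term(term: str, table: MappingTable) -> str:
    """Resolve one raw term to a base code, or UNMAPPED (never raises)."""
    return table.lookup(term)


def resolve_writeins(
    texts: Sequence[str], table: MappingTable
) -> tuple[set[str], list[str]]:
    """Resolve a record's write-in fields to (base codes, unmapped terms).

    Every text is tokenized, every term mapped; codes are deduplicated.
    Unmapped terms are returned normalized, in first-occurrence order,
    without duplicates.  Empty texts contribute nothing.
    """
    codes: set[str] = set()
    unmapped: list[str] = []
    for text in texts:
        for term in tokenize_writein(text):
            code = table.lookup(term)
            if code == UNMAPPED:
                norm = normalize_term(term)
                if norm and norm not in unmapped:
                    unmapped.append(norm)
            else:
                codes.add(code)
    return codes, unmapped


def load_mapping_table(path: str | Path, taxonomy: Taxonomy | None = None) -> MappingTable:
    """Load a crosswalk from a 2–3 column delimited file (term, code[, provenance])."""
    taxonomy = taxonomy or default_taxonomy()
    entries: dict[str, str] = {}
    provenance: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"term", "code"} <= set(reader.fieldnames):
            raise MappingTableError("mapping file needs 'term' and 'code' columns")
        for row in reader:
            term = row["term"]
            entries[term] = row["code"]
            if row.get("provenance"):
                provenance[term] = row["provenance"]
    return MappingTable(entries=entries, provenance=provenance, taxonomy=taxonomy)


def save_mapping_table(table: MappingTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["term", "code", "provenance"])
        for term in sorted(table.entries):
            writer.writerow([term, table.entries[term], table.provenance.get(term, "")])


def default_mapping_table(taxonomy: Taxonomy | None = None) -> MappingTable:
    """The shipped crosswalk: federal-definition examples, common ethnonyms,
    the category labels themselves, an illustrative federally recognized tribe
    list, and known-unmappable terms ("Brazilian", "American", "mixed", ...)."""
    ref = resources.files("ombcrosswalk").joinpath("data/default_mapping.csv")
    with resources.as_file(ref) as path:
        return load_mapping_table(path, taxonomy)
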