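"""Reconstruction of the pooled worked example and randomized simulation.

:func:`build_pooled_fixture` re-creates the pooled eight-study dataset of
8087 parent-reported child race/ethnicity records as *raw survey responses*
(checkboxes, write-ins, ethnicity flags), not as pre-computed allocations.
Every cell of the published original-vs-reallocated cross-tabulation is
realized with a response pattern licensed by the study narrative (e.g. the
other-race-to-Black cell is an "other race" checkbox plus a written term
such as "Haitian"), so the harmonization engine must route each pattern
correctly for the printed table to emerge.  The seed controls record order
only; the composition is fixed.

:func:`simulate_survey` draws randomized synthetic datasets for
property-style testing at arbitrary sizes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .taxonomy import (
    AIAN,
    ASIAN,
    BLACK,
    FLAG_MISSING,
    FLAG_NO,
    FLAG_YES,
    HISPANIC,
    MULTIRACIAL,
    NHPI,
    OTHER,
    WHITE,
    RawRecord,
    SurveySchema,
)

# ---------------------------------------------------------------------------
# Pooled worked-example fixture
# ---------------------------------------------------------------------------

# Study quotas (consented participants per study, A..H).
STUDY_QUOTAS = {
    "A": 983,
    "B": 448,
    "C": 693,
    "D": 560,
    "E": 1301,
    "F": 959,
    "G": 1726,
    "H": 1417,
}

_RACE_BOXES = {
    "White": WHITE,
    "Black or African American": BLACK,
    "Asian": ASIAN,
    "Native Hawaiian or Other Pacific Islander": NHPI,
    "American Indian or Alaska Native": AIAN,
    "Other race": OTHER,
}
_HISPANIC_BOX = {"Hispanic or Latino": HISPANIC}
_MULTI_BOX = {"Multiracial": MULTIRACIAL}


def pooled_schemas() -> dict[str, SurveySchema]:
    """Survey schemas for the eight pooled studies.

    A and B ask Hispanic ethnicity as a separate yes/no item; the other six
    use a single combined question.  G and H (the earliest studies) offered a
    multiracial checkbox.
    """
    schemas: dict[str, SurveySchema] = {}
    for sid in ("A", "B"):
        schemas[sid] = SurveySchema(
            schema_id=sid,
            ethnicity_mode="separate",
            has_multiracial_checkbox=False,
            checkbox_map=dict(_RACE_BOXES),
            writein_fields=("please_specify",),
        )
    for sid in ("C", "D", "E", "F"):
        schemas[sid] = SurveySchema(
            schema_id=sid,
            ethnicity_mode="combined",
            has_multiracial_checkbox=False,
            checkbox_map={**_RACE_BOXES, **_HISPANIC_BOX},
            writein_fields=("please_specify",),
        )
    for sid in ("G", "H"):
        schemas[sid] = SurveySchema(
            schema_id=sid,
            ethnicity_mode="combined",
            has_multiracial_checkbox=True,
            checkbox_map={**_RACE_BOXES, **_HISPANIC_BOX, **_MULTI_BOX},
            writein_fields=("please_specify",),
        )
    return schemas


@dataclass(frozen=True)
class _Pattern:
    """One raw-response pattern realizing part of a cross-tabulation cell."""

    count: int
    checked: frozenset[str]
    writeins: tuple[str, ...]
    hispanic_flag: str
    cell: str  # "original->reallocated" bookkeeping label
    note: str


def _pat(count, checked, writeins, flag, cell, note) -> _Pattern:
    return _Pattern(count, frozenset(checked), tuple(writeins), flag, cell, note)


# Additional identity combinations within the multiracial group, beyond the
# three printed ones and those pinned by cell-specific patterns.  Fixed spread
# chosen to realize the published structure: 22 distinct combinations in all,
# AIAN present in 13 of them, 81 multiracial children holding AIAN.
_EXTRA_COMBINATIONS: list[tuple[tuple[str, ...], int]] = [
    ((HISPANIC, ASIAN), 14),
    ((WHITE, NHPI), 10),
    ((BLACK, NHPI), 8),
    ((WHITE, BLACK, HISPANIC), 9),
    ((HISPANIC, NHPI), 4),
    ((HISPANIC, AIAN), 13),
    ((ASIAN, AIAN), 6),
    ((NHPI, AIAN), 3),
    ((WHITE, BLACK, AIAN), 9),
    ((WHITE, HISPANIC, AIAN), 12),
    ((BLACK, HISPANIC, AIAN), 10),
    ((WHITE, ASIAN, AIAN), 7),
    ((BLACK, ASIAN, AIAN), 5),
    ((WHITE, BLACK, HISPANIC, AIAN), 4),
    ((WHITE, NHPI, AIAN), 3),
    ((HISPANIC, NHPI, AIAN), 3),
]


def _separate_mode_patterns() -> list[_Pattern]:
    """Patterns that require a separate Hispanic-ethnicity item (studies A/B).

    735 children identified as Hispanic or Latino: 491 with no usable race
    response (race blank) and 244 with a race checkbox (White), the latter
    landing in the multiracial group with indicators {White, Hispanic}.
    The remaining 696 A/B children are non-Hispanic White.
    """
    return [
        _pat(491, (), (), FLAG_YES, "Hispanic->Hispanic",
             "separate mode: Hispanic yes, race question left blank"),
        _pat(244, (WHITE,), (), FLAG_YES, "Multiracial->Multiracial",
             "separate mode: Hispanic yes + White box -> {White, Hispanic}"),
        _pat(696, (WHITE,), (), FLAG_NO, "White->White",
             "separate mode: non-Hispanic, White box"),
    ]


def _multibox_patterns() -> list[_Pattern]:
    """Patterns that require the multiracial checkbox (study H)."""
    return [
        _pat(9, (MULTIRACIAL,), ("German",), FLAG_MISSING, "Multiracial->White",
             "multiracial box + single written term mapping to White"),
        _pat(20, (MULTIRACIAL,), ("Haitian",), FLAG_MISSING, "Multiracial->Black",
             "multiracial box + single written term mapping to Black"),
        _pat(9, (MULTIRACIAL,), ("Cape Verdean",), FLAG_MISSING, "Multiracial->Black",
             "multiracial box + single written term mapping to Black"),
        _pat(15, (MULTIRACIAL,), ("Puerto Rican",), FLAG_MISSING, "Multiracial->Hispanic",
             "multiracial box + single written term mapping to Hispanic"),
        _pat(1, (MULTIRACIAL,), ("Japanese",), FLAG_MISSING, "Multiracial->Asian or NHPI",
             "multiracial box + single written term mapping to Asian"),
        _pat(2, (MULTIRACIAL,), ("Cherokee",), FLAG_MISSING, "Multiracial->AIAN",
             "multiracial box + single written term mapping to AIAN"),
        _pat(55, (MULTIRACIAL,), (), FLAG_MISSING, "Multiracial->Other race",
             "multiracial box with no written detail: no indicators constructible"),
        _pat(100, (MULTIRACIAL,), ("White and Black",), FLAG_MISSING,
             "Multiracial->Multiracial",
             "multiracial box + two written identities -> {White, Black}"),
    ]


def _general_patterns() -> list[_Pattern]:
    """Patterns valid under any combined-question schema."""
    pats = [
        # Diagonal single-category records.
        _pat(2095, (WHITE,), (), FLAG_MISSING, "White->White", "single box"),
        _pat(1477, (BLACK,), (), FLAG_MISSING, "Black->Black", "single box"),
        _pat(1380, (HISPANIC,), (), FLAG_MISSING, "Hispanic->Hispanic", "single box"),
        _pat(280, (ASIAN,), (), FLAG_MISSING, "Asian or NHPI->Asian or NHPI", "single box"),
        _pat(34, (NHPI,), (), FLAG_MISSING, "Asian or NHPI->Asian or NHPI", "single box"),
        _pat(35, (AIAN,), (), FLAG_MISSING, "AIAN->AIAN", "single box"),
        # Single box + distinct-category write-in -> multiracial.
        _pat(1, (WHITE,), ("Cherokee",), FLAG_MISSING, "White->Multiracial",
             "White box + written tribe -> {White, AIAN}"),
        _pat(5, (BLACK,), ("Cherokee",), FLAG_MISSING, "Black->Multiracial",
             "Black box + written tribe -> {Black, AIAN}"),
        _pat(23, (HISPANIC,), ("White",), FLAG_MISSING, "Hispanic->Multiracial",
             "Hispanic box + written distinct identity -> {White, Hispanic}"),
        # Multiple checkboxes (original multiracial, stays multiracial).
        _pat(2, (WHITE, HISPANIC), (), FLAG_MISSING, "Multiracial->Multiracial",
             "White + Hispanic boxes"),
        _pat(69, (WHITE, BLACK), (), FLAG_MISSING, "Multiracial->Multiracial",
             "White + Black boxes"),
        _pat(86, (BLACK, HISPANIC), (), FLAG_MISSING, "Multiracial->Multiracial",
             "Black + Hispanic boxes"),
        # Other-race box + mapped write-ins -> single categories.
        _pat(20, (OTHER,), ("German",), FLAG_MISSING, "Other race->White", "other box + written term"),
        _pat(13, (OTHER,), ("Lebanese",), FLAG_MISSING, "Other race->White", "other box + written term"),
        _pat(40, (OTHER,), ("Haitian",), FLAG_MISSING, "Other race->Black", "other box + written term"),
        _pat(25, (OTHER,), ("Cape Verdean",), FLAG_MISSING, "Other race->Black", "other box + written term"),
        _pat(23, (OTHER,), ("Black",), FLAG_MISSING, "Other race->Black", "other box + written term"),
        _pat(10, (OTHER,), ("Puerto Rican",), FLAG_MISSING, "Other race->Hispanic", "other box + written term"),
        _pat(8, (OTHER,), ("Mexican",), FLAG_MISSING, "Other race->Hispanic", "other box + written term"),
        _pat(7, (OTHER,), ("Japanese",), FLAG_MISSING, "Other race->Asian or NHPI", "other box + written term"),
        _pat(2, (OTHER,), ("Hawaiian",), FLAG_MISSING, "Other race->Asian or NHPI", "other box + written term"),
        # Other-race box + two distinct mapped write-ins -> multiracial.
        _pat(15, (OTHER,), ("French", "Japanese"), FLAG_MISSING, "Other race->Multiracial",
             "other box + two written identities -> {White, Asian}"),
        # Other-race box kept: no write-in or unmappable write-in.
        _pat(58, (OTHER,), (), FLAG_MISSING, "Other race->Other race", "other box alone"),
        _pat(40, (OTHER,), ("Brazilian",), FLAG_MISSING, "Other race->Other race",
             "other box + unmappable written term"),
        _pat(20, (OTHER,), ("American",), FLAG_MISSING, "Other race->Other race",
             "other box + unmappable written term"),
        # Nonrespondents.
        _pat(557, (), (), FLAG_MISSING, "Missing->Missing", "no responses"),
    ]
    # Remaining multiracial combinations, realized as multiple checkboxes.
    for combo, count in _EXTRA_COMBINATIONS:
        pats.append(
            _pat(count, combo, (), FLAG_MISSING, "Multiracial->Multiracial",
                 f"checkboxes for {'+'.join(combo)}")
        )
    return pats


def fixture_manifest() -> list[dict]:
    """Every cell -> raw-response pattern choice, with counts and notes."""
    manifest = []
    for group, pats in (
        ("separate (A/B)", _separate_mode_patterns()),
        ("multiracial checkbox (H)", _multibox_patterns()),
        ("combined (C-H)", _general_patterns()),
    ):
        for p in pats:
            manifest.append(
                {
                    "group": group,
                    "cell": p.cell,
                    "count": p.count,
                    "checked": sorted(p.checked),
                    "writeins": list(p.writeins),
                    "hispanic_flag": p.hispanic_flag,
                    "note": p.note,
                }
            )
    return manifest


def _expand(patterns: list[_Pattern]) -> list[_Pattern]:
    out: list[_Pattern] = []
    for p in patterns:
        out.extend((p,) * p.count)
    return out


def build_pooled_fixture(seed: int = 1) -> list[RawRecord]:
    """Reconstruct the pooled 8087-record worked example.

    Exactly 557 records are fully missing; the remaining 7530 are built
    cell-by-cell so the harmonization cascade reproduces the published
    cross-tabulation.  Output order is shuffled by ``seed``; two builds with
    the same seed are identical.
    """
    sep = _expand(_separate_mode_patterns())
    multi = _expand(_multibox_patterns())
    general = _expand(_general_patterns())
    assert len(sep) == 1431 and len(multi) == 211
    assert len(sep) + len(multi) + len(general) == 8087

    # Study assignment.  A/B absorb the separate-mode patterns (interleaved so
    # both studies carry the Hispanic pattern); H takes every
    # multiracial-checkbox pattern; C..G and the rest of H are filled from the
    # general pool in order.
    # Deterministic proportional split of the separate pool between A and B.
    assignments: list[tuple[str, _Pattern]] = []
    a_quota = STUDY_QUOTAS["A"]
    n_a = 0
    for i, p in enumerate(sep):
        if round((i + 1) * a_quota / len(sep)) > n_a:
            assignments.append(("A", p))
            n_a += 1
        else:
            assignments.append(("B", p))
    assert n_a == a_quota

    for p in multi:
        assignments.append(("H", p))

    fill_order = [
        ("C", STUDY_QUOTAS["C"]),
        ("D", STUDY_QUOTAS["D"]),
        ("E", STUDY_QUOTAS["E"]),
        ("F", STUDY_QUOTAS["F"]),
        ("G", STUDY_QUOTAS["G"]),
        ("H", STUDY_QUOTAS["H"] - len(multi)),
    ]
    gi = iter(general)
    for sid, quota in fill_order:
        for _ in range(quota):
            assignments.append((sid, next(gi)))
    assert sum(1 for _ in gi) == 0

    records = [
        RawRecord(
            record_id=f"R{i:06d}",
            schema_id=sid,
            checked=p.checked,
            writeins=p.writeins,
            hispanic_flag=p.hispanic_flag,
        )
        for i, (sid, p) in enumerate(assignments, start=1)
    ]
    rng = random.Random(seed)
    rng.shuffle(records)
    return records


# ---------------------------------------------------------------------------
# Randomized survey simulation
# ---------------------------------------------------------------------------

SIM_COMBINED = "SIM-COMBINED"
SIM_SEPARATE = "SIM-SEPARATE"


def simulation_schemas() -> dict[str, SurveySchema]:
    """The two schema archetypes the simulator draws from."""
    return {
        SIM_COMBINED: SurveySchema(
            schema_id=SIM_COMBINED,
            ethnicity_mode="combined",
            has_multiracial_checkbox=True,
            checkbox_map={**_RACE_BOXES, **_HISPANIC_BOX, **_MULTI_BOX},
        ),
        SIM_SEPARATE: SurveySchema(
            schema_id=SIM_SEPARATE,
            ethnicity_mode="separate",
            has_multiracial_checkbox=False,
            checkbox_map=dict(_RACE_BOXES),
        ),
    }


@dataclass(frozen=True)
class SimulationParams:
    """Generator parameters for randomized survey records.

    ``category_probs`` are relative weights for the single-category draw
    (normalized internally).  ``other_rate`` and ``multiracial_rate`` divert a
    record to the other-race / multiracial checkbox before a category is
    drawn; ``writein_prob`` attaches a term drawn uniformly from
    ``vocabulary`` to other-race and multiracial records; ``missing_rate`` is
    the probability of a fully blank record; ``separate_frac`` is the share of
    records under the separate-ethnicity-question schema.  Defaults mirror a
    pooled community-based child sample: a White plurality, substantial Black
    and Hispanic groups, ~7% nonresponse, ~4% other-race and ~9% multiracial
    checkbox use, and an 18% separate-question share.
    """

    category_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            WHITE: 0.45,
            BLACK: 0.20,
            HISPANIC: 0.25,
            ASIAN: 0.06,
            NHPI: 0.015,
            AIAN: 0.025,
        }
    )
    other_rate: float = 0.04
    multiracial_rate: float = 0.09
    writein_prob: float = 0.30
    vocabulary: Mapping[str, str] = field(
        default_factory=lambda: {
            "Haitian": BLACK,
            "German": WHITE,
            "Cherokee": AIAN,
            "Japanese": ASIAN,
            "Puerto Rican": HISPANIC,
            "Hawaiian": NHPI,
            "Brazilian": "UNMAPPED",
        }
    )
    missing_rate: float = 0.07
    separate_frac: float = 0.18

    def validate(self) -> None:
        for name in ("other_rate", "multiracial_rate", "writein_prob", "missing_rate", "separate_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = sum(self.category_probs.values())
        if total <= 0 or any(p < 0 for p in self.category_probs.values()):
            raise ValueError("category_probs must be nonnegative and normalizable")


def simulate_survey(
    seed: int, n: int, params: SimulationParams | None = None
) -> list[RawRecord]:
    """Draw ``n`` independent records under ``params``; deterministic by seed."""
    params = params or SimulationParams()
    params.validate()
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    cats = list(params.category_probs)
    weights = np.array([params.category_probs[c] for c in cats], dtype=float)
    weights = weights / weights.sum()
    terms = list(params.vocabulary)
    records: list[RawRecord] = []
    for i in range(n):
        rid = f"S{i:06d}"
        separate = rng.random() < params.separate_frac
        sid = SIM_SEPARATE if separate else SIM_COMBINED
        if rng.random() < params.missing_rate:
            records.append(RawRecord(rid, sid))
            continue
        u = rng.random()
        writein: tuple[str, ...] = ()
        if u < params.other_rate:
            checked: frozenset[str] = frozenset({OTHER})
            flag = FLAG_NO if separate else FLAG_MISSING
            if terms and rng.random() < params.writein_prob:
                writein = (terms[rng.integers(len(terms))],)
        elif u < params.other_rate + params.multiracial_rate:
            if separate:
                race = cats[rng.choice(len(cats), p=weights)]
                if race == HISPANIC:
                    race = WHITE
                checked, flag = frozenset({race}), FLAG_YES
            else:
                checked, flag = frozenset({MULTIRACIAL}), FLAG_MISSING
                if terms and rng.random() < params.writein_prob:
                    writein = (terms[rng.integers(len(terms))],)
        else:
            cat = cats[rng.choice(len(cats), p=weights)]
            if separate and cat == HISPANIC:
                checked, flag = frozenset(), FLAG_YES
            else:
                checked = frozenset({cat})
                flag = FLAG_NO if separate else FLAG_MISSING
        records.append(RawRecord(rid, sid, checked, writein, flag))
    return records
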