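"""Analytical outputs: cross-tabulation, flows, chi-square, disaggregation.

All reporting uses the pooled 7-level outcome set (White, Black, Hispanic,
Asian or NHPI, AIAN, Multiracial, Other race).  Records whose original or
reallocated outcome is MISSING are excluded from the cross-tabulation and the
chi-square — nonresponse is reported separately in the summary, never folded
into a category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .taxonomy import (
    MISSING,
    MULTIRACIAL,
    Allocation,
    Taxonomy,
    default_taxonomy,
)


class EmptyInputError(ValueError):
    """No non-missing allocations to tabulate."""


class DegenerateTableError(ValueError):
    """A contingency table with a zero margin."""


class UndefinedChangeError(ValueError):
    """Percent change from a zero baseline."""


@dataclass(frozen=True)
class CrossTab:
    """Original-by-reallocated contingency table with margins."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray  # shape (rows, cols), nonnegative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (counts < 0).any():
            raise ValueError("negative cell count")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    @property
    def off_diagonal_total(self) -> int:
        return self.grand_total - int(np.trace(self.counts))

    def cell(self, row: str, col: str) -> int:
        return int(self.counts[self.row_labels.index(row), self.col_labels.index(col)])

    def to_frame(self, margins: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.row_labels), columns=list(self.col_labels))
        if margins:
            df["Total"] = df.sum(axis=1)
            df.loc["Total"] = df.sum(axis=0)
        return df


@dataclass(frozen=True)
class FlowRecord:
    """One off-diagonal movement between categories."""

    from_category: str
    to_category: str
    count: int

    def __post_init__(self) -> None:
        if self.from_category == self.to_category:
            raise ValueError("flow must move between distinct categories")
        if self.count < 1:
            raise ValueError("flow count must be >= 1")


@dataclass(frozen=True)
class CombinationCount:
    """One identity combination within the multiracial group."""

    identities: tuple[str, ...]  # base codes, canonical order
    count: int

    def __post_init__(self) -> None:
        if len(self.identities) < 2:
            raise ValueError("a combination needs at least two identities")


def _pooled(alloc_category: str, taxonomy: Taxonomy) -> str:
    return taxonomy.reporting_label(alloc_category)


def crosstab(allocations: Sequence[Allocation], taxonomy: Taxonomy | None = None) -> CrossTab:
    """Original-vs-reallocated cross-tabulation over the pooled 7 levels.

    Allocations with a MISSING original or reallocated outcome are excluded.
    """
    taxonomy = taxonomy or default_taxonomy()
    levels = taxonomy.reporting_levels()
    idx = {lab: i for i, lab in enumerate(levels)}
    counts = np.zeros((len(levels), len(levels)), dtype=np.int64)
    n = 0
    for a in allocations:
        if a.original_category == MISSING or a.reallocated_category == MISSING:
            continue
        counts[idx[_pooled(a.original_category, taxonomy)], idx[_pooled(a.reallocated_category, taxonomy)]] += 1
        n += 1
    if n == 0:
        raise EmptyInputError("no non-missing allocations to tabulate")
    return CrossTab(tuple(levels), tuple(levels), counts)


def flows(allocations: Sequence[Allocation], taxonomy: Taxonomy | None = None) -> list[FlowRecord]:
    """Off-diagonal movements, count-descending; ties broken by the pooled
    reporting order of (from, to)."""
    taxonomy = taxonomy or default_taxonomy()
    levels = taxonomy.reporting_levels()
    order = {lab: i for i, lab in enumerate(levels)}
    tally: dict[tuple[str, str], int] = {}
    for a in allocations:
        if a.original_category == MISSING or a.reallocated_category == MISSING:
            continue
        src = _pooled(a.original_category, taxonomy)
        dst = _pooled(a.reallocated_category, taxonomy)
        if src != dst:
            tally[(src, dst)] = tally.get((src, dst), 0) + 1
    return [
        FlowRecord(src, dst, c)
        for (src, dst), c in sorted(
            tally.items(), key=lambda kv: (-kv[1], order[kv[0][0]], order[kv[0][1]])
        )
    ]


def percent_change(before: int, after: int) -> float:
    """Signed percent change 100*(after-before)/before, rounded half-up to 2 dp."""
    if before == 0:
        raise UndefinedChangeError("percent change undefined for a zero baseline")
    raw = Decimal(100) * (Decimal(after) - Decimal(before)) / Decimal(before)
    return float(raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def pearson_chi_square(ct: CrossTab) -> tuple[float, int]:
    """Pearson chi-square (no continuity correction) and degrees of freedom.

    Expected counts come from the margins; requires every margin positive.
    """
    if (ct.row_totals == 0).any() or (ct.col_totals == 0).any():
        raise DegenerateTableError("zero row or column margin")
    res = stats.chi2_contingency(ct.counts, correction=False)
    return float(res.statistic), int(res.dof)


def chi_square_p_display(statistic: float, df: int, cap: float = 0.001) -> str:
    """Survival-function p-value with a '<.001' display cap."""
    p = float(stats.chi2.sf(statistic, df))
    if p < cap:
        return "<.001"
    return f"{p:.3f}"


def round_sigfigs(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (half-up on the leading digits)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    quantum = Decimal(1).scaleb(exponent - sig + 1)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def combinations(
    allocations: Sequence[Allocation], taxonomy: Taxonomy | None = None
) -> tuple[list[CombinationCount], pd.DataFrame]:
    """Disaggregate the reallocated-multiracial group into identity combinations.

    Returns the combination counts (count-descending, ties broken by canonical
    identity order) and a binary membership matrix (combination x base
    identity) suitable for UpSet rendering.
    """
    taxonomy = taxonomy or default_taxonomy()
    tally: dict[tuple[str, ...], int] = {}
    for a in allocations:
        if a.reallocated_category != MULTIRACIAL:
            continue
        key = taxonomy.sort_identities(a.indicators)
        tally[key] = tally.get(key, 0) + 1
    order = {c: i for i, c in enumerate(taxonomy.canonical_order)}
    combos = [
        CombinationCount(ids, c)
        for ids, c in sorted(
            tally.items(), key=lambda kv: (-kv[1], tuple(order[c] for c in kv[0]))
        )
    ]
    matrix = pd.DataFrame(
        [[code in cc.identities for code in taxonomy.canonical_order] for cc in combos],
        columns=list(taxonomy.canonical_order),
        index=["+".join(cc.identities) for cc in combos],
        dtype=bool,
    )
    matrix["count"] = [cc.count for cc in combos]
    return combos, matrix


def summarize(
    allocations: Sequence[Allocation], taxonomy: Taxonomy | None = None
) -> dict:
    """Machine-readable summary of the full analysis.

    Contains record counts, the cross-tabulation with margins, flows, percent
    changes per category, the chi-square (full precision and 2 significant
    figures, with capped p display), and the multiracial combinations.
    """
    taxonomy = taxonomy or default_taxonomy()
    n_total = len(allocations)
    n_missing = sum(1 for a in allocations if a.reallocated_category == MISSING)
    ct = crosstab(allocations, taxonomy)
    stat, df = pearson_chi_square(ct)
    combos, _ = combinations(allocations, taxonomy)
    multi_label = taxonomy.reporting_label(MULTIRACIAL)
    multiracial_after = int(ct.col_totals[ct.col_labels.index(multi_label)])
    original_multiracial = int(ct.row_totals[ct.row_labels.index(multi_label)])
    return {
        "records": n_total,
        "missing": n_missing,
        "non_missing": n_total - n_missing,
        "reallocated": ct.off_diagonal_total,
        "reallocated_pct_of_non_missing": round(
            100 * ct.off_diagonal_total / ct.grand_total, 2
        ),
        "crosstab": {
            "labels": list(ct.row_labels),
            "counts": ct.counts.tolist(),
            "row_totals": ct.row_totals.tolist(),
            "col_totals": ct.col_totals.tolist(),
            "grand_total": ct.grand_total,
        },
        "flows": [
            {"from": f.from_category, "to": f.to_category, "count": f.count}
            for f in flows(allocations, taxonomy)
        ],
        "percent_changes": {
            lab: percent_change(int(b), int(a))
            for lab, b, a in zip(ct.row_labels, ct.row_totals, ct.col_totals)
            if b > 0
        },
        "chi_square": {
            "statistic": stat,
            "statistic_2sf": round_sigfigs(stat, 2),
            "df": df,
            "p_display": chi_square_p_display(stat, df),
        },
        "combinations": [
            {"identities": list(c.identities), "count": c.count} for c in combos
        ],
        "multiracial_denominators": {
            "reallocated": multiracial_after,
            "original": original_multiracial,
        },
    }
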