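"""Unique/common accounting between two directional differential lists.

Two significant-protein lists (identifier + regulation direction) are
intersected by case-normalized identifier; the shared identifiers are split
into same- and opposite-direction sets and the standard percentages are
reported: the overlap as a percentage of each list and the same-direction
fraction of the overlap. Reported percentages are rounded half away from
zero to one decimal; the exact integer counts are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .containers import ComparisonResult
from .errors import InputError, PlanError


def round1(x: float) -> float:
    """Round to one decimal, half away from zero (matches printed reports)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _normalize(pairs, which: str):
    out = {}
    for ident, direction in pairs:
        key = str(ident).upper()
        if key in out:
            raise InputError(f"duplicate identifier {key!r} in list {which}")
        if direction not in ("up", "down"):
            raise InputError(f"direction must be 'up' or 'down', got {direction!r}")
        out[key] = direction
    return out


@dataclass
class OverlapSummary:
    """Counts and percentages of the overlap between lists A and B."""

    n_a: int
    n_b: int
    n_common: int
    n_same_direction: int
    n_opposite_direction: int
    members: dict = field(default_factory=dict)  # unique_a/unique_b/common_same/common_opposite
    label: str = ""

    @property
    def pct_of_a(self) -> float:
        return round1(100.0 * self.n_common / self.n_a) if self.n_a else 0.0

    @property
    def pct_of_b(self) -> float:
        return round1(100.0 * self.n_common / self.n_b) if self.n_b else 0.0

    @property
    def pct_same_of_common(self) -> float | None:
        if self.n_common == 0:
            return None
        return round1(100.0 * self.n_same_direction / self.n_common)

    def to_row(self) -> dict:
        return {
            "label": self.label, "n_a": self.n_a, "n_b": self.n_b,
            "n_common": self.n_common,
            "n_same_direction": self.n_same_direction,
            "n_opposite_direction": self.n_opposite_direction,
            "pct_of_a": self.pct_of_a, "pct_of_b": self.pct_of_b,
            "pct_same_of_common": self.pct_same_of_common,
            "common_same": ";".join(sorted(self.members.get("common_same", []))),
            "common_opposite": ";".join(sorted(self.members.get("common_opposite", []))),
        }


def overlap_summary(list_a, list_b, label: str = "") -> OverlapSummary:
    """Compare two directional lists of ``(identifier, direction)`` pairs."""
    a = _normalize(list_a, "A")
    b = _normalize(list_b, "B")
    common = sorted(set(a) & set(b))
    same = [g for g in common if a[g] == b[g]]
    opposite = [g for g in common if a[g] != b[g]]
    return OverlapSummary(
        n_a=len(a), n_b=len(b), n_common=len(common),
        n_same_direction=len(same), n_opposite_direction=len(opposite),
        members={
            "unique_a": sorted(set(a) - set(b)),
            "unique_b": sorted(set(b) - set(a)),
            "common_same": same, "common_opposite": opposite,
        },
        label=label,
    )


def significant_list(result: ComparisonResult, by: str = "gene") -> list:
    """Directional list from a comparison's significant proteins.

    Identifiers are gene symbols with accession fallback when the symbol is
    empty (cross-dataset matching is gene-level). If one symbol is hit by
    several protein groups, the entry with the smallest q-value wins.
    """
    sig = result.significant.sort_values("q_value", kind="stable")
    pairs = {}
    for pid, row in sig.iterrows():
        ident = row["gene_name"] if by == "gene" and row["gene_name"] else pid
        ident = str(ident).upper()
        if ident not in pairs:
            pairs[ident] = row["direction"]
    return list(pairs.items())


def overlap_matrix(results: dict, plan) -> pd.DataFrame:
    """One OverlapSummary row per planned pair.

    ``results`` maps comparison names to directional lists (or
    ComparisonResult objects, converted gene-level); ``plan`` is an iterable
    of ``(label, name_a, name_b)``.
    """
    def as_list(name):
        if name not in results:
            raise PlanError(f"pairing references missing comparison {name!r}")
        obj = results[name]
        if isinstance(obj, ComparisonResult):
            return significant_list(obj)
        return obj

    rows = []
    for label, name_a, name_b in plan:
        s = overlap_summary(as_list(name_a), as_list(name_b), label=label)
        row = s.to_row()
        row["comparison_a"] = name_a
        row["comparison_b"] = name_b
        rows.append(row)
    return pd.DataFrame(rows)
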