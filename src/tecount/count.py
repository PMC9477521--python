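"""Aggregation of fragment verdicts into a per-consensus count table."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from tecount.errors import DataError
from tecount.select import FragmentAssignment, Status

TOTAL_KEYS = ("fragments_total", "unmapped", "non_te", "discarded_ambiguous", "te_specific")

_STATUS_TO_KEY = {
    Status.UNMAPPED: "unmapped",
    Status.NON_TE: "non_te",
    Status.DISCARDED_AMBIGUOUS: "discarded_ambiguous",
    Status.TE_SPECIFIC: "te_specific",
}


@dataclass
class CountTable:
    """Per-TE fragment counts plus the totals partition.

    ``counts`` is keyed by TE id in reference order and zero-filled, so
    unexpressed consensus sequences appear explicitly.  ``normalized``
    holds counts-per-million when :func:`normalize_cpm` has been applied.
    """

    counts: dict[str, float]
    totals: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in TOTAL_KEYS}
    )
    normalized: Optional[dict[str, float]] = None

    @property
    def te_mass(self) -> float:
        return sum(self.counts.values())

    @property
    def mapped_fragments(self) -> int:
        t = self.totals
        return t["te_specific"] + t["non_te"] + t["discarded_ambiguous"]


def count(
    assignments: Iterable[FragmentAssignment], te_ids: Sequence[str]
) -> CountTable:
    """Tally a stream of fragment verdicts over the full TE id universe."""
    if not te_ids:
        raise DataError("count() needs at least one TE id")
    table = CountTable(counts={te: 0.0 for te in te_ids})
    totals = table.totals
    counts = table.counts
    for a in assignments:
        totals["fragments_total"] += 1
        totals[_STATUS_TO_KEY[a.status]] += 1
        for te_id, weight in a.assigned:
            if te_id not in counts:
                raise DataError(
                    f"assignment for read '{a.read_id}' names unknown TE id '{te_id}'"
                )
            counts[te_id] += weight
    return table


def normalize_cpm(table: CountTable, denominator: str = "mapped_fragments") -> CountTable:
    """Attach counts-per-million next to the raw counts.

    ``denominator`` is ``te_specific`` or ``mapped_fragments`` (the latter
    = te_specific + non_te + discarded_ambiguous).
    """
    if denominator == "te_specific":
        denom = table.totals["te_specific"]
    elif denominator == "mapped_fragments":
        denom = table.mapped_fragments
    else:
        raise DataError(f"unknown CPM denominator '{denominator}'")
    if denom <= 0:
        raise DataError(
            f"CPM denominator '{denominator}' is zero; report raw counts instead"
        )
    normalized = {te: c / denom * 1e6 for te, c in table.counts.items()}
    return CountTable(counts=dict(table.counts), totals=dict(table.totals),
                      normalized=normalized)


def format_count(x: float) -> str:
    """Integers print bare; fractional counts print with 6 decimals."""
    if float(x).is_integer():
        return str(int(x))
    return f"{x:.6f}"


def write_counts(table: CountTable, path: Union[str, Path]) -> None:
    with open(path, "wt") as out:
        header = "te_id\tcount"
        if table.normalized is not None:
            header += "\tcpm"
        out.write(header + "\n")
        for te, c in table.counts.items():
            row = f"{te}\t{format_count(c)}"
            if table.normalized is not None:
                row += f"\t{table.normalized[te]:.6f}"
            out.write(row + "\n")


def write_totals(table: CountTable, path: Union[str, Path]) -> None:
    with open(path, "wt") as out:
        out.write("metric\tvalue\n")
        for key in TOTAL_KEYS:
            out.write(f"{key}\t{table.totals[key]}\n")
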