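"""Best-score arbitration: the core filtering rule of the pipeline.

Per fragment, keep only the placements achieving the maximum score.  If
that best set contains any non-TE reference (coding, non-coding or mask),
the fragment cannot be attributed to autonomous TE transcription and is
excluded from TE counting — either as NON_TE (no TE in the best set) or
DISCARDED_AMBIGUOUS (TE and non-TE tie).  Only fragments whose best set is
purely TE are counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Optional, Sequence

from tecount.align import FragmentAlignments, Placement
from tecount.errors import DataError
from tecount.reference import Category


class Status(str, Enum):
    TE_SPECIFIC = "TE_SPECIFIC"
    DISCARDED_AMBIGUOUS = "DISCARDED_AMBIGUOUS"
    NON_TE = "NON_TE"
    UNMAPPED = "UNMAPPED"


class Policy(str, Enum):
    """How to split weight when a fragment ties across several TE ids."""

    FRACTIONAL = "fractional"
    FIRST_ID = "first_id"


@dataclass(frozen=True)
class FragmentAssignment:
    read_id: str
    status: Status
    assigned: tuple[tuple[str, float], ...] = ()
    best_score: Optional[int] = None


def select_best(frag: FragmentAlignments) -> list[Placement]:
    """Exactly the placements achieving the fragment's maximum score."""
    if not frag.placements:
        return []
    best = max(p.score for p in frag.placements)
    return [p for p in frag.placements if p.score == best]


def resolve_multi_te(
    te_ids: Sequence[str], policy: Policy = Policy.FRACTIONAL
) -> tuple[tuple[str, float], ...]:
    """Assignment weights over the distinct TE ids of a best set.

    Distinct-id collapse happens first: several placements on the same
    consensus still count once.  ``fractional`` gives 1/k to each of the k
    ids (count-mass preserving); ``first_id`` gives everything to the
    lexicographically smallest id (integer-exact, deterministic).
    """
    distinct = sorted(set(te_ids))
    if not distinct:
        raise DataError("resolve_multi_te called with no TE placements")
    if Policy(policy) is Policy.FIRST_ID:
        return ((distinct[0], 1.0),)
    w = 1.0 / len(distinct)
    return tuple((te, w) for te in distinct)


def classify(
    best: Sequence[Placement],
    category_of: Callable[[str], Category],
    read_id: str = "",
    policy: Policy = Policy.FRACTIONAL,
) -> FragmentAssignment:
    """Turn a best-score placement set into a fragment verdict."""
    if not best:
        return FragmentAssignment(read_id, Status.UNMAPPED)
    best_score = best[0].score
    te_ids = []
    has_non_te = False
    for p in best:
        cat = category_of(p.ref_id)
        if cat is Category.TE:
            te_ids.append(p.ref_id)
        else:
            has_non_te = True
    if te_ids and has_non_te:
        return FragmentAssignment(read_id, Status.DISCARDED_AMBIGUOUS, best_score=best_score)
    if not te_ids:
        return FragmentAssignment(read_id, Status.NON_TE, best_score=best_score)
    assigned = resolve_multi_te(te_ids, policy)
    return FragmentAssignment(read_id, Status.TE_SPECIFIC, assigned, best_score)


def assign_fragment(
    frag: FragmentAlignments,
    category_of: Callable[[str], Category],
    policy: Policy = Policy.FRACTIONAL,
    sense_only: bool = False,
) -> FragmentAssignment:
    """select_best + classify in one step, with optional strand filtering.

    ``sense_only`` restricts eligible placements to fragments oriented in
    the reference sense ('+' first mate) before best-score selection.
    """
    if sense_only:
        frag = FragmentAlignments(
            frag.read_id, frag.paired, [p for p in frag.placements if p.strand == "+"]
        )
    return classify(select_best(frag), category_of, frag.read_id, policy)
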