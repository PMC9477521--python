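"""End-to-end quantification: FASTQ/SAM in, count table + audit out.

Glue between the aligner, the best-score arbitration and the counter; both
the CLI and the validation harness drive the pipeline through here.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Union

from tecount.align import Aligner, AlignParams, read_sam
from tecount.count import CountTable, count
from tecount.errors import DataError
from tecount.reference import ReferenceSet
from tecount.select import FragmentAssignment, Policy, assign_fragment

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

LOG_EVERY = 100_000


def iter_fastq(path: PathLike) -> Iterator[tuple[str, str]]:
    """Minimal 4-line FASTQ reader yielding (name, sequence)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fq:
        while True:
            header = fq.readline()
            if not header:
                break
            seq = fq.readline().rstrip("\n")
            plus = fq.readline()
            qual = fq.readline()
            if not qual:
                raise DataError(f"truncated FASTQ record at end of '{path}'")
            if not header.startswith("@") or not plus.startswith("+"):
                raise DataError(f"malformed FASTQ record near '{header.strip()}' in '{path}'")
            yield header[1:].split()[0].rstrip("\n"), seq.upper()


@dataclass
class QuantifyResult:
    table: CountTable
    assignments: list[FragmentAssignment] = field(default_factory=list)


def quantify(
    ref: ReferenceSet,
    fastq: Optional[PathLike] = None,
    fastq2: Optional[PathLike] = None,
    sam: Optional[PathLike] = None,
    params: Optional[AlignParams] = None,
    policy: Policy = Policy.FRACTIONAL,
    sense_only: bool = False,
    keep_assignments: bool = True,
) -> QuantifyResult:
    """Run the full pipeline on one sample.

    Exactly one of ``fastq`` (with optional ``fastq2`` for pairs) or
    ``sam`` must be given.  Raises :class:`DataError` if the reference has
    no TE records.
    """
    te_ids = ref.te_ids()
    if not te_ids:
        raise DataError("reference set contains no TE records")
    if (fastq is None) == (sam is None):
        raise DataError("provide exactly one of FASTQ or SAM input")
    category_of = ref.category_of
    assignments: list[FragmentAssignment] = []
    n = 0

    def _assign_all() -> Iterator[FragmentAssignment]:
        nonlocal n
        if sam is not None:
            frags = read_sam(sam, ref)
            for frag in frags:
                yield assign_fragment(frag, category_of, policy, sense_only)
                n += 1
                if n % LOG_EVERY == 0:
                    log.info("processed %d fragments", n)
        else:
            aligner = Aligner(ref, params)
            if fastq2 is not None:
                it2 = iter_fastq(fastq2)
                for (name1, seq1), (name2, seq2) in zip(iter_fastq(fastq), it2):
                    base1 = name1.rsplit("/", 1)[0]
                    if base1 != name2.rsplit("/", 1)[0]:
                        raise DataError(
                            f"mate name mismatch: '{name1}' vs '{name2}'"
                        )
                    frag = aligner.align_fragment(base1, seq1, seq2)
                    yield assign_fragment(frag, category_of, policy, sense_only)
                    n += 1
                    if n % LOG_EVERY == 0:
                        log.info("processed %d fragments", n)
            else:
                for name, seq in iter_fastq(fastq):
                    frag = aligner.align_fragment(name, seq)
                    yield assign_fragment(frag, category_of, policy, sense_only)
                    n += 1
                    if n % LOG_EVERY == 0:
                        log.info("processed %d fragments", n)

    def _tee() -> Iterator[FragmentAssignment]:
        for a in _assign_all():
            if keep_assignments:
                assignments.append(a)
            yield a

    table = count(_tee(), te_ids)
    log.info(
        "done: %d fragments (%d TE-specific, %d discarded-ambiguous, %d non-TE, %d unmapped)",
        table.totals["fragments_total"], table.totals["te_specific"],
        table.totals["discarded_ambiguous"], table.totals["non_te"],
        table.totals["unmapped"],
    )
    return QuantifyResult(table=table, assignments=assignments)


def write_audit(assignments, path: PathLike) -> None:
    """Per-fragment audit trail: read_id, status, best score, assignments."""
    with open(path, "wt") as out:
        out.write("read_id\tstatus\tbest_score\tassigned\n")
        for a in assignments:
            score = "" if a.best_score is None else str(a.best_score)
            assigned = ",".join(f"{te}:{w:g}" for te, w in a.assigned)
            out.write(f"{a.read_id}\t{a.status.value}\t{score}\t{assigned}\n")
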