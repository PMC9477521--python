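"""Joint reference construction: TE consensus + coding/non-coding transcripts.

The reference is a flat collection of already-spliced sequences.  Every
record carries a category tag that drives the read-arbitration step:
reads whose best placements touch any non-TE record (CODING, NONCODING or
MASK) are excluded from TE counts downstream.  Categories are stored in a
TSV sidecar next to the FASTA, never encoded in FASTA headers.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

from Bio import SeqIO

from tecount.errors import DataError

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

_VALID_BASES = frozenset("ACGTN")
_FOLD = str.maketrans("acgtnuU", "ACGTNTT")
FASTA_WRAP = 60


class Category(str, Enum):
    """Role of a reference record in read arbitration."""

    TE = "TE"
    CODING = "CODING"
    NONCODING = "NONCODING"
    MASK = "MASK"

    @property
    def is_te(self) -> bool:
        return self is Category.TE


NON_TE_CATEGORIES = frozenset({Category.CODING, Category.NONCODING, Category.MASK})


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference sequence with an immutable category tag."""

    id: str
    sequence: str
    category: Category

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(raw: str, rec_id: str) -> str:
    """Uppercase, fold U->T, reject anything outside {A,C,G,T,N}."""
    seq = raw.translate(_FOLD).upper().replace("U", "T")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise DataError(
            f"record '{rec_id}' contains invalid characters {sorted(bad)}; "
            "only A/C/G/T/N (and lowercase / U) are accepted"
        )
    if not seq:
        raise DataError(f"record '{rec_id}' has a zero-length sequence")
    return seq


class ReferenceSet:
    """Ordered, id-unique collection of :class:`ReferenceRecord`."""

    def __init__(self, records: Iterable[ReferenceRecord]):
        self.records: list[ReferenceRecord] = []
        self.by_id: dict[str, ReferenceRecord] = {}
        for rec in records:
            prev = self.by_id.get(rec.id)
            if prev is not None:
                raise DataError(
                    f"duplicate reference id '{rec.id}': first seen with category "
                    f"{prev.category.value}, seen again with category {rec.category.value}"
                )
            self.records.append(rec)
            self.by_id[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self.records)

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self.by_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceSet):
            return NotImplemented
        return self.records == other.records

    def category_of(self, rec_id: str) -> Category:
        try:
            return self.by_id[rec_id].category
        except KeyError:
            raise DataError(f"unknown reference id '{rec_id}'") from None

    def sequence_of(self, rec_id: str) -> str:
        return self.by_id[rec_id].sequence

    def te_ids(self) -> list[str]:
        """TE record ids in reference order."""
        return [r.id for r in self.records if r.category is Category.TE]

    def non_te_ids(self) -> list[str]:
        return [r.id for r in self.records if r.category is not Category.TE]

    def subset(self, categories: Iterable[Category]) -> "ReferenceSet":
        wanted = set(categories)
        return ReferenceSet(r for r in self.records if r.category in wanted)

    def merged_with(self, other: "ReferenceSet") -> "ReferenceSet":
        return ReferenceSet(list(self.records) + list(other.records))


def _open_text(path: PathLike) -> IO[str]:
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, "rt")
    return open(p, "rt")


def read_fasta_records(path: PathLike, category: Category) -> list[ReferenceRecord]:
    """Parse a (optionally gzipped) FASTA into categorized records.

    Headers are truncated at the first whitespace; the remainder is dropped
    with a warning, matching common aligner behaviour.
    """
    records: list[ReferenceRecord] = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.description != rec.id and rec.description.strip() != rec.id:
                log.warning(
                    "FASTA header for '%s' truncated at first whitespace "
                    "(dropped: %r)", rec.id, rec.description[len(rec.id):].strip()
                )
            seq = normalize_sequence(str(rec.seq), rec.id)
            records.append(ReferenceRecord(rec.id, seq, category))
    return records


def build_reference(
    te_fasta: PathLike,
    cdna_fasta: Optional[PathLike] = None,
    ncrna_fasta: Optional[PathLike] = None,
    mask_fasta: Optional[PathLike] = None,
) -> ReferenceSet:
    """Assemble the joint reference: TE records first, then coding,
    non-coding and mask records, in source-file order.

    Raises :class:`DataError` on duplicate ids (within or across files),
    an empty TE FASTA, zero-length sequences or invalid characters.
    """
    te_records = read_fasta_records(te_fasta, Category.TE)
    if not te_records:
        raise DataError(f"TE FASTA '{te_fasta}' contains no records")
    records = list(te_records)
    if cdna_fasta is not None:
        records += read_fasta_records(cdna_fasta, Category.CODING)
    if ncrna_fasta is not None:
        records += read_fasta_records(ncrna_fasta, Category.NONCODING)
    if mask_fasta is not None:
        records += read_fasta_records(mask_fasta, Category.MASK)
    return ReferenceSet(records)


def sidecar_path(fasta_path: PathLike) -> Path:
    return Path(str(fasta_path) + ".categories.tsv")


def write_reference(ref: ReferenceSet, out_path: PathLike) -> Path:
    """Serialize to ``out_path`` (60-column FASTA) plus a TSV sidecar
    (id, category, length — the single source of truth for categories)."""
    if len(ref) == 0:
        raise DataError("refusing to write an empty reference set")
    out_path = Path(out_path)
    try:
        with open(out_path, "wt") as fa:
            for rec in ref:
                fa.write(f">{rec.id}\n")
                for i in range(0, len(rec.sequence), FASTA_WRAP):
                    fa.write(rec.sequence[i : i + FASTA_WRAP] + "\n")
        with open(sidecar_path(out_path), "wt") as tsv:
            for rec in ref:
                tsv.write(f"{rec.id}\t{rec.category.value}\t{len(rec)}\n")
    except OSError as exc:
        raise DataError(f"cannot write reference to '{out_path}': {exc}") from exc
    return out_path


def read_reference(fasta_path: PathLike, sidecar: Optional[PathLike] = None) -> ReferenceSet:
    """Inverse of :func:`write_reference`: FASTA + sidecar -> ReferenceSet."""
    sidecar = Path(sidecar) if sidecar is not None else sidecar_path(fasta_path)
    categories: dict[str, Category] = {}
    with _open_text(sidecar) as tsv:
        for lineno, line in enumerate(tsv, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise DataError(f"{sidecar}:{lineno}: expected 3 columns, got {len(fields)}")
            categories[fields[0]] = Category(fields[1])
    records = []
    with _open_text(fasta_path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id not in categories:
                raise DataError(f"record '{rec.id}' missing from category sidecar {sidecar}")
            seq = normalize_sequence(str(rec.seq), rec.id)
            records.append(ReferenceRecord(rec.id, seq, categories[rec.id]))
    return ReferenceSet(records)
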