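"""Read simulation with known ground truth.

Two regimes back the validation harness:

* regime A — reads drawn from TE consensus sequences with a known
  per-consensus fragment count (the truth table), used to measure how well
  the pipeline recovers relative expression;
* regime B — reads drawn from synthetic canonical transcripts that embed
  TE-derived fragments, for which true autonomous TE expression is zero by
  construction, used to audit false positives from exonized fragments.

Everything is substitution-only (no indels), deterministic under the seed,
and written as plain Phred+33 FASTQ with constant quality.  Read names
carry the ground truth (source id, coordinates, strand) in the style of
standard read simulators.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Optional, Sequence, Union

import numpy as np

from tecount.errors import DataError
from tecount.reference import Category, ReferenceRecord, ReferenceSet

PathLike = Union[str, Path]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    read_length: int = 50
    paired: bool = False
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.001
    seed: int = 0
    n_consensus: int = 50
    consensus_length_range: tuple[int, int] = (300, 6000)
    # truth-count law: log-uniform on [count_low, count_high] with a fixed
    # zero-inflation mass, optionally rescaled to a target total
    count_low: int = 1
    count_high: int = 1000
    zero_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate <= 0.1):
            raise DataError("error_rate must lie in [0, 0.1]")
        if self.consensus_length_range[0] < self.read_length:
            raise DataError(
                "consensus_length_range minimum is below read_length; "
                "reads could not be drawn"
            )


@dataclass(frozen=True)
class ExonizedFragment:
    """One TE-derived fragment embedded in a synthetic transcript."""

    transcript_id: str
    te_source_id: str
    te_start: int  # half-open interval on the TE consensus
    te_end: int
    tx_start: int  # half-open interval on the transcript
    tx_end: int
    identity: float  # fraction of unmutated bases after divergence


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently at ``rate``; never to itself."""
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


_RC = bytes.maketrans(b"ACGTN", b"TGCAN")


def _revcomp(seq: str) -> str:
    return seq.encode().translate(_RC)[::-1].decode()


def make_consensus_set(cfg: SimConfig) -> ReferenceSet:
    """Generate ``n_consensus`` random TE consensus sequences (TE0001...).

    Stands in for curated consensus libraries; the arbitration logic under
    test is sequence-content-agnostic.
    """
    if cfg.n_consensus < 1:
        raise DataError("n_consensus must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.consensus_length_range
    records = []
    for i in range(cfg.n_consensus):
        length = int(rng.integers(lo, hi + 1))
        records.append(
            ReferenceRecord(f"TE{i + 1:04d}", _random_seq(rng, length), Category.TE)
        )
    return ReferenceSet(records)


def draw_truth_counts(
    te_ids: Sequence[str],
    cfg: SimConfig,
    target_total: Optional[int] = None,
) -> dict[str, int]:
    """Log-uniform truth counts with zero inflation.

    With ``target_total`` the drawn counts are rescaled (keeping zeros at
    zero) so they sum approximately to the requested read total.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    lo, hi = np.log10(cfg.count_low), np.log10(cfg.count_high)
    counts = {}
    for te in te_ids:
        if rng.random() < cfg.zero_fraction:
            counts[te] = 0
        else:
            counts[te] = int(round(10 ** rng.uniform(lo, hi)))
    if target_total is not None:
        total = sum(counts.values())
        if total > 0:
            scale = target_total / total
            counts = {te: int(round(c * scale)) for te, c in counts.items()}
    return counts


def _open_out(path: PathLike) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "wt")


class _FastqWriter:
    def __init__(self, path: PathLike):
        self.handle = _open_out(path)

    def write(self, name: str, seq: str) -> None:
        self.handle.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")

    def close(self) -> None:
        self.handle.close()


def _emit_fragment(
    rng: np.random.Generator,
    cfg: SimConfig,
    source: ReferenceRecord,
    serial: int,
    w1: _FastqWriter,
    w2: Optional[_FastqWriter],
) -> None:
    seq = source.sequence
    length = len(seq)
    rl = min(cfg.read_length, length)  # spans truncated to feasibility
    if cfg.paired and w2 is not None:
        insert = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
        insert = max(rl, min(insert, length))
        start = int(rng.integers(0, length - insert + 1))
        end = start + insert
        fwd = rng.random() < 0.5
        r1 = seq[start : start + rl]
        r2 = _revcomp(seq[end - rl : end])
        if not fwd:
            r1, r2 = _revcomp(seq[end - rl : end]), seq[start : start + rl]
        strand = "+" if fwd else "-"
        name = f"{source.id}:{start}:{end}:{strand}:{serial}"
        w1.write(name, _mutate(rng, r1, cfg.error_rate))
        w2.write(name, _mutate(rng, r2, cfg.error_rate))
    else:
        start = int(rng.integers(0, length - rl + 1))
        fwd = rng.random() < 0.5
        read = seq[start : start + rl]
        strand = "+"
        if not fwd:
            read = _revcomp(read)
            strand = "-"
        name = f"{source.id}:{start}:{start + rl}:{strand}:{serial}"
        w1.write(name, _mutate(rng, read, cfg.error_rate))


def simulate_te_reads(
    consensus: ReferenceSet,
    cfg: SimConfig,
    out_prefix: PathLike,
    truth: Optional[dict[str, int]] = None,
    target_total: Optional[int] = None,
) -> tuple[list[Path], dict[str, int]]:
    """Regime A: per-consensus reads at known truth counts.

    Returns the FASTQ path(s) and the truth table; the FASTQ read-name
    census matches the truth table exactly.
    """
    for rec in consensus:
        if rec.category is not Category.TE:
            raise DataError(f"record '{rec.id}' is not a TE consensus")
    if truth is None:
        truth = draw_truth_counts([r.id for r in consensus], cfg, target_total)
    else:
        unknown = set(truth) - {r.id for r in consensus}
        if unknown:
            raise DataError(f"truth table names unknown consensus ids {sorted(unknown)}")
    rng = np.random.default_rng(cfg.seed + 2)
    out_prefix = Path(out_prefix)
    if cfg.paired:
        paths = [Path(f"{out_prefix}_1.fastq"), Path(f"{out_prefix}_2.fastq")]
        w1, w2 = _FastqWriter(paths[0]), _FastqWriter(paths[1])
    else:
        paths = [Path(f"{out_prefix}.fastq")]
        w1, w2 = _FastqWriter(paths[0]), None
    serial = 0
    for rec in consensus:
        for _ in range(truth.get(rec.id, 0)):
            _emit_fragment(rng, cfg, rec, serial, w1, w2)
            serial += 1
    w1.close()
    if w2 is not None:
        w2.close()
    return paths, dict(truth)


def build_exonized_transcriptome(
    consensus: ReferenceSet,
    cfg: SimConfig,
    n_transcripts: int,
    frags_per_transcript: int,
    frag_length_range: tuple[int, int],
    frag_divergence: float = 0.0,
    backbone_length_range: tuple[int, int] = (500, 3000),
    coding_fraction: float = 0.5,
    exonized_fraction: float = 1.0,
) -> tuple[ReferenceSet, list[ExonizedFragment]]:
    """Regime B material: synthetic transcripts with embedded TE fragments.

    Each transcript is a random backbone; with probability
    ``exonized_fraction`` it receives 1..frags_per_transcript fragments
    copied from random consensus intervals, mutated at ``frag_divergence``
    and inserted at random backbone positions.  Every insertion is recorded
    in the annotation.  Transcripts are labelled CODING or NONCODING at
    ``coding_fraction``.
    """
    min_cons = min(len(r.sequence) for r in consensus.records)
    if frag_length_range[1] > min_cons:
        raise DataError(
            "frag_length_range maximum exceeds the shortest consensus length"
        )
    rng = np.random.default_rng(cfg.seed + 3)
    te_records = list(consensus.records)
    records: list[ReferenceRecord] = []
    annotation: list[ExonizedFragment] = []
    for i in range(n_transcripts):
        tx_id = f"TX{i + 1:04d}"
        backbone = _random_seq(
            rng, int(rng.integers(backbone_length_range[0], backbone_length_range[1] + 1))
        )
        n_frags = 0
        if frags_per_transcript > 0 and rng.random() < exonized_fraction:
            n_frags = int(rng.integers(1, frags_per_transcript + 1))
        # insertion points chosen in backbone coordinates up front, so
        # fragments never nest inside each other
        points = sorted(int(p) for p in rng.integers(0, len(backbone) + 1, size=n_frags))
        pieces: list[str] = []
        cursor = 0  # backbone position consumed so far
        offset = 0  # length added by fragments so far
        for pos in points:
            src = te_records[int(rng.integers(0, len(te_records)))]
            flen = int(rng.integers(frag_length_range[0], frag_length_range[1] + 1))
            te_start = int(rng.integers(0, len(src.sequence) - flen + 1))
            fragment = src.sequence[te_start : te_start + flen]
            mutated = _mutate(rng, fragment, frag_divergence)
            identity = sum(a == b for a, b in zip(fragment, mutated)) / flen
            pieces.append(backbone[cursor:pos])
            pieces.append(mutated)
            tx_start = pos + offset
            annotation.append(
                ExonizedFragment(tx_id, src.id, te_start, te_start + flen,
                                 tx_start, tx_start + flen, identity)
            )
            cursor = pos
            offset += flen
        pieces.append(backbone[cursor:])
        category = Category.CODING if rng.random() < coding_fraction else Category.NONCODING
        records.append(ReferenceRecord(tx_id, "".join(pieces), category))
    return ReferenceSet(records), annotation


def simulate_transcript_reads(
    transcripts: ReferenceSet,
    cfg: SimConfig,
    depth: int,
    out_prefix: PathLike,
) -> list[Path]:
    """Regime B: ``depth`` fragments sampled uniformly across transcripts.

    Read names encode the source transcript and coordinates — never a TE
    id — so true autonomous TE expression for these reads is zero.
    """
    if len(transcripts) == 0:
        raise DataError("no transcripts to simulate from")
    rng = np.random.default_rng(cfg.seed + 4)
    recs = list(transcripts.records)
    out_prefix = Path(out_prefix)
    if cfg.paired:
        paths = [Path(f"{out_prefix}_1.fastq"), Path(f"{out_prefix}_2.fastq")]
        w1, w2 = _FastqWriter(paths[0]), _FastqWriter(paths[1])
    else:
        paths = [Path(f"{out_prefix}.fastq")]
        w1, w2 = _FastqWriter(paths[0]), None
    for serial in range(depth):
        src = recs[int(rng.integers(0, len(recs)))]
        _emit_fragment(rng, cfg, src, serial, w1, w2)
    w1.close()
    if w2 is not None:
        w2.close()
    return paths


def truth_from_fastq(path: PathLike) -> dict[str, int]:
    """Census of source ids parsed from simulator read names."""
    counts: dict[str, int] = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fq:
        for i, line in enumerate(fq):
            if i % 4 == 0:
                src = line[1:].split(":", 1)[0]
                counts[src] = counts.get(src, 0) + 1
    return counts


def write_truth(truth: dict[str, int], path: PathLike) -> None:
    with open(path, "wt") as out:
        out.write("te_id\ttruth_count\n")
        for te, c in truth.items():
            out.write(f"{te}\t{c}\n")


def read_truth(path: PathLike) -> dict[str, int]:
    truth = {}
    with open(path, "rt") as fh:
        next(fh)
        for line in fh:
            te, c = line.rstrip("\n").split("\t")
            truth[te] = int(c)
    return truth


def write_annotation(annotation: Sequence[ExonizedFragment], path: PathLike) -> None:
    with open(path, "wt") as out:
        out.write("transcript_id\tte_source_id\tte_start\tte_end\ttx_start\ttx_end\tidentity\n")
        for f in annotation:
            out.write(
                f"{f.transcript_id}\t{f.te_source_id}\t{f.te_start}\t{f.te_end}"
                f"\t{f.tx_start}\t{f.tx_end}\t{f.identity:.4f}\n"
            )
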