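"""Shared fixtures: tiny FASTA/FASTQ builders and the two-read worked example."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from tecount.reference import Category, ReferenceRecord, ReferenceSet

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def write_fasta(path: Path, records: dict[str, str], wrap: int = 60) -> Path:
    with open(path, "wt") as out:
        for name, seq in records.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                out.write(seq[i : i + wrap] + "\n")
    return path


def write_fastq(path: Path, reads: list[tuple[str, str]]) -> Path:
    with open(path, "wt") as out:
        for name, seq in reads:
            out.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


def make_ref(**records_by_category) -> ReferenceSet:
    """make_ref(TE={"TE1": seq}, CODING={"G1": seq}) -> ReferenceSet."""
    records = []
    for cat_name, mapping in records_by_category.items():
        for rec_id, seq in mapping.items():
            records.append(ReferenceRecord(rec_id, seq, Category[cat_name]))
    return ReferenceSet(records)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def worked_example(rng):
    """One TE consensus and one gene sharing an exact embedded TE segment,
    plus two reads: one interior to the shared segment (must tie and be
    discarded) and one TE-only (must be counted)."""
    te_seq = random_dna(rng, 300)
    backbone = random_dna(rng, 400)
    gene_seq = backbone[:200] + te_seq[100:200] + backbone[200:]
    ref = make_ref(TE={"TE1": te_seq}, CODING={"G1": gene_seq})
    read_discard = te_seq[120:170]  # interior of the embedded segment
    read_te = te_seq[0:50]  # outside the embedded segment
    return {
        "ref": ref,
        "te_seq": te_seq,
        "gene_seq": gene_seq,
        "reads": [("read_discard", read_discard), ("read_te", read_te)],
    }


@pytest.fixture
def worked_example_files(worked_example, tmp_path):
    te_fasta = write_fasta(tmp_path / "te.fasta", {"TE1": worked_example["te_seq"]})
    cdna_fasta = write_fasta(tmp_path / "cdna.fasta", {"G1": worked_example["gene_seq"]})
    fastq = write_fastq(tmp_path / "reads.fastq", worked_example["reads"])
    return {"te": te_fasta, "cdna": cdna_fasta, "fastq": fastq, "dir": tmp_path}
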