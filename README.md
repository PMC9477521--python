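# tecount

Consensus-level quantification of transposable-element (TE) expression from
short RNA-seq reads. The pipeline's distinguishing rule: a fragment is
counted toward a TE consensus only if **all** of its best-scoring alignments
land on TE sequences. Fragments whose best-score set also touches any
annotated coding/non-coding transcript (or a user-supplied mask sequence
such as a retained intron) are discarded, so passively transcribed TE
fragments exonized into canonical transcripts never inflate TE counts.

The package also ships the validation harness: a deterministic read
simulator with known per-consensus truth counts (regime A, truth-recovery
correlation) and an exonized-transcript generator for which true TE
expression is zero by construction (regime B, null audit).

## Layout

| module | responsibility |
| --- | --- |
| `tecount.reference` | joint reference construction (TE + cDNA + ncRNA + mask FASTA), validation, FASTA + category-sidecar serialization |
| `tecount.align` | deterministic ungapped seed-and-extend aligner (match +1 / mismatch −1), brute-force oracle, SAM ingestion (`AS` tag scores) |
| `tecount.select` | best-score selection and fragment classification (TE-specific / discarded-ambiguous / non-TE / unmapped), multi-TE tie policies |
| `tecount.count` | per-consensus count table, totals partition, optional CPM |
| `tecount.simulate` | consensus generation, truth-count read simulation, exonized-transcript construction, transcript read simulation |
| `tecount.evaluate` | tie-corrected Spearman correlation, null-expression audit |
| `tecount.pipeline` / `tecount.cli` | end-to-end runs and the command-line interface |

## CLI

```sh
# build and serialize a joint reference
tecount build-ref --TE te.fasta --cdna cdna.fasta --ncrna ncrna.fasta \
    --mask introns.fasta --out reference.fasta

# quantify one sample from FASTQ (internal aligner) ...
tecount quantify --TE te.fasta --cdna cdna.fasta --sample reads.fastq --out run/

# ... or from externally produced alignments (SAM with AS tags)
tecount quantify --TE te.fasta --cdna cdna.fasta --sam aligned.sam --out run/

# paired-end, sense-stranded, integer-exact tie policy
tecount quantify --TE te.fasta --cdna cdna.fasta --paired \
    --sample r1.fastq --sample r2.fastq --strand sense --policy first_id --out run/

# simulate reads with known ground truth
tecount simulate --regime te --seed 1 --out sim/          # truth-count reads
tecount simulate --regime exonized --seed 1 --out sim/    # null-experiment reads

# run both validation regimes end to end
tecount validate --seed 1 --out validation/
```

`quantify` writes `counts.tsv` (per-TE fragment counts), `totals.tsv`
(fragments_total / unmapped / non_te / discarded_ambiguous / te_specific),
`audit.tsv` (per-fragment verdicts) and `run.log`. Exit codes: 0 success,
1 usage error, 2 data error; partial outputs are removed on failure.

## Notes

- The aligner is ungapped and substitution-only by design; its per-read
  seed length is chosen so that every placement at or above the score
  threshold (default 0.9 × read length per mate) is provably found, which
  makes it exactly equivalent to the brute-force oracle on the reported set.
- Fragments tying across several TE consensus sequences are split
  fractionally by default (`--policy fractional`); `first_id` assigns the
  whole fragment to the lexicographically smallest TE id instead.
- Mask sequences behave exactly like coding/non-coding transcripts during
  arbitration; they are a separate category for reporting only.
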