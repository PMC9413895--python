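# retroquant

Locus-resolved quantification of LINE-1 (and LTR) retrotransposon mRNA
expression from 3'-tagged single-cell RNA-seq, cross-validated against bulk
RNA-seq locus lists — with a synthetic-data generator so every stage is
testable without external downloads.

## The problem

Measuring which *individual* L1 loci are transcribed is hard: the human
genome carries thousands of near-identical copies, so a short read rarely
identifies its source copy, and most L1 sequence in RNA-seq arrives
*passively* inside other genes' transcripts (introns, 3' UTRs) rather than
from the element's own promoter. Droplet 3' single-cell chemistry makes it
harder still — reads pile up at transcript 3' ends and the 5' promoter
context is invisible.

`retroquant` implements the strict strategy for this regime:

1. **Tag** — the cell barcode and UMI from read 1 are moved into the read
   name of the genomic read (read 2) so they survive alignment.
2. **Align uniquely** — ungapped alignment reporting a read only when
   exactly one placement attains the minimum Hamming distance (≤ 3
   mismatches) over *all* positions on both strands; any tie is discarded.
   This mirrors the classic `-m 1 -y -v 3` short-read settings: multi-mapped
   reads are sacrificed for locus specificity.
3. **Deduplicate** — positional PCR dedup (one read per identical alignment
   coordinate), then barcode-UMI dedup keeping one random representative
   per (barcode, UMI) pair.
4. **Demux** — split by cell barcode; optionally classify cells by a marker
   locus and filter on mitochondrial read fraction (< 5%, strict).
5. **Quantify** — strand-separated counting: a read supports a locus only
   when it overlaps the interval *in the locus orientation*. Supervised
   mode counts only loci validated as expressed in matched bulk RNA-seq;
   unsupervised mode counts everything and so retains the passive
   background. Normalization uses

   `RPM(z) = reads(z) / million mapped reads in the cell cluster` and
   `FPKM(z) = reads(z) / (million mapped reads in the sample × 6)`

   with 6 kb the canonical full-length L1 length.

A bulk module adds paired-end concordant quantification (FR pairs, span
≤ 600 bp), the LTR inclusion rule (> 2 kb and ≥ 10 reads), shared-locus set
comparison, FPKM–RPM Pearson correlation and a per-cell read-downsampling
experiment; `retroquant.simulate` generates the small genome with diverged
repeat copies, authentic vs read-through transcripts, 3'-biased barcoded
reads, PCR duplicates and a complete truth ledger used by the test suite.

## Worked example

```python
from retroquant import (SimConfig, build_genome, simulate_cells, UniqueAligner,
                        GenomeAlignment, dedup_pipeline, split_by_barcode,
                        quantify_supervised, expressed_loci)

cfg = SimConfig(seed=1, genome_length=150_000, n_repeat_copies=16,
                n_expressed=5, n_passive=5, n_cells=30, reads_per_cell=400)
genome = build_genome(cfg)
reads = simulate_cells(cfg, genome)

aligner = UniqueAligner(genome.ref, max_mismatch=3)
alignments = []
for (rid, r1, _), (_, r2, _) in zip(reads.r1, reads.r2):
    hit = aligner.align(r2)
    if hit:
        chrom, start, strand, nm = hit
        alignments.append(GenomeAlignment(rid, r1[:16], r1[16:], chrom,
                                          start, strand, nm, cfg.read_len))
deduped, report = dedup_pipeline(alignments, seed=17)
cells = split_by_barcode(deduped)
matrix = quantify_supervised(cells, genome.repeat_loci, genome.validated_ids,
                             reads.cluster_of)
sample_set, per_cell = expressed_loci(matrix, scope="sample")
print(report)
print(sorted(sample_set))
print(round(per_cell.mean(), 2))
```

prints

```
DedupReport(input_count=13850, after_positional=8671, after_umi=8671, rng_seed=17)
['L1_002', 'L1_003', 'L1_004', 'L1_005', 'L1_006']
4.53
```

— 13,850 uniquely aligned reads collapse to 8,671 unique coordinates
(coordinate dedup removes both PCR copies and coincident molecules, so the
barcode-UMI stage finds nothing further here), the five planted
authentically expressed loci (and no others) are called expressed at sample
scope, and an average cell detects 4.53 of them.

The same flow is available from the shell (`retroquant simulate / tag /
align / dedup / demux / quant / bulk / compare / downsample / run`), with
`retroquant run --config run.yaml` executing the whole pipeline from one
config file.

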