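# Methods

## The quantification model

`retroquant` measures transcription of individual retrotransposon loci
under two deliberately conservative rules:

* **Unique best alignment.** A read is placed only when exactly one
  position (over all positions, both strands) attains the minimum Hamming
  distance, at most `max_mismatch` (default 3) substitutions; gaps are not
  modeled and base qualities are ignored. Any tie at the minimum — including
  the same position on opposite strands, as happens for a palindromic read —
  suppresses the read. This trades sensitivity on the youngest, least
  diverged repeat copies (which rarely align uniquely) for locus
  specificity: a uniquely aligned read cannot be attributed to a wrong copy
  unless a sequencing error makes it *exactly* match a sister copy (see
  Limitations).

* **Same-sense counting against a validated list.** A deduplicated read
  supports locus *z* only if its alignment overlaps the locus interval by at
  least `min_overlap` bp (default 1) **and** matches the locus strand.
  Supervised mode restricts counting to loci independently validated as
  expressed in matched bulk RNA-seq; everything outside that list is
  treated as passive background. Unsupervised mode counts all annotated
  loci and is provided to expose how large that background is — on the
  packaged synthetic study it inflates both the expressed-locus count and
  total RPM by ~2–2.5×.

The alignment search is exhaustive but seeded: candidates come from an
exact k-mer index with k = L // (m+1), so by pigeonhole every placement
with ≤ m mismatches contains an exact seed (an N in the read, which never
matches, only tightens the budget for the remaining segments). Candidates
are then verified by direct vectorized Hamming comparison. The design
target is desk-scale references (≲ 1 Mb); there is no attempt at
human-genome-scale performance.

## Duplicate removal

Two stages, in a fixed order:

1. **Positional** — one read survives per (chrom, start, strand)
   coordinate, the single-end coordinate-dedup model. Strand is part of the
   key so sense and antisense reads at one position are not merged (they
   feed strand-separated counting later); this is a deliberate divergence
   from literal single-end `samtools rmdup`, which ignores strandness of
   the later analysis.
2. **Barcode-UMI** — one read survives per (cell barcode, UMI) pair, the
   representative of a duplicated pair chosen uniformly at random.

The representative draw derives a per-group RNG from
`sha256(seed:barcode:umi)` over a canonical within-group ordering, so the
outcome depends only on the seed and the group, never on input order.
Positional-first is part of the method being modeled and has a real cost:
two genuine molecules with distinct UMIs landing on the same coordinate are
collapsed to one before the UMI stage ever sees them. At 3'-biased depths
this is the dominant loss mode (read pile-ups at transcript ends saturate
the coordinate space). The `DedupReport` surfaces the per-stage counts
rather than "fixing" the order.

## Normalization

RPM divides a locus count by the *million mapped reads of the cell cluster*
(the summed depth of all cells sharing the label) — this is the printed
denominator; a per-cell-depth variant exists behind
`rpm_matrix(per_cell_denominator=True)` because per-cell plots admit either
reading. FPKM divides by million mapped sample reads × 6, with 6 kb the
fixed canonical full-length L1 length; a per-locus-length variant is
available via the `length_kb` argument and is labeled non-default. The two
are algebraically locked: `fpkm(c, d) == rpm(c, d) / 6`. Zero denominators
yield NaN (missing), never zero.

## Bulk comparison

Bulk fragments enter counting only as concordant FR pairs (same contig,
opposite strands, forward mate upstream, outer span ≤ 600 bp); a fragment
counts once toward a locus when either mate overlaps it in the fragment's
sense (the R1/sense-mate strand). Per-read counting exists behind a flag;
per-fragment is the default to avoid double-counting when both mates land
in one locus. LTR loci are retained when strictly longer than 2 kb *and*
covered by ≥ 10 reads. The `authenticity_proxy` is an explicit package
heuristic standing in for manual promoter-origin review: a locus is
`passive-suspect` when same-sense coverage in the 1 kb window immediately
5' of the element exceeds 10% of the locus coverage, `authentic` when clean
and covered by ≥ 10 fragments, else `low-evidence`. The window (1 kb) and
ratio (0.1) are package defaults with no external calibration; any report
built on the proxy should state them.

The downsampling experiment thins each cell's *deduplicated* reads without
replacement to round(f·n) at each fraction f (independent seeded draws per
fraction) and re-runs supervised counting; f = 1.0 is bit-identical to the
full analysis, and a locus carried by a single read is detected with
probability round(f·n)/n ≈ f.

## The synthetic study

The generator emulates exactly the features the method's guarantees rest
on, and nothing more:

* **Genome** — `chr1` (500 kb default) with 60 copies of a random 6 kb
  master element placed on random strands in random unique-sequence gaps;
  plus a mitochondrial contig and a marker-transgene contig for QC and
  cell-classification. Copies are mutated i.i.d. from the master at
  *half* the `pairwise_divergence` knob (substitutions only, matching the
  ungapped aligner), so two copies differ by ≈ `pairwise_divergence` per
  site — at the 10% default a 90-mer from one copy carries ~9 mismatches
  against its sister, far beyond the 3-mismatch budget, which is what makes
  unique alignment effective.
* **Transcription** — `n_expressed` (10) full-length copies are
  authentically transcribed on their own strand with per-locus lognormal
  (σ = 1) levels; `n_passive` (15) copies are 5'-truncated (25–50% of the
  element retained) and embedded sense inside host-gene transcripts, the
  read-through background; 5 housekeeping genes fill out the mixture.
  Among non-mito, non-marker molecules the authentic : passive :
  housekeeping block weights are 1 : 5 : 4 — passive L1 background is not
  quantified anywhere authoritative, so the 5 : 1 passive-to-authentic
  molecule ratio is a package choice made once to keep passive signal
  clearly dominant, as it is in real transcriptomes.
* **Single-cell reads** — 200 cells × 2,000 molecules; one 90 bp sense R2
  read per molecule, with probability `three_prime_bias` (0.67) drawn
  entirely within the 1 kb terminal window of the transcript 3' end
  (matching the ~2× 3'-end enrichment characteristic of poly-A-primed 3'
  chemistry), else uniform; 16 bp barcode + 12 bp UMI in R1 (10X 3' v3
  geometry — the barcode/UMI lengths are configuration, not inference);
  UMIs unique per molecule within a cell; PCR duplicates appended per
  molecule with probability 0.15 sharing coordinate/barcode/UMI but with
  independent sequencing errors; substitution errors at 0.1% per base.
  10% of cells carry marker-transgene molecules (5% of their library);
  per-cell mitochondrial fractions are drawn from `mito_fraction_range`.
* **Bulk reads** — 30,000 stranded FR fragments, uniform along transcripts
  (no 3' bias), inserts 200–500 bp, from the same planted expression levels.

RNG streams are spawned per stage and per cell from the master seed, so the
generator is byte-reproducible and adding cells does not perturb earlier
cells' reads.

**What the generator does not model** — and hence what passing tests do not
show about real data: barcode sequencing errors and collisions, ambient
RNA, template switching, splicing of repeat transcripts, indels (so the
ungapped aligner is exactly matched by construction), mappability structure
of a real genome, and empirical L1 expression-level distributions. Results
on the fixture validate the *pipeline's mechanics and guarantees*, not
biological effect sizes.

## Numerical and design choices

* Coordinates are 0-based half-open internally; BED native; 1-based only at
  the SAM boundary (handled by pysam).
* N bases never match anything, including another N, in read or reference.
* Reads shorter than `seed_min` (20 bp) are dropped with a tally; reads
  with characters outside ACGTN are dropped with a tally.
* A read overlapping several same-strand loci (nested/adjacent copies)
  counts toward each, with a warning tally — mirroring independent
  per-locus coverage runs.
* The expressed-locus threshold is ≥ 1 unique same-sense deduplicated read
  at the chosen scope (cell, cluster or sample).
* `compare_shared` reports both percent-shared conventions
  (|A∩B|/|A∪B| and |A∩B|/|A|) because published Venn annotations mix them;
  the caller picks.
* The mitochondrial filter is strict (`fraction < 0.05` keeps) and is *off*
  by default on the locus-quantification path, available as a flag —
  whether the filter applies beyond gene-level QC is ambiguous, so it is
  exposed rather than imposed.
* Problem sizes in the test suite and `scripts/acceptance.py` (500 kb
  genome, 60 copies, 200 cells × 2,000 reads; 1,000-read oracle checks;
  500-seed uniformity and 1,000-seed thinning measurements) are the
  package's packaged study conditions, chosen so the full suite runs on a
  single CPU in a few minutes.

## Limitations

* The unique-alignment zero-misassignment guarantee is exact only for
  error-free reads: a sequencing error can make a read identical to a
  sister copy's window, where it then aligns uniquely but wrongly. At the
  default 0.1%/base error rate and 10% pairwise divergence this occurs for
  ~1 in 10⁴ repeat-derived reads (measured on the default fixture:
  4/43,626). The end-to-end recovery checks therefore run the generator
  with errors disabled, which is the stated condition of that guarantee;
  with errors on, expect a ~10⁻⁴ residual misassignment rate, not zero.
* Positional-before-UMI dedup undercounts molecules wherever coordinate
  space saturates (strong 3' bias, deep cells); cluster-level RPM
  comparisons remain valid, absolute molecule counts do not.
* The aligner holds the reference and its seed indexes in memory and scans
  exhaustively; it is not suitable for mammalian-genome-scale work, where
  an external `-m 1 -y -v 3`-style aligner should produce the SAM ingested
  by `ingest_sam`.
* Supervised counting can only confirm loci present in the validated bulk
  list; expression unique to cell types too rare to register in bulk is
  invisible by design.
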