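"""Synthetic genome, transcripts and reads with a complete truth ledger.

The generator emulates the data features the quantification method depends
on, at desk scale:

* a small genome carrying diverged copies of a ~6 kb master repeat, placed
  on random strands — copies are mutated i.i.d. from the master at half the
  configured pairwise divergence, so two copies differ by approximately
  ``pairwise_divergence`` per site (no indels, matching the ungapped
  aligner);
* *authentic* transcription: full-length repeat copies transcribed from
  their own promoter on the element strand;
* *passive* transcription: 5'-truncated repeat copies embedded sense inside
  host-gene transcripts, the read-through background that inflates naive
  counting;
* 3'-biased, poly-A-primed single-cell reads with per-cell barcodes, per-
  molecule UMIs, PCR duplicates and substitution sequencing errors, plus a
  mitochondrial contig and a marker transgene contig for the cell-QC and
  cell-classification steps;
* uniform-coverage, stranded, proper-pair bulk fragments for the matched
  bulk sample.

One master seed drives everything; per-stage and per-cell RNG streams are
spawned from it, so adding cells never perturbs earlier cells' reads and
identical configs reproduce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import ReferenceGenome, revcomp
from .quant import LocusAnnotation, write_loci_bed
from .tagging import write_fastq

__all__ = ["SimConfig", "SimGenome", "SimReads", "build_genome", "simulate_cells", "simulate_bulk"]

_BASES = np.array(list("ACGT"))
_SUBFAMILIES = ("L1Hs", "L1PA2", "L1Tf", "L1Gf")


@dataclass
class SimConfig:
    """Knobs of the synthetic study; defaults are the packaged conditions."""

    seed: int = 0
    genome_length: int = 500_000
    n_repeat_copies: int = 60
    repeat_length: int = 6000
    pairwise_divergence: float = 0.10
    n_expressed: int = 10
    n_passive: int = 15
    n_cells: int = 200
    cluster_spec: dict[str, int] | None = None
    reads_per_cell: int = 2000
    read_len: int = 90
    three_prime_bias: float = 0.67
    terminal_window: int = 1000
    pcr_dup_rate: float = 0.15
    seq_error_rate: float = 0.001
    marker_cells_fraction: float = 0.10
    mito_fraction_range: tuple[float, float] = (0.0, 0.04)
    # molecule-mixture weights among non-mito, non-marker molecules
    passive_to_authentic: float = 5.0
    hk_weight: float = 4.0
    n_hk_genes: int = 5
    hk_gene_length: int = 2000
    gene_flank: int = 500
    truncation_range: tuple[float, float] = (0.25, 0.5)
    marker_molecule_fraction: float = 0.05
    barcode_len: int = 16
    umi_len: int = 12
    mito_length: int = 6000
    marker_length: int = 3000
    bulk_fragments: int = 30_000
    bulk_insert_range: tuple[int, int] = (200, 500)

    def __post_init__(self) -> None:
        for name in (
            "pairwise_divergence",
            "three_prime_bias",
            "pcr_dup_rate",
            "seq_error_rate",
            "marker_cells_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.mito_fraction_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("mito_fraction_range must satisfy 0 <= lo <= hi <= 1")
        if self.n_expressed + self.n_passive > self.n_repeat_copies:
            raise ValueError("n_expressed + n_passive exceeds n_repeat_copies")

    def clusters(self) -> dict[str, int]:
        if self.cluster_spec is not None:
            if sum(self.cluster_spec.values()) != self.n_cells:
                raise ValueError("cluster_spec cell counts must sum to n_cells")
            return dict(self.cluster_spec)
        half = self.n_cells // 2
        return {"clusterA": half, "clusterB": self.n_cells - half}


@dataclass(frozen=True)
class Transcript:
    """A contiguous genomic interval transcribed on a known strand."""

    source_id: str
    kind: str  # authentic | passive | hk | mito | marker
    chrom: str
    start0: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start0


@dataclass
class SimGenome:
    """Reference plus annotations and planted expression truth."""

    ref: ReferenceGenome
    repeat_loci: list[LocusAnnotation]
    gene_loci: list[LocusAnnotation]
    validated_ids: list[str]  # = planted authentically expressed loci
    transcripts: list[Transcript]
    locus_truth: pd.DataFrame  # locus_id, expressed, passive, weight
    marker_interval: tuple[str, int, int]
    mito_chrom: str = "chrM"

    def write(self, outdir: str) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.ref.to_fasta(str(out / "genome.fa"))
        write_loci_bed(self.repeat_loci, str(out / "repeats.bed"))
        write_loci_bed(self.gene_loci, str(out / "genes.bed"))
        validated = [lc for lc in self.repeat_loci if lc.locus_id in set(self.validated_ids)]
        write_loci_bed(validated, str(out / "validated.bed"))
        self.locus_truth.to_csv(out / "locus_truth.tsv", sep="\t", index=False)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("latin1"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode("latin1")


def build_genome(config: SimConfig) -> SimGenome:
    """Assemble the synthetic reference and its annotations.

    Repeat copies are laid out left to right along ``chr1`` separated by
    random unique-sequence gaps; passive copies keep only their 3' portion
    (5' truncation) and sit inside a host-gene interval extending
    ``gene_flank`` bp on both sides.  Housekeeping genes are carved out of
    repeat-free gaps.  Raises when the requested copies cannot fit.
    """
    ss = np.random.SeedSequence([config.seed, 101])
    rng = np.random.default_rng(ss)
    n = config.n_repeat_copies
    master = _random_seq(rng, config.repeat_length)

    # which copies are truncated+passive, which full-length, which expressed
    roles = ["full"] * (n - config.n_passive) + ["passive"] * config.n_passive
    rng.shuffle(roles)
    full_idx = [i for i, r in enumerate(roles) if r == "full"]
    expressed_idx = set(
        rng.choice(full_idx, size=config.n_expressed, replace=False).tolist()
    ) if config.n_expressed else set()

    lengths = []
    for i in range(n):
        if roles[i] == "passive":
            frac = rng.uniform(*config.truncation_range)
            lengths.append(max(config.read_len, int(round(config.repeat_length * frac))))
        else:
            lengths.append(config.repeat_length)

    min_gap = max(config.read_len, 2 * config.gene_flank + 200)
    slack = config.genome_length - sum(lengths) - (n + 1) * min_gap
    if n and slack < 0:
        raise ValueError(
            f"cannot place {n} repeat copies in a {config.genome_length} bp genome"
        )
    if n:
        gaps = min_gap + rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    else:
        gaps = np.array([config.genome_length])

    pieces: list[str] = []
    pos = 0
    repeat_loci: list[LocusAnnotation] = []
    gene_loci: list[LocusAnnotation] = []
    transcripts: list[Transcript] = []
    truth_rows = []
    per_copy_rate = config.pairwise_divergence / 2.0

    gap_seqs = [_random_seq(rng, int(g)) for g in gaps]
    hk_remaining = config.n_hk_genes  # assigned greedily to wide gaps below

    for i in range(n + 1):
        gseq = gap_seqs[i]
        if hk_remaining > 0 and len(gseq) >= config.hk_gene_length + 200:
            g_start = pos + 100
            g_end = g_start + config.hk_gene_length
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"hk{config.n_hk_genes - hk_remaining}"
            gene_loci.append(
                LocusAnnotation(gid, "chr1", g_start, g_end, strand, family="gene", subfamily="hk")
            )
            transcripts.append(Transcript(gid, "hk", "chr1", g_start, g_end, strand))
            hk_remaining -= 1
        pieces.append(gseq)
        pos += len(gseq)
        if i == n:
            break
        # place repeat copy i
        length = lengths[i]
        strand = "+" if rng.random() < 0.5 else "-"
        if roles[i] == "passive":
            template = master[-length:]  # 3' portion of the element
        else:
            template = master
        copy_seq = _mutate(rng, template, per_copy_rate)
        if strand == "-":
            copy_seq = revcomp(copy_seq)
        start0, end = pos, pos + length
        locus_id = f"L1_{i:03d}"
        subfamily = _SUBFAMILIES[i % len(_SUBFAMILIES)]
        repeat_loci.append(
            LocusAnnotation(locus_id, "chr1", start0, end, strand, "L1", subfamily)
        )
        expressed = i in expressed_idx
        weight = float(rng.lognormal(0.0, 1.0))
        truth_rows.append(
            {
                "locus_id": locus_id,
                "expressed": expressed,
                "passive": roles[i] == "passive",
                "weight": weight if (expressed or roles[i] == "passive") else 0.0,
            }
        )
        if expressed:
            transcripts.append(Transcript(locus_id, "authentic", "chr1", start0, end, strand))
        if roles[i] == "passive":
            h_start = start0 - config.gene_flank
            h_end = end + config.gene_flank
            gid = f"host_{locus_id}"
            gene_loci.append(
                LocusAnnotation(gid, "chr1", h_start, h_end, strand, family="gene", subfamily="host")
            )
            transcripts.append(Transcript(gid, "passive", "chr1", h_start, h_end, strand))
        pieces.append(copy_seq)
        pos += length

    chr1 = "".join(pieces)
    mito = _random_seq(rng, config.mito_length)
    marker = _random_seq(rng, config.marker_length)
    ref = ReferenceGenome({"chr1": chr1, "chrM": mito, "FRT_marker": marker})
    transcripts.append(Transcript("mito", "mito", "chrM", 0, config.mito_length, "+"))
    transcripts.append(Transcript("marker", "marker", "FRT_marker", 0, config.marker_length, "+"))

    truth = pd.DataFrame(truth_rows, columns=["locus_id", "expressed", "passive", "weight"])
    validated_ids = [r["locus_id"] for r in truth_rows if r["expressed"]]
    return SimGenome(
        ref=ref,
        repeat_loci=repeat_loci,
        gene_loci=gene_loci,
        validated_ids=validated_ids,
        transcripts=transcripts,
        locus_truth=truth,
        marker_interval=("FRT_marker", 0, config.marker_length),
    )


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SimReads:
    """Simulated FASTQ records plus the per-read truth ledger."""

    r1: list[tuple[str, str, str]] = field(default_factory=list)
    r2: list[tuple[str, str, str]] = field(default_factory=list)
    truth: pd.DataFrame | None = None
    barcodes: list[str] = field(default_factory=list)
    cluster_of: dict[str, str] = field(default_factory=dict)
    marker_cells: set[str] = field(default_factory=set)
    mito_fraction_of: dict[str, float] = field(default_factory=dict)

    def write(self, outdir: str, prefix: str = "sc") -> tuple[str, str]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        p1 = str(out / f"{prefix}_R1.fastq")
        p2 = str(out / f"{prefix}_R2.fastq")
        write_fastq(self.r1, p1)
        write_fastq(self.r2, p2)
        if self.truth is not None:
            self.truth.to_csv(out / f"{prefix}_truth.tsv", sep="\t", index=False)
        if self.cluster_of:
            with open(out / "clusters.tsv", "w") as fh:
                for bc, lab in self.cluster_of.items():
                    fh.write(f"{bc}\t{lab}\n")
        return p1, p2


def _distinct_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        s = _random_seq(rng, k)
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def _read_window(
    rng: np.random.Generator, t: Transcript, read_len: int, bias: float, terminal: int
) -> int:
    """Genomic leftmost start of one read drawn from transcript ``t``.

    With probability ``bias`` the read falls entirely within ``terminal`` bp
    of the transcript's 3' end; otherwise uniformly along the transcript.
    """
    lo, hi = t.start0, t.end - read_len  # inclusive start range
    if hi < lo:
        raise ValueError(f"transcript {t.source_id} shorter than the read length")
    if rng.random() < bias:
        if t.strand == "+":
            lo = max(lo, t.end - terminal)
        else:
            hi = min(hi, t.start0 + terminal - read_len)
        if hi < lo:  # terminal window shorter than a read: clamp to 3'-most read
            lo = hi = (t.end - read_len) if t.strand == "+" else t.start0
    return int(rng.integers(lo, hi + 1))


def simulate_cells(config: SimConfig, genome: SimGenome) -> SimReads:
    """Generate the 3'-tagged single-cell library and its truth ledger.

    Each molecule yields one R2 genomic read (sense of its transcript) and
    one R1 barcode+UMI read; PCR duplicates re-sequence the same template
    with independent substitution errors.
    """
    root = np.random.SeedSequence([config.seed, 202])
    setup_rng = np.random.default_rng(root)
    barcodes = _distinct_kmers(setup_rng, config.n_cells, config.barcode_len)
    cluster_of: dict[str, str] = {}
    i = 0
    for label, count in config.clusters().items():
        for _ in range(count):
            cluster_of[barcodes[i]] = label
            i += 1
    n_marker_cells = int(round(config.marker_cells_fraction * config.n_cells))
    marker_cells = set(
        setup_rng.choice(barcodes, size=n_marker_cells, replace=False).tolist()
    ) if n_marker_cells else set()
    mito_frac = {
        bc: float(setup_rng.uniform(*config.mito_fraction_range)) for bc in barcodes
    }

    by_kind: dict[str, list[Transcript]] = {}
    for t in genome.transcripts:
        by_kind.setdefault(t.kind, []).append(t)
    weights = dict(zip(genome.locus_truth["locus_id"], genome.locus_truth["weight"]))

    authentic = by_kind.get("authentic", [])
    passive = by_kind.get("passive", [])
    hk = by_kind.get("hk", [])
    sources: list[Transcript] = authentic + passive + hk
    probs = []
    a_w = np.array([weights[t.source_id] for t in authentic], dtype=float)
    p_w = np.array(
        [weights[t.source_id.removeprefix("host_")] for t in passive], dtype=float
    )
    h_w = np.ones(len(hk))
    block = np.array(
        [1.0 if len(authentic) else 0.0,
         config.passive_to_authentic if len(passive) else 0.0,
         config.hk_weight if len(hk) else 0.0]
    )
    if block.sum() == 0:
        probs = np.array([])
    else:
        block = block / block.sum()
        parts = []
        for bw, w in zip(block, (a_w, p_w, h_w)):
            if w.size:
                parts.append(bw * w / w.sum())
        probs = np.concatenate(parts) if parts else np.array([])

    mito_t = by_kind["mito"][0]
    marker_t = by_kind["marker"][0]

    sim = SimReads(
        barcodes=barcodes,
        cluster_of=cluster_of,
        marker_cells=marker_cells,
        mito_fraction_of=mito_frac,
    )
    truth_rows = []
    r1_qual = "I" * (config.barcode_len + config.umi_len)
    r2_qual = "I" * config.read_len
    cell_seeds = root.spawn(config.n_cells)

    for ci, bc in enumerate(barcodes):
        rng = np.random.default_rng(cell_seeds[ci])
        n = config.reads_per_cell
        n_mito = int(round(n * mito_frac[bc]))
        n_marker = int(round(n * config.marker_molecule_fraction)) if bc in marker_cells else 0
        n_rest = n - n_mito - n_marker
        plan: list[Transcript] = [mito_t] * n_mito + [marker_t] * n_marker
        if n_rest > 0 and probs.size:
            counts = rng.multinomial(n_rest, probs)
            for t, c in zip(sources, counts):
                plan.extend([t] * int(c))
        umis = _distinct_kmers(rng, len(plan), config.umi_len)
        for mi, t in enumerate(plan):
            start = _read_window(
                rng, t, config.read_len, config.three_prime_bias, config.terminal_window
            )
            template = genome.ref[t.chrom][start : start + config.read_len]
            if t.strand == "-":
                template = revcomp(template)
            umi = umis[mi]
            n_copies = 1 + (1 if rng.random() < config.pcr_dup_rate else 0)
            for dup in range(n_copies):
                read_id = f"c{ci}m{mi}d{dup}"
                seq = _mutate(rng, template, config.seq_error_rate)
                sim.r1.append((read_id, bc + umi, r1_qual))
                sim.r2.append((read_id, seq, r2_qual))
                truth_rows.append(
                    {
                        "read_id": read_id,
                        "barcode": bc,
                        "umi": umi,
                        "origin": t.source_id,
                        "kind": t.kind,
                        "chrom": t.chrom,
                        "start0": start,
                        "strand": t.strand,
                        "is_pcr_duplicate": dup > 0,
                    }
                )
    sim.truth = pd.DataFrame(truth_rows)
    return sim


def simulate_bulk(config: SimConfig, genome: SimGenome) -> SimReads:
    """Generate the matched bulk library: stranded FR pairs, no 3' bias.

    Fragments are uniform along transcripts with insert sizes drawn from
    ``bulk_insert_range`` (capped by transcript length); R1 is the sense
    mate.  No barcodes, UMIs or PCR duplicates.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    by_kind: dict[str, list[Transcript]] = {}
    for t in genome.transcripts:
        if t.kind in ("authentic", "passive", "hk"):
            by_kind.setdefault(t.kind, []).append(t)
    weights = dict(zip(genome.locus_truth["locus_id"], genome.locus_truth["weight"]))
    authentic = by_kind.get("authentic", [])
    passive = by_kind.get("passive", [])
    hk = by_kind.get("hk", [])
    sources = authentic + passive + hk
    a_w = np.array([weights[t.source_id] for t in authentic], dtype=float)
    p_w = np.array(
        [weights[t.source_id.removeprefix("host_")] for t in passive], dtype=float
    )
    h_w = np.ones(len(hk))
    block = np.array(
        [1.0 if len(authentic) else 0.0,
         config.passive_to_authentic if len(passive) else 0.0,
         config.hk_weight if len(hk) else 0.0]
    )
    parts = []
    if block.sum():
        block = block / block.sum()
        for bw, w in zip(block, (a_w, p_w, h_w)):
            if w.size:
                parts.append(bw * w / w.sum())
    probs = np.concatenate(parts) if parts else np.array([])

    sim = SimReads()
    truth_rows = []
    qual = "I" * config.read_len
    if probs.size:
        counts = rng.multinomial(config.bulk_fragments, probs)
    else:
        counts = np.zeros(0, dtype=int)
    fi = 0
    for t, c in zip(sources, counts):
        lo_ins = max(config.read_len, config.bulk_insert_range[0])
        hi_ins = min(config.bulk_insert_range[1], t.length)
        if hi_ins < lo_ins:
            continue  # transcript too short for a proper pair
        for _ in range(int(c)):
            ins = int(rng.integers(lo_ins, hi_ins + 1))
            off = int(rng.integers(0, t.length - ins + 1))
            if t.strand == "+":
                f_start = t.start0 + off
            else:
                f_start = t.end - off - ins
            f_end = f_start + ins
            g = genome.ref[t.chrom]
            if t.strand == "+":
                r1 = g[f_start : f_start + config.read_len]
                r2 = revcomp(g[f_end - config.read_len : f_end])
            else:
                r1 = revcomp(g[f_end - config.read_len : f_end])
                r2 = g[f_start : f_start + config.read_len]
            read_id = f"blk{fi}"
            fi += 1
            sim.r1.append((read_id, _mutate(rng, r1, config.seq_error_rate), qual))
            sim.r2.append((read_id, _mutate(rng, r2, config.seq_error_rate), qual))
            truth_rows.append(
                {
                    "read_id": read_id,
                    "origin": t.source_id,
                    "kind": t.kind,
                    "chrom": t.chrom,
                    "start0": f_start,
                    "end": f_end,
                    "strand": t.strand,
                }
            )
    sim.truth = pd.DataFrame(truth_rows)
    return sim
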