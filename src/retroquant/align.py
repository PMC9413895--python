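"""Best-unique ungapped alignment of tagged reads to a small reference.

The quantification strategy relies on *unique* alignment: a read is placed
only if exactly one position on either strand attains the minimum Hamming
distance (at most ``max_mismatch`` substitutions, qualities ignored,
no gaps).  Any tie at the best distance — including the same position on
opposite strands — suppresses the read.  This mirrors the classic short-read
aligner settings ``-m 1`` (unique), ``-y`` (exhaustive best search) and
``-v 3`` (mismatch-count alignment) used for repetitive-element work, where
discarding multi-mapped reads trades sensitivity on the youngest, least
diverged repeat copies for locus specificity.

The search is exhaustive over all placements: candidate positions come from
an exact k-mer seed index with k = L // (m+1), so by the pigeonhole
principle every placement with at most m mismatches contains at least one
exact seed (an N in the read only tightens the budget for the remaining
segments).  This is intended for desk-scale genomes (hundreds of kb), not
for full mammalian references.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tagging import HeaderParseError, TaggedRead, parse_tagged_header, read_fastq

__all__ = [
    "ReferenceGenome",
    "GenomeAlignment",
    "UniqueAligner",
    "AlignReport",
    "align_unique",
    "align_fastq",
    "write_sam",
    "ingest_sam",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# genome codes: ACGT -> 0..3, N -> 4, inter-chromosome pad -> 5
# read codes:   ACGT -> 0..3, N -> 6  (N never matches anything, incl. N)
_GENOME_LUT = np.full(256, 4, dtype=np.uint8)
_READ_LUT = np.full(256, 6, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _GENOME_LUT[ord(_b)] = _i
    _READ_LUT[ord(_b)] = _i

_PAD = 5


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceGenome:
    """An in-memory reference: chromosome name -> uppercase ACGTN sequence."""

    def __init__(self, sequences: dict[str, str]):
        if len(sequences) == 0:
            raise ValueError("reference has no sequences")
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        for name, seq in self.sequences.items():
            if not set(seq) <= set("ACGTN"):
                raise ValueError(f"contig {name!r} contains non-ACGTN characters")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    @classmethod
    def from_fasta(cls, path: str) -> "ReferenceGenome":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
        return cls(seqs)

    def to_fasta(self, path: str) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, path, "fasta")


@dataclass(frozen=True)
class GenomeAlignment:
    """One best-unique placement of a tagged read on the reference."""

    read_id: str
    barcode: str
    umi: str
    chrom: str
    start0: int  # 0-based leftmost reference position
    strand: str  # '+' or '-'
    mismatches: int
    read_len: int
    seq: str = "*"
    qual: str = "*"

    @property
    def end(self) -> int:
        """Half-open end coordinate."""
        return self.start0 + self.read_len


@dataclass
class AlignReport:
    input_reads: int = 0
    aligned: int = 0
    unaligned: int = 0  # no placement within max_mismatch
    suppressed_multimap: int = 0  # >=2 placements tied at the best distance
    dropped_short: int = 0
    dropped_bad_chars: int = 0


class UniqueAligner:
    """Exhaustive best-unique Hamming aligner over a small reference.

    Deterministic: no randomness anywhere; identical inputs give identical
    outputs.  Seed indexes are built lazily per seed length and cached, so
    aligning a homogeneous read set costs one index build.
    """

    def __init__(self, ref: ReferenceGenome, max_mismatch: int = 3, seed_min: int = 20):
        if max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        self.ref = ref
        self.max_mismatch = max_mismatch
        self.seed_min = seed_min
        self._chroms = list(ref.sequences)
        pad = "N" * 8  # pads between chroms; boundary filter is authoritative
        self._concat = pad.join(ref.sequences[c] for c in self._chroms)
        starts = []
        pos = 0
        for c in self._chroms:
            starts.append(pos)
            pos += len(ref.sequences[c]) + len(pad)
        self._chrom_starts = np.array(starts, dtype=np.int64)
        self._chrom_lens = np.array(
            [len(ref.sequences[c]) for c in self._chroms], dtype=np.int64
        )
        codes = _GENOME_LUT[np.frombuffer(self._concat.encode("latin1"), np.uint8)]
        for s, ln in zip(starts, self._chrom_lens):
            if s + ln < len(codes):
                codes[s + ln : s + ln + len(pad)] = _PAD
        self._codes = codes
        self._indexes: dict[int, dict[bytes, np.ndarray]] = {}

    # -- seed index -------------------------------------------------------

    def _index_for(self, k: int) -> dict[bytes, np.ndarray]:
        idx = self._indexes.get(k)
        if idx is not None:
            return idx
        buckets: dict[bytes, list[int]] = {}
        concat = self._concat
        for start, ln in zip(self._chrom_starts, self._chrom_lens):
            end = int(start + ln)
            s = int(start)
            for p in range(s, end - k + 1):
                kmer = concat[p : p + k]
                if "N" in kmer:
                    continue
                buckets.setdefault(kmer.encode("latin1"), []).append(p)
        idx = {key: np.array(v, dtype=np.int64) for key, v in buckets.items()}
        self._indexes[k] = idx
        return idx

    # -- candidate generation --------------------------------------------

    def _seed_candidates(self, query: str, max_mm: int) -> np.ndarray:
        L = len(query)
        k = L // (max_mm + 1)
        if k < 4:
            return self._all_starts(L)
        idx = self._index_for(k)
        chunks = []
        for j in range(max_mm + 1):
            seed = query[j * k : (j + 1) * k].encode("latin1")
            hits = idx.get(seed)
            if hits is not None:
                chunks.append(hits - j * k)
        if not chunks:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(chunks))

    def _all_starts(self, L: int) -> np.ndarray:
        chunks = [
            np.arange(s, s + ln - L + 1, dtype=np.int64)
            for s, ln in zip(self._chrom_starts, self._chrom_lens)
            if ln >= L
        ]
        if not chunks:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(chunks)

    def _valid(self, starts: np.ndarray, L: int) -> np.ndarray:
        """Keep starts whose window lies fully inside a single chromosome."""
        if starts.size == 0:
            return starts
        ci = np.searchsorted(self._chrom_starts, starts, side="right") - 1
        ok = (ci >= 0) & (starts >= 0)
        cs = self._chrom_starts[np.clip(ci, 0, None)]
        ok &= (starts - cs + L) <= self._chrom_lens[np.clip(ci, 0, None)]
        return starts[ok]

    def _hamming(self, starts: np.ndarray, qcodes: np.ndarray) -> np.ndarray:
        L = qcodes.size
        windows = self._codes[starts[:, None] + np.arange(L)]
        return (windows != qcodes).sum(axis=1)

    # -- public API -------------------------------------------------------

    def _search(self, seq: str) -> tuple[int, list[tuple[int, str]]]:
        """Minimum mismatch count and all placements attaining it.

        Returns ``(best, placements)``; ``best > max_mismatch`` means no
        placement qualifies.  Placements are (global start, strand) pairs.
        """
        mm = self.max_mismatch
        best = mm + 1
        placements: list[tuple[int, str]] = []
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            starts = self._valid(self._seed_candidates(query, mm), len(query))
            if starts.size == 0:
                continue
            qcodes = _READ_LUT[np.frombuffer(query.encode("latin1"), np.uint8)]
            dists = self._hamming(starts, qcodes)
            lo = int(dists.min())
            if lo > mm or lo > best:
                continue
            hits = starts[dists == lo]
            if lo < best:
                best = lo
                placements = [(int(p), strand) for p in hits]
            else:
                placements.extend((int(p), strand) for p in hits)
        return best, placements

    def align(self, seq: str) -> tuple[str, int, str, int] | None:
        """Best-unique placement of ``seq``.

        Returns ``(chrom, start0, strand, mismatches)`` or ``None`` when no
        placement is within ``max_mismatch`` or when two or more placements
        tie at the minimum.  Raises ``ValueError`` on non-ACGTN characters.
        """
        seq = seq.upper()
        if not set(seq) <= set("ACGTN"):
            raise ValueError("read contains non-ACGTN characters")
        best, placements = self._search(seq)
        if best > self.max_mismatch or len(placements) != 1:
            return None
        gpos, strand = placements[0]
        ci = int(np.searchsorted(self._chrom_starts, gpos, side="right") - 1)
        return self._chroms[ci], int(gpos - self._chrom_starts[ci]), strand, best

    def align_tagged(self, read: TaggedRead) -> GenomeAlignment | None:
        hit = self.align(read.seq)
        if hit is None:
            return None
        chrom, start0, strand, nm = hit
        return GenomeAlignment(
            read_id=read.read_id,
            barcode=read.barcode,
            umi=read.umi,
            chrom=chrom,
            start0=start0,
            strand=strand,
            mismatches=nm,
            read_len=len(read.seq),
            seq=read.seq,
            qual=read.qual,
        )


def align_unique(
    read: TaggedRead, ref: ReferenceGenome, max_mismatch: int = 3
) -> GenomeAlignment | None:
    """One-shot convenience wrapper; builds a throwaway :class:`UniqueAligner`."""
    return UniqueAligner(ref, max_mismatch=max_mismatch).align_tagged(read)


def align_fastq(
    tagged_fastq: str,
    ref: ReferenceGenome,
    max_mismatch: int = 3,
    seed_min: int = 20,
) -> tuple[list[GenomeAlignment], AlignReport]:
    """Align every read of a tagged FASTQ; returns alignments plus tallies."""
    aligner = UniqueAligner(ref, max_mismatch=max_mismatch, seed_min=seed_min)
    report = AlignReport()
    out: list[GenomeAlignment] = []
    for header, seq, qual in read_fastq(tagged_fastq):
        report.input_reads += 1
        if len(seq) < seed_min:
            report.dropped_short += 1
            continue
        read_id, barcode, umi = parse_tagged_header(header)
        seq = seq.upper()
        if not set(seq) <= set("ACGTN"):
            report.dropped_bad_chars += 1
            continue
        best, placements = aligner._search(seq)
        if best > max_mismatch:
            report.unaligned += 1
            continue
        if len(placements) != 1:
            report.suppressed_multimap += 1
            continue
        gpos, strand = placements[0]
        ci = int(np.searchsorted(aligner._chrom_starts, gpos, side="right") - 1)
        report.aligned += 1
        out.append(
            GenomeAlignment(
                read_id=read_id,
                barcode=barcode,
                umi=umi,
                chrom=aligner._chroms[ci],
                start0=int(gpos - aligner._chrom_starts[ci]),
                strand=strand,
                mismatches=best,
                read_len=len(seq),
                seq=seq,
                qual=qual,
            )
        )
    return out, report


# ---------------------------------------------------------------------------
# SAM boundary


def _sam_header(ref: ReferenceGenome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [
                {"SN": name, "LN": len(seq)} for name, seq in ref.sequences.items()
            ],
        }
    )


def write_sam(alignments: Iterable[GenomeAlignment], ref: ReferenceGenome, path: str) -> int:
    """Write alignments as text SAM with NM tags; returns record count."""
    header = _sam_header(ref)
    tids = {name: i for i, name in enumerate(ref.sequences)}
    n = 0
    with pysam.AlignmentFile(path, "wh", header=header) as fh:
        for aln in alignments:
            rec = pysam.AlignedSegment(header)
            rec.query_name = aln.read_id if "_" in aln.read_id else (
                f"{aln.read_id}_{aln.barcode}_{aln.umi}"
            )
            rec.flag = 16 if aln.strand == "-" else 0
            rec.reference_id = tids[aln.chrom]
            rec.reference_start = aln.start0
            rec.mapping_quality = 255
            rec.cigarstring = f"{aln.read_len}M"
            if aln.seq != "*":
                rec.query_sequence = aln.seq if aln.strand == "+" else revcomp(aln.seq)
                if aln.qual != "*":
                    q = aln.qual if aln.strand == "+" else aln.qual[::-1]
                    rec.query_qualities = pysam.qualitystring_to_array(q)
            rec.set_tag("NM", aln.mismatches)
            fh.write(rec)
            n += 1
    return n


def ingest_sam(
    path: str,
    keep_unique_only: bool = True,
    on_bad_header: str = "drop",
) -> Iterator[GenomeAlignment]:
    """Stream mapped SAM records back as :class:`GenomeAlignment`.

    Read names are expected to carry barcode/UMI as produced by tagging;
    ``on_bad_header`` is ``"drop"`` (default, tallied by the caller via
    generator length) or ``"error"``.  With ``keep_unique_only`` records
    flagged secondary or supplementary are skipped.
    """
    if on_bad_header not in ("drop", "error"):
        raise ValueError("on_bad_header must be 'drop' or 'error'")
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if keep_unique_only and (rec.is_secondary or rec.is_supplementary):
                continue
            try:
                read_id, barcode, umi = parse_tagged_header(rec.query_name)
            except HeaderParseError:
                if on_bad_header == "error":
                    raise
                continue
            strand = "-" if rec.is_reverse else "+"
            seq = rec.query_sequence or "*"
            if seq != "*" and strand == "-":
                seq = revcomp(seq)
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            yield GenomeAlignment(
                read_id=read_id,
                barcode=barcode,
                umi=umi,
                chrom=rec.reference_name,
                start0=rec.reference_start,
                strand=strand,
                mismatches=int(nm),
                read_len=rec.query_length or rec.infer_read_length() or 0,
                seq=seq,
            )
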