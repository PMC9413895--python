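"""Cell-barcode / UMI tagging of 3'-library read pairs.

In a 10X Chromium 3' library, read 1 (R1) carries the cell barcode followed
by the UMI, while read 2 (R2) is the genomic cDNA read.  Before alignment the
barcode and UMI are moved into the R2 read name so they survive any SAM-based
downstream step.  The encoded name is whitespace-free (aligners truncate
names at the first space) and losslessly reversible.

Encoding scheme: ``<escaped read id>_<BARCODE>_<UMI>`` where the read id has
``%``, ``_`` and all whitespace percent-escaped.  Because barcode and UMI are
ACGTN-only and contain no ``_``, splitting the encoded name on the last two
underscores is unambiguous.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

__all__ = [
    "RawReadPair",
    "TaggedRead",
    "TaggingReport",
    "tag_read_pair",
    "encode_tagged_header",
    "parse_tagged_header",
    "tag_fastq_files",
    "read_fastq",
    "write_fastq",
]

_BC_RE = re.compile(r"^[ACGTN]+$")

# characters that must not survive in a read name: '%' (escape char itself),
# '_' (field separator) and every ASCII whitespace character
_ESCAPE_CHARS = "%_ \t\n\r\x0b\x0c"
_ESCAPE_RE = re.compile("[" + re.escape(_ESCAPE_CHARS) + "]")
_UNESCAPE_RE = re.compile(r"%([0-9A-Fa-f]{2})")


@dataclass(frozen=True)
class RawReadPair:
    """One demultiplexed read pair: R1 = barcode+UMI, R2 = genomic read."""

    read_id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual):
            raise ValueError(f"R1 seq/qual length mismatch for {self.read_id!r}")
        if len(self.r2_seq) != len(self.r2_qual):
            raise ValueError(f"R2 seq/qual length mismatch for {self.read_id!r}")


@dataclass(frozen=True)
class TaggedRead:
    """A genomic read carrying its cell barcode and UMI in-record."""

    read_id: str
    barcode: str
    umi: str
    seq: str
    qual: str

    @property
    def header(self) -> str:
        return encode_tagged_header(self.read_id, self.barcode, self.umi)


@dataclass
class TaggingReport:
    """Bookkeeping for one tagging run; input == tagged + skipped."""

    input_pairs: int = 0
    tagged: int = 0
    skipped_short_r1: int = 0
    skipped_whitelist: int = 0


class HeaderParseError(ValueError):
    """Raised when a read name is not a valid tagged header."""


def _escape_char(m: re.Match) -> str:
    return "%%%02X" % ord(m.group(0))


def encode_tagged_header(read_id: str, barcode: str, umi: str) -> str:
    """Encode (read_id, barcode, umi) into a single whitespace-free name."""
    if not _BC_RE.match(barcode):
        raise ValueError(f"barcode contains non-ACGTN characters: {barcode!r}")
    if not _BC_RE.match(umi):
        raise ValueError(f"UMI contains non-ACGTN characters: {umi!r}")
    return f"{_ESCAPE_RE.sub(_escape_char, read_id)}_{barcode}_{umi}"


def parse_tagged_header(header: str) -> tuple[str, str, str]:
    """Inverse of :func:`encode_tagged_header`.

    Returns ``(read_id, barcode, umi)``; raises :class:`HeaderParseError`
    on a name that tagging cannot have produced.
    """
    parts = header.rsplit("_", 2)
    if len(parts) != 3:
        raise HeaderParseError(f"not a tagged header (missing fields): {header!r}")
    enc_id, barcode, umi = parts
    if not barcode or not _BC_RE.match(barcode):
        raise HeaderParseError(f"invalid barcode field in header: {header!r}")
    if not umi or not _BC_RE.match(umi):
        raise HeaderParseError(f"invalid UMI field in header: {header!r}")
    read_id = _UNESCAPE_RE.sub(lambda m: chr(int(m.group(1), 16)), enc_id)
    return read_id, barcode, umi


def tag_read_pair(pair: RawReadPair, barcode_len: int = 16, umi_len: int = 12) -> TaggedRead:
    """Split barcode and UMI off R1 and attach them to the R2 genomic read.

    The barcode is the first ``barcode_len`` bases of R1 and the UMI the next
    ``umi_len``; R1 bases beyond that (if any) are discarded.  Raises
    ``ValueError`` when R1 is too short to contain both.
    """
    need = barcode_len + umi_len
    if len(pair.r1_seq) < need:
        raise ValueError(
            f"R1 of {pair.read_id!r} is {len(pair.r1_seq)} bp, "
            f"shorter than barcode+UMI ({need} bp)"
        )
    barcode = pair.r1_seq[:barcode_len].upper()
    umi = pair.r1_seq[barcode_len:need].upper()
    return TaggedRead(pair.read_id, barcode, umi, pair.r2_seq, pair.r2_qual)


# ---------------------------------------------------------------------------
# FASTQ plumbing


def _open_text(path: str, mode: str = "rt") -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str) -> Iterator[tuple[str, str, str]]:
    """Yield (name, seq, qual) records from a plain or gzipped FASTQ."""
    with _open_text(path) as fh:
        while True:
            head = fh.readline()
            if not head:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise ValueError(f"truncated FASTQ record in {path}")
            yield head.rstrip("\n")[1:], seq, qual


def write_fastq(records: Iterable[tuple[str, str, str]], path: str) -> int:
    """Write (name, seq, qual) records as 4-line FASTQ; returns record count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def iter_read_pairs(r1_path: str, r2_path: str) -> Iterator[RawReadPair]:
    """Pair up R1/R2 FASTQ files record by record."""
    for (id1, s1, q1), (id2, s2, q2) in zip(
        read_fastq(r1_path), read_fastq(r2_path), strict=True
    ):
        # Illumina read ids match up to the first space / mate suffix
        base1 = id1.split(" ")[0].split("/")[0]
        base2 = id2.split(" ")[0].split("/")[0]
        if base1 != base2:
            raise ValueError(f"R1/R2 read ids out of sync: {id1!r} vs {id2!r}")
        yield RawReadPair(base1, s1, q1, s2, q2)


def tag_fastq_files(
    r1_path: str,
    r2_path: str,
    out_path: str,
    barcode_len: int = 16,
    umi_len: int = 12,
    whitelist: set[str] | None = None,
) -> TaggingReport:
    """Tag every pair in R1/R2 FASTQ files, writing single-end tagged FASTQ.

    Pairs whose R1 is shorter than ``barcode_len + umi_len`` are skipped and
    tallied; with a ``whitelist``, pairs whose barcode is not listed are
    likewise skipped (exact match, no error correction).
    """
    report = TaggingReport()

    def _gen() -> Iterator[tuple[str, str, str]]:
        for pair in iter_read_pairs(r1_path, r2_path):
            report.input_pairs += 1
            try:
                tagged = tag_read_pair(pair, barcode_len, umi_len)
            except ValueError:
                report.skipped_short_r1 += 1
                continue
            if whitelist is not None and tagged.barcode not in whitelist:
                report.skipped_whitelist += 1
                continue
            report.tagged += 1
            yield tagged.header, tagged.seq, tagged.qual

    write_fastq(_gen(), out_path)
    return report
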