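"""Two-stage duplicate removal: positional PCR dedup, then barcode-UMI dedup.

Stage 1 keeps one read per identical alignment coordinate (chrom, start,
strand), the single-end ``samtools rmdup`` model.  Stage 2 keeps one read per
(cell barcode, UMI) pair, choosing the representative of a duplicated pair
uniformly at random.  The order is fixed — positional first — and is part of
the method: two genuine molecules with distinct UMIs that happen to land on
the same coordinate are collapsed by stage 1, a known cost of coordinate
dedup surfaced in the report rather than corrected.

Random representative selection derives a per-group RNG from the top-level
seed and a hash of the group key, so the outcome is independent of input
ordering and reproducible from the seed alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from .align import GenomeAlignment

__all__ = ["DedupReport", "positional_dedup", "umi_dedup", "dedup_pipeline"]


@dataclass
class DedupReport:
    input_count: int
    after_positional: int
    after_umi: int
    rng_seed: int

    def __post_init__(self) -> None:
        if not (self.input_count >= self.after_positional >= self.after_umi >= 0):
            raise ValueError("dedup counts must be non-increasing")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def positional_dedup(alignments: list[GenomeAlignment]) -> list[GenomeAlignment]:
    """Keep the first read seen at each (chrom, start0, strand) coordinate.

    Strand is part of the key so sense and antisense reads at the same
    position survive independently, preserving downstream strand-separated
    counting.  Survivor order follows the input.
    """
    seen: set[tuple[str, int, str]] = set()
    out = []
    for aln in alignments:
        key = (aln.chrom, aln.start0, aln.strand)
        if key not in seen:
            seen.add(key)
            out.append(aln)
    return out


def _group_rng(seed: int, barcode: str, umi: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{seed}:{barcode}:{umi}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def umi_dedup(alignments: list[GenomeAlignment], seed: int) -> list[GenomeAlignment]:
    """Keep exactly one alignment per (barcode, UMI) pair.

    Singleton pairs pass through; for duplicated pairs one member is chosen
    uniformly at random.  The choice depends only on (seed, barcode, umi,
    group size), never on input order.  Missing barcode/UMI is a wiring bug
    and raises.
    """
    groups: dict[tuple[str, str], list[GenomeAlignment]] = {}
    order: list[tuple[str, str]] = []
    for aln in alignments:
        if not aln.barcode or not aln.umi:
            raise ValueError(f"alignment {aln.read_id!r} lacks barcode/UMI")
        key = (aln.barcode, aln.umi)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(aln)
    out = []
    for key in order:
        members = groups[key]
        if len(members) == 1:
            out.append(members[0])
        else:
            # canonical within-group order makes the draw input-order-free
            ranked = sorted(members, key=lambda a: (a.read_id, a.chrom, a.start0))
            rng = _group_rng(seed, *key)
            out.append(ranked[int(rng.integers(len(ranked)))])
    return out


def dedup_pipeline(
    alignments: list[GenomeAlignment], seed: int
) -> tuple[list[GenomeAlignment], DedupReport]:
    """Positional then barcode-UMI dedup, with a reconciling report."""
    pos = positional_dedup(alignments)
    final = umi_dedup(pos, seed)
    report = DedupReport(
        input_count=len(alignments),
        after_positional=len(pos),
        after_umi=len(final),
        rng_seed=seed,
    )
    return final, report
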