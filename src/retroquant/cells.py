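"""Per-cell partitioning, marker classification and cell-level QC.

After deduplication, alignments are split by cell barcode.  Cells can then
be (a) classified by whether any read hits a marker locus — the strategy
used to identify spiked-in transgene-carrying cells inside a cell mixture
by alignment to the transgene — and (b) filtered on the fraction of reads
mapping to the mitochondrial contig (dying or lysed cells leak cytoplasmic
RNA and are dominated by mito reads).  Cluster / cell-type labels come from
an external two-column table, since clustering itself is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import GenomeAlignment

__all__ = [
    "CellProfile",
    "split_by_barcode",
    "classify_by_marker_locus",
    "qc_filter_cells",
    "load_cluster_table",
    "cell_profiles",
]


@dataclass
class CellProfile:
    barcode: str
    mapped_reads: int
    mito_fraction: float
    label: str = "unassigned"
    marker_hit: bool = False

    def __post_init__(self) -> None:
        if self.mapped_reads < 0:
            raise ValueError("mapped_reads must be >= 0")
        if not 0.0 <= self.mito_fraction <= 1.0:
            raise ValueError("mito_fraction must be in [0, 1]")


def split_by_barcode(
    alignments: list[GenomeAlignment],
) -> dict[str, list[GenomeAlignment]]:
    """Partition alignments into per-cell lists keyed by barcode.

    Every alignment lands in exactly one list; the union equals the input.
    """
    cells: dict[str, list[GenomeAlignment]] = {}
    for aln in alignments:
        cells.setdefault(aln.barcode, []).append(aln)
    return cells


def classify_by_marker_locus(
    cells: dict[str, list[GenomeAlignment]],
    marker_chrom: str,
    marker_start0: int,
    marker_end: int,
    known_chroms: set[str] | None = None,
) -> dict[str, bool]:
    """Flag cells with >=1 alignment overlapping the marker interval.

    Overlap is any-strand, >=1 bp against the half-open interval
    ``[marker_start0, marker_end)``.  If ``known_chroms`` is given, an
    interval on an unknown contig raises.
    """
    if marker_end <= marker_start0:
        raise ValueError("marker interval must have end > start")
    if known_chroms is not None and marker_chrom not in known_chroms:
        raise ValueError(f"marker contig {marker_chrom!r} not in reference")
    hits: dict[str, bool] = {}
    for barcode, alns in cells.items():
        hits[barcode] = any(
            a.chrom == marker_chrom and a.start0 < marker_end and a.end > marker_start0
            for a in alns
        )
    return hits


def mito_fraction(alignments: list[GenomeAlignment], mito_chrom: str = "chrM") -> float:
    """Fraction of a cell's alignments on the mitochondrial contig."""
    if not alignments:
        raise ValueError("cannot compute mito fraction of an empty cell")
    n_mito = sum(1 for a in alignments if a.chrom == mito_chrom)
    return n_mito / len(alignments)


def qc_filter_cells(
    cells: dict[str, list[GenomeAlignment]],
    max_mito_fraction: float = 0.05,
    mito_chrom: str = "chrM",
) -> tuple[dict[str, list[GenomeAlignment]], dict[str, int]]:
    """Keep cells whose mito read fraction is strictly below the threshold.

    Returns the surviving cells (alignment lists untouched) and a tally
    ``{"kept": ..., "discarded_mito": ..., "discarded_empty": ...}``.
    A cell with zero mapped reads has no computable fraction and goes to its
    own discard category.
    """
    kept: dict[str, list[GenomeAlignment]] = {}
    tally = {"kept": 0, "discarded_mito": 0, "discarded_empty": 0}
    for barcode, alns in cells.items():
        if not alns:
            tally["discarded_empty"] += 1
            continue
        if mito_fraction(alns, mito_chrom) < max_mito_fraction:
            kept[barcode] = alns
            tally["kept"] += 1
        else:
            tally["discarded_mito"] += 1
    return kept, tally


def load_cluster_table(path: str) -> dict[str, str]:
    """Read a two-column (barcode TAB label) table into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["barcode", "label"], dtype=str)
    return dict(zip(df["barcode"], df["label"]))


def cell_profiles(
    cells: dict[str, list[GenomeAlignment]],
    labels: dict[str, str] | None = None,
    marker_hits: dict[str, bool] | None = None,
    mito_chrom: str = "chrM",
) -> pd.DataFrame:
    """Per-cell summary table: depth, mito fraction, label, marker status."""
    rows = []
    for barcode, alns in cells.items():
        rows.append(
            CellProfile(
                barcode=barcode,
                mapped_reads=len(alns),
                mito_fraction=mito_fraction(alns, mito_chrom) if alns else 0.0,
                label=(labels or {}).get(barcode, "unassigned"),
                marker_hit=(marker_hits or {}).get(barcode, False),
            )
        )
    return pd.DataFrame(
        [
            {
                "barcode": p.barcode,
                "mapped_reads": p.mapped_reads,
                "mito_fraction": p.mito_fraction,
                "label": p.label,
                "marker_hit": p.marker_hit,
            }
            for p in rows
        ]
    )
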