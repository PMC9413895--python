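"""Bulk RNA-seq locus quantification and the bulk vs single-cell analyses.

Bulk libraries are paired-end and stranded: a fragment enters counting only
when its mates form a concordant FR pair (opposite strands, same contig,
insert span at most 600 bp by default) and each mate aligned uniquely.  A
fragment counts once toward a locus when either mate overlaps it in the
fragment's sense orientation (per-fragment counting; a per-read mode exists
behind a flag).  The fragment's sense strand is the strand of the R1 (sense)
mate.

This module also provides the cross-dataset utilities: shared expressed-
locus set comparison, the FPKM-RPM Pearson correlation, the LTR length /
read-count inclusion rule, a configurable *proxy* for manual upstream-signal
authenticity review (not a reproduction of visual inspection), and the
per-cell read-downsampling experiment used to study detection saturation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import GenomeAlignment
from .quant import LocusAnnotation, count_same_sense, fpkm, quantify_supervised

__all__ = [
    "Fragment",
    "BulkSample",
    "AuthenticityCall",
    "make_fragments",
    "bulk_quantify",
    "ltr_filter",
    "authenticity_proxy",
    "compare_shared",
    "SharedSetReport",
    "correlate_fpkm_rpm",
    "downsample_experiment",
]


@dataclass(frozen=True)
class Fragment:
    """A concordant sequenced fragment; mate1 is the sense mate."""

    mate1: GenomeAlignment
    mate2: GenomeAlignment | None = None

    @property
    def chrom(self) -> str:
        return self.mate1.chrom

    @property
    def strand(self) -> str:
        return self.mate1.strand

    @property
    def span(self) -> int:
        if self.mate2 is None:
            return self.mate1.read_len
        lo = min(self.mate1.start0, self.mate2.start0)
        hi = max(self.mate1.end, self.mate2.end)
        return hi - lo

    def mates(self) -> list[GenomeAlignment]:
        return [self.mate1] if self.mate2 is None else [self.mate1, self.mate2]


@dataclass
class BulkSample:
    sample_id: str
    fragments: list[Fragment]

    @property
    def mapped_reads(self) -> int:
        return sum(len(f.mates()) for f in self.fragments)


def make_fragments(
    pairs: Iterable[tuple[GenomeAlignment | None, GenomeAlignment | None]],
    paired_max_span: int = 600,
) -> tuple[list[Fragment], dict[str, int]]:
    """Filter aligned mate pairs down to concordant FR fragments.

    A pair is concordant when both mates aligned uniquely, on the same
    contig, on opposite strands, in FR orientation (mates pointing inward)
    and the outer span is at most ``paired_max_span``.  Pairs failing any
    clause are tallied and dropped.
    """
    fragments: list[Fragment] = []
    tally = {"concordant": 0, "mate_unaligned": 0, "discordant": 0}
    for m1, m2 in pairs:
        if m1 is None or m2 is None:
            tally["mate_unaligned"] += 1
            continue
        fwd, rev = (m1, m2) if m1.strand == "+" else (m2, m1)
        span = max(m1.end, m2.end) - min(m1.start0, m2.start0)
        ok = (
            m1.chrom == m2.chrom
            and m1.strand != m2.strand
            and fwd.start0 <= rev.start0  # FR: forward mate upstream
            and span <= paired_max_span
        )
        if not ok:
            tally["discordant"] += 1
            continue
        tally["concordant"] += 1
        fragments.append(Fragment(m1, m2))
    return fragments, tally


def bulk_quantify(
    sample: BulkSample,
    loci: Sequence[LocusAnnotation],
    min_overlap: int = 1,
    per_read: bool = False,
    length_kb: float = 6.0,
) -> pd.DataFrame:
    """Strand-separated same-sense counts and FPKM per locus.

    Default per-fragment counting: a fragment counts once toward a locus
    when either mate overlaps it and the fragment sense matches the locus
    strand.  ``per_read=True`` counts each mate independently on its own
    alignment strand instead.
    """
    counts = {lc.locus_id: 0 for lc in loci}
    if per_read:
        reads = [m for f in sample.fragments for m in f.mates()]
        counts.update(count_same_sense(reads, loci, min_overlap))
    else:
        by_key: dict[tuple[str, str], list[LocusAnnotation]] = {}
        for lc in loci:
            by_key.setdefault((lc.chrom, lc.strand), []).append(lc)
        for frag in sample.fragments:
            hit_ids: set[str] = set()
            for lc in by_key.get((frag.chrom, frag.strand), []):
                for m in frag.mates():
                    if min(m.end, lc.end) - max(m.start0, lc.start0) >= min_overlap:
                        hit_ids.add(lc.locus_id)
                        break
            for lid in hit_ids:
                counts[lid] += 1
    depth = sample.mapped_reads
    rows = [
        {
            "locus_id": lc.locus_id,
            "count": counts[lc.locus_id],
            "length_bp": lc.length_bp,
            "fpkm": fpkm(counts[lc.locus_id], depth, length_kb),
        }
        for lc in loci
    ]
    return pd.DataFrame(rows)


def ltr_filter(
    loci: Sequence[LocusAnnotation],
    counts: dict[str, int],
    min_len: int = 2000,
    min_reads: int = 10,
) -> list[LocusAnnotation]:
    """Keep LTR loci strictly longer than ``min_len`` bp with at least
    ``min_reads`` aligned reads (both inequalities as printed: > 2 kb,
    >= 10 reads)."""
    return [
        lc
        for lc in loci
        if lc.length_bp > min_len and counts.get(lc.locus_id, 0) >= min_reads
    ]


@dataclass(frozen=True)
class AuthenticityCall:
    locus_id: str
    count: int
    upstream_count: int
    call: str  # authentic | passive-suspect | low-evidence
    window_truncated: bool = False

    def __post_init__(self) -> None:
        if self.call not in ("authentic", "passive-suspect", "low-evidence"):
            raise ValueError(f"unknown call {self.call!r}")


def authenticity_proxy(
    sample: BulkSample,
    locus: LocusAnnotation,
    chrom_length: int,
    upstream_window: int = 1000,
    max_upstream_ratio: float = 0.1,
    min_reads: int = 10,
    min_overlap: int = 1,
) -> AuthenticityCall:
    """Automated stand-in for manual promoter-origin review of a locus.

    Expression driven by the element's own promoter should show no
    locus-sense transcription immediately 5' of the element, whereas
    read-through from an upstream gene promoter does.  The call is
    ``passive-suspect`` when same-sense fragments in the ``upstream_window``
    bp 5' of the locus exceed ``max_upstream_ratio`` of the locus fragment
    count, ``authentic`` when clean and covered by at least ``min_reads``
    fragments, else ``low-evidence``.  This is an explicit package heuristic,
    not a reproduction of visual inspection; report its parameters alongside
    any call.
    """
    if locus.strand == "+":
        w_start, w_end = locus.start0 - upstream_window, locus.start0
        truncated = w_start < 0
        w_start = max(w_start, 0)
    else:
        w_start, w_end = locus.end, locus.end + upstream_window
        truncated = w_end > chrom_length
        w_end = min(w_end, chrom_length)
    window = LocusAnnotation(
        f"_upstream_{locus.locus_id}", locus.chrom, w_start, w_end, locus.strand
    ) if w_end > w_start else None

    count = int(
        bulk_quantify(sample, [locus], min_overlap=min_overlap)["count"].iloc[0]
    )
    upstream = (
        int(bulk_quantify(sample, [window], min_overlap=min_overlap)["count"].iloc[0])
        if window is not None
        else 0
    )
    if count == 0:
        call = "low-evidence"
    elif upstream / count > max_upstream_ratio:
        call = "passive-suspect"
    elif count >= min_reads:
        call = "authentic"
    else:
        call = "low-evidence"
    return AuthenticityCall(locus.locus_id, count, upstream, call, truncated)


@dataclass(frozen=True)
class SharedSetReport:
    shared: frozenset[str]
    a_only: frozenset[str]
    b_only: frozenset[str]
    percent_shared_of_union: float
    percent_shared_of_a: float

    @property
    def union_size(self) -> int:
        return len(self.shared) + len(self.a_only) + len(self.b_only)


def compare_shared(set_a: set[str], set_b: set[str]) -> SharedSetReport:
    """Expressed-locus set overlap with both percent-shared conventions.

    ``percent_shared_of_union`` uses |A ∩ B| / |A ∪ B|;
    ``percent_shared_of_a`` uses |A ∩ B| / |A| (A as the reference set, the
    convention for "x% of bulk loci were found in single cells").  Both are
    percentages in [0, 100]; NaN on empty denominators.
    """
    shared = set_a & set_b
    union = set_a | set_b
    pct_union = 100.0 * len(shared) / len(union) if union else float("nan")
    pct_a = 100.0 * len(shared) / len(set_a) if set_a else float("nan")
    return SharedSetReport(
        frozenset(shared),
        frozenset(set_a - set_b),
        frozenset(set_b - set_a),
        pct_union,
        pct_a,
    )


def correlate_fpkm_rpm(
    bulk_fpkm: dict[str, float], sc_rpm: dict[str, float]
) -> tuple[float, float, int]:
    """Two-tailed Pearson correlation over loci present in both tables.

    Untransformed values.  Returns ``(r, p, n)``; a constant vector makes r
    undefined and yields ``(nan, nan, n)``.  Fewer than 3 shared loci raise.
    """
    shared = sorted(set(bulk_fpkm) & set(sc_rpm))
    n = len(shared)
    if n < 3:
        raise ValueError(f"need >= 3 shared loci for a correlation, got {n}")
    x = np.array([bulk_fpkm[k] for k in shared], dtype=float)
    y = np.array([sc_rpm[k] for k in shared], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), n
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n


def downsample_experiment(
    cells: dict[str, list[GenomeAlignment]],
    loci: Sequence[LocusAnnotation],
    validated_ids: Sequence[str],
    fractions: Sequence[float] | None = None,
    seed: int = 0,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Per-cell read downsampling vs number of detected expressed loci.

    At each fraction f, round(f * n) deduplicated reads are drawn without
    replacement from every cell (an independent draw per fraction), the
    supervised expressed-locus counting is rerun, and the mean detected-
    locus count across cells is reported.  f = 1.0 reproduces the full
    analysis exactly.
    """
    if fractions is None:
        fractions = [round(0.1 * k, 1) for k in range(10, 0, -1)]
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fractions must be in (0, 1], got {f}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    rows = []
    for f in fractions:
        sub: dict[str, list[GenomeAlignment]] = {}
        for bc, alns in cells.items():
            if f == 1.0:
                sub[bc] = list(alns)
                continue
            m = int(round(f * len(alns)))
            if m == 0:
                sub[bc] = []
                continue
            idx = rng.choice(len(alns), size=m, replace=False)
            sub[bc] = [alns[i] for i in sorted(idx)]
        matrix = quantify_supervised(sub, loci, validated_ids, min_overlap=min_overlap)
        n_expressed = (matrix.counts >= 1).sum(axis=1)
        rows.append(
            {
                "fraction": f,
                "mean_expressed_loci": float(n_expressed.mean()) if len(n_expressed) else 0.0,
                "total_expressed_loci": int(((matrix.counts.sum(axis=0)) >= 1).sum()),
            }
        )
    return pd.DataFrame(rows)
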