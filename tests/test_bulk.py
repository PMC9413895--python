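"""Bulk quantification, comparison utilities and the downsampling study."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retroquant.align import GenomeAlignment
from retroquant.bulk import (
    BulkSample,
    Fragment,
    authenticity_proxy,
    bulk_quantify,
    compare_shared,
    correlate_fpkm_rpm,
    downsample_experiment,
    ltr_filter,
    make_fragments,
)
from retroquant.quant import LocusAnnotation


def _aln(read_id, start, strand="+", chrom="chr1", length=90):
    return GenomeAlignment(read_id, "A" * 16, "C" * 12, chrom, start, strand, 0, length)


def _pair(read_id, start, span, chrom="chr1", sense="+"):
    """A concordant FR pair of total span ``span``; R1 is the sense mate."""
    if sense == "+":
        m1 = _aln(read_id, start, "+", chrom)
        m2 = _aln(read_id, start + span - 90, "-", chrom)
    else:
        m1 = _aln(read_id, start + span - 90, "-", chrom)
        m2 = _aln(read_id, start, "+", chrom)
    return m1, m2


LOCUS = LocusAnnotation("L1", "chr1", 5000, 11000, "+")


def test_discordant_span_is_excluded():
    good = _pair("ok", 5100, 400)
    bad = _pair("far", 5100, 900)  # span over the 600 bp limit
    frags, tally = make_fragments([good, bad], paired_max_span=600)
    assert len(frags) == 1 and frags[0].mate1.read_id == "ok"
    assert tally == {"concordant": 1, "mate_unaligned": 0, "discordant": 1}


def test_unaligned_mate_and_orientation_rules():
    m1, m2 = _pair("p", 5100, 400)
    frags, tally = make_fragments([(m1, None)], 600)
    assert not frags and tally["mate_unaligned"] == 1
    same_strand = (m1, _aln("p", 5300, "+"))
    frags, tally = make_fragments([same_strand], 600)
    assert not frags and tally["discordant"] == 1


def test_fragment_counts_once_even_when_both_mates_overlap():
    sample = BulkSample("s", [Fragment(*_pair("p", 5100, 400))])
    df = bulk_quantify(sample, [LOCUS]).set_index("locus_id")
    assert df.loc["L1", "count"] == 1
    per_read = bulk_quantify(sample, [LOCUS], per_read=True).set_index("locus_id")
    # per-read mode counts only the same-sense mate (the minus mate is antisense)
    assert per_read.loc["L1", "count"] == 1


def test_bulk_counts_are_strand_separated_and_fpkm_uses_sample_depth():
    frags = [Fragment(*_pair(f"p{i}", 5100 + i, 400)) for i in range(5)]
    frags.append(Fragment(*_pair("anti", 5100, 400, sense="-")))
    sample = BulkSample("s", frags)
    df = bulk_quantify(sample, [LOCUS]).set_index("locus_id")
    assert df.loc["L1", "count"] == 5  # antisense fragment not counted
    depth = sample.mapped_reads
    assert df.loc["L1", "fpkm"] == pytest.approx(5 / ((depth / 1e6) * 6))


@pytest.mark.parametrize(
    "length,reads,kept",
    [
        (2500, 12, True),
        (1900, 50, False),
        (2000, 50, False),  # not strictly > 2 kb
        (2001, 10, True),
        (2500, 9, False),  # below the 10-read floor
    ],
)
def test_ltr_filter_boundaries(length, reads, kept):
    lc = LocusAnnotation("ltr", "chr1", 0, length, "+", family="LTR")
    result = ltr_filter([lc], {"ltr": reads})
    assert (lc in result) is kept


def test_authenticity_proxy_flags_upstream_signal():
    clean = [Fragment(*_pair(f"c{i}", 5100 + 7 * i, 400)) for i in range(15)]
    sample = BulkSample("s", clean)
    call = authenticity_proxy(sample, LOCUS, chrom_length=50_000)
    assert call.call == "authentic"
    # add locus-sense fragments immediately 5' of the element (read-through)
    upstream = [Fragment(*_pair(f"u{i}", 4200 + 10 * i, 300)) for i in range(5)]
    call2 = authenticity_proxy(
        BulkSample("s", clean + upstream), LOCUS, chrom_length=50_000
    )
    assert call2.call == "passive-suspect"
    assert call2.upstream_count >= 5


def test_authenticity_proxy_low_evidence_and_truncated_window():
    empty = BulkSample("s", [])
    call = authenticity_proxy(empty, LOCUS, chrom_length=50_000)
    assert call.call == "low-evidence" and call.count == 0
    near_edge = LocusAnnotation("E", "chr1", 300, 6300, "+")
    frags = [Fragment(*_pair(f"e{i}", 400 + i, 300)) for i in range(12)]
    call2 = authenticity_proxy(BulkSample("s", frags), near_edge, chrom_length=50_000)
    assert call2.window_truncated


def test_compare_shared_conventions_and_conservation():
    rep = compare_shared({"1", "2", "3"}, {"2", "3", "4"})
    assert set(rep.shared) == {"2", "3"}
    assert rep.percent_shared_of_union == pytest.approx(50.0)
    assert rep.percent_shared_of_a == pytest.approx(200 / 3)
    assert len(rep.shared) + len(rep.a_only) + len(rep.b_only) == rep.union_size
    assert compare_shared({"a"}, {"a"}).percent_shared_of_union == 100.0
    assert compare_shared({"a"}, {"b"}).percent_shared_of_union == 0.0


def test_pearson_perfect_proportionality_and_degenerate_cases():
    bulk = {f"L{i}": float(i + 1) for i in range(6)}
    sc = {k: 3.5 * v for k, v in bulk.items()}
    r, p, n = correlate_fpkm_rpm(bulk, sc)
    assert r == pytest.approx(1.0)
    assert n == 6
    flat = {k: 2.0 for k in bulk}
    r2, p2, _ = correlate_fpkm_rpm(bulk, flat)
    assert math.isnan(r2) and math.isnan(p2)
    with pytest.raises(ValueError, match=">= 3"):
        correlate_fpkm_rpm({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})


def test_pearson_matches_independent_formula(rng):
    bulk = {f"L{i}": float(v) for i, v in enumerate(rng.gamma(2.0, 3.0, 30))}
    sc = {k: v * 2 + float(rng.normal(0, 1)) for k, v in bulk.items()}
    r, _, _ = correlate_fpkm_rpm(bulk, sc)
    x = np.array([bulk[k] for k in sorted(bulk)])
    y = np.array([sc[k] for k in sorted(sc)])
    manual = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert r == pytest.approx(manual, abs=1e-12)


def _downsample_cells():
    loci = [LocusAnnotation(f"D{i}", "chr1", i * 10_000, i * 10_000 + 6000, "+")
            for i in range(4)]
    cells = {
        "C1": [_aln(f"r{i}{j}", i * 10_000 + 50 * j) for i in range(4) for j in range(3)],
        "C2": [_aln("solo", 50)],  # one locus, one read
    }
    return cells, loci


def test_downsample_full_fraction_is_identity():
    cells, loci = _downsample_cells()
    ids = [lc.locus_id for lc in loci]
    table = downsample_experiment(cells, loci, ids, fractions=[1.0], seed=7)
    full = downsample_experiment(cells, loci, ids, fractions=[1.0], seed=99)
    pd.testing.assert_frame_equal(table, full)  # f=1 is seed-independent
    assert table.loc[0, "mean_expressed_loci"] == pytest.approx((4 + 1) / 2)


def test_downsample_mean_detected_loci_nondecreasing_in_f():
    cells, loci = _downsample_cells()
    ids = [lc.locus_id for lc in loci]
    means = []
    for f in (0.25, 0.5, 1.0):
        vals = [
            downsample_experiment(cells, loci, ids, fractions=[f], seed=s)
            .loc[0, "mean_expressed_loci"]
            for s in range(40)
        ]
        means.append(float(np.mean(vals)))
    assert means[0] <= means[1] + 1e-9 <= means[2] + 1e-9


def test_single_read_locus_detected_with_frequency_f():
    """Bernoulli thinning: a one-read locus survives fraction f with P ~= f."""
    cells, loci = _downsample_cells()
    ids = [lc.locus_id for lc in loci]
    f = 0.4
    n = 300
    # 10 filler reads outside every locus plus one read inside D0: the
    # detected-locus count is Bernoulli(P = round(f*11)/11 ~ f)
    distinct = {"C": [_aln(f"x{i}", 40_000 + i) for i in range(10)] + [_aln("y", 50)]}
    hit = 0
    for s in range(n):
        t = downsample_experiment(distinct, loci, ids, fractions=[f], seed=s)
        hit += t.loc[0, "total_expressed_loci"]
    assert abs(hit / n - f) <= 0.1


def test_downsample_rejects_bad_fraction():
    cells, loci = _downsample_cells()
    with pytest.raises(ValueError):
        downsample_experiment(cells, loci, [lc.locus_id for lc in loci],
                              fractions=[0.0])
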