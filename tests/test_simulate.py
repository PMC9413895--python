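"""Generator guarantees: reproducibility, truth conservation, planted biases."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retroquant.align import UniqueAligner
from retroquant.simulate import SimConfig, build_genome, simulate_bulk, simulate_cells


def test_config_validation():
    with pytest.raises(ValueError, match="exceeds"):
        SimConfig(n_repeat_copies=5, n_expressed=4, n_passive=3)
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        SimConfig(three_prime_bias=1.5)
    with pytest.raises(ValueError, match="sum to n_cells"):
        SimConfig(n_cells=10, cluster_spec={"a": 4}).clusters()


def test_genome_layout_and_annotations(small_sim):
    cfg, genome, _ = small_sim
    assert genome.ref.total_length >= cfg.genome_length
    assert len(genome.repeat_loci) == cfg.n_repeat_copies
    assert len(genome.validated_ids) == cfg.n_expressed
    truth = genome.locus_truth.set_index("locus_id")
    # validated == planted expressed; passive loci are never validated
    assert set(genome.validated_ids) == set(truth.index[truth.expressed])
    assert not (truth.expressed & truth.passive).any()
    # passive copies are 5'-truncated, hence shorter than the full element
    for lc in genome.repeat_loci:
        if truth.loc[lc.locus_id, "passive"]:
            assert lc.length_bp < cfg.repeat_length
            host = [g for g in genome.gene_loci if g.locus_id == f"host_{lc.locus_id}"]
            assert host and host[0].start0 < lc.start0 and host[0].end > lc.end
            assert host[0].strand == lc.strand  # embedded sense
        else:
            assert lc.length_bp == cfg.repeat_length
    # loci do not overlap one another
    placed = sorted((lc.start0, lc.end) for lc in genome.repeat_loci)
    for (s1, e1), (s2, e2) in zip(placed, placed[1:]):
        assert e1 <= s2


def test_zero_copies_gives_plain_genome():
    cfg = SimConfig(seed=3, genome_length=30_000, n_repeat_copies=0, n_expressed=0,
                    n_passive=0, n_cells=2, reads_per_cell=20, n_hk_genes=2)
    genome = build_genome(cfg)
    assert genome.repeat_loci == []
    assert genome.validated_ids == []
    reads = simulate_cells(cfg, genome)
    assert (reads.truth["kind"].isin(["hk", "mito", "marker"])).all()


def test_infeasible_placement_raises():
    with pytest.raises(ValueError, match="cannot place"):
        build_genome(SimConfig(genome_length=50_000, n_repeat_copies=20,
                               n_expressed=5, n_passive=5))


def test_reproducibility_is_byte_identical(small_sim):
    cfg, genome, reads = small_sim
    genome2 = build_genome(cfg)
    assert genome2.ref.sequences == genome.ref.sequences
    reads2 = simulate_cells(cfg, genome2)
    assert reads2.r1 == reads.r1
    assert reads2.r2 == reads.r2
    pd.testing.assert_frame_equal(reads2.truth, reads.truth)
    bulk1 = simulate_bulk(cfg, genome)
    bulk2 = simulate_bulk(cfg, genome2)
    assert bulk1.r1 == bulk2.r1 and bulk1.r2 == bulk2.r2


def test_truth_conservation(small_sim):
    cfg, genome, reads = small_sim
    truth = reads.truth
    assert len(reads.r1) == len(reads.r2) == len(truth)
    molecules = (~truth.is_pcr_duplicate).sum()
    dups = truth.is_pcr_duplicate.sum()
    assert molecules + dups == len(truth)
    # every duplicate shares origin/barcode/UMI with its template molecule
    key = truth.groupby(["barcode", "umi"])["origin"].nunique()
    assert (key == 1).all()
    # molecule count per cell equals the configured depth
    per_cell = truth[~truth.is_pcr_duplicate].groupby("barcode").size()
    assert (per_cell == cfg.reads_per_cell).all()


def test_three_prime_bias_knob_is_verifiable():
    cfg = SimConfig(seed=11, genome_length=150_000, n_repeat_copies=8, n_expressed=8,
                    n_passive=0, n_cells=10, reads_per_cell=1200,
                    three_prime_bias=0.7, pcr_dup_rate=0.0, hk_weight=0.0,
                    marker_cells_fraction=0.0, mito_fraction_range=(0.0, 0.0),
                    n_hk_genes=0)
    genome = build_genome(cfg)
    reads = simulate_cells(cfg, genome)
    truth = reads.truth[reads.truth.kind == "authentic"]
    loci = {lc.locus_id: lc for lc in genome.repeat_loci}
    in_window = 0
    for row in truth.itertuples():
        lc = loci[row.origin]
        if lc.strand == "+":
            ok = row.start0 + cfg.read_len > lc.end - cfg.terminal_window
        else:
            ok = row.start0 < lc.start0 + cfg.terminal_window
        in_window += ok
    frac = in_window / len(truth)
    # biased reads all fall in the window; uniform reads land there by chance
    chance = (cfg.terminal_window) / cfg.repeat_length
    expected = cfg.three_prime_bias + (1 - cfg.three_prime_bias) * chance
    assert len(truth) >= 10_000
    assert abs(frac - expected) <= 0.02


def test_divergence_zero_makes_repeat_reads_multimap():
    cfg = SimConfig(seed=5, genome_length=60_000, n_repeat_copies=2, n_expressed=2,
                    n_passive=0, n_cells=4, reads_per_cell=100,
                    pairwise_divergence=0.0, seq_error_rate=0.0,
                    marker_cells_fraction=0.0, mito_fraction_range=(0.0, 0.0),
                    hk_weight=0.0, n_hk_genes=0)
    genome = build_genome(cfg)
    reads = simulate_cells(cfg, genome)
    aligner = UniqueAligner(genome.ref)
    repeat_reads = [
        seq for (_, seq, _), kind in zip(reads.r2, reads.truth.kind)
        if kind == "authentic"
    ]
    assert repeat_reads
    assert all(aligner.align(seq) is None for seq in repeat_reads[:50])


def test_reads_are_sense_to_their_source_locus(small_sim):
    cfg, genome, reads = small_sim
    truth = reads.truth[reads.truth.kind == "authentic"]
    strands = {lc.locus_id: lc.strand for lc in genome.repeat_loci}
    assert all(row.strand == strands[row.origin] for row in truth.itertuples())


def test_marker_and_mito_planting(small_sim):
    cfg, genome, reads = small_sim
    truth = reads.truth
    marker_cells_seen = set(truth.loc[truth.kind == "marker", "barcode"])
    assert marker_cells_seen == reads.marker_cells
    expected = int(round(cfg.marker_cells_fraction * cfg.n_cells))
    assert len(reads.marker_cells) == expected
    mito = truth[~truth.is_pcr_duplicate].groupby("barcode").apply(
        lambda g: (g.kind == "mito").mean(), include_groups=False
    )
    for bc, frac in reads.mito_fraction_of.items():
        assert abs(mito.get(bc, 0.0) - round(frac * cfg.reads_per_cell) / cfg.reads_per_cell) < 1e-9


def test_bulk_uniform_coverage_and_proper_pairs():
    cfg = SimConfig(seed=21, genome_length=120_000, n_repeat_copies=4, n_expressed=4,
                    n_passive=0, n_cells=2, reads_per_cell=10, hk_weight=0.0,
                    n_hk_genes=0, bulk_fragments=12_000, seq_error_rate=0.0)
    genome = build_genome(cfg)
    bulk = simulate_bulk(cfg, genome)
    truth = bulk.truth
    assert (truth["end"] - truth["start0"] <= 600).all()
    assert (truth["end"] - truth["start0"] >= cfg.read_len).all()
    # read-start positions along one expressed locus are uniform (chi^2, 10 bins)
    lc = next(l for l in genome.repeat_loci
              if l.locus_id == genome.validated_ids[0])
    frag_starts = truth.loc[truth.origin == lc.locus_id, "start0"].to_numpy()
    assert len(frag_starts) >= 200
    hist, _ = np.histogram(frag_starts, bins=10,
                           range=(lc.start0, lc.end - 500))
    chi2 = ((hist - hist.mean()) ** 2 / hist.mean()).sum()
    assert chi2 < stats.chi2.ppf(0.99, df=9)


def test_zero_expressed_loci_gives_zero_supervised_bulk_counts():
    from retroquant.bulk import BulkSample, Fragment, bulk_quantify
    from retroquant.align import GenomeAlignment

    cfg = SimConfig(seed=8, genome_length=100_000, n_repeat_copies=6, n_expressed=0,
                    n_passive=3, n_cells=2, reads_per_cell=10, bulk_fragments=2_000)
    genome = build_genome(cfg)
    bulk = simulate_bulk(cfg, genome)
    # align truth fragments directly (no sequencing errors needed here)
    frags = []
    for row in bulk.truth.itertuples():
        m1 = GenomeAlignment(row.read_id, "A" * 16, "C" * 12, row.chrom,
                             row.start0 if row.strand == "+" else row.end - cfg.read_len,
                             row.strand, 0, cfg.read_len)
        frags.append(Fragment(m1))
    sample = BulkSample("b", frags)
    validated = [lc for lc in genome.repeat_loci if lc.locus_id in genome.validated_ids]
    assert validated == []
    df = bulk_quantify(sample, validated)
    assert df.empty or (df["count"] == 0).all()


def test_fixture_writer_roundtrip(tmp_path, small_sim):
    cfg, genome, reads = small_sim
    genome.write(str(tmp_path))
    p1, p2 = reads.write(str(tmp_path))
    from retroquant.quant import load_loci_bed
    from retroquant.tagging import read_fastq

    assert len(load_loci_bed(str(tmp_path / "repeats.bed"))) == cfg.n_repeat_copies
    assert len(load_loci_bed(str(tmp_path / "validated.bed"))) == cfg.n_expressed
    assert sum(1 for _ in read_fastq(p1)) == len(reads.r1)
    assert (tmp_path / "clusters.tsv").exists()
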