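"""End-to-end orchestration: tag -> align -> dedup -> demux -> quantify.

One :class:`RunConfig` drives a full run; every stage writes its artifact
under the output directory and contributes record counts to the
:class:`RunReport`, which reconciles stage to stage and embeds the config
(seeds included) for provenance.  Reruns with the same config reproduce
identical count matrices: alignment is deterministic and the only stochastic
stage (UMI-duplicate representative choice) is seeded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import align as _align
from . import cells as _cells
from . import dedup as _dedup
from . import quant as _quant
from .tagging import tag_fastq_files

logger = logging.getLogger("retroquant")

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass
class RunConfig:
    r1: str
    r2: str
    reference: str
    loci: str
    outdir: str
    validated: str | None = None
    clusters: str | None = None
    mode: str = "both"  # supervised | unsupervised | both
    barcode_len: int = 16
    umi_len: int = 12
    max_mismatch: int = 3
    seed_min: int = 20
    dedup_seed: int = 17
    min_overlap: int = 1
    marker: str | None = None  # "chrom:start-end"
    apply_mito_filter: bool = False
    max_mito_fraction: float = 0.05
    mito_chrom: str = "chrM"

    def __post_init__(self) -> None:
        if self.mode not in ("supervised", "unsupervised", "both"):
            raise ValueError("mode must be supervised, unsupervised or both")
        if self.mode in ("supervised", "both") and not self.validated:
            raise ValueError(f"mode={self.mode} requires a validated locus list")

    def validate_paths(self) -> None:
        for name in ("r1", "r2", "reference", "loci", "validated", "clusters"):
            path = getattr(self, name)
            if path and not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    config: dict
    config_hash: str
    stages: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "config_hash": self.config_hash,
                       "stages": self.stages}, fh, indent=2, default=str)


def _parse_marker(spec: str) -> tuple[str, int, int]:
    chrom, _, span = spec.partition(":")
    lo, _, hi = span.partition("-")
    return chrom, int(lo), int(hi)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage; any failure aborts naming the stage."""
    config.validate_paths()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict(), config_hash=config.digest())

    stage = "tag"
    try:
        tagged_path = str(out / "tagged.fastq")
        tag_report = tag_fastq_files(
            config.r1, config.r2, tagged_path,
            barcode_len=config.barcode_len, umi_len=config.umi_len,
        )
        report.stages["tag"] = dataclasses.asdict(tag_report)
        logger.info("tag: %d pairs in, %d tagged", tag_report.input_pairs, tag_report.tagged)

        stage = "align"
        ref = _align.ReferenceGenome.from_fasta(config.reference)
        alignments, aln_report = _align.align_fastq(
            tagged_path, ref, max_mismatch=config.max_mismatch, seed_min=config.seed_min
        )
        _align.write_sam(alignments, ref, str(out / "alignments.sam"))
        report.stages["align"] = dataclasses.asdict(aln_report)
        logger.info("align: %d unique of %d", aln_report.aligned, aln_report.input_reads)

        stage = "dedup"
        deduped, dd_report = _dedup.dedup_pipeline(alignments, seed=config.dedup_seed)
        _align.write_sam(deduped, ref, str(out / "dedup.sam"))
        dd_report.to_json(str(out / "dedup.json"))
        report.stages["dedup"] = dataclasses.asdict(dd_report)
        logger.info("dedup: %d -> %d -> %d", dd_report.input_count,
                    dd_report.after_positional, dd_report.after_umi)

        stage = "demux"
        cells = _cells.split_by_barcode(deduped)
        labels = _cells.load_cluster_table(config.clusters) if config.clusters else {}
        marker_hits = None
        if config.marker:
            mk = _parse_marker(config.marker)
            marker_hits = _cells.classify_by_marker_locus(
                cells, *mk, known_chroms=set(ref.sequences)
            )
        demux_info = {"n_cells": len(cells), "total_reads": sum(map(len, cells.values()))}
        if config.apply_mito_filter:
            cells, qc_tally = _cells.qc_filter_cells(
                cells, config.max_mito_fraction, config.mito_chrom
            )
            demux_info["qc"] = qc_tally
        profiles = _cells.cell_profiles(cells, labels, marker_hits, config.mito_chrom)
        profiles.to_csv(out / "cell_profiles.tsv", sep="\t", index=False)
        report.stages["demux"] = demux_info
        logger.info("demux: %d cells", len(cells))

        stage = "quant"
        loci = _quant.load_loci_bed(config.loci)
        quant_info = {}
        matrices = {}
        if config.mode in ("unsupervised", "both"):
            m = _quant.quantify_unsupervised(cells, loci, labels, config.min_overlap)
            matrices["unsupervised"] = m
        if config.mode in ("supervised", "both"):
            validated = [lc.locus_id for lc in _quant.load_loci_bed(config.validated)]
            m = _quant.quantify_supervised(cells, loci, validated, labels, config.min_overlap)
            matrices["supervised"] = m
        for name, m in matrices.items():
            m.to_tsv(str(out / f"{name}_counts.tsv"))
            m.to_mtx(str(out / f"{name}_counts"))
            m.rpm_matrix().to_csv(out / f"{name}_rpm.tsv", sep="\t")
            sample_set, per_cell = _quant.expressed_loci(m, scope="sample")
            quant_info[name] = {
                "n_loci": len(m.locus_ids),
                "expressed_loci_sample": sorted(sample_set),
                "mean_expressed_per_cell": float(per_cell.mean()) if len(per_cell) else 0.0,
            }
        with open(out / "expressed_loci.json", "w") as fh:
            json.dump(quant_info, fh, indent=2)
        report.stages["quant"] = quant_info
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report.to_json(str(out / "run_report.json"))
    return report
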