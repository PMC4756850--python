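"""End-to-end run: VCF -> segments -> per-segment calling -> filters -> hcf.

Segments are processed in input (chromosome, coordinate) order, one at a
time — only the current segment's fragments are held in memory — and the
output is deterministic: identical inputs and configuration produce a
byte-identical hcf file.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from . import hcf as hcf_io
from .filters import FilterConfig, apply_stringency
from .loci import read_snvs
from .model import LocalHaplotypeModel, ModelParams
from .reads import (
    DEFAULT_BASEQ_MIN,
    DEFAULT_MAPQ_MIN,
    assign_error_rates,
    collapse_patterns,
    extract_fragments,
)
from .segments import DEFAULT_K, DEFAULT_R_MAX, SegmentDef, build_segments

log = logging.getLogger("haplocal")


@dataclass
class RunConfig:
    bam: Path
    vcf: Path
    out_hcf: Path
    igv_track: Path | None = None
    K: int = DEFAULT_K
    r_max: int = DEFAULT_R_MAX
    params: ModelParams = field(default_factory=ModelParams)
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    mapq_min: int = DEFAULT_MAPQ_MIN
    baseq_min: int = DEFAULT_BASEQ_MIN
    keep_filtered_vcf: bool = False


def _record_for(
    segment: SegmentDef, model: LocalHaplotypeModel, results
) -> hcf_io.HcfRecord:
    sel = set(results.selected)
    return hcf_io.HcfRecord(
        chrom=segment.chrom,
        positions=segment.positions,
        alleles=tuple((s.ref, s.alt) for s in segment.snvs),
        haplotype_calls=tuple(
            (h.seq, float(x), h.j in sel)
            for h, x in zip(results.haplotypes, results.xi)
        ),
        support=tuple(sorted(model.patterns.counts.items())),
    )


def run(config: RunConfig) -> int:
    """Execute the full pipeline; returns 0 on success."""
    for path in (config.bam, config.vcf):
        if not Path(path).exists():
            log.error("input not found: %s", path)
            return 1

    scan = read_snvs(config.vcf, keep_filtered=config.keep_filtered_vcf)
    segments, orphans = build_segments(scan.snvs, config.K, config.r_max)
    log.info(
        "%d SNVs -> %d segments (%d orphan SNVs, %d excluded records)",
        len(scan.snvs), len(segments), orphans, scan.n_excluded,
    )

    records: list[hcf_io.HcfRecord] = []
    obs_by_record: dict[tuple[str, tuple[int, ...]], list] = {}
    n_not_analyzed = 0
    try:
        aln = pysam.AlignmentFile(str(config.bam))
    except (OSError, ValueError) as exc:
        log.error("cannot open alignments %s: %s", config.bam, exc)
        return 1
    with aln:
        if not aln.has_index():
            log.error("alignment file %s has no index (.bai); run samtools index", config.bam)
            return 1
        for segment in segments:
            if not segment.analyzed:
                n_not_analyzed += 1
                continue
            observations = extract_fragments(
                aln, segment, mapq_min=config.mapq_min, baseq_min=config.baseq_min
            )
            observations = assign_error_rates(
                observations, mode=config.params.e_mode, e_const=config.params.e_const
            )
            model = LocalHaplotypeModel.from_observations(
                segment, observations, config.params
            )
            results = model.fit()
            rec = _record_for(segment, model, results)
            records.append(rec)
            obs_by_record[(rec.chrom, rec.positions)] = observations

    records = apply_stringency(
        records, obs_by_record, scan.indel_positions, config.filter_cfg
    )

    counts: dict[int, int] = {}
    for rec in records:
        counts[rec.n_significant] = counts.get(rec.n_significant, 0) + 1
    summary = hcf_io.HcfSummary(
        n_snvs_in_vcf=len(scan.snvs),
        counts_by_n_significant=counts,
        n_not_analyzed=n_not_analyzed,
    )
    parameters = {
        "K": config.K,
        "R_max": config.r_max,
        "alpha": config.params.alpha,
        "beta": config.params.beta,
        "f0": config.params.f0,
        "e_mode": config.params.e_mode,
        "e_const": config.params.e_const,
        "mapq_min": config.mapq_min,
        "baseq_min": config.baseq_min,
        "filter_level": config.filter_cfg.level,
    }
    hcf_io.write_hcf(records, summary, config.out_hcf, parameters=parameters)
    if config.igv_track is not None:
        hcf_io.write_igv_track(records, config.igv_track)
    n_lhv = sum(1 for r in records if r.is_lhv and r.filter_status == "PASS")
    log.info("wrote %d records (%d PASS LHVs) to %s", len(records), n_lhv, config.out_hcf)
    return 0


def configure_logging(verbosity: int = 0) -> None:
    level = logging.WARNING - 10 * min(verbosity, 2)
    logging.basicConfig(stream=sys.stderr, level=level, format="%(levelname)s %(message)s")
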