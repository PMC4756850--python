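"""Synthetic inputs: exact scenario fixtures, a generative simulator, and
tiny alignment/VCF fixtures for end-to-end tests.

The eight scenario fixtures are fixed read-pattern multisets over one
segment (two or three SNVs, patterns over {A,C,G,T,M}) covering the regimes
that matter for the caller: clear three-haplotype support, information-free
single-SNV coverage, sparse uniform support, and heavily missing real-data
counts. The simulator realizes the model's own generative assumptions —
fragments drawn from a mixture over true haplotypes, per-SNV independent
MCAR missingness, uniform substitution error over the three other bases —
so recovery and FDR-calibration experiments run against a known truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .loci import SnvLocus
from .reads import MISSING, FragmentObservation, PatternCounts
from .segments import SegmentDef


def _segment(chrom: str, snvs: list[tuple[int, str, str]]) -> SegmentDef:
    return SegmentDef(
        chrom,
        tuple(SnvLocus(chrom, pos, ref, alt) for pos, ref, alt in snvs),
        analyzed=True,
    )


# (snvs as (pos, ref, alt), pattern -> count); ref is the majority/first allele
_SCENARIOS: dict[int, tuple[list[tuple[int, str, str]], dict[str, int]]] = {
    1: ([(100, "G", "A"), (197, "A", "C")], {"GA": 4, "GC": 2, "AC": 2}),
    2: ([(100, "A", "G"), (197, "A", "G")], {"AM": 1, "MA": 1, "GM": 2, "MG": 4}),
    3: (
        [(100, "A", "G"), (160, "G", "A"), (220, "A", "C")],
        {"AGA": 2, "AGC": 2, "GAC": 1},
    ),
    4: (
        [(100, "A", "G"), (160, "A", "C"), (220, "A", "T")],
        {p: 1 for p in ("AAA", "AAT", "ACA", "ACT", "GAA", "GAT", "GCA", "GCT")},
    ),
    5: (
        [(100, "A", "G"), (160, "A", "C"), (220, "A", "T")],
        {
            "AAA": 5, "AAT": 5, "ACA": 5,
            "ACT": 1, "GAA": 1, "GAT": 1, "GCA": 1, "GCT": 1,
        },
    ),
    6: ([(100, "G", "A"), (197, "A", "C")], {"GA": 20, "GC": 10, "AC": 10}),
    7: (
        [(100, "G", "A"), (197, "G", "C")],
        {"GG": 23, "GC": 10, "AG": 9, "MG": 43, "GM": 26, "AM": 13, "MC": 11},
    ),
    8: (
        [(100, "T", "C"), (197, "T", "G")],
        {"TT": 22, "CG": 14, "CT": 13, "MT": 46, "MG": 46, "CM": 34, "TM": 12},
    ),
}


def scenario_fixture(n: int) -> tuple[SegmentDef, PatternCounts]:
    """Exact pattern multiset for simulation scenario n in 1..8."""
    if n not in _SCENARIOS:
        raise ValueError(f"scenario must be in 1..8, got {n}")
    snvs, counts = _SCENARIOS[n]
    return _segment(f"sim{n}", snvs), PatternCounts(dict(counts))


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative settings for one simulated segment.

    true_haplotypes are drawn with the given mixture proportions; each SNV
    of each fragment is missing independently with probability
    missing_rate (MCAR); an observed base is miscalled to each of the
    other three bases with probability error_rate/3. Bases outside the
    SNV's two alleles are coerced to missing, matching extraction.
    """

    segment: SegmentDef
    true_haplotypes: tuple[str, ...]
    proportions: tuple[float, ...]
    n_fragments: int
    missing_rate: float = 0.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.true_haplotypes) != len(self.proportions):
            raise ValueError("one proportion per true haplotype")
        if abs(sum(self.proportions) - 1.0) > 1e-12:
            raise ValueError("proportions must sum to 1")
        if len(set(self.true_haplotypes)) != len(self.true_haplotypes):
            raise ValueError("true haplotypes must be distinct")
        space = {
            "".join(c)
            for c in __import__("itertools").product(
                *[(s.ref, s.alt) for s in self.segment.snvs]
            )
        }
        if not set(self.true_haplotypes) <= space:
            raise ValueError("true haplotypes must use each SNV's ref/alt alleles")
        if not 0 <= self.missing_rate < 1 or not 0 <= self.error_rate < 0.75:
            raise ValueError("rates out of range")


_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def simulate_segment(
    spec: SyntheticSpec,
) -> tuple[list[FragmentObservation], dict[str, int]]:
    """Draw fragments under ``spec``; returns observations and the per-
    haplotype truth counts. Reproducible given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    alleles = [{s.ref, s.alt} for s in spec.segment.snvs]
    truth: dict[str, int] = {h: 0 for h in spec.true_haplotypes}
    out: list[FragmentObservation] = []
    sources = rng.choice(len(spec.true_haplotypes), size=spec.n_fragments, p=spec.proportions)
    for i, src in enumerate(sources):
        hap = spec.true_haplotypes[src]
        truth[hap] += 1
        calls = []
        for r, h in enumerate(hap):
            if rng.random() < spec.missing_rate:
                calls.append(MISSING)
                continue
            base = h
            if spec.error_rate > 0 and rng.random() < spec.error_rate:
                base = _OTHER[h][rng.integers(3)]
            if base not in alleles[r]:
                base = MISSING  # third allele -> missing, as in extraction
            calls.append(base)
        calls_s = "".join(calls)
        if calls_s == MISSING * spec.segment.R:
            continue
        out.append(
            FragmentObservation(
                fragment_id=f"frag{i}",
                calls=calls_s,
                strands=tuple("+" if c != MISSING else None for c in calls_s),
                end_offsets=tuple(25 if c != MISSING else None for c in calls_s),
            )
        )
    return out, truth


def emit_alignment_fixture(
    segment: SegmentDef,
    patterns: PatternCounts,
    out_dir: "str | os.PathLike",
    mapq: int = 60,
    baseq: int = 40,
    prefix: str = "fixture",
) -> tuple[Path, Path, Path]:
    """Write a coordinate-sorted BAM (+ .bai) and VCF realizing ``patterns``.

    Each fragment becomes a properly paired read pair: mate 1 spans all of
    the segment's SNVs, carrying the pattern's base (quality ``baseq``) at
    observed SNVs and the reference base at quality 2 (below any sensible
    gate) at missing ones; mate 2 aligns downstream of the last SNV and
    covers no SNV. Extraction therefore reproduces ``patterns`` exactly.
    Returns (bam_path, bai_path, vcf_path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chrom = segment.chrom
    first, last = segment.span
    read1_start0 = max(first - 11, 0)  # 0-based
    read1_len = (last - 1) - read1_start0 + 11
    read2_start0 = last + 10
    read2_len = 50
    contig_len = read2_start0 + read2_len + 100

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": contig_len}],
    }
    snv_off = {s.pos - 1 - read1_start0: (r, s.ref) for r, s in enumerate(segment.snvs)}

    unsorted = out_dir / f"{prefix}.unsorted.bam"
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as bam:
        frag_no = 0
        for pattern in sorted(patterns.counts):
            for _ in range(patterns.counts[pattern]):
                name = f"frag{frag_no:05d}"
                frag_no += 1
                seq = ["A"] * read1_len
                quals = [baseq] * read1_len
                for off, (r, ref) in snv_off.items():
                    if pattern[r] == MISSING:
                        seq[off], quals[off] = ref, 2
                    else:
                        seq[off] = pattern[r]
                a1 = pysam.AlignedSegment()
                a1.query_name = name
                a1.query_sequence = "".join(seq)
                a1.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in quals)
                )
                a1.flag = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate rev, first
                a1.reference_id = 0
                a1.reference_start = read1_start0
                a1.mapping_quality = mapq
                a1.cigarstring = f"{read1_len}M"
                a1.next_reference_id = 0
                a1.next_reference_start = read2_start0
                a1.template_length = read2_start0 + read2_len - read1_start0

                a2 = pysam.AlignedSegment()
                a2.query_name = name
                a2.query_sequence = "A" * read2_len
                a2.query_qualities = pysam.qualitystring_to_array(
                    chr(baseq + 33) * read2_len
                )
                a2.flag = 0x1 | 0x2 | 0x10 | 0x80  # paired, proper, reverse, second
                a2.reference_id = 0
                a2.reference_start = read2_start0
                a2.mapping_quality = mapq
                a2.cigarstring = f"{read2_len}M"
                a2.next_reference_id = 0
                a2.next_reference_start = read1_start0
                a2.template_length = -(read2_start0 + read2_len - read1_start0)
                bam.write(a1)
                bam.write(a2)

    bam_path = out_dir / f"{prefix}.bam"
    pysam.sort("-o", str(bam_path), str(unsorted))
    unsorted.unlink()
    pysam.index(str(bam_path))
    bai_path = Path(str(bam_path) + ".bai")

    vcf_path = out_dir / f"{prefix}.vcf"
    with open(vcf_path, "w") as vf:
        vf.write("##fileformat=VCFv4.2\n")
        vf.write(f"##contig=<ID={chrom},length={contig_len}>\n")
        vf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in segment.snvs:
            vf.write(f"{chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t100\tPASS\t.\n")
    return bam_path, bai_path, vcf_path
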