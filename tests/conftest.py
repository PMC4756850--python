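"""Shared fixtures: tiny VCF/BAM builders for I/O-level tests."""

from pathlib import Path

import pysam
import pytest

from haplocal.loci import SnvLocus
from haplocal.segments import SegmentDef


def make_segment(snvs, chrom="chr1"):
    """Segment from (pos, ref, alt) triples."""
    return SegmentDef(
        chrom, tuple(SnvLocus(chrom, p, r, a) for p, r, a in snvs), analyzed=True
    )


@pytest.fixture
def two_snv_segment():
    return make_segment([(100, "G", "A"), (197, "G", "C")])


def write_vcf(path: Path, body_lines, contig="chr1", length=100000):
    header = (
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID={contig},length={length}>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )
    path.write_text(header + "".join(line + "\n" for line in body_lines))
    return path


def sam_read(qname, flag, pos, seq, qual, mapq=60, chrom="chr1",
             pnext=0, tlen=0, cigar=None):
    """One SAM body line; pos is 1-based, qual a list of Phred values."""
    cigar = cigar or f"{len(seq)}M"
    qstr = "".join(chr(q + 33) for q in qual)
    return (
        f"{qname}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t=\t{pnext}\t{tlen}"
        f"\t{seq}\t{qstr}"
    )


def write_bam(tmp_path: Path, body_lines, chrom="chr1", length=100000,
              name="reads") -> Path:
    """Write SAM body lines to a sorted, indexed BAM; returns the BAM path."""
    sam = tmp_path / f"{name}.sam"
    sam.write_text(
        f"@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:{chrom}\tLN:{length}\n"
        + "".join(line + "\n" for line in body_lines)
    )
    bam = tmp_path / f"{name}.bam"
    pysam.sort("-o", str(bam), str(sam))
    pysam.index(str(bam))
    return bam


def spanning_pair(qname, pattern, segment, baseq=40, mapq=60, miss_q=2):
    """A properly paired fragment whose first mate spans all segment SNVs.

    Observed SNVs carry the pattern base at ``baseq``; missing ones the ref
    base at ``miss_q`` (below any sensible gate). Mate 2 covers no SNV.
    """
    first, last = segment.span
    start = first - 10  # 1-based
    length = last - start + 11
    seq = ["A"] * length
    qual = [baseq] * length
    for r, snv in enumerate(segment.snvs):
        off = snv.pos - start
        if pattern[r] == "M":
            seq[off], qual[off] = snv.ref, miss_q
        else:
            seq[off] = pattern[r]
    m2_pos = last + 11
    lines = [
        sam_read(qname, 0x1 | 0x2 | 0x20 | 0x40, start, "".join(seq), qual,
                 mapq=mapq, chrom=segment.chrom, pnext=m2_pos,
                 tlen=m2_pos + 50 - start),
        sam_read(qname, 0x1 | 0x2 | 0x10 | 0x80, m2_pos, "A" * 50, [baseq] * 50,
                 mapq=mapq, chrom=segment.chrom, pnext=start,
                 tlen=-(m2_pos + 50 - start)),
    ]
    return lines
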