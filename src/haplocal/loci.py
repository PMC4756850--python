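"""SNV loci and VCF input.

A segment analysis starts from a call set of biallelic single-nucleotide
variants. Only SNVs enter the haplotype model; indel records are retained
separately because the post-processing filters flag SNVs adjacent to them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pysam

_BASES = frozenset("ACGT")


class VcfFormatError(ValueError):
    """Raised when the SNV input cannot be interpreted."""


@dataclass(frozen=True)
class SnvLocus:
    """One biallelic SNV: chromosome, 1-based position, ref/alt alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str
    source_line: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNV position must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"alleles must be single bases, got {self.ref!r}/{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class VcfScan:
    """Result of scanning a VCF: SNVs kept, indel positions, and bookkeeping."""

    snvs: list[SnvLocus]
    indel_positions: list[tuple[str, int]]
    n_records: int = 0
    n_excluded: int = 0
    exclusions: dict[str, int] = field(default_factory=dict)


def _record_is_pass(rec: "pysam.VariantRecord") -> bool:
    f = set(rec.filter.keys())
    return not f or f <= {"PASS", "."}


def read_snvs(vcf_source: str | os.PathLike, keep_filtered: bool = False) -> VcfScan:
    """Read biallelic SNVs (and indel positions) from a VCF.

    Multi-allelic records, indels/MNVs and — unless ``keep_filtered`` — non-PASS
    records are excluded and tallied in the returned :class:`VcfScan`.
    Records must be coordinate-sorted per chromosome.
    """
    try:
        vf = pysam.VariantFile(str(vcf_source))
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"cannot parse VCF {vcf_source}: {exc}") from exc

    scan = VcfScan(snvs=[], indel_positions=[])
    last: dict[str, int] = {}
    with vf:
        for rec in vf:
            scan.n_records += 1
            prev = last.get(rec.chrom)
            if prev is not None and rec.pos < prev:
                raise VcfFormatError(
                    f"unsorted VCF at {rec.chrom}:{rec.pos} (previous {prev}); "
                    "sort the input (e.g. bcftools sort) and retry"
                )
            last[rec.chrom] = rec.pos
            alts = rec.alts or ()
            if not keep_filtered and not _record_is_pass(rec):
                _count(scan, "non_pass")
                continue
            if len(alts) != 1:
                _count(scan, "multiallelic")
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                # indel or symbolic allele; keep position for proximity filtering
                scan.indel_positions.append((rec.chrom, rec.pos))
                _count(scan, "indel_or_mnv")
                continue
            scan.snvs.append(
                SnvLocus(rec.chrom, rec.pos, ref, alt, source_line=f"{rec.chrom}:{rec.pos}")
            )
    return scan


def _count(scan: VcfScan, reason: str) -> None:
    scan.n_excluded += 1
    scan.exclusions[reason] = scan.exclusions.get(reason, 0) + 1
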