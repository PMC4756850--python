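"""Fragment-level genotype extraction from paired-end alignments.

Each sequenced fragment (read pair) yields one observation vector over the
segment's R SNVs: the called base at every covered SNV, 'M' where the
fragment misses the SNV or the base fails a quality gate. Merging the two
mates into one observation is what lets a fragment scaffold SNVs further
apart than a single read.

Quality gates: alignments must be primary, properly paired, not duplicate,
not QC-fail, with MAPQ >= 30; a base with Phred quality < 30 is treated as
missing, as is any base that is neither the ref nor the alt allele at its
SNV (the model allows only two alleles per site). Strand and distance to
the nearest read end are recorded per SNV during the same pass so the
post-processing filters need no second traversal of the alignments.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import pysam

from .segments import SegmentDef

MISSING = "M"

DEFAULT_MAPQ_MIN = 30
DEFAULT_BASEQ_MIN = 30


@dataclass(frozen=True)
class FragmentObservation:
    """One fragment's calls over a segment's SNVs.

    calls
        Length-R string over {A,C,G,T,M}; M marks a missing readout.
    errors
        Per-base error probabilities; meaningful only where calls != M.
        May be None until :func:`assign_error_rates` runs.
    quals
        Phred base qualities where observed (None elsewhere).
    strands, end_offsets
        Strand of the covering read and distance (bp) of the covering base
        from the nearest read end, per SNV; None where unobserved.
    """

    fragment_id: str
    calls: str
    errors: tuple[float, ...] | None = None
    quals: tuple[int | None, ...] | None = None
    strands: tuple[str | None, ...] | None = None
    end_offsets: tuple[int | None, ...] | None = None

    @property
    def n_missing(self) -> int:
        return self.calls.count(MISSING)


@dataclass
class PatternCounts:
    """Multiset of observed call patterns: pattern -> fragment count."""

    counts: dict[str, int]

    @property
    def N(self) -> int:
        return sum(self.counts.values())


def collapse_patterns(observations: list[FragmentObservation]) -> PatternCounts:
    """Group identical call vectors; counts are preserved."""
    counts: dict[str, int] = {}
    for o in observations:
        counts[o.calls] = counts.get(o.calls, 0) + 1
    return PatternCounts(counts)


def expand_patterns(patterns: PatternCounts) -> list[FragmentObservation]:
    """Inverse of collapse up to fragment identity: one observation per count."""
    out = []
    for pat in sorted(patterns.counts):
        for i in range(patterns.counts[pat]):
            out.append(FragmentObservation(fragment_id=f"{pat}.{i}", calls=pat))
    return out


def assign_error_rates(
    observations: list[FragmentObservation],
    mode: str = "constant",
    e_const: float = 0.001,
) -> list[FragmentObservation]:
    """Attach per-base error probabilities e_ir.

    ``constant`` sets e_const at every observed base — the conservative
    default, since 0.001 is the largest error compatible with the Q>=30
    gate. ``phred`` converts recorded qualities via 10^(-Q/10), clipped to
    [1e-6, 1e-3].
    """
    if not 0 < e_const < 0.75:
        raise ValueError(f"error rate must lie in (0, 0.75), got {e_const}")
    if mode not in ("constant", "phred"):
        raise ValueError(f"unknown error mode {mode!r}")
    out = []
    for o in observations:
        if mode == "constant":
            errs = tuple(e_const for _ in o.calls)
        else:
            if o.quals is None:
                raise ValueError("phred mode requires recorded base qualities")
            errs = tuple(
                min(max(10.0 ** (-(q or 30) / 10.0), 1e-6), 1e-3) for q in o.quals
            )
        out.append(replace(o, errors=errs))
    return out


def _usable(aln: "pysam.AlignedSegment", mapq_min: int) -> bool:
    return (
        not aln.is_unmapped
        and not aln.is_secondary
        and not aln.is_supplementary
        and not aln.is_duplicate
        and not aln.is_qcfail
        and aln.is_proper_pair
        and aln.mapping_quality >= mapq_min
    )


def extract_fragments(
    alignments: "str | os.PathLike | pysam.AlignmentFile",
    segment: SegmentDef,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    baseq_min: int = DEFAULT_BASEQ_MIN,
) -> list[FragmentObservation]:
    """Fragment observations over a segment's SNVs from an indexed BAM/SAM.

    Mates sharing a query name are merged; when both mates cover an SNV and
    disagree, the call is conservatively set to missing. Observations that
    cover no SNV at all are dropped.
    """
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments))
        own = True
    try:
        if segment.chrom not in alignments.references:
            raise ValueError(
                f"segment chromosome {segment.chrom!r} absent from alignment header"
            )
        if not alignments.has_index():
            raise FileNotFoundError(
                f"alignment file {alignments.filename!r} has no index; "
                "run samtools index first"
            )
        start0, end0 = segment.span[0] - 1, segment.span[1]
        snv_pos0 = [s.pos - 1 for s in segment.snvs]
        alleles = [{s.ref, s.alt} for s in segment.snvs]
        R = segment.R

        # per fragment, per SNV: list of (base-or-M, qual, strand, end_offset)
        per_frag: dict[str, list[list[tuple[str, int, str, int]]]] = {}
        for aln in alignments.fetch(segment.chrom, start0, end0):
            if not _usable(aln, mapq_min):
                continue
            pairs = {
                rpos: qpos
                for qpos, rpos in aln.get_aligned_pairs(matches_only=True)
            }
            seq = aln.query_sequence
            quals = aln.query_qualities
            if seq is None or quals is None:
                continue
            slots = per_frag.setdefault(aln.query_name, [[] for _ in range(R)])
            strand = "-" if aln.is_reverse else "+"
            for r, rpos in enumerate(snv_pos0):
                qpos = pairs.get(rpos)
                if qpos is None:  # deletion, refskip or not covered
                    continue
                q = quals[qpos]
                base = seq[qpos]
                if q < baseq_min or base not in alleles[r]:
                    base = MISSING  # low quality or third allele
                slots[r].append((base, q, strand, min(qpos, len(seq) - 1 - qpos)))

        observations = []
        for name in sorted(per_frag):
            calls, qv, sv, ev = [], [], [], []
            for covers in per_frag[name]:
                base, q, strand, off = _merge_mate_calls(covers)
                calls.append(base)
                qv.append(q)
                sv.append(strand)
                ev.append(off)
            calls_s = "".join(calls)
            if calls_s == MISSING * R:
                continue
            observations.append(
                FragmentObservation(
                    fragment_id=name,
                    calls=calls_s,
                    quals=tuple(qv),
                    strands=tuple(sv),
                    end_offsets=tuple(ev),
                )
            )
        return observations
    finally:
        if own:
            alignments.close()


def _merge_mate_calls(
    covers: list[tuple[str, int, str, int]],
) -> tuple[str, int | None, str | None, int | None]:
    """Combine the mates' readouts at one SNV into a single call.

    No coverage -> M; one informative mate -> its call; two informative
    mates agreeing -> the higher-quality copy; disagreeing -> M.
    """
    informative = [c for c in covers if c[0] != MISSING]
    if not informative:
        if covers:  # covered but quality-masked: keep strand/offset for filters
            base, q, strand, off = max(covers, key=lambda c: c[1])
            return MISSING, None, strand, off
        return MISSING, None, None, None
    bases = {c[0] for c in informative}
    if len(bases) > 1:
        return MISSING, None, None, None
    base, q, strand, off = max(informative, key=lambda c: c[1])
    return base, q, strand, off
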