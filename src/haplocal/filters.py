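"""Post-processing filters for called segments.

Sequencing and alignment artifacts (clustered calls, indel-adjacent SNVs,
read-end pileup, strand bias) can fabricate apparent extra haplotypes.
Each filter is a pure predicate on a record plus its fragment observations;
three stringency levels compose them. Records are never deleted — a failing
record keeps its posteriors and gets the failing filter names in its
FILTER column; only PASS records count as reported LHVs.

Level I  : close-SNV proximity filter.
Level II : level I + indel adjacency + read-end bias.
Level III: level II + strand bias (two-sided Fisher exact test per SNV).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from scipy.stats import fisher_exact

from .hcf import HcfRecord
from .reads import MISSING, FragmentObservation

LEVELS = ("I", "II", "III")


@dataclass(frozen=True)
class FilterConfig:
    level: str = "I"
    min_snv_gap: int = 50
    indel_window: int = 10
    end_window: int = 5
    end_fraction_max: float = 0.9
    strand_bias_p: float = 0.005

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"filter level must be one of {LEVELS}, got {self.level!r}")
        if min(self.min_snv_gap, self.indel_window, self.end_window) < 0:
            raise ValueError("filter windows must be >= 0")
        if not 0 < self.end_fraction_max <= 1:
            raise ValueError("end_fraction_max must lie in (0, 1]")
        if not 0 < self.strand_bias_p < 1:
            raise ValueError("strand_bias_p must lie in (0, 1)")


def filter_close_snvs(record: HcfRecord, cfg: FilterConfig) -> str | None:
    """Fail when any adjacent SNV pair is closer than min_snv_gap bp."""
    for a, b in zip(record.positions, record.positions[1:]):
        if b - a < cfg.min_snv_gap:
            return "close_snvs"
    return None


def filter_near_indel(
    record: HcfRecord, indel_positions: list[tuple[str, int]], cfg: FilterConfig
) -> str | None:
    """Fail when any segment SNV lies within indel_window bp of an indel."""
    for chrom, ipos in indel_positions:
        if chrom != record.chrom:
            continue
        for pos in record.positions:
            if abs(pos - ipos) <= cfg.indel_window:
                return "near_indel"
    return None


def filter_read_end_bias(
    record: HcfRecord, observations: list[FragmentObservation], cfg: FilterConfig
) -> str | None:
    """Fail when an SNV's bases pile up near read ends.

    Per SNV: the fraction of covering reads whose base sits within
    end_window bp of a read end must not exceed end_fraction_max. An SNV
    with no covering reads is vacuously passing.
    """
    R = len(record.positions)
    for r in range(R):
        offsets = [
            o.end_offsets[r]
            for o in observations
            if o.end_offsets is not None and o.end_offsets[r] is not None
        ]
        if not offsets:
            continue
        near = sum(1 for off in offsets if off <= cfg.end_window)
        if near / len(offsets) > cfg.end_fraction_max:
            return "read_end_bias"
    return None


def filter_strand_bias(
    record: HcfRecord, observations: list[FragmentObservation], cfg: FilterConfig
) -> str | None:
    """Fail when allele and strand are associated at any SNV.

    Builds the 2x2 (ref/alt) x (+/-) table of covering reads and applies a
    two-sided Fisher exact test; p < strand_bias_p fails. Degenerate margins
    (an allele or strand entirely absent) pass: the test is undefined.
    """
    for r, (ref, alt) in enumerate(record.alleles):
        table = {("+", ref): 0, ("+", alt): 0, ("-", ref): 0, ("-", alt): 0}
        for o in observations:
            if o.strands is None:
                continue
            base = o.calls[r]
            strand = o.strands[r]
            if base == MISSING or strand not in ("+", "-"):
                continue
            table[(strand, base)] += 1
        m = [
            [table[("+", ref)], table[("+", alt)]],
            [table[("-", ref)], table[("-", alt)]],
        ]
        if min(sum(m[0]), sum(m[1])) == 0 or min(m[0][0] + m[1][0], m[0][1] + m[1][1]) == 0:
            continue
        _, p = fisher_exact(m, alternative="two-sided")
        if p < cfg.strand_bias_p:
            return "strand_bias"
    return None


def apply_stringency(
    records: list[HcfRecord],
    observations_by_record: dict[tuple[str, tuple[int, ...]], list[FragmentObservation]],
    indel_positions: list[tuple[str, int]],
    cfg: FilterConfig,
) -> list[HcfRecord]:
    """Apply the configured stringency level; set each record's FILTER field.

    ``observations_by_record`` maps ``(chrom, positions)`` to the segment's
    fragment observations.
    """
    out = []
    for rec in records:
        obs = observations_by_record.get((rec.chrom, rec.positions), [])
        failures = []
        verdict = filter_close_snvs(rec, cfg)
        if verdict:
            failures.append(verdict)
        if cfg.level in ("II", "III"):
            for verdict in (
                filter_near_indel(rec, indel_positions, cfg),
                filter_read_end_bias(rec, obs, cfg),
            ):
                if verdict:
                    failures.append(verdict)
        if cfg.level == "III":
            verdict = filter_strand_bias(rec, obs, cfg)
            if verdict:
                failures.append(verdict)
        out.append(replace(rec, filter_status=";".join(failures) if failures else "PASS"))
    return out
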