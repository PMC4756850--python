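"""SNV segmentation.

SNVs are chained left-to-right into maximal segments in which every pair of
consecutive SNVs lies within K bp; a segment is the unit of local-haplotype
analysis. Isolated SNVs (no neighbour within K) belong to no segment.
Segments with more than R_max SNVs are kept but marked not-analyzed: the
configuration space of the presence model grows as 2^(2^R), so exact
inference is restricted to small R.
"""

from __future__ import annotations

from dataclasses import dataclass

from .loci import SnvLocus

DEFAULT_K = 500
DEFAULT_R_MAX = 3


@dataclass(frozen=True)
class SegmentDef:
    """A maximal run of proximal SNVs on one chromosome."""

    chrom: str
    snvs: tuple[SnvLocus, ...]
    analyzed: bool

    @property
    def R(self) -> int:
        return len(self.snvs)

    @property
    def span(self) -> tuple[int, int]:
        return (self.snvs[0].pos, self.snvs[-1].pos)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.pos for s in self.snvs)


def build_segments(
    snvs: list[SnvLocus], K: int = DEFAULT_K, r_max: int = DEFAULT_R_MAX
) -> tuple[list[SegmentDef], int]:
    """Greedy pairwise-gap chaining of sorted SNVs into segments.

    Returns ``(segments, orphan_count)`` where orphans are SNVs in no
    segment. ``K`` is inclusive: a gap of exactly K bp still chains.
    Chromosome boundaries always break segments.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if r_max < 2:
        raise ValueError(f"r_max must be >= 2, got {r_max}")
    for a, b in zip(snvs, snvs[1:]):
        if a.chrom == b.chrom and b.pos < a.pos:
            raise ValueError(f"SNVs not sorted: {a.chrom}:{a.pos} precedes {b.chrom}:{b.pos}")

    segments: list[SegmentDef] = []
    orphans = 0
    run: list[SnvLocus] = []

    def close() -> None:
        nonlocal orphans
        if len(run) >= 2:
            segments.append(SegmentDef(run[0].chrom, tuple(run), analyzed=len(run) <= r_max))
        elif run:
            orphans += 1
        run.clear()

    for snv in snvs:
        if run and (snv.chrom != run[-1].chrom or snv.pos - run[-1].pos > K):
            close()
        run.append(snv)
    close()
    return segments, orphans
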