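"""Haplotype call format (hcf) I/O and the IGV-loadable track.

An hcf file is a vcf-like tab-delimited text file: '##' header lines, a
'#'-prefixed column header, one line per analyzed segment with seven
fields (CHROM, POSITIONS, ALLELES, HAPLOTYPES, SUPPORT, N_SIG, FILTER),
and an end-of-file summary block counting segments by number of
significant haplotypes. Compound fields are comma-separated with
':'-separated subfields; posteriors are serialized to six decimals so the
write/read round trip is lossless at that precision. Output is
byte-stable for identical inputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import IO, Iterable

FORMAT_VERSION = "HCFv1.0"
COLUMNS = ("CHROM", "POSITIONS", "ALLELES", "HAPLOTYPES", "SUPPORT", "N_SIG", "FILTER")
END_MARK = "##END"


class HcfFormatError(ValueError):
    """Raised when an hcf file violates the dialect."""


@dataclass(frozen=True)
class HcfRecord:
    """One analyzed segment: its SNVs, haplotype posteriors and support."""

    chrom: str
    positions: tuple[int, ...]
    alleles: tuple[tuple[str, str], ...]
    haplotype_calls: tuple[tuple[str, float, bool], ...]  # (seq, xi, significant)
    support: tuple[tuple[str, int], ...]  # (pattern over {A,C,G,T,M}^R, count)
    filter_status: str = "PASS"

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.alleles):
            raise ValueError("positions and alleles must have equal length")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")
        for _, xi, _ in self.haplotype_calls:
            if not 0.0 <= xi <= 1.0:
                raise ValueError(f"posterior {xi} outside [0,1]")

    @property
    def n_significant(self) -> int:
        return sum(1 for _, _, sig in self.haplotype_calls if sig)

    @property
    def is_lhv(self) -> bool:
        return self.n_significant >= 3


@dataclass
class HcfSummary:
    """End-of-file tallies: SNVs read, segments per significance count."""

    n_snvs_in_vcf: int = 0
    counts_by_n_significant: dict[int, int] = field(default_factory=dict)
    n_not_analyzed: int = 0

    def __post_init__(self) -> None:
        for k, v in self.counts_by_n_significant.items():
            if not 0 <= k <= 8 or v < 0:
                raise ValueError("significance counts limited to keys 0..8, values >= 0")


def _fmt_record(rec: HcfRecord) -> str:
    pos = ",".join(str(p) for p in rec.positions)
    alle = ",".join(f"{r}:{a}" for r, a in rec.alleles)
    haps = ",".join(
        f"{seq}:{xi:.6f}:{1 if sig else 0}" for seq, xi, sig in rec.haplotype_calls
    ) or "."
    supp = ",".join(f"{pat}:{n}" for pat, n in rec.support) or "."
    return "\t".join(
        (rec.chrom, pos, alle, haps, supp, str(rec.n_significant), rec.filter_status)
    )


def write_hcf(
    records: Iterable[HcfRecord],
    summary: HcfSummary,
    sink: "str | os.PathLike | IO[str]",
    parameters: dict[str, object] | None = None,
) -> None:
    """Write records plus the summary block to ``sink`` (path or text handle)."""
    own = isinstance(sink, (str, os.PathLike))
    fh = open(sink, "w") if own else sink
    try:
        fh.write(f"##fileformat={FORMAT_VERSION}\n")
        fh.write("##source=haplocal\n")
        for key, val in (parameters or {}).items():
            fh.write(f"##{key}={val}\n")
        fh.write("#" + "\t".join(COLUMNS) + "\n")
        for rec in records:
            fh.write(_fmt_record(rec) + "\n")
        fh.write("##SUMMARY\n")
        fh.write(f"##n_snvs_in_vcf={summary.n_snvs_in_vcf}\n")
        for k in range(9):
            fh.write(
                f"##segments_with_{k}_significant="
                f"{summary.counts_by_n_significant.get(k, 0)}\n"
            )
        fh.write(f"##segments_not_analyzed={summary.n_not_analyzed}\n")
        fh.write(END_MARK + "\n")
    finally:
        if own:
            fh.close()


def _parse_record(line: str, lineno: int) -> HcfRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 7:
        raise HcfFormatError(
            f"line {lineno}: expected 7 tab-delimited fields, found {len(fields)}"
        )
    chrom, pos_s, alle_s, haps_s, supp_s, n_sig_s, filt = fields
    positions = tuple(int(p) for p in pos_s.split(","))
    alleles = tuple(tuple(a.split(":")) for a in alle_s.split(","))
    haps = ()
    if haps_s != ".":
        haps = tuple(
            (seq, float(xi), flag == "1")
            for seq, xi, flag in (h.split(":") for h in haps_s.split(","))
        )
    supp = ()
    if supp_s != ".":
        supp = tuple(
            (pat, int(n)) for pat, n in (s.split(":") for s in supp_s.split(","))
        )
    rec = HcfRecord(chrom, positions, alleles, haps, supp, filt)
    if rec.n_significant != int(n_sig_s):
        raise HcfFormatError(
            f"line {lineno}: N_SIG={n_sig_s} disagrees with significant flags"
        )
    return rec


def read_hcf(source: "str | os.PathLike | IO[str]") -> tuple[list[HcfRecord], HcfSummary]:
    """Parse a file produced by :func:`write_hcf`."""
    own = isinstance(source, (str, os.PathLike))
    fh = open(source) if own else source
    try:
        lines = fh.read().splitlines()
    finally:
        if own:
            fh.close()
    if not lines or not lines[0].startswith("##fileformat="):
        raise HcfFormatError("missing ##fileformat header line")
    version = lines[0].split("=", 1)[1]
    if version != FORMAT_VERSION:
        raise HcfFormatError(f"unsupported hcf version {version!r}")
    if lines[-1] != END_MARK:
        raise HcfFormatError("truncated hcf file: end marker missing")

    records: list[HcfRecord] = []
    summary = HcfSummary()
    in_summary = False
    for lineno, line in enumerate(lines[1:], start=2):
        if line == END_MARK:
            break
        if line == "##SUMMARY":
            in_summary = True
            continue
        if in_summary:
            key, _, val = line.removeprefix("##").partition("=")
            if key == "n_snvs_in_vcf":
                summary.n_snvs_in_vcf = int(val)
            elif key == "segments_not_analyzed":
                summary.n_not_analyzed = int(val)
            elif key.startswith("segments_with_"):
                k = int(key.split("_")[2])
                summary.counts_by_n_significant[k] = int(val)
            continue
        if line.startswith("#"):
            continue
        records.append(_parse_record(line, lineno))
    return records, summary


RED = "255,0,0"
BLUE = "0,0,255"


def write_igv_track(
    records: Iterable[HcfRecord], sink: "str | os.PathLike | IO[str]"
) -> None:
    """BED9 track: red bars for LHV segments (>2 significant), blue otherwise.

    Intervals are 0-based half-open spanning the segment's SNVs.
    """
    own = isinstance(sink, (str, os.PathLike))
    fh = open(sink, "w") if own else sink
    try:
        fh.write('track name="haplocal LHV" itemRgb="On"\n')
        for rec in records:
            start = rec.positions[0] - 1
            end = rec.positions[-1]
            color = RED if rec.is_lhv else BLUE
            name = "LHV" if rec.is_lhv else "LH"
            fh.write(
                f"{rec.chrom}\t{start}\t{end}\t{name}\t0\t.\t{start}\t{end}\t{color}\n"
            )
    finally:
        if own:
            fh.close()
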