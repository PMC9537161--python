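"""Cut-site demultiplexing from PAF alignments.

Reads are assigned to the cut-site (and hence sample) whose position they
start and/or end at, after filtering for reads that (a) align only to the
mitochondrial contig, (b) have all segments on one strand, (c) traverse the
circular genome consistently and (d) are almost fully mapped.  Four
selection strategies of decreasing stringency are supported: ``both``
(full-length reads only), ``start``, ``either`` and ``xor`` (fragments
only; excludes full-length reads).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from .model import ConfigError, CutSite, CutSiteConfig, MitoGenome

# assignment statuses, in reporting order
STATUSES = (
    "assigned",
    "non_mito",
    "strand_inconsistent",
    "order_inconsistent",
    "low_mapped_fraction",
    "overlong_span",
    "no_cutsite_match",
    "ambiguous",
    "missing_from_fastq",
    "unaligned",
)


class PafParseError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentSegment:
    """One PAF record: a contiguous aligned segment of a read."""

    read_id: str
    read_len: int
    read_start: int
    read_end: int
    strand: str
    target: str
    target_start: int
    target_end: int
    mapq: int
    is_secondary: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.read_start < self.read_end <= self.read_len):
            raise PafParseError(
                f"{self.read_id}: bad read interval "
                f"[{self.read_start},{self.read_end}) of length {self.read_len}"
            )
        if not self.target_start < self.target_end:
            raise PafParseError(f"{self.read_id}: bad target interval")
        if self.strand not in "+-":
            raise PafParseError(f"{self.read_id}: bad strand {self.strand!r}")


@dataclass
class ReadAlignment:
    """All (non-secondary) aligned segments of one read."""

    read_id: str
    segments: list[AlignmentSegment]


@dataclass
class ReadAssignment:
    read_id: str
    status: str
    cut_site: str = ""
    matched_ends: str = ""  # "start", "end", "both" or ""

    def __post_init__(self) -> None:
        if (self.status == "assigned") != bool(self.cut_site):
            raise ValueError("cut_site must be set exactly when status is 'assigned'")


def parse_paf(stream: TextIO | Iterable[str]) -> dict[str, ReadAlignment]:
    """Parse PAF lines into per-read alignments (insertion-ordered).

    Only the 12 mandatory columns are used, plus the ``tp:A`` tag to drop
    secondary alignments.  Malformed lines raise :class:`PafParseError`
    with the offending line number.
    """
    reads: dict[str, ReadAlignment] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise PafParseError(f"PAF line {lineno}: expected >=12 columns, got {len(cols)}")
        try:
            secondary = any(c == "tp:A:S" for c in cols[12:])
            seg = AlignmentSegment(
                read_id=cols[0],
                read_len=int(cols[1]),
                read_start=int(cols[2]),
                read_end=int(cols[3]),
                strand=cols[4],
                target=cols[5],
                target_start=int(cols[7]),
                target_end=int(cols[8]),
                mapq=int(cols[11]),
                is_secondary=secondary,
            )
        except (ValueError, PafParseError) as exc:
            raise PafParseError(f"PAF line {lineno}: {exc}") from exc
        if seg.is_secondary:
            continue
        ra = reads.get(seg.read_id)
        if ra is None:
            reads[seg.read_id] = ReadAlignment(seg.read_id, [seg])
        else:
            ra.segments.append(seg)
    return reads


def validate_read(
    ra: ReadAlignment,
    genome_name: str,
    genome_length: int,
    min_mapped_frac: float = 0.90,
) -> str:
    """Apply the read-consistency filters; return ``"pass"`` or a status.

    A read passes only if every segment maps to the mitochondrial contig
    with positive mapping quality on at least one segment, all segments
    share a strand, the segments traverse the (circular) genome in read
    order without backtracking, the traversed span does not exceed one
    genome length, and at least ``min_mapped_frac`` of the read bases are
    covered by segments.
    """
    if not ra.segments:
        raise ValueError("empty ReadAlignment")
    l = genome_length
    if any(s.target != genome_name for s in ra.segments):
        return "non_mito"
    if all(s.mapq == 0 for s in ra.segments):
        return "non_mito"  # not uniquely aligned
    strands = {s.strand for s in ra.segments}
    if len(strands) > 1:
        return "strand_inconsistent"
    strand = strands.pop()

    segs = sorted(ra.segments, key=lambda s: s.read_start)
    # direction-adjusted genomic start of each segment: the genome position
    # of the segment's first sequenced base
    if strand == "+":
        starts = [s.target_start for s in segs]
        lens = [s.target_end - s.target_start for s in segs]
    else:
        # read bases advance towards decreasing genome coordinates; flip so
        # progression is increasing in the adjusted coordinate
        starts = [l - s.target_end for s in segs]
        lens = [s.target_end - s.target_start for s in segs]

    # rotate so the first read-space segment is the origin; progression must
    # be non-decreasing and stay within one genome length
    origin = starts[0]
    rel = [(st - origin) % l for st in starts]
    if any(b < a for a, b in zip(rel, rel[1:])):
        return "order_inconsistent"
    span = rel[-1] + lens[-1]
    if span > l:
        return "overlong_span"

    covered = _union_length([(s.read_start, s.read_end) for s in segs])
    if covered < min_mapped_frac * segs[0].read_len:
        return "low_mapped_fraction"
    return "pass"


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total, last_end = 0, -1
    for a, b in sorted(intervals):
        a = max(a, last_end)
        if b > a:
            total += b - a
            last_end = b
    return total


def read_span(ra: ReadAlignment, genome_length: int) -> tuple[int, int, str]:
    """Genome positions of the read's 5' and 3' ends (0-based), with strand.

    For a plus-strand read the 5' end is the lowest genome coordinate of
    the first read-space segment; for a minus-strand read the 5' end is the
    highest genome coordinate (the first sequenced base).
    """
    segs = sorted(ra.segments, key=lambda s: s.read_start)
    strand = segs[0].strand
    if strand == "+":
        return segs[0].target_start, segs[-1].target_end - 1, "+"
    return segs[0].target_end - 1, segs[-1].target_start, "-"


def match_cut_site(
    span: tuple[int, int, str], config: CutSiteConfig, genome_length: int
) -> tuple[CutSite | None, CutSite | None]:
    """Match the read's 5' and 3' ends against the configured cut-sites.

    A Cas9 break at 1-based position ``m.c`` opens the circle between
    0-based positions ``c-2`` and ``c-1``: plus-strand reads start at
    ``c-1`` and run forward, minus-strand reads start at ``c-2`` and run
    backward.  The start of a read matches a cut-site if it lies at most
    ``tolerance_bp`` after the break in the direction of synthesis, and the
    end if it lies at most ``tolerance_bp`` before the break.  Ties
    (several cut-sites within tolerance) are reported as ambiguous by the
    caller; the closest match is returned here.
    """
    p5, p3, strand = span
    l = genome_length
    tol = config.tolerance_bp
    best_start: tuple[int, CutSite] | None = None
    best_end: tuple[int, CutSite] | None = None
    for cut in config.cut_sites:
        c = cut.position0
        if strand == "+":
            off_start = (p5 - c) % l
            off_end = (c - 1 - p3) % l
        else:
            off_start = (c - 1 - p5) % l
            off_end = (p3 - c) % l
        if off_start <= tol and (best_start is None or off_start < best_start[0]):
            best_start = (off_start, cut)
        if off_end <= tol and (best_end is None or off_end < best_end[0]):
            best_end = (off_end, cut)
    return (
        best_start[1] if best_start else None,
        best_end[1] if best_end else None,
    )


def select_read(
    read_id: str,
    matches: tuple[CutSite | None, CutSite | None],
    strategy: str,
) -> ReadAssignment:
    """Turn cut-site matches into an assignment under a selection strategy.

    ``both`` assigns only reads whose start and end match the same
    cut-site (full-length reads); ``start`` needs a start match; ``either``
    needs a start or end match; ``xor`` needs exactly one of the two
    (fragments only).  A read whose start and end match different cut-sites
    is rejected as ambiguous rather than arbitrarily assigned.
    """
    start, end = matches
    if strategy not in ("both", "start", "either", "xor"):
        raise ConfigError(f"unknown strategy {strategy!r}")
    if start is not None and end is not None and start.name != end.name:
        return ReadAssignment(read_id, "ambiguous")
    ends = "both" if (start and end) else ("start" if start else ("end" if end else ""))
    if strategy == "both":
        chosen = start if (start and end and start.name == end.name) else None
    elif strategy == "start":
        chosen = start
    elif strategy == "either":
        chosen = start or end
    else:  # xor
        chosen = (start or end) if bool(start) != bool(end) else None
    if chosen is None:
        return ReadAssignment(read_id, "no_cutsite_match")
    return ReadAssignment(read_id, "assigned", cut_site=chosen.name, matched_ends=ends)


def assign_reads(
    alignments: dict[str, ReadAlignment],
    config: CutSiteConfig,
    genome: MitoGenome,
    strategy: str | None = None,
    min_mapped_frac: float | None = None,
) -> dict[str, ReadAssignment]:
    """Run the full validation + matching + selection chain on every read."""
    strategy = strategy or config.strategy
    frac = config.min_mapped_frac if min_mapped_frac is None else min_mapped_frac
    out: dict[str, ReadAssignment] = {}
    for read_id, ra in alignments.items():
        status = validate_read(ra, genome.name, genome.l, frac)
        if status != "pass":
            out[read_id] = ReadAssignment(read_id, status)
            continue
        span = read_span(ra, genome.l)
        matches = match_cut_site(span, config, genome.l)
        out[read_id] = select_read(read_id, matches, strategy)
    return out


@dataclass
class DemuxReport:
    """Per-status and per-cut-site read counts for one demultiplexing run."""

    status_counts: dict[str, int] = field(default_factory=dict)
    cutsite_counts: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0

    def to_tsv(self) -> str:
        lines = ["category\tname\tcount"]
        for s in STATUSES:
            lines.append(f"status\t{s}\t{self.status_counts.get(s, 0)}")
        for name in sorted(self.cutsite_counts):
            lines.append(f"cut_site\t{name}\t{self.cutsite_counts[name]}")
        lines.append(f"total\t-\t{self.total_reads}")
        return "\n".join(lines) + "\n"


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, full 4-line record, sequence) from a FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise ValueError(f"truncated FASTQ record at end of {path}")
            read_id = header[1:].split()[0]
            yield read_id, header + seq + plus + qual, seq.strip()


def demultiplex(
    fastq: str | Path,
    paf: str | Path,
    config: CutSiteConfig,
    genome: MitoGenome,
    out_dir: str | Path,
    strategy: str | None = None,
) -> DemuxReport:
    """Split a FASTQ into one file per cut-site according to PAF alignments.

    Each assigned read is written verbatim to
    ``<out_dir>/<sample>_<cutsite>.fastq``; every read in the FASTQ is
    counted under exactly one status, so status counts sum to the input
    read count.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(paf) as fh:
        alignments = parse_paf(fh)
    assignments = assign_reads(alignments, config, genome, strategy=strategy)

    report = DemuxReport()
    handles: dict[str, TextIO] = {}
    try:
        for cut in config.cut_sites:
            path = out_dir / f"{cut.sample}_{cut.name}.fastq"
            handles[cut.name] = open(path, "w")
        seen: set[str] = set()
        for read_id, record, _seq in _iter_fastq(fastq):
            seen.add(read_id)
            asn = assignments.get(read_id)
            if asn is None:
                status = "unaligned"
            else:
                status = asn.status
                if status == "assigned":
                    handles[asn.cut_site].write(record)
                    report.cutsite_counts[asn.cut_site] = (
                        report.cutsite_counts.get(asn.cut_site, 0) + 1
                    )
            report.status_counts[status] = report.status_counts.get(status, 0) + 1
            report.total_reads += 1
        missing = set(alignments) - seen
        if missing:
            print(
                f"warning: {len(missing)} aligned read(s) absent from FASTQ",
                file=sys.stderr,
            )
            report.status_counts["missing_from_fastq"] = len(missing)
    finally:
        for fh in handles.values():
            fh.close()
    return report
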