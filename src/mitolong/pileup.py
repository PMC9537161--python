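"""Per-read pileup over the collapsed circular genome.

Alignments against the doubled custom references are ingested with pysam,
every aligned base is collapsed back onto the circle with
``(x - d) mod l``, and the result is held as two dense matrices (one read
per row, one genome position per column): base codes and base qualities.
The matrices serve three consumers:

* per-site stratified allele counts (:class:`SiteCounts`) for the
  maximum-likelihood caller,
* the per-read text view used for SNV phasing,
* per-read deletion intervals for long-deletion disentangling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
import pysam

from .model import CoordinateError, QualityModel

# base codes in the pileup matrix
SKIP, A, C, G, T, DEL = 0, 1, 2, 3, 4, 5
CODE_OF = {"A": A, "C": C, "G": G, "T": T, "N": SKIP}
CHAR_OF = np.array([".", "A", "C", "G", "T", "-"])
DEL_ALLELE = "-"

# byte-value -> base-code lookup for fast sequence encoding
_BYTE_CODE = np.zeros(256, dtype=np.uint8)
for _b, _c in CODE_OF.items():
    _BYTE_CODE[ord(_b)] = _c
    _BYTE_CODE[ord(_b.lower())] = _c


def encode_seq(seq: str) -> np.ndarray:
    """DNA string -> base-code array (unknown characters become SKIP)."""
    return _BYTE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ReadDeletionInterval:
    """One CIGAR D run on one read, in collapsed genome coordinates."""

    row: int
    read_id: str
    start: int
    length: int
    qual: int  # quality of the preceding base


@dataclass
class SiteCounts:
    """Stratified allele observations at one genome position.

    ``counts`` maps ``(allele, strand, q)`` to a count, where ``allele`` is
    a base, ``-`` for a deletion, or ``base+seq`` for a base carrying an
    insertion; ``strand`` is ``+``/``-`` and ``q`` the Phred quality level.
    """

    position: int
    counts: dict[tuple[str, str, int], int] = field(default_factory=dict)

    def add(self, allele: str, strand: str, q: int, n: int = 1) -> None:
        key = (allele, strand, q)
        self.counts[key] = self.counts.get(key, 0) + n

    def depth(self) -> int:
        return sum(self.counts.values())

    def alleles(self) -> list[str]:
        return sorted({a for a, _, _ in self.counts})

    def strand_counts(self, allele: str) -> tuple[int, int]:
        fwd = sum(n for (a, s, _), n in self.counts.items() if a == allele and s == "+")
        rev = sum(n for (a, s, _), n in self.counts.items() if a == allele and s == "-")
        return fwd, rev

    def by_quality(self, allele: str) -> dict[int, int]:
        out: dict[int, int] = {}
        for (a, _s, q), n in self.counts.items():
            if a == allele:
                out[q] = out.get(q, 0) + n
        return out

    def qualities(self, allele: str) -> list[int]:
        """Per-observation quality list for one allele (for rank tests)."""
        out: list[int] = []
        for (a, _s, q), n in self.counts.items():
            if a == allele:
                out.extend([q] * n)
        return out


class Pileup:
    """Dense per-read pileup over a circular genome of length ``l``.

    ``codes[r, p]`` is the base code of read ``r`` at collapsed position
    ``p`` (0 = not covered), ``quals[r, p]`` the base quality (-1 where not
    covered; deletions carry the quality of the preceding base).
    """

    def __init__(self, l: int) -> None:
        self.l = l
        self.codes = np.zeros((0, l), dtype=np.uint8)
        self.quals = np.full((0, l), -1, dtype=np.int8)
        self.strands: list[str] = []
        self.read_ids: list[str] = []
        self.insertions: dict[tuple[int, int], tuple[str, int]] = {}
        self.deletions: list[ReadDeletionInterval] = []

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    def coverage(self) -> np.ndarray:
        """Read depth at every genome position (aligned bases + deletions)."""
        return (self.codes != SKIP).sum(axis=0)

    # -- construction -----------------------------------------------------

    def _grow(self, n: int) -> None:
        self.codes = np.vstack([self.codes, np.zeros((n, self.l), dtype=np.uint8)])
        self.quals = np.vstack([self.quals, np.full((n, self.l), -1, dtype=np.int8)])

    def add_read(
        self,
        read_id: str,
        strand: str,
        ref_start: int,
        cigartuples: Sequence[tuple[int, int]],
        seq: str,
        quals: Sequence[int],
        d: int,
    ) -> None:
        """Add one aligned read, collapsing custom-reference coordinates."""
        row = self.n_reads
        self._grow(1)
        self.read_ids.append(read_id)
        self.strands.append(strand)
        codes_row = self.codes[row]
        quals_row = self.quals[row]
        l = self.l
        pos = ref_start  # custom-reference coordinate
        qpos = 0
        seq_codes = encode_seq(seq) if seq else np.zeros(0, dtype=np.uint8)
        qarr = np.asarray(quals, dtype=np.int8)
        for op, n in cigartuples:
            if op in (0, 7, 8):  # M, =, X
                g = (pos - d) % l
                self._assign(codes_row, g, seq_codes[qpos : qpos + n])
                self._assign(quals_row, g, qarr[qpos : qpos + n])
                pos += n
                qpos += n
            elif op == 1:  # I: anchored at the preceding aligned base
                anchor = (pos - 1 - d) % l
                ins_seq = seq[qpos : qpos + n]
                ins_q = int(qarr[qpos : qpos + n].min()) if n else 0
                self.insertions[(row, anchor)] = (ins_seq, ins_q)
                qpos += n
            elif op == 2:  # D
                g = (pos - d) % l
                prev_q = int(qarr[qpos - 1]) if qpos > 0 else int(qarr[0])
                self._assign(codes_row, g, np.full(n, DEL, dtype=np.uint8))
                self._assign(quals_row, g, np.full(n, prev_q, dtype=np.int8))
                self.deletions.append(
                    ReadDeletionInterval(row, read_id, g, n, prev_q)
                )
                pos += n
            elif op == 3:  # N: skip
                pos += n
            elif op == 4:  # S
                qpos += n
            elif op == 5:  # H
                raise ValueError(f"hard-clipped alignment not supported ({read_id})")
            else:
                raise ValueError(f"unsupported CIGAR op {op} in {read_id}")

    def _assign(self, row: np.ndarray, g: int, values: np.ndarray) -> None:
        """Assign a block starting at collapsed position g, wrapping mod l."""
        n = len(values)
        if n == 0:
            return
        l = self.l
        if g + n <= l:
            row[g : g + n] = values
        else:
            k = l - g
            row[g:] = values[:k]
            row[: n - k] = values[k:]

    # -- derived products -------------------------------------------------

    def site_counts(
        self, position: int, qm: QualityModel, exclude_rows: set[int] | None = None
    ) -> SiteCounts:
        """Stratified counts at one position, applying the quality floor."""
        col_codes = self.codes[:, position]
        col_quals = self.quals[:, position]
        sc = SiteCounts(position)
        for row in np.nonzero(col_codes != SKIP)[0]:
            if exclude_rows and int(row) in exclude_rows:
                continue
            q = int(col_quals[row])
            if q < qm.q_min:
                continue
            code = int(col_codes[row])
            allele = str(CHAR_OF[code])
            ins = self.insertions.get((int(row), position))
            if ins is not None and code != DEL:
                allele = f"{allele}+{ins[0]}"
                q = min(q, ins[1])
            sc.add(allele, self.strands[row], q)
        return sc

    def code_counts(self, qm: QualityModel) -> np.ndarray:
        """(code, strand, position) observation counts above the quality floor."""
        ok = (self.codes != SKIP) & (self.quals >= qm.q_min)
        fwd = np.array([s == "+" for s in self.strands], dtype=bool)[:, None]
        out = np.zeros((DEL + 1, 2, self.l), dtype=np.int32)
        for code in range(1, DEL + 1):
            hit = (self.codes == code) & ok
            out[code, 0] = (hit & fwd).sum(axis=0)
            out[code, 1] = (hit & ~fwd).sum(axis=0)
        return out

    def candidate_columns(self, qm: QualityModel, ref_codes: np.ndarray) -> np.ndarray:
        """Positions where a non-reference allele could pass the per-strand rule.

        Vectorised pre-screen: a position is returned if some code other
        than the reference base there has >= 2 observations on each
        strand, or an insertion is anchored there.  Exact candidacy is
        re-checked per site by the caller.
        """
        counts = self.code_counts(qm)
        passing = (counts[:, 0, :] >= 2) & (counts[:, 1, :] >= 2)  # (code, pos)
        codes = np.arange(DEL + 1)[:, None]
        nonref = passing & (codes != ref_codes[None, :])
        cand = nonref[1:].any(axis=0)
        for (_row, col) in self.insertions:
            cand[col] = True
        return np.nonzero(cand)[0]

    def rows_covering(self, positions: Sequence[int]) -> np.ndarray:
        cov = np.ones(self.n_reads, dtype=bool)
        for p in positions:
            cov &= self.codes[:, p] != SKIP
        return np.nonzero(cov)[0]


def build_pileup(
    alignments: str | Path | Iterable[str | Path],
    l: int,
    d: int,
    quality_model: QualityModel | None = None,
) -> Pileup:
    """Build a pileup from one or more SAM/BAM files against custom references.

    Files are read in the given order and records in file (read) order, so
    merged multi-cut-site inputs keep their read order.  Alignments must
    carry base qualities; coordinates must lie within the doubled
    reference ``[0, 2(l + d))``.
    """
    if isinstance(alignments, (str, Path)):
        alignments = [alignments]
    pile = Pileup(l)
    for path in alignments:
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for aln in af:
                if aln.is_unmapped or aln.is_secondary:
                    continue
                if aln.query_qualities is None:
                    raise ValueError(f"read {aln.query_name} lacks base qualities")
                ref_end = aln.reference_end or aln.reference_start
                if not (0 <= aln.reference_start and ref_end <= 2 * (l + d)):
                    raise CoordinateError(
                        f"read {aln.query_name} aligned outside the custom reference"
                    )
                pile.add_read(
                    read_id=aln.query_name,
                    strand="-" if aln.is_reverse else "+",
                    ref_start=aln.reference_start,
                    cigartuples=aln.cigartuples or [],
                    seq=aln.query_sequence or "",
                    quals=list(aln.query_qualities),
                    d=d,
                )
    return pile


def view_matrix(pile: Pileup, header: bool = False) -> str:
    """Render the pileup as fixed-width text: one row per read, ``l`` columns.

    Aligned bases print as ``ACGT``, deletions as ``-``, uncovered
    positions as ``.``; a base carrying an insertion immediately after it
    is printed lower-case (the insertion itself is anchored, not
    expanded).
    """
    rows = CHAR_OF[pile.codes]
    lines = []
    if header:
        lines.append("".join(str((p + 1) % 10) for p in range(pile.l)))
    for r in range(pile.n_reads):
        chars = rows[r]
        anchors = [col for (row, col) in pile.insertions if row == r]
        if anchors:
            chars = chars.copy()
            for col in anchors:
                chars[col] = chars[col].lower()
        lines.append("".join(chars))
    return "\n".join(lines) + "\n"


def write_view(pile: Pileup, out: TextIO | str | Path, header: bool = False) -> None:
    text = view_matrix(pile, header=header)
    if hasattr(out, "write"):
        out.write(text)  # type: ignore[union-attr]
    else:
        Path(out).write_text(text)


def phase_frequencies(
    pile: Pileup, positions: Sequence[int]
) -> dict[tuple[str, ...], tuple[int, float]]:
    """Haplotype counts and frequencies across a set of 1-based positions.

    Only reads covering *all* selected positions contribute; each read's
    haplotype is the tuple of its view characters at those positions.
    Returns ``{haplotype: (count, frequency)}`` with frequencies summing
    to 1 over the covering reads.
    """
    if not positions:
        raise ValueError("empty position set")
    cols = [p - 1 for p in positions]
    for col in cols:
        if not (0 <= col < pile.l):
            raise CoordinateError(f"position {col + 1} outside [1, {pile.l}]")
    rows = pile.rows_covering(cols)
    haps: dict[tuple[str, ...], int] = {}
    for r in rows:
        hap = tuple(CHAR_OF[pile.codes[r, col]] for col in cols)
        haps[hap] = haps.get(hap, 0) + 1
    total = sum(haps.values())
    return {h: (n, n / total if total else 0.0) for h, n in haps.items()}
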