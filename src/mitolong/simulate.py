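"""Synthetic Cas9-enriched mitochondrial long-read data.

The generator emulates the statistical structure the pipeline assumes: a
circular genome opened at sample-specific Cas9 cut-sites, a mixture of
mtDNA populations (haplotypes) carrying SNVs and/or long deletions,
full-length and fragmented reads on both strands, and quality-stratified
substitution errors (``Bernoulli(e(q))`` per base with Phred ``q`` drawn
from a discrete mix).  Alongside the FASTQ it emits the truth table and
*ideal* alignments — PAF against the mitochondrial contig and SAM against
each cut-site's doubled custom reference — constructed from the known read
geometry, so every downstream module can be tested without an external
aligner.

A molecule that has lost a cut-site to a deletion cannot be opened there,
so population mixture fractions are renormalised per cut-site over the
populations that retain the cut (this is what makes different guide RNAs
see different population subsets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .model import ConfigError, CutSite, MitoGenome, phred_error
from .pileup import SiteCounts
from .refbuild import CustomReference, build_custom_reference

BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")

DEFAULT_QUALITY_LEVELS = (10, 15, 20, 25, 30)
DEFAULT_QUALITY_WEIGHTS = (0.05, 0.15, 0.40, 0.25, 0.15)


def random_genome(l: int, rng: np.random.Generator, name: str = "chrM") -> MitoGenome:
    """A uniform-random circular genome of length ``l``."""
    seq = "".join(rng.choice(BASES, size=l))
    return MitoGenome(name=name, sequence=seq)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Population:
    """One mtDNA haplotype in the mixture.

    ``snvs`` maps 0-based positions to alternative bases; ``deletions``
    are ``(start0, length)`` intervals (may wrap the origin).
    """

    name: str
    fraction: float
    snvs: dict[int, str] = field(default_factory=dict)
    deletions: tuple[tuple[int, int], ...] = ()

    def covers_cut(self, cut0: int, l: int) -> bool:
        """True if a deletion removes the cut position."""
        for (s, ln) in self.deletions:
            if (cut0 - s) % l < ln:
                return True
        return False


@dataclass
class SimConfig:
    genome: MitoGenome
    populations: list[Population]
    cut_sites: list[CutSite]
    reads_per_sample: int = 100
    full_length_fraction: float = 1.0
    fragment_length_mean: float = 4000.0
    fragment_length_min: int = 200
    quality_levels: Sequence[int] = DEFAULT_QUALITY_LEVELS
    quality_weights: Sequence[float] = DEFAULT_QUALITY_WEIGHTS
    substitution_errors: bool = True
    indel_error_rate: float = 0.0
    start_offset_max: int = 0
    d: int = 5
    seed: int = 1

    def __post_init__(self) -> None:
        tot = sum(p.fraction for p in self.populations)
        if abs(tot - 1.0) > 1e-9:
            raise ConfigError(f"population fractions sum to {tot}, expected 1")
        l = self.genome.l
        for p in self.populations:
            for pos in p.snvs:
                if not 0 <= pos < l:
                    raise ConfigError(f"SNV position {pos} outside genome")
            for (s, ln) in p.deletions:
                if not (0 <= s < l and 1 <= ln <= l - 1):
                    raise ConfigError(f"bad deletion ({s}, {ln})")
        for cut in self.cut_sites:
            if all(p.covers_cut(cut.position0, l) for p in self.populations):
                raise ConfigError(
                    f"every population deletes cut-site {cut.name}; "
                    "no molecule can be opened there"
                )


@dataclass
class SimRead:
    read_id: str
    sample: str
    cut_site: str
    population: str
    strand: str
    g0: int  # forward-order genome start of the aligned span
    span: int  # reference span (circular), before deletions
    blocks: list[tuple[int, int]]  # matched (genome_start, length) runs, fwd order
    cigar: list[tuple[int, int]]  # reference-order CIGAR vs custom reference
    seq_fwd: str  # reference-orientation sequence
    quals_fwd: np.ndarray
    n_errors: int

    @property
    def read_len(self) -> int:
        return len(self.seq_fwd)

    def fastq_record(self) -> str:
        seq = self.seq_fwd if self.strand == "+" else revcomp(self.seq_fwd)
        quals = self.quals_fwd if self.strand == "+" else self.quals_fwd[::-1]
        qstr = "".join(chr(q + 33) for q in quals)
        return f"@{self.read_id}\n{seq}\n+\n{qstr}\n"


@dataclass
class TruthTable:
    reads: list[SimRead]
    site_vafs: dict[int, dict[str, float]]  # 0-based pos -> {alt base: VAF}
    deletions: dict[tuple[int, int], float]  # (start0, length) -> mixture fraction

    def to_tsv(self) -> str:
        lines = ["read_id\tsample\tcut_site\tpopulation\tstrand\tstart\tspan\tn_errors"]
        for r in self.reads:
            lines.append(
                f"{r.read_id}\t{r.sample}\t{r.cut_site}\t{r.population}\t"
                f"{r.strand}\t{r.g0}\t{r.span}\t{r.n_errors}"
            )
        return "\n".join(lines) + "\n"


def _truth_vafs(cfg: SimConfig) -> tuple[dict[int, dict[str, float]], dict[tuple[int, int], float]]:
    site: dict[int, dict[str, float]] = {}
    for p in cfg.populations:
        for pos, alt in p.snvs.items():
            site.setdefault(pos, {}).setdefault(alt, 0.0)
            site[pos][alt] += p.fraction
    dels: dict[tuple[int, int], float] = {}
    for p in cfg.populations:
        for iv in p.deletions:
            dels[iv] = dels.get(iv, 0.0) + p.fraction
    return site, dels


def _simulate_read(
    cfg: SimConfig,
    rng: np.random.Generator,
    read_id: str,
    cut: CutSite,
    pop: Population,
) -> SimRead:
    genome = cfg.genome
    l = genome.l
    x = cut.position0
    strand = "+" if rng.random() < 0.5 else "-"
    a = int(rng.integers(0, cfg.start_offset_max + 1))
    b = int(rng.integers(0, cfg.start_offset_max + 1))

    full_length = rng.random() < cfg.full_length_fraction
    if full_length:
        span = l - a - b
        g0 = (x + (a if strand == "+" else b)) % l
    else:
        frag = int(rng.exponential(cfg.fragment_length_mean))
        span = min(max(frag, cfg.fragment_length_min), l - a - b)
        if rng.random() < 0.5:  # 5' end anchored at the cut
            b = 0
            g0 = (x + a) % l if strand == "+" else (x - a - span) % l
        else:  # 3' end anchored at the cut
            a = 0
            g0 = (x - b - span) % l if strand == "+" else (x + b) % l

    # walk the window in forward order, excising deleted intervals
    positions: list[int] = []
    cigar: list[tuple[int, int]] = []
    blocks: list[tuple[int, int]] = []

    def deleted_by(pos: int) -> int:
        """Remaining deleted length if pos is the start of a deletion run."""
        for (s, ln) in pop.deletions:
            off = (pos - s) % l
            if off < ln:
                return ln - off
        return 0

    pos = g0
    remaining = span
    while remaining > 0:
        dlen = deleted_by(pos)
        if dlen:
            dlen = min(dlen, remaining)
            cigar.append((2, dlen))  # D
            pos = (pos + dlen) % l
            remaining -= dlen
            continue
        # matched run up to the next deletion start (or window end)
        run = remaining
        for (s, _ln) in pop.deletions:
            gap = (s - pos) % l
            if 0 < gap < run:
                run = gap
        block_start = pos
        for _ in range(run):
            positions.append(pos)
            pos = (pos + 1) % l
        if cigar and cigar[-1][0] == 0:
            cigar[-1] = (0, cigar[-1][1] + run)
        else:
            cigar.append((0, run))
        blocks.append((block_start, run))
        remaining -= run
    # trailing/leading deletions do not consume the alignment
    while cigar and cigar[0][0] == 2:
        cigar.pop(0)
    while cigar and cigar[-1][0] == 2:
        cigar.pop()

    pos_arr = np.array(positions, dtype=np.int64)
    base_arr = np.array(list(genome.sequence))[pos_arr]
    for p_, alt in pop.snvs.items():
        base_arr[pos_arr == p_] = alt

    levels = np.asarray(cfg.quality_levels)
    weights = np.asarray(cfg.quality_weights, dtype=float)
    weights = weights / weights.sum()
    quals = rng.choice(levels, size=len(base_arr), p=weights).astype(np.int64)
    n_errors = 0
    if cfg.substitution_errors:
        errs = np.array([phred_error(int(q), e_cap=0.5 - 1e-9) for q in levels])
        e_per_base = errs[np.searchsorted(levels, quals)]
        flip = rng.random(len(base_arr)) < e_per_base
        n_errors = int(flip.sum())
        if n_errors:
            for i in np.nonzero(flip)[0]:
                others = [bb for bb in "ACGT" if bb != base_arr[i]]
                base_arr[i] = others[int(rng.integers(0, 3))]

    seq = "".join(base_arr)
    quals_fwd = quals

    if cfg.indel_error_rate > 0 and len(seq) > 2:
        seq, quals_fwd, cigar = _apply_indel_errors(
            seq, quals_fwd, cigar, cfg.indel_error_rate, rng
        )
        n_errors += 0  # indel errors tracked via CIGAR only

    return SimRead(
        read_id=read_id,
        sample=cut.sample,
        cut_site=cut.name,
        population=pop.name,
        strand=strand,
        g0=g0,
        span=span,
        blocks=blocks,
        cigar=cigar,
        seq_fwd=seq,
        quals_fwd=quals_fwd,
        n_errors=n_errors,
    )


def _apply_indel_errors(seq, quals, cigar, rate, rng):
    """Inject 1-bp insertion/deletion errors, rewriting the CIGAR."""
    out_seq: list[str] = []
    out_quals: list[int] = []
    new_cigar: list[tuple[int, int]] = []

    def push(op: int, n: int) -> None:
        if n <= 0:
            return
        if new_cigar and new_cigar[-1][0] == op:
            new_cigar[-1] = (op, new_cigar[-1][1] + n)
        else:
            new_cigar.append((op, n))

    i = 0
    for op, n in cigar:
        if op != 0:
            push(op, n)
            continue
        j = 0
        while j < n:
            r = rng.random()
            if r < rate / 2 and 0 < j < n - 1:  # delete this base
                push(2, 1)
                i += 1
                j += 1
            elif r < rate and 0 < j < n - 1:  # insert a random base before it
                out_seq.append("ACGT"[int(rng.integers(0, 4))])
                out_quals.append(int(quals[i]))
                push(1, 1)
            else:
                out_seq.append(seq[i])
                out_quals.append(int(quals[i]))
                push(0, 1)
                i += 1
                j += 1
    return "".join(out_seq), np.array(out_quals, dtype=np.int64), new_cigar


@dataclass
class SimResult:
    config: SimConfig
    reads: list[SimRead]
    truth: TruthTable
    references: dict[str, CustomReference]  # cut-site name -> reference

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(r.fastq_record())

    def write_paf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(paf_lines(r, self.config.genome))

    def write_sam(self, out_dir: str | Path) -> dict[str, Path]:
        """One SAM per cut-site (reads aligned to its custom reference)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        by_cut: dict[str, list[SimRead]] = {}
        for r in self.reads:
            by_cut.setdefault(r.cut_site, []).append(r)
        for cut_name, reads in by_cut.items():
            cr = self.references[cut_name]
            path = out_dir / f"{cr.name}.sam"
            write_sam(reads, cr, path)
            paths[cut_name] = path
        return paths

    def write_truth(self, path: str | Path) -> None:
        Path(path).write_text(self.truth.to_tsv())


def paf_lines(read: SimRead, genome: MitoGenome) -> str:
    """Ideal PAF records against the mitochondrial contig.

    One record per matched block, split at the reference origin; read
    coordinates follow the read orientation (for minus-strand reads the
    first matched block in forward order is at the *end* of the read).
    """
    l = genome.l
    # split each block at the origin
    pieces: list[tuple[int, int]] = []
    for (s, ln) in read.blocks:
        if s + ln <= l:
            pieces.append((s, ln))
        else:
            pieces.append((s, l - s))
            pieces.append((0, ln - (l - s)))
    total = sum(ln for (_s, ln) in pieces)
    lines = []
    # read-space offset of each piece, walking in synthesis order
    order = pieces if read.strand == "+" else list(reversed(pieces))
    qoff = 0
    for (s, ln) in order:
        qs, qe = qoff, qoff + ln
        lines.append(
            "\t".join(
                str(v)
                for v in (
                    read.read_id,
                    read.read_len,
                    qs,
                    qe,
                    read.strand,
                    genome.name,
                    l,
                    s,
                    s + ln,
                    ln,
                    ln,
                    60,
                )
            )
            + "\ttp:A:P\n"
        )
        qoff = qe
    assert qoff == total
    return "".join(lines)


def write_sam(reads: list[SimRead], cr: CustomReference, path: str | Path) -> None:
    """Ideal SAM against one cut-site's doubled custom reference.

    The alignment is a single linear segment: a read opened at its
    cut-site maps inside the unmasked window without wrapping.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": cr.name, "LN": cr.length}],
        }
    )
    x = cr.cut_site.position0
    l, d = cr.l, cr.d
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            aln = pysam.AlignedSegment(header)
            aln.query_name = r.read_id
            aln.query_sequence = r.seq_fwd
            aln.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(int(q) + 33) for q in r.quals_fwd)
            )
            aln.flag = 16 if r.strand == "-" else 0
            aln.reference_id = 0
            first_match = r.blocks[0][0] if r.blocks else r.g0
            aln.reference_start = x + d + ((first_match - x) % l)
            aln.mapping_quality = 60
            aln.cigartuples = r.cigar
            out.write(aln)


def simulate_sample(cfg: SimConfig) -> SimResult:
    """Generate reads, truth table and ideal alignments for one run.

    Reads are split evenly over each sample's cut-sites; for every read
    the source population is drawn from the mixture restricted to the
    populations that retain that cut-site.  Deterministic for a fixed
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    l = cfg.genome.l
    site_vafs, del_fracs = _truth_vafs(cfg)
    reads: list[SimRead] = []
    samples: dict[str, list[CutSite]] = {}
    for cut in cfg.cut_sites:
        samples.setdefault(cut.sample, []).append(cut)
    references = {
        cut.name: build_custom_reference(cfg.genome, cut, cfg.d)
        for cut in cfg.cut_sites
    }
    counter = 0
    for sample, cuts in samples.items():
        per_cut = cfg.reads_per_sample // len(cuts)
        for cut in cuts:
            eligible = [p for p in cfg.populations if not p.covers_cut(cut.position0, l)]
            weights = np.array([p.fraction for p in eligible])
            weights = weights / weights.sum()
            for _ in range(per_cut):
                pop = eligible[int(rng.choice(len(eligible), p=weights))]
                counter += 1
                reads.append(
                    _simulate_read(cfg, rng, f"read{counter:06d}", cut, pop)
                )
    truth = TruthTable(reads=reads, site_vafs=site_vafs, deletions=del_fracs)
    return SimResult(config=cfg, reads=reads, truth=truth, references=references)


def simulate_pileup_counts(
    f: Sequence[float],
    alleles: Sequence[str],
    quality_levels: Sequence[int],
    quality_weights: Sequence[float],
    n: int,
    seed: int,
    position: int = 0,
) -> SiteCounts:
    """Draw stratified allele counts at one site from the generative model.

    Each observation: true allele ~ ``f``, quality level ~ the mix,
    strand ~ Bernoulli(0.5); the observed allele is flipped with
    probability ``e(q)`` to one of the *other* listed alleles (uniformly).
    """
    f = np.asarray(f, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9 or len(f) != len(alleles):
        raise ValueError("f must sum to 1 with one entry per allele")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    levels = np.asarray(quality_levels)
    weights = np.asarray(quality_weights, dtype=float)
    weights = weights / weights.sum()
    sc = SiteCounts(position)
    m = len(alleles)
    true_ix = rng.choice(m, size=n, p=f)
    q_ix = rng.choice(len(levels), size=n, p=weights)
    strands = rng.random(n) < 0.5
    u = rng.random(n)
    for k in range(n):
        q = int(levels[q_ix[k]])
        e = phred_error(q, e_cap=0.5 - 1e-9)
        obs = int(true_ix[k])
        if m > 1 and u[k] < e:
            others = [i for i in range(m) if i != obs]
            obs = others[int(rng.integers(0, m - 1))]
        sc.add(alleles[obs], "+" if strands[k] else "-", q)
    return sc
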