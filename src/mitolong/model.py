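"""Core domain types shared by the whole pipeline.

The mitochondrial genome is circular, so every coordinate computation in
this package goes through :func:`circular_remap` and friends.  Internally
all positions are 0-based half-open; the 1-based ``m.####`` convention used
in configuration files, VCF output and reports is applied only at I/O
boundaries.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

#: selection strategies for cut-site demultiplexing
STRATEGIES = ("both", "start", "either", "xor")


class CoordinateError(ValueError):
    """A position falls outside the coordinate system it was used with."""


class ConfigError(ValueError):
    """An invalid cut-site configuration."""


@dataclass(frozen=True)
class MitoGenome:
    """A single circular mitochondrial contig.

    Parameters
    ----------
    name:
        Contig identifier (e.g. ``chrM``).
    sequence:
        Upper-case DNA sequence; alphabet restricted to ``ACGTN``.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) == 0:
            raise ValueError("genome sequence must be non-empty")
        if not set(seq) <= VALID_BASES:
            bad = sorted(set(seq) - VALID_BASES)
            raise ValueError(f"invalid characters in genome sequence: {bad}")

    @property
    def l(self) -> int:
        """Genome length in bp (16,569 for the human rCRS)."""
        return len(self.sequence)

    @classmethod
    def from_fasta(cls, path: str | Path, contig: str | None = None) -> "MitoGenome":
        """Load a (single-contig) genome from a FASTA file.

        If *contig* is given, that record is selected; otherwise the file
        must contain exactly one record.
        """
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        if contig is None:
            if len(records) > 1:
                raise ValueError(
                    f"{path} has {len(records)} contigs; specify which one is mitochondrial"
                )
            rec = records[0]
        else:
            by_name = {r.id: r for r in records}
            if contig not in by_name:
                raise ValueError(f"contig {contig!r} not found in {path}")
            rec = by_name[contig]
        return cls(name=rec.id, sequence=str(rec.seq).upper())


@dataclass(frozen=True)
class CutSite:
    """A Cas9 cut position used as a demultiplexing barcode.

    ``position`` is the 1-based mitochondrial coordinate (``m.3127`` style);
    reads produced from this cut start at this base and end just before it.
    """

    name: str
    sample: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"cut-site {self.name}: position must be >= 1")

    @property
    def position0(self) -> int:
        """0-based cut position."""
        return self.position - 1


@dataclass
class CutSiteConfig:
    """Samples, their cut-sites, and the demultiplexing/remapping parameters.

    ``tolerance_bp`` is the maximum distance between a read end and a
    cut-site for a match (default 100 bp).  ``d`` is the padding added to
    each end of the doubled custom reference (default 5 bp).
    """

    genome: str
    cut_sites: list[CutSite]
    tolerance_bp: int = 100
    strategy: str = "both"
    d: int = 5
    q_min: int = 5
    min_mapped_frac: float = 0.90

    def __post_init__(self) -> None:
        if self.tolerance_bp < 0:
            raise ConfigError("tolerance_bp must be >= 0")
        if self.d < 1:
            raise ConfigError("d must be >= 1")
        if self.strategy not in STRATEGIES:
            raise ConfigError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}"
            )
        names = [c.name for c in self.cut_sites]
        if len(names) != len(set(names)):
            raise ConfigError("cut-site names must be unique")

    def validate_against(self, genome: MitoGenome) -> list[str]:
        """Check cut-sites against a genome; return a list of warnings.

        Raises for hard errors (cut-site off the genome); returns warnings
        for soft problems (cut-sites closer than twice the matching
        tolerance, which makes demultiplexing ambiguous).
        """
        warnings: list[str] = []
        for c in self.cut_sites:
            if c.position > genome.l:
                raise ConfigError(
                    f"cut-site {c.name} position {c.position} beyond genome length {genome.l}"
                )
        sites = sorted(self.cut_sites, key=lambda c: c.position0)
        for a, b in zip(sites, sites[1:] + sites[:1]):
            gap = (b.position0 - a.position0) % genome.l
            if len(sites) > 1 and gap < 2 * self.tolerance_bp:
                warnings.append(
                    f"cut-sites {a.name} and {b.name} are {gap} bp apart "
                    f"(< 2 x tolerance {self.tolerance_bp}); reads may be ambiguous"
                )
        return warnings

    def sample_of(self, cut_site_name: str) -> str:
        for c in self.cut_sites:
            if c.name == cut_site_name:
                return c.sample
        raise KeyError(cut_site_name)

    @classmethod
    def from_file(cls, path: str | Path) -> "CutSiteConfig":
        """Read a plain-text configuration.

        Format: an INI file with a ``[global]`` section holding ``genome``,
        ``tolerance_bp``, ``strategy``, ``d``, ``q_min`` and
        ``min_mapped_frac``, and one section per sample mapping cut-site
        names to 1-based positions::

            [global]
            genome = chrM
            tolerance_bp = 100
            strategy = both
            d = 5

            [sampleA]
            mt3 = 3127
            mt11 = 11239
        """
        parser = configparser.ConfigParser()
        read = parser.read(str(path))
        if not read:
            raise FileNotFoundError(path)
        g = parser["global"] if parser.has_section("global") else {}
        cut_sites = []
        for section in parser.sections():
            if section == "global":
                continue
            for name, pos in parser.items(section):
                try:
                    position = int(pos)
                except ValueError as exc:
                    raise ConfigError(
                        f"cut-site {name} in [{section}]: position {pos!r} is not an integer"
                    ) from exc
                cut_sites.append(CutSite(name=name, sample=section, position=position))
        if not cut_sites:
            raise ConfigError(f"no cut-sites defined in {path}")
        return cls(
            genome=g.get("genome", "chrM"),
            cut_sites=cut_sites,
            tolerance_bp=int(g.get("tolerance_bp", 100)),
            strategy=g.get("strategy", "both"),
            d=int(g.get("d", 5)),
            q_min=int(g.get("q_min", 5)),
            min_mapped_frac=float(g.get("min_mapped_frac", 0.90)),
        )


@dataclass(frozen=True)
class QualityModel:
    """Phred quality -> error probability, with a floor and a cap.

    Bases below ``q_min`` are discarded upstream; error probabilities are
    capped at ``e_cap`` so that ``1 - 2e`` stays positive, which keeps the
    per-observation likelihood strictly increasing in the allele frequency.
    """

    q_min: int = 5
    e_cap: float = 0.45

    def __post_init__(self) -> None:
        if not (0 < self.e_cap < 0.5):
            raise ValueError("e_cap must be in (0, 0.5)")
        if self.q_min < 0:
            raise ValueError("q_min must be >= 0")

    def error_prob(self, q: int) -> float:
        return phred_error(q, e_cap=self.e_cap)

    def accepts(self, q: int) -> bool:
        return q >= self.q_min


def circular_remap(x: int, d: int, l: int) -> int:
    """Collapse a 0-based custom-reference position onto the circular genome.

    The custom reference holds two tandem copies of the genome with ``d``
    bases of padding at each end; a base at custom position ``x``
    originates from genome position ``(x - d) mod l``.
    """
    if l <= 0:
        raise CoordinateError("genome length must be positive")
    if d < 0:
        raise CoordinateError("padding d must be >= 0")
    if not (0 <= x < 2 * (l + d)):
        raise CoordinateError(
            f"position {x} outside custom reference of length {2 * (l + d)}"
        )
    return (x - d) % l


def phred_error(q: int, e_cap: float = 0.45) -> float:
    """Error probability for a Phred quality ``q``: ``min(10^(-q/10), e_cap)``."""
    if q < 0:
        raise ValueError(f"negative base quality {q}")
    return min(10.0 ** (-0.1 * q), e_cap)


def obs_likelihood(f: float, e: float) -> float:
    """Probability of observing an allele with true frequency ``f``.

    A molecule carries the allele with probability ``f`` and is read
    correctly with probability ``1 - e``; a molecule without the allele is
    misread as it with probability ``e``::

        p(f, e) = f (1 - e) + (1 - f) e

    Affine and strictly increasing in ``f`` whenever ``e < 1/2``.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"allele frequency {f} outside [0, 1]")
    if not 0.0 < e < 0.5:
        raise ValueError(f"error probability {e} outside (0, 0.5)")
    return f * (1.0 - e) + (1.0 - f) * e


def write_fasta(path: str | Path, name: str, sequence: str, width: int = 60) -> None:
    """Write a single-contig FASTA with fixed-width line wrapping."""
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")
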