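"""Doubled, masked custom references for circular remapping.

Mapping long reads from a circular genome against a linear reference
splits origin-spanning reads and blurs coverage around the origin.  The
fix: align each demultiplexed read set against a cut-site-specific
reference built from two tandem copies of the genome plus ``d`` bases of
padding at each end, with everything outside one genome-length window
around the cut masked to ``N``.  A read starting at its cut-site then maps
in one piece, and custom coordinates collapse back to the circle with
``(x - d) mod l`` — the same coordinate system for every cut-site, so
alignments from different cut-sites of one sample can be merged directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .model import CutSite, CutSiteConfig, MitoGenome, write_fasta


class UnsupportedCutSiteError(ValueError):
    """The cut lies within ``d`` bases of the reference origin."""


@dataclass(frozen=True)
class CustomReference:
    """A doubled, masked reference for one cut-site.

    ``sequence`` has length ``2(l + d)``; ``unmasked_interval`` is the
    0-based inclusive window ``[x, x + l + 2d]`` on the custom sequence
    (``x`` = 0-based cut position on the genome), of length ``l + 2d + 1``.
    """

    cut_site: CutSite
    d: int
    l: int
    sequence: str
    unmasked_interval: tuple[int, int]

    @property
    def name(self) -> str:
        return f"{self.cut_site.sample}_{self.cut_site.name}_d{self.d}"

    @property
    def length(self) -> int:
        return len(self.sequence)


def build_custom_reference(genome: MitoGenome, cut: CutSite, d: int) -> CustomReference:
    """Build the doubled masked reference for one cut-site.

    Layout: the last ``d`` bases of the genome, two full copies of the
    genome, then the first ``d`` bases.  The cut at 0-based genome
    position ``x`` appears at custom positions ``x + d`` and ``x + l + d``;
    all bases outside ``[x, x + l + 2d]`` (inclusive) are masked to ``N``
    so that both copies of the cut keep ``d`` bases of flanking context and
    any read longer than ``d`` allocated to this cut-site maps uniquely.
    """
    l = genome.l
    seq = genome.sequence
    if d < 1:
        raise ValueError("padding d must be >= 1")
    x = cut.position0
    if x < d or x >= l - d:
        raise UnsupportedCutSiteError(
            f"cut-site {cut.name} at 0-based {x} lies within {d} bp of the origin; "
            "shift the reference origin or reduce d"
        )
    doubled = seq[-d:] + seq + seq + seq[:d]
    assert len(doubled) == 2 * (l + d)
    lo, hi = x, x + l + 2 * d  # inclusive window
    masked = "N" * lo + doubled[lo : hi + 1] + "N" * (len(doubled) - hi - 1)
    return CustomReference(
        cut_site=cut, d=d, l=l, sequence=masked, unmasked_interval=(lo, hi)
    )


def build_all(genome: MitoGenome, config: CutSiteConfig) -> list[CustomReference]:
    return [build_custom_reference(genome, cut, config.d) for cut in config.cut_sites]


def write_reference(cr: CustomReference, path: str | Path) -> None:
    """Write the custom reference as a single-contig 60-column FASTA."""
    write_fasta(path, cr.name, cr.sequence)


def write_all(genome: MitoGenome, config: CutSiteConfig, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for cr in build_all(genome, config):
        p = out_dir / f"{cr.name}.fasta"
        write_reference(cr, p)
        paths.append(p)
    return paths
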