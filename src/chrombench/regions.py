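"""Genomic regions for chromatin models and contact matrices.

Printed coordinates (as found in browsers, papers and file headers) are
1-based inclusive; internally regions are 0-based half-open, BED-style.
Both conventions give the same bin count for any region, so the choice only
affects parsing and printing.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

__all__ = ["GenomicRegion", "parse_region", "bead_count", "RegionParseError"]


class RegionParseError(ValueError):
    """Raised when a region string cannot be interpreted."""


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A half-open genomic interval [start, end) on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name, kept verbatim (``"chr1"``, ``"X"``, ...).
    start, end : int
        0-based half-open bounds in base pairs; ``0 <= start < end``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise RegionParseError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise RegionParseError(
                f"need 0 <= start < end, got [{self.start}, {self.end})"
            )

    def length(self) -> int:
        """Region length in base pairs."""
        return self.end - self.start

    def __str__(self) -> str:
        # printed form is 1-based inclusive
        return f"{self.chrom}:{self.start + 1}-{self.end}"


_REGION_RE = re.compile(r"^\s*([^:\s]+)\s*:\s*([0-9.,]+)\s*[-–]\s*([0-9.,]+)\s*$")


def _parse_coord(token: str) -> int:
    """Parse a coordinate, tolerating ',' or '.' thousands separators."""
    cleaned = token.replace(",", "").replace(".", "")
    if not cleaned.isdigit():
        raise RegionParseError(f"malformed coordinate {token!r}")
    return int(cleaned)


def parse_region(text: str) -> GenomicRegion:
    """Parse ``"chrom:start-end"`` into a :class:`GenomicRegion`.

    The printed coordinates are taken as 1-based inclusive, so
    ``"chrX:1-10"`` has length 10.  Thousands separators (``","`` or
    ``"."``) and an en-dash range separator are tolerated.

    >>> parse_region("chr1:178.421.513-179.491.193").length()
    1069681
    """
    m = _REGION_RE.match(text)
    if m is None:
        raise RegionParseError(f"cannot parse region string {text!r}")
    chrom, start_tok, end_tok = m.groups()
    start1 = _parse_coord(start_tok)
    end1 = _parse_coord(end_tok)
    if start1 < 1:
        raise RegionParseError(f"1-based start must be >= 1, got {start_tok!r}")
    if start1 >= end1:
        raise RegionParseError(f"start {start_tok!r} must be < end {end_tok!r}")
    return GenomicRegion(chrom, start1 - 1, end1)


def bead_count(region: GenomicRegion, bp_per_bead: float) -> int:
    """Number of beads/bins tiling *region* at *bp_per_bead* resolution.

    Ceiling division: the last bead may cover a partial bin, so the whole
    region is always covered.  The ~1 Mb TAD chr1:178,421,513-179,491,193
    at 5 kb/bead gives 214 beads.
    """
    if bp_per_bead <= 0:
        raise ValueError(f"bp_per_bead must be positive, got {bp_per_bead}")
    return math.ceil(region.length() / bp_per_bead)
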