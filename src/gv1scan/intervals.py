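"""Genomic intervals and coordinate-text parsing.

Internally every interval is 0-based half-open (the BED convention).  Only
parsers convert: megabase-quoted coordinates such as ``13:65.79-66.60 Mb``
are scaled by 1e6 and treated as half-open positions, while plain basepair
coordinates such as ``13:66432223-66432240`` follow the 1-based inclusive
dialect genome browsers print, so that 18-bp region really is 18 bp long.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

_UNIT_SCALE = {"bp": 1.0, "kb": 1e3, "Mb": 1e6}

# en dash, em dash, minus sign and ASCII hyphen all appear in printed ranges
_RANGE_RE = re.compile(
    r"^\s*(?P<chrom>[\w.]+):(?P<lo>[\d,.]+)\s*[–—−-]\s*"
    r"(?P<hi>[\d,.]+)\s*(?P<unit>bp|kb|Mb)?\s*$"
)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start_bp: int
    end_bp: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start_bp}-{self.end_bp}"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end_bp - self.start_bp

    def span(self, unit: str = "bp") -> float:
        """Interval length scaled to *unit* (``bp``, ``kb`` or ``Mb``)."""
        if unit not in _UNIT_SCALE:
            raise ValueError(f"unknown unit {unit!r}")
        return (self.end_bp - self.start_bp) / _UNIT_SCALE[unit]

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start_bp < other.end_bp
            and other.start_bp < self.end_bp
        )

    def to_bed_fields(self) -> tuple:
        return (self.chrom, self.start_bp, self.end_bp)


def parse_mb_interval(text: str) -> GenomicInterval:
    """Parse a printed coordinate range into a :class:`GenomicInterval`.

    Two dialects are accepted:

    * With a ``Mb``/``kb`` unit the numbers are scaled and used directly as
      half-open positions: ``"13:65.79-66.60 Mb"`` -> (65790000, 66600000).
      Scaling is exact at the printed precision (no float dust).
    * Bare integers (optionally with ``bp``) are 1-based inclusive:
      ``"13:66432223-66432240"`` -> an 18-bp half-open interval.

    En dash, em dash and hyphen all separate the bounds.  Empty or inverted
    ranges raise ``ValueError``.
    """
    m = _RANGE_RE.match(text)
    if not m:
        raise ValueError(f"unparseable interval text: {text!r}")
    chrom = m.group("chrom")
    lo_s = m.group("lo").replace(",", "")
    hi_s = m.group("hi").replace(",", "")
    unit = m.group("unit")

    if unit in ("Mb", "kb"):
        scale = _UNIT_SCALE[unit]
        # round, not truncate: 65.79 * 1e6 can land at 65789999.999...
        start = round(float(lo_s) * scale)
        end = round(float(hi_s) * scale)
    else:
        if "." in lo_s or "." in hi_s:
            raise ValueError(
                f"fractional coordinates need an explicit unit: {text!r}"
            )
        # 1-based inclusive bp -> 0-based half-open
        start = int(lo_s) - 1
        end = int(hi_s)
    return GenomicInterval(chrom, start, end)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching (start, end) half-open pairs."""
    if not intervals:
        return []
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if e < s:
            raise ValueError(f"inverted interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def complement_intervals(
    intervals: list[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    """Complement of the union of *intervals* within [0, length)."""
    out: list[tuple[int, int]] = []
    pos = 0
    for s, e in merge_intervals(intervals):
        if e > length or s < 0:
            raise ValueError(f"interval ({s}, {e}) exceeds bounds [0, {length})")
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        out.append((pos, length))
    return out
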