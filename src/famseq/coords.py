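"""Coordinate conventions.

Internally every interval is 1-based and inclusive on both ends, the
convention of genetic maps and of the breakpoint arithmetic used throughout
the package.  BED files on disk are 0-based, half-open.  All conversion
goes through the two functions below so the off-by-one lives in exactly one
place.
"""

from __future__ import annotations

from typing import Iterable


def to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    return start - 1, end


def from_bed(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    if start >= end:
        raise ValueError(f"empty or inverted BED interval [{start}, {end})")
    return start + 1, end


def span_bp(start: int, end: int) -> int:
    """Length in bp of a 1-based inclusive interval."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    return end - start + 1


def write_bed(path, records: Iterable[tuple]) -> None:
    """Write (contig, start, end, *rest) records, internal coordinates, as BED."""
    with open(path, "w") as fh:
        for contig, start, end, *rest in records:
            b0, b1 = to_bed(start, end)
            fields = [str(contig), str(b0), str(b1)] + [str(r) for r in rest]
            fh.write("\t".join(fields) + "\n")


def read_bed(path) -> list[tuple[str, int, int, list[str]]]:
    """Read BED; returns (contig, start, end, extra_fields) in internal coordinates."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            s, e = from_bed(int(parts[1]), int(parts[2]))
            out.append((parts[0], s, e, parts[3:]))
    return out
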