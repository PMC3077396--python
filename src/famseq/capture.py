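"""Capture-array design accounting: target padding, probe tiling, feature layout.

A hybrid-capture array is described by its target regions (exons, promoters,
or whole gene bodies), the oligonucleotide probes tiled across them, and the
layout scheme that maps designed probes to physical array features (a probe
may be printed several times, and/or together with its reverse complement).
Only coordinates are modelled; probe sequence content and hybridization
thermodynamics are not.

Coordinates are 1-based inclusive (see :mod:`famseq.coords`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .coords import span_bp

PROBE_LENGTH_DEFAULT = 60  # nt, standard array oligo length


@dataclass(frozen=True)
class TargetRegion:
    contig: str
    start: int  # 1-based inclusive
    end: int
    label: str = "target"  # exon / promoter / gene-body / ...

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return span_bp(self.start, self.end)


@dataclass(frozen=True)
class Probe:
    contig: str
    start: int
    length: int = PROBE_LENGTH_DEFAULT

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class ProbeSet:
    probes: list[Probe]
    scheme: str = "identity"

    def __len__(self) -> int:
        return len(self.probes)


def pad_and_merge(
    regions: list[TargetRegion],
    pad_bp: int,
    contig_length: int | None = None,
) -> list[TargetRegion]:
    """Extend each region by ``pad_bp`` on both sides and merge overlaps.

    Padding flanking sequence around each target promotes uniform capture
    coverage across the original interval.  Regions touching or overlapping
    after padding are merged; the merged region keeps the label of its first
    constituent.  Output is sorted by (contig, start).
    """
    if pad_bp < 0:
        raise ValueError("pad_bp must be >= 0")
    padded = []
    for r in regions:
        s = max(1, r.start - pad_bp)
        e = r.end + pad_bp
        if contig_length is not None:
            e = min(e, contig_length)
        padded.append(TargetRegion(r.contig, s, e, r.label))
    padded.sort(key=lambda r: (r.contig, r.start))
    merged: list[TargetRegion] = []
    for r in padded:
        if merged and merged[-1].contig == r.contig and r.start <= merged[-1].end + 1:
            last = merged.pop()
            merged.append(TargetRegion(last.contig, last.start, max(last.end, r.end), last.label))
        else:
            merged.append(r)
    return merged


def total_bp(regions: list[TargetRegion]) -> int:
    return sum(r.length for r in regions)


def tile_probes(
    regions: list[TargetRegion],
    probe_len: int = PROBE_LENGTH_DEFAULT,
    step: int = 3,
    masks: list[TargetRegion] | None = None,
) -> ProbeSet:
    """Tile fixed-length probes across regions at a fixed start spacing.

    Probes start at region start, start+step, ... while they still fit inside
    the region.  A probe overlapping any masked base (e.g. a repetitive
    element) is dropped; repeat detection itself is an input, not computed
    here.  For an unmasked region of length L >= probe_len the probe count is
    floor((L - probe_len) / step) + 1.
    """
    if probe_len < 1 or step < 1:
        raise ValueError("probe_len and step must be >= 1")
    mask_by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if masks:
        per: dict[str, list[tuple[int, int]]] = {}
        for m in masks:
            per.setdefault(m.contig, []).append((m.start, m.end))
        for contig, ivals in per.items():
            ivals.sort()
            mask_by_contig[contig] = (
                np.array([s for s, _ in ivals]),
                np.array([e for _, e in ivals]),
            )

    probes: list[Probe] = []
    for r in regions:
        starts = np.arange(r.start, r.end - probe_len + 2, step, dtype=np.int64)
        if starts.size and r.contig in mask_by_contig:
            ms, me = mask_by_contig[r.contig]
            ends = starts + probe_len - 1
            # probe [s, e] overlaps some mask [ms_i, me_i] iff s <= me_i and e >= ms_i
            idx = np.searchsorted(ms, ends, side="right") - 1
            overlapping = (idx >= 0) & (me[np.clip(idx, 0, None)] >= starts)
            # also catch masks starting inside the probe beyond idx
            idx2 = np.searchsorted(ms, starts, side="left")
            inside = (idx2 < ms.size) & (ms[np.clip(idx2, None, ms.size - 1)] <= ends)
            starts = starts[~(overlapping | inside)]
        probes.extend(Probe(r.contig, int(s), probe_len) for s in starts)
    return ProbeSet(probes=probes)


def layout_features(
    n_probes: int,
    scheme: str,
    subsample_steps: tuple[int, ...] = (2, 17),
) -> int:
    """Number of physical features on the array for ``n_probes`` designed probes.

    ``identity``
        one feature per probe.
    ``quad``
        each probe and its reverse complement both printed in duplicate:
        4 features per probe.
    ``custom-subsample``
        every probe once, plus the reverse complement of every j-th probe for
        each j in ``subsample_steps`` (counting from the j-th probe, so an
        extra floor(n/j) features per step).
    """
    if n_probes < 0:
        raise ValueError("n_probes must be >= 0")
    if scheme == "identity":
        return n_probes
    if scheme == "quad":
        return 4 * n_probes
    if scheme == "custom-subsample":
        return n_probes + sum(n_probes // j for j in subsample_steps)
    raise ValueError(f"unknown layout scheme: {scheme!r}")


def design_summary(
    regions: list[TargetRegion],
    probeset: ProbeSet,
    scheme: str = "quad",
) -> dict:
    """JSON-serializable design accounting: bp totals, probe/feature counts, coverage."""
    covered: dict[str, set] = {}
    for p in probeset.probes:
        covered.setdefault(p.contig, set()).update(range(p.start, p.end + 1))
    target_bp = total_bp(regions)
    covered_bp = 0
    for r in regions:
        c = covered.get(r.contig)
        if c:
            covered_bp += len(c.intersection(range(r.start, r.end + 1)))
    return {
        "n_regions": len(regions),
        "target_bp": target_bp,
        "n_probes": len(probeset),
        "n_features": layout_features(len(probeset), scheme),
        "layout_scheme": scheme,
        "probe_covered_bp": covered_bp,
        "coverage_fraction": covered_bp / target_bp if target_bp else 0.0,
    }


def write_design_summary(path, summary: dict) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
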