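"""Read-level QC for multiplexed targeted capture.

Three stages mirror the bookkeeping of a pooled hybrid-capture experiment:
inline-barcode demultiplexing of the pooled FASTQ, PCR-duplicate marking on
aligned single-end reads, and capture-efficiency statistics (aligned /
on-target fractions, and the fraction of targeted bases at or above a
ladder of fold-coverage thresholds, before and after duplicate removal).

Aligned reads are held in a pandas DataFrame with columns
``sample, contig, start, length, strand, qual, aligned, duplicate``
(start 1-based; strand '+'/'-'; qual = base-quality sum used only to pick
the retained copy among duplicates).  Alignment itself is an input, never
computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .capture import TargetRegion

COVERAGE_THRESHOLDS = (1, 5, 10, 20, 30, 40, 50)

READ_COLUMNS = ["sample", "contig", "start", "length", "strand",
                "qual", "aligned", "duplicate"]


def empty_reads() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        READ_COLUMNS,
        ["object", "object", "int64", "int64", "object", "float64", "bool", "bool"],
    )})


# --------------------------------------------------------------------------
# Demultiplexing
# --------------------------------------------------------------------------

def demultiplex(
    reads,
    barcode_map: dict[str, str],
) -> tuple[dict[str, list], list]:
    """Partition FASTQ records by exact inline-barcode prefix match.

    ``reads`` is an iterable of Bio.SeqRecord (e.g. from ``SeqIO.parse(path,
    "fastq")``).  The barcode is the first ``len(barcode)`` bases of the
    read; an exact match assigns the read to that sample and the barcode
    bases (with their qualities) are trimmed.  Anything else — including a
    single mismatch — goes to ``unassigned``.  Assignment is a partition:
    every input read lands in exactly one output bin.
    """
    if len(set(barcode_map.values())) != len(barcode_map):
        raise ValueError("duplicate barcode in barcode map")
    lengths = {len(b) for b in barcode_map.values()}
    if len(lengths) != 1:
        raise ValueError("all barcodes must have the same length")
    (bc_len,) = lengths
    by_barcode = {bc: sample for sample, bc in barcode_map.items()}

    assigned: dict[str, list] = {sample: [] for sample in barcode_map}
    unassigned: list = []
    for rec in reads:
        prefix = str(rec.seq[:bc_len])
        sample = by_barcode.get(prefix)
        if sample is None:
            unassigned.append(rec)
        else:
            assigned[sample].append(rec[bc_len:])
    return assigned, unassigned


def demultiplex_fastq(path, barcode_map: dict[str, str], outdir=None):
    """Demultiplex a FASTQ file; optionally write per-sample FASTQs to outdir."""
    assigned, unassigned = demultiplex(SeqIO.parse(str(path), "fastq"), barcode_map)
    if outdir is not None:
        import os
        for sample, recs in assigned.items():
            SeqIO.write(recs, os.path.join(outdir, f"{sample}.fastq"), "fastq")
        SeqIO.write(unassigned, os.path.join(outdir, "unassigned.fastq"), "fastq")
    return assigned, unassigned


# --------------------------------------------------------------------------
# Duplicate marking
# --------------------------------------------------------------------------

def mark_duplicates(reads: pd.DataFrame) -> pd.DataFrame:
    """Flag PCR duplicates among aligned single-end reads.

    Reads sharing (sample, contig, start, strand) are presumed to arise from
    amplification of the same library fragment; all but one are flagged.
    The retained copy is the one with the highest base-quality sum, ties
    broken by input order.  Insert end coordinates are unavailable for
    single-end reads, so they do not enter the key.
    """
    out = reads.copy()
    out["duplicate"] = False
    aligned = out[out["aligned"]]
    if len(aligned) == 0:
        return out
    # stable sort: best quality first within key, original order on ties
    ranked = aligned.sort_values("qual", ascending=False, kind="stable")
    dup = ranked.duplicated(subset=["sample", "contig", "start", "strand"], keep="first")
    out.loc[dup.index[dup], "duplicate"] = True
    return out


# --------------------------------------------------------------------------
# Coverage statistics
# --------------------------------------------------------------------------

@dataclass
class CoverageReport:
    """Per-sample capture QC: totals, on-target fraction, coverage ladder."""
    per_sample: pd.DataFrame  # rows: sample; columns: totals + ge_{k}x fractions
    dedup: bool
    thresholds: tuple[int, ...] = COVERAGE_THRESHOLDS

    def to_tsv(self, path) -> None:
        self.per_sample.to_csv(path, sep="\t")

    def to_dict(self) -> dict:
        return {
            "dedup": self.dedup,
            "thresholds": list(self.thresholds),
            "per_sample": self.per_sample.to_dict(orient="index"),
        }


def _merged_check(targets: list[TargetRegion]) -> None:
    if not targets:
        raise ValueError("coverage statistics require at least one target region")
    by_contig: dict[str, list[TargetRegion]] = {}
    for t in targets:
        by_contig.setdefault(t.contig, []).append(t)
    for ts in by_contig.values():
        ts.sort(key=lambda t: t.start)
        for a, b in zip(ts, ts[1:]):
            if b.start <= a.end:
                raise ValueError("targets must be merged and non-overlapping")


def _on_target_mask(reads: pd.DataFrame, targets: list[TargetRegion]) -> np.ndarray:
    """True where a read overlaps >= 1 target base."""
    mask = np.zeros(len(reads), dtype=bool)
    starts = reads["start"].to_numpy()
    ends = starts + reads["length"].to_numpy() - 1
    contigs = reads["contig"].to_numpy()
    for t in targets:
        mask |= (contigs == t.contig) & (starts <= t.end) & (ends >= t.start)
    return mask


def coverage_stats(
    reads: pd.DataFrame,
    targets: list[TargetRegion],
    dedup: bool,
    thresholds: tuple[int, ...] = COVERAGE_THRESHOLDS,
) -> CoverageReport:
    """Capture-efficiency statistics per sample.

    A read is on-target iff it overlaps at least one target base (the common
    capture-QC convention).  Depth is computed over target bases only.  With
    ``dedup`` True, duplicate-flagged reads are excluded from both the
    on-target accounting and the depth; the coverage ladder is then
    pointwise no higher than the pre-dedup one.
    """
    _merged_check(targets)
    rows = {}
    for sample, grp in reads.groupby("sample", sort=True):
        total = len(grp)
        aligned = grp[grp["aligned"]]
        if dedup:
            aligned = aligned[~aligned["duplicate"]]
        on_mask = _on_target_mask(aligned, targets)
        n_aligned = len(aligned)
        row = {
            "total_reads": total,
            "aligned_reads": n_aligned,
            "aligned_fraction": n_aligned / total if total else 0.0,
            "on_target_fraction": float(on_mask.mean()) if n_aligned else 0.0,
        }
        # depth over target bases
        fractions = _depth_fractions(aligned, targets, thresholds)
        for k, frac in zip(thresholds, fractions):
            row[f"ge_{k}x"] = frac
        rows[sample] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample"
    return CoverageReport(per_sample=df, dedup=dedup, thresholds=thresholds)


def _depth_fractions(
    reads: pd.DataFrame,
    targets: list[TargetRegion],
    thresholds: tuple[int, ...],
) -> list[float]:
    total_bases = sum(t.length for t in targets)
    counts = np.zeros(len(thresholds), dtype=np.int64)
    starts_all = reads["start"].to_numpy()
    ends_all = starts_all + reads["length"].to_numpy() - 1
    contigs_all = reads["contig"].to_numpy()
    for t in targets:
        sel = contigs_all == t.contig
        s = np.clip(starts_all[sel], t.start, t.end + 1)
        e = np.clip(ends_all[sel], t.start - 1, t.end)
        keep = s <= e
        s, e = s[keep], e[keep]
        diff = np.zeros(t.length + 1, dtype=np.int64)
        np.add.at(diff, s - t.start, 1)
        np.add.at(diff, e - t.start + 1, -1)
        depth = np.cumsum(diff[:-1])
        for i, k in enumerate(thresholds):
            counts[i] += int((depth >= k).sum())
    return [c / total_bases for c in counts]


# --------------------------------------------------------------------------
# Tabular aligned-read I/O (plus SAM export through pysam)
# --------------------------------------------------------------------------

def reads_to_tsv(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", index=False)


def reads_from_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "contig": str,
                                              "strand": str})


def reads_to_sam(reads: pd.DataFrame, path, contig_lengths: dict[str, int]) -> None:
    """Export aligned reads as a text SAM file (coordinates only, no sequence)."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": c, "LN": ln} for c, ln in contig_lengths.items()]}
    refid = {c: i for i, c in enumerate(contig_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for i, row in enumerate(reads.itertuples(index=False)):
            a = pysam.AlignedSegment(sam.header)
            a.query_name = f"{row.sample}.{i}"
            a.flag = (16 if row.strand == "-" else 0) | (1024 if row.duplicate else 0)
            if not row.aligned:
                a.flag |= 4
                a.reference_id = -1
                a.reference_start = -1
            else:
                a.reference_id = refid[row.contig]
                a.reference_start = int(row.start) - 1
                a.cigarstring = f"{int(row.length)}M"
            a.mapping_quality = 60 if row.aligned else 0
            a.query_sequence = "N" * int(row.length)
            a.query_qualities = pysam.qualitystring_to_array("I" * int(row.length))
            sam.write(a)
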