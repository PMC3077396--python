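"""Read-depth CNV detection and MLPA copy-number confirmation.

A multiplexed capture pool is its own copy-number control: because every
sample in the pool was hybridized to the same array simultaneously, the
ratio of one sample's windowed read counts to the cohort average cancels
the capture-efficiency profile, and a heterozygous deletion shows up as a
run of 50-bp windows with log2 ratio near -1 (half the expected reads).

Counts are first scaled to equal on-target library sizes (raw division
would conflate depth differences between samples with copy number); the
cohort baseline for a sample is the mean of the *other* samples
(leave-one-out).  Runs of consecutive low-ratio windows become candidate
deletion segments; the MLPA stage confirms exon-level copy number from
peak-height ratios against control probes and reference samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .capture import TargetRegion
from .coords import span_bp, to_bed

WINDOW_BP = 50
DEL_THRESHOLD = -0.7    # log2; the expected het-del signal is ~ -1
HOMDEL_THRESHOLD = -2.5
MIN_WINDOWS = 5
MLPA_DEL_THRESHOLD = 0.8
MLPA_GAIN_THRESHOLD = 1.2


# --------------------------------------------------------------------------
# Windowed counts
# --------------------------------------------------------------------------

def window_counts(
    reads: pd.DataFrame,
    targets: list[TargetRegion],
    window_bp: int = WINDOW_BP,
    use_duplicates: bool = False,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample read counts in fixed windows tiling the merged targets.

    Windows start at each merged target's start and advance in steps of
    ``window_bp``; a trailing remainder shorter than the window is dropped.
    A read increments every window it overlaps.  Duplicate-flagged reads
    are excluded unless ``use_duplicates`` (the duplicate-removed counts
    are the honest depth signal; the flag used is recorded by the caller).

    Returns a DataFrame with columns contig, start, end, target_index and
    one count column per sample, windows in genomic order.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if samples is None:
        samples = sorted(reads["sample"].unique())
    use = reads[reads["aligned"]]
    if not use_duplicates and "duplicate" in use.columns:
        use = use[~use["duplicate"]]

    frames = []
    for ti, t in enumerate(targets):
        n_win = t.length // window_bp
        if n_win == 0:
            continue
        win_start = t.start + window_bp * np.arange(n_win)
        tab = pd.DataFrame({
            "contig": t.contig,
            "start": win_start,
            "end": win_start + window_bp - 1,
            "target_index": ti,
        })
        last_covered = t.start + n_win * window_bp - 1
        for sample in samples:
            grp = use[(use["sample"] == sample) & (use["contig"] == t.contig)]
            rs = grp["start"].to_numpy()
            re_ = rs + grp["length"].to_numpy() - 1
            sel = (rs <= last_covered) & (re_ >= t.start)
            rs, re_ = rs[sel], re_[sel]
            first = np.clip((rs - t.start) // window_bp, 0, n_win - 1)
            first = np.where(rs < t.start, 0, first)
            last = np.clip((re_ - t.start) // window_bp, 0, n_win - 1)
            counts = np.zeros(n_win, dtype=np.int64)
            k = 0
            remaining = first.copy()
            while True:
                active = remaining <= last
                if not active.any():
                    break
                np.add.at(counts, remaining[active], 1)
                remaining = remaining + 1
                k += 1
            tab[sample] = counts
        frames.append(tab)
    if not frames:
        cols = ["contig", "start", "end", "target_index"] + samples
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Leave-one-out log2 ratios
# --------------------------------------------------------------------------

def log2_ratio(
    windows: pd.DataFrame,
    test_sample: str,
    cohort: list[str],
    normalize: bool = True,
) -> pd.DataFrame:
    """log2 of the test sample's windowed counts over the cohort mean.

    ``cohort`` lists the baseline samples; the test sample is excluded from
    its own baseline, and at least two other samples are required.  With
    ``normalize`` (default) every sample's counts are first scaled so that
    all library sizes (total windowed counts) are equal, making the ratio
    invariant to per-sample sequencing depth.  Windows with a zero baseline
    are flagged and excluded from segmentation rather than given a ratio.

    Returns a copy of ``windows`` with columns ``ratio`` (NaN where
    flagged) and ``flagged``.
    """
    others = [s for s in cohort if s != test_sample]
    if len(others) < 2:
        raise ValueError("cohort must contain >= 2 samples besides the test sample")
    out = windows.copy()
    counts = {s: windows[s].to_numpy(dtype=float) for s in [test_sample] + others}
    if normalize:
        sizes = {s: c.sum() for s, c in counts.items()}
        mean_size = np.mean([v for v in sizes.values()])
        for s in counts:
            if sizes[s] > 0:
                counts[s] = counts[s] * (mean_size / sizes[s])
    baseline = np.mean([counts[s] for s in others], axis=0)
    test = counts[test_sample]
    flagged = baseline == 0
    ratio = np.full(len(out), np.nan)
    ok = ~flagged & (test > 0)
    ratio[ok] = np.log2(test[ok] / baseline[ok])
    # zero test counts over a live baseline: strong depletion, use a floor
    zero_test = ~flagged & (test == 0)
    ratio[zero_test] = np.log2(0.5 / baseline[zero_test])
    out["ratio"] = ratio
    out["flagged"] = flagged
    return out


# --------------------------------------------------------------------------
# Segment calling
# --------------------------------------------------------------------------

@dataclass
class CnvSegment:
    contig: str
    start: int  # 1-based inclusive
    end: int
    mean_ratio: float
    n_windows: int
    call: str  # het-del / hom-del / dup / neutral

    @property
    def length_bp(self) -> int:
        return span_bp(self.start, self.end)

    def to_dict(self) -> dict:
        return {"contig": self.contig, "start": self.start, "end": self.end,
                "length_bp": self.length_bp, "mean_log2_ratio": self.mean_ratio,
                "n_windows": self.n_windows, "call": self.call}


def call_segments(
    windows: pd.DataFrame,
    del_threshold: float = DEL_THRESHOLD,
    min_windows: int = MIN_WINDOWS,
    homdel_threshold: float = HOMDEL_THRESHOLD,
    bridge_flagged: int = 1,
) -> list[CnvSegment]:
    """Call deletion segments from maximal runs of low-ratio windows.

    A candidate segment is a maximal run of >= ``min_windows`` consecutive
    windows with ratio <= ``del_threshold``; up to ``bridge_flagged``
    consecutive flagged (zero-baseline) windows inside a run are bridged
    rather than breaking it.  Runs are never extended across a gap in the
    window tiling (adjacent windows must abut).  A mean ratio at or below
    ``homdel_threshold`` reclassifies the segment as homozygous.
    """
    segments: list[CnvSegment] = []
    if len(windows) == 0:
        return segments
    contigs = windows["contig"].to_numpy()
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()
    ratios = windows["ratio"].to_numpy(dtype=float)
    flagged = windows["flagged"].to_numpy(dtype=bool)

    run: list[int] = []       # indices of qualifying windows in the open run
    pending_flagged = 0

    def close_run():
        nonlocal run, pending_flagged
        if len(run) >= min_windows:
            vals = ratios[run]
            mean = float(np.mean(vals))
            call = "hom-del" if mean <= homdel_threshold else "het-del"
            segments.append(CnvSegment(
                contig=str(contigs[run[0]]),
                start=int(starts[run[0]]), end=int(ends[run[-1]]),
                mean_ratio=mean, n_windows=len(run), call=call))
        run = []
        pending_flagged = 0

    for i in range(len(windows)):
        contiguous = bool(run) and contigs[i] == contigs[run[-1]] \
            and starts[i] == ends[i - 1] + 1
        if run and not contiguous:
            close_run()
        if flagged[i]:
            if run:
                pending_flagged += 1
                if pending_flagged > bridge_flagged:
                    close_run()
            continue
        if not math.isnan(ratios[i]) and ratios[i] <= del_threshold:
            run.append(i)
            pending_flagged = 0
        else:
            close_run()
    close_run()
    return segments


def span_length(start: int, end: int) -> int:
    """bp spanned by a 1-based inclusive interval: end - start + 1."""
    return span_bp(start, end)


def write_segments_bed(path, segments: list[CnvSegment]) -> None:
    with open(path, "w") as fh:
        for s in segments:
            b0, b1 = to_bed(s.start, s.end)
            fh.write(f"{s.contig}\t{b0}\t{b1}\t{s.call}\t{s.mean_ratio:.4f}\n")


# --------------------------------------------------------------------------
# MLPA
# --------------------------------------------------------------------------

@dataclass
class MlpaRecord:
    sample: str
    probe: str
    peak_height: float
    probe_ratio: float       # peak / mean(control peaks) within the sample
    normalized_ratio: float  # probe_ratio / mean over reference samples
    copy_number: int         # 1 if below threshold else 2
    gain_flag: bool

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def mlpa_copy_number(
    peaks: pd.DataFrame,
    control_probes: list[str],
    reference_samples: list[str],
    threshold: float = MLPA_DEL_THRESHOLD,
    gain_threshold: float = MLPA_GAIN_THRESHOLD,
) -> list[MlpaRecord]:
    """Call exon copy number from MLPA peak heights.

    ``peaks`` has columns sample, probe, height.  Within each sample, a
    probe's ratio is its peak height over the mean of that sample's control
    probes; the ratio is then normalized by the mean ratio of the same probe
    across the reference (control-individual) samples, so 1.0 means two
    copies.  A normalized ratio below ``threshold`` calls one copy; above
    ``gain_threshold`` the record is flagged as a possible gain.
    """
    if not control_probes:
        raise ValueError("at least one control probe required")
    if not reference_samples:
        raise ValueError("at least one reference sample required")
    wide = peaks.pivot(index="sample", columns="probe", values="height")
    missing = [s for s in reference_samples if s not in wide.index]
    if missing:
        raise ValueError(f"reference samples missing from peak table: {missing}")
    controls = wide[control_probes]
    if (controls <= 0).any().any() or controls.isna().any().any():
        raise ValueError("zero or missing control-probe peak")
    ratios = wide.div(controls.mean(axis=1), axis=0)
    ref_mean = ratios.loc[reference_samples].mean(axis=0)
    normalized = ratios.div(ref_mean, axis=1)

    records = []
    test_probes = [p for p in wide.columns if p not in control_probes]
    for sample in wide.index:
        for probe in test_probes:
            h = wide.loc[sample, probe]
            if pd.isna(h):
                continue
            nr = float(normalized.loc[sample, probe])
            records.append(MlpaRecord(
                sample=str(sample), probe=str(probe), peak_height=float(h),
                probe_ratio=float(ratios.loc[sample, probe]),
                normalized_ratio=nr,
                copy_number=1 if nr < threshold else 2,
                gain_flag=nr > gain_threshold))
    return records


def mlpa_records_to_tsv(records: list[MlpaRecord], path) -> None:
    pd.DataFrame([r.to_dict() for r in records]).to_csv(path, sep="\t", index=False)
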