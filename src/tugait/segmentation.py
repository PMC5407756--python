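"""Segmentation of a recording into the three consecutive TUG trials.

A recording covers three Timed-Up-and-Go trials (single task, dual-task
manual, dual-task cognitive) separated by quiet rest.  Segmentation works
on the fused magnitude signal: subtract the global mean, smooth with a
rolling median to suppress within-trial variance, sum the rectified
deviation over half-second windows, and threshold that activity statistic.
Contiguous above-threshold windows become candidate segments; nearby
candidates are merged and short blips discarded.  Exactly three surviving
segments are named TUG, TUG-M, TUG-C in temporal order; any other count
raises :class:`~tugait.errors.SegmentationFailure` carrying the candidates
so the caller can fall back to a manual override.

The literal signed window sum (compared against the pre-subtraction mean)
is available via ``literal_sum=True``; it is kept for auditability but
cannot separate activity from rest, because the signed sum of a mean-free
smoothed signal is near zero over any window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d

from .errors import ParameterError, SegmentationFailure, ValidationError
from .preprocess import MagnitudeSignal

SEGMENT_NAMES = ("TUG", "TUG-M", "TUG-C")

DEFAULT_WINDOW_S = 0.5
DEFAULT_K_S = 0.5
DEFAULT_MIN_GAP_S = 1.0
DEFAULT_MIN_DUR_S = 2.0
# Coarse activity threshold sits at half the mean rectified deviation: rest
# runs ~2% of burst level, so 0.5 lands in the empty band between the two
# even when activity fills most of the recording (1.0 would sit inside the
# burst-level distribution and fragment trials).
DEFAULT_THRESHOLD_SCALE = 0.5
# Boundary refinement threshold: just above the rest-noise floor, since its
# job is to find where activity decays to rest, not to re-classify windows.
DEFAULT_REFINE_SCALE = 0.15


@dataclass(frozen=True)
class Segment:
    """Half-open sample interval [start, end) with a trial name."""

    start: int
    end: int
    name: str

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class SegmentationResult:
    window_labels: np.ndarray  # one integer label per analysis window, 0 = rest
    segments: list[Segment]
    k: int  # rolling-median window, samples
    window_s: float
    rate: float
    n_samples: int

    def __post_init__(self):
        starts = [s.start for s in self.segments]
        if starts != sorted(starts):
            raise ValidationError("segments must be ordered by start")
        for a, b in zip(self.segments, self.segments[1:]):
            if a.end > b.start:
                raise ValidationError("segments must not overlap")
        for s in self.segments:
            if s.n_samples <= 0:
                raise ValidationError("segments must be non-empty")

    @property
    def successful(self) -> bool:
        return len(self.segments) == len(SEGMENT_NAMES)

    def by_name(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise LookupError(f"no segment named {name!r} in result")


def _candidate_runs(active: np.ndarray, w: int, n: int) -> list[tuple[int, int]]:
    """Convert a boolean per-window mask into sample-interval runs."""
    runs = []
    start = None
    for h, flag in enumerate(active):
        if flag and start is None:
            start = h
        elif not flag and start is not None:
            runs.append((start * w, min(h * w, n)))
            start = None
    if start is not None:
        runs.append((start * w, n))
    return runs


def segment_tugs(
    sig: MagnitudeSignal,
    k: int | None = None,
    window_s: float = DEFAULT_WINDOW_S,
    min_gap_s: float = DEFAULT_MIN_GAP_S,
    min_dur_s: float = DEFAULT_MIN_DUR_S,
    threshold_scale: float = DEFAULT_THRESHOLD_SCALE,
    literal_sum: bool = False,
    refine: bool = True,
    refine_scale: float = DEFAULT_REFINE_SCALE,
) -> SegmentationResult:
    """Locate the three TUG trials in a magnitude signal.

    Parameters
    ----------
    sig : MagnitudeSignal
        Fused (and optionally filtered) magnitude signal.
    k : int, optional
        Rolling-median window in samples; defaults to 0.5 s worth.
    window_s : float
        Width of the activity-analysis windows (0.5 s).
    min_gap_s, min_dur_s : float
        Post-processing: candidate segments closer than ``min_gap_s`` are
        merged; segments shorter than ``min_dur_s`` are discarded.
    threshold_scale : float
        Multiplier c on the data-driven activity threshold
        c * mean(|u|) * window_samples.
    literal_sum : bool
        Use the signed window sum compared against the pre-subtraction
        mean instead of the rectified statistic (see module docstring).
    refine : bool
        Refine each boundary at sample resolution: within one analysis
        window of the coarse boundary, take the first/last sample whose
        smoothed rectified deviation exceeds ``refine_scale * mean(|u|)``.
        Without refinement boundaries are quantized to the half-second
        window grid.

    Raises
    ------
    SegmentationFailure
        If post-processing leaves a segment count other than three.  The
        exception carries the candidate segments.
    """
    if k is None:
        k = max(1, int(round(DEFAULT_K_S * sig.rate)))
    if k < 1:
        raise ParameterError(f"rolling-median window k must be >= 1, got {k}")
    if window_s <= 0:
        raise ParameterError(f"window_s must be positive, got {window_s}")

    s = sig.values
    s_bar = s.mean()
    centered = s - s_bar
    u = median_filter(centered, size=k, mode="nearest")

    n = len(s)
    w = max(1, int(round(window_s * sig.rate)))
    n_win = int(np.ceil(n / w))
    stat = u if literal_sum else np.abs(u)
    g = np.array([stat[h * w : (h + 1) * w].sum() for h in range(n_win)])
    if literal_sum:
        threshold = s_bar
    else:
        threshold = threshold_scale * np.abs(u).mean() * w
    active = g > threshold

    runs = _candidate_runs(active, w, n)
    # merge candidates separated by less than min_gap_s
    min_gap = min_gap_s * sig.rate
    merged: list[list[int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] < min_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    # discard segments shorter than min_dur_s
    min_dur = min_dur_s * sig.rate
    kept = [(a, b) for a, b in merged if b - a >= min_dur]

    if refine and kept:
        abs_u = np.abs(u)
        act = uniform_filter1d(abs_u, size=max(1, k // 5), mode="nearest")
        sample_thr = refine_scale * abs_u.mean()
        refined = []
        for a, b in kept:
            lo, hi = max(0, a - w), min(n, a + w)
            idx = np.flatnonzero(act[lo:hi] > sample_thr)
            a2 = lo + int(idx[0]) if len(idx) else a
            lo, hi = max(0, b - w), min(n, b + w)
            idx = np.flatnonzero(act[lo:hi] > sample_thr)
            b2 = lo + int(idx[-1]) + 1 if len(idx) else b
            if b2 <= a2:  # refinement degenerate; keep coarse interval
                a2, b2 = a, b
            refined.append([a2, b2])
        for prev, cur in zip(refined, refined[1:]):  # refinement must not create overlap
            if prev[1] > cur[0]:
                mid = (prev[1] + cur[0]) // 2
                prev[1], cur[0] = mid, mid
        kept = [tuple(r) for r in refined]

    if len(kept) != len(SEGMENT_NAMES):
        candidates = [Segment(a, b, f"candidate-{i + 1}") for i, (a, b) in enumerate(kept)]
        raise SegmentationFailure(
            f"expected {len(SEGMENT_NAMES)} trial segments, found {len(kept)}",
            candidates=candidates,
        )

    segments = [Segment(a, b, name) for (a, b), name in zip(kept, SEGMENT_NAMES)]
    labels = np.zeros(n_win, dtype=int)
    for i, seg in enumerate(segments, start=1):
        first = seg.start // w
        last = int(np.ceil(seg.end / w))
        labels[first:last] = i
    return SegmentationResult(
        window_labels=labels,
        segments=segments,
        k=k,
        window_s=window_s,
        rate=sig.rate,
        n_samples=n,
    )


def extract_segment(
    sig: MagnitudeSignal, seg: SegmentationResult, which: str
) -> MagnitudeSignal:
    """Extract a named trial, or the concatenation of all three.

    ``which="whole"`` returns the three labelled segments concatenated,
    i.e. rest intervals between trials are dropped from the "whole signal"
    used for feature extraction.
    """
    if which == "whole":
        parts = [sig.values[s.start : s.end] for s in seg.segments]
        if not parts:
            raise LookupError("segmentation result contains no segments")
        return MagnitudeSignal(values=np.concatenate(parts), rate=sig.rate)
    s = seg.by_name(which)
    return MagnitudeSignal(values=sig.values[s.start : s.end].copy(), rate=sig.rate)


def apply_manual_segments(
    sig: MagnitudeSignal, intervals: list[tuple[float, float]]
) -> SegmentationResult:
    """Build a successful result from hand-picked (start_s, end_s) intervals.

    Used for the occasional recording the automatic algorithm cannot
    segment.  Exactly three ascending, non-overlapping in-range intervals
    are required.
    """
    if len(intervals) != len(SEGMENT_NAMES):
        raise ValidationError(
            f"need exactly {len(SEGMENT_NAMES)} intervals, got {len(intervals)}"
        )
    n = len(sig.values)
    segs = []
    prev_end = -1.0
    for (start_s, end_s), name in zip(intervals, SEGMENT_NAMES):
        if end_s <= start_s:
            raise ValidationError(f"interval ({start_s}, {end_s}) is empty or reversed")
        if start_s < prev_end:
            raise ValidationError("intervals overlap or are out of order")
        a = int(round(start_s * sig.rate))
        b = int(round(end_s * sig.rate))
        if a < 0 or b > n:
            raise ValidationError(f"interval ({start_s}, {end_s}) s outside the recording")
        segs.append(Segment(a, b, name))
        prev_end = end_s
    w = max(1, int(round(DEFAULT_WINDOW_S * sig.rate)))
    n_win = int(np.ceil(n / w))
    labels = np.zeros(n_win, dtype=int)
    for i, seg in enumerate(segs, start=1):
        labels[seg.start // w : int(np.ceil(seg.end / w))] = i
    return SegmentationResult(
        window_labels=labels,
        segments=segs,
        k=0,
        window_s=DEFAULT_WINDOW_S,
        rate=sig.rate,
        n_samples=n,
    )
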