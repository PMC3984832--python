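"""Stage 2: adaptive sliding-window refinement of candidate intervals.

Stage 1 produces coarse candidate intervals on segment boundaries.  This
module sharpens them against the per-position SNR track: the track is
first smoothed with a +-gamma moving average (the adaptive-window
adjustment), then each candidate boundary is *contracted* inward past
positions below the threshold T0 and *extended* outward while adjacent
positions stay at or above T0.  Candidates whose surviving span is too
short, or whose mean smoothed SNR falls below T0, are discarded; nearby
survivors are merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval, check_sorted
from .spectral import SNRProfile


@dataclass
class RefineParams:
    """Thresholding and post-processing parameters.

    T0 is the species-specific SNR threshold and gamma the smoothing
    half-width — the two quantities the swarm optimiser tunes.  Exons
    shorter than ~50 nt rarely carry a usable period-3 signal, hence the
    default minimum length.
    """

    t0: float = 2.0
    gamma: int = 3
    min_exon_length: int = 50
    merge_gap: int = 30
    max_extension: int = 2000

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if self.gamma < 0 or self.merge_gap < 0:
            raise ValueError("gamma and merge_gap must be >= 0")
        if self.min_exon_length < 1 or self.max_extension < 1:
            raise ValueError("min_exon_length and max_extension must be >= 1")


def smooth_profile(profile: SNRProfile, gamma: int) -> SNRProfile:
    """Moving average over [n - gamma, n + gamma], window clipped at the
    track ends (so the effective window shrinks there).  gamma = 0 is the
    identity."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if gamma == 0:
        return profile
    snr = profile.snr
    n = snr.shape[0]
    cs = np.concatenate([[0.0], np.cumsum(snr)])
    idx = np.arange(n)
    lo = np.maximum(idx - gamma, 0)
    hi = np.minimum(idx + gamma + 1, n)
    smoothed = (cs[hi] - cs[lo]) / (hi - lo)
    return SNRProfile(
        snr=smoothed,
        window_length=profile.window_length,
        normalizer=profile.normalizer,
        normalization=profile.normalization,
    )


def refine_interval(
    interval: GenomicInterval,
    profile: SNRProfile,
    params: RefineParams,
) -> GenomicInterval | None:
    """Contract then extend one candidate against the smoothed SNR track.

    Returns the refined exon interval with its mean smoothed SNR as
    score, or None when the candidate dissolves (span below
    ``min_exon_length``).

    When the contracted-and-extended span retains deep sub-threshold
    interior dips that drag its mean below T0 (a candidate bridging two
    exons across a long weak stretch), the span is narrowed to the
    maximal at-or-above-threshold run around the candidate's SNR peak,
    so a reported interval always has mean smoothed SNR >= T0 and the
    span shrinks monotonically as T0 grows.
    """
    if interval.end > profile.n:
        raise ValueError("interval exceeds profile bounds")
    snr = smooth_profile(profile, params.gamma).snr
    t0 = params.t0
    a, b = interval.start, interval.end

    # Contract: drop leading/trailing sub-threshold positions.
    while a < b and snr[a] < t0:
        a += 1
    while b > a and snr[b - 1] < t0:
        b -= 1
    if a >= b:
        return None

    # Extend: absorb adjacent at-or-above-threshold positions, capped.
    moved = 0
    while a > 0 and moved < params.max_extension and snr[a - 1] >= t0:
        a -= 1
        moved += 1
    moved = 0
    while b < profile.n and moved < params.max_extension and snr[b] >= t0:
        b += 1
        moved += 1

    if float(snr[a:b].mean()) < t0:
        # Fall back to the run of >= T0 positions around the strongest
        # site of the candidate; every retained position clears T0.
        peak = interval.start + int(np.argmax(snr[interval.start : interval.end]))
        a, b = peak, peak + 1
        moved = 0
        while a > 0 and moved < params.max_extension and snr[a - 1] >= t0:
            a -= 1
            moved += 1
        moved = 0
        while b < profile.n and moved < params.max_extension and snr[b] >= t0:
            b += 1
            moved += 1

    if b - a < params.min_exon_length:
        return None
    return GenomicInterval(interval.seq_id, a, b, "exon", float(snr[a:b].mean()))


def merge_and_filter(
    intervals: list[GenomicInterval], params: RefineParams
) -> list[GenomicInterval]:
    """Merge intervals separated by at most ``merge_gap`` (overlaps
    included), combining scores as length-weighted means, then drop
    anything shorter than ``min_exon_length``.  Input must be sorted by
    start."""
    check_sorted(intervals)
    merged: list[GenomicInterval] = []
    for iv in intervals:
        if merged and iv.start - merged[-1].end <= params.merge_gap:
            prev = merged[-1]
            new_end = max(prev.end, iv.end)
            w_prev, w_iv = prev.length, iv.length
            score = (prev.score * w_prev + iv.score * w_iv) / (w_prev + w_iv)
            merged[-1] = GenomicInterval(
                prev.seq_id, prev.start, new_end, "exon", score
            )
        else:
            merged.append(
                GenomicInterval(iv.seq_id, iv.start, iv.end, "exon", iv.score)
            )
    return [iv for iv in merged if iv.length >= params.min_exon_length]
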