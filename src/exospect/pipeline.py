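"""End-to-end detection pipelines.

``two_stage_detect`` is the full method: SNN coarse localisation over the
N-equal partition, then adaptive-window refinement of each candidate
against the sliding SNR track.  ``baseline_detect`` is the classical
fixed-window comparator: threshold the raw SNR track at R0 and keep the
resulting runs.
"""

from __future__ import annotations

import numpy as np

from .intervals import GenomicInterval
from .metrics import ConfusionCounts, confusion
from .refine import RefineParams, merge_and_filter, refine_interval
from .seqmap import NucleotideSequence
from .snn import (
    DEFAULT_SEGMENT_LENGTH,
    OrderParameterState,
    PrototypeSet,
    detect_initial_intervals,
    learn_prototypes,
    training_features,
)
from .spectral import SpectralParams, windowed_snr_track


def baseline_detect(
    seq: NucleotideSequence,
    spectral_params: SpectralParams | None = None,
    refine_params: RefineParams | None = None,
) -> list[GenomicInterval]:
    """Fixed-window detection: runs of positions with SNR >= R0."""
    sp = spectral_params or SpectralParams()
    rp = refine_params or RefineParams()
    profile = windowed_snr_track(seq, sp)
    above = profile.snr >= sp.r0
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    bounds = [0] + (edges + 1).tolist() + [seq.n]
    intervals = []
    for a, b in zip(bounds, bounds[1:]):
        if above[a]:
            score = float(profile.snr[a:b].mean())
            intervals.append(GenomicInterval(seq.id, a, b, "exon", score))
    return merge_and_filter(intervals, rp)


def two_stage_detect(
    seq: NucleotideSequence,
    protos: PrototypeSet,
    spectral_params: SpectralParams | None = None,
    refine_params: RefineParams | None = None,
    segment_length: int | None = None,
    dynamics: OrderParameterState | None = None,
) -> list[GenomicInterval]:
    """SNN coarse localisation followed by adaptive boundary refinement."""
    sp = spectral_params or SpectralParams()
    rp = refine_params or RefineParams()
    profile = windowed_snr_track(seq, sp)
    initial = detect_initial_intervals(
        seq, protos, sp, segment_length=segment_length, dynamics=dynamics
    )
    refined = []
    for iv in initial:
        out = refine_interval(iv, profile, rp)
        if out is not None:
            refined.append(out)
    refined.sort(key=lambda iv: iv.start)
    # Extension may make neighbours overlap; merging resolves that.
    return merge_and_filter(refined, rp)


def train_prototypes(
    pairs: list[tuple[NucleotideSequence, list[GenomicInterval]]],
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
    spectral_params: SpectralParams | None = None,
) -> PrototypeSet:
    """Learn exon/intron prototypes from annotated sequences."""
    feats = []
    labels = []
    for seq, truth in pairs:
        f, l = training_features(seq, truth, segment_length, spectral_params)
        feats.extend(f)
        labels.extend(l)
    return learn_prototypes(feats, labels)


def evaluate_pairs(
    predictions: list[list[GenomicInterval]],
    pairs: list[tuple[NucleotideSequence, list[GenomicInterval]]],
    mode: str = "feature",
    overlap_fraction: float = 0.5,
) -> ConfusionCounts:
    """Pool confusion counts over a corpus of (sequence, truth) pairs."""
    total: ConfusionCounts | None = None
    for pred, (seq, truth) in zip(predictions, pairs):
        c = confusion(pred, truth, seq.n, mode=mode, overlap_fraction=overlap_fraction)
        total = c if total is None else total + c
    if total is None:
        raise ValueError("no sequences to evaluate")
    return total
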