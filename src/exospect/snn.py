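"""Synergetic neural network (SNN) for coarse exon segment labelling.

A synergetic network classifies a pattern q by letting *order parameters*
compete.  Each class k owns a unit prototype vector v_k and an adjoint
v_k+ satisfying biorthogonality (v_k+ . v_k' = delta_kk').  The initial
order parameters are the adjoint projections xi_k(0) = v_k+ . q, and they
evolve under the Haken dynamics

    d xi_k / dt = lambda_k xi_k
                  - B (sum_{k' != k} xi_k'^2) xi_k
                  - C |sum_k' xi_k'^2| xi_k ,

a winner-take-all competition: with equal positive attention parameters
lambda_k the order parameter with the largest initial square survives and
converges to the amplitude sqrt(lambda / C); all others decay to zero.

Applied to exon recognition, a sequence is partitioned into equal-length
segments (the N-equal method); each segment is summarised by a spectral
feature vector, classified exon/intron by the competition, and maximal
runs of exon-labelled segments become the initial candidate intervals for
the refinement stage.

The feature vector is the segment's four-indicator power spectrum
restricted to a relative-frequency band around 1/3 (where the codon
period lives), resampled to a fixed dimension so segments of different
lengths are comparable, and normalised to unit length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    DegenerateFeatureError,
    InstabilityError,
    NoCompetitionError,
    RankError,
)
from .intervals import GenomicInterval
from .seqmap import NucleotideSequence, indicator_tracks
from .spectral import SpectralParams, power_spectrum_indicator

#: Default feature dimension (number of resampled spectral bins).
FEATURE_DIM = 32

#: Relative-frequency band resampled into the feature vector, centred on 1/3.
FEATURE_BAND = (0.25, 5.0 / 12.0)

#: Segments shorter than this carry too little spectral signal to classify.
MIN_SEGMENT_LENGTH = 30

#: Default segment length of the N-equal partition: one third of the
#: default spectral window (odd, divisible by 3).  Segments must be short
#: enough that an exon at the lower end of realistic exon lengths
#: (~120 nt) can still dominate at least one segment; with longer
#: segments such exons never exceed half a segment's content and the
#: winner-take-all competition labels every segment intron.
DEFAULT_SEGMENT_LENGTH = 117


@dataclass(frozen=True)
class SegmentFeature:
    """A unit-norm spectral feature vector for one segment."""

    interval: GenomicInterval
    q: np.ndarray


@dataclass(frozen=True)
class PrototypeSet:
    """Class prototypes (rows, unit norm) and their biorthogonal adjoints."""

    labels: tuple[str, ...]
    prototypes: np.ndarray  # (M, D)
    adjoints: np.ndarray    # (M, D), adjoints @ prototypes.T == I

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    @property
    def dim(self) -> int:
        return self.prototypes.shape[1]


@dataclass
class OrderParameterState:
    """State and parameters of the order-parameter dynamics.

    ``xi`` is the current order-parameter vector (one entry per class);
    ``lambda_`` the attention parameter(s), ``B``/``C`` the competition
    and saturation coefficients, ``noise`` the amplitude of an optional
    Gaussian fluctuation term, integrated with forward Euler steps of
    ``step_size`` until the largest update falls below ``tol``.
    """

    xi: np.ndarray | None = None
    lambda_: float = 1.0
    B: float = 1.0
    C: float = 1.0
    noise: float = 0.0
    step_size: float = 0.1
    max_iters: int = 1000
    tol: float = 1e-6
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.lambda_) <= 0):
            raise ValueError("attention parameters lambda must be positive")
        if self.B <= 0 or self.C <= 0:
            raise ValueError("B and C must be positive")
        if self.noise < 0:
            raise ValueError("noise amplitude must be >= 0")
        if self.step_size <= 0 or self.max_iters < 1 or self.tol <= 0:
            raise ValueError("invalid integration parameters")


def segment_features(
    seq: NucleotideSequence,
    interval: GenomicInterval,
    params: SpectralParams | None = None,
    dim: int = FEATURE_DIM,
) -> SegmentFeature:
    """Spectral feature vector of one segment.

    The segment's indicator power spectrum is accumulated into ``dim``
    equal sub-bands of ``FEATURE_BAND`` (each feature entry is the summed
    power of the spectrum bins falling in that sub-band) and normalised
    to unit Euclidean norm.  Binning rather than point interpolation is
    essential: the period-3 peak occupies a single spectrum bin whose
    exact relative frequency depends on the segment length, and a point
    sample on a fixed grid would usually miss it.  Identical segments
    always yield identical features.
    """
    if interval.length < MIN_SEGMENT_LENGTH:
        raise ValueError(
            f"segment [{interval.start}, {interval.end}) shorter than "
            f"{MIN_SEGMENT_LENGTH} nt"
        )
    if interval.end > seq.n:
        raise ValueError("segment exceeds sequence bounds")
    sub = seq.subsequence(interval.start, interval.end)
    spec = power_spectrum_indicator(indicator_tracks(sub))
    length = sub.n
    rel_freq = np.arange(length) / length
    in_band = (rel_freq >= FEATURE_BAND[0]) & (rel_freq < FEATURE_BAND[1])
    v, _ = np.histogram(
        rel_freq[in_band],
        bins=dim,
        range=FEATURE_BAND,
        weights=spec.values[in_band],
    )
    norm = np.linalg.norm(v)
    if norm == 0.0:
        raise DegenerateFeatureError(
            f"segment [{interval.start}, {interval.end}) has an all-zero "
            "band spectrum (all-N?)"
        )
    return SegmentFeature(interval=interval, q=v / norm)


def learn_prototypes(
    features: list[SegmentFeature], labels: list[str]
) -> PrototypeSet:
    """Build prototypes as unit-normalised per-class feature means and
    adjoints as the pseudo-inverse rows of the prototype matrix.

    Raises :class:`RankError` if fewer than two classes are present or the
    class means are linearly dependent (adjoints would not exist).
    """
    if len(features) != len(labels):
        raise ValueError("features and labels must have equal length")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise RankError(
            f"need at least two classes for competition, got {classes}"
        )
    protos = []
    for cls in classes:
        qs = [f.q for f, lab in zip(features, labels) if lab == cls]
        mean = np.mean(qs, axis=0)
        norm = np.linalg.norm(mean)
        if norm == 0.0:
            raise RankError(f"class {cls!r} has a zero mean feature vector")
        protos.append(mean / norm)
    v = np.stack(protos)  # (M, D)
    if np.linalg.matrix_rank(v) < len(classes):
        raise RankError("class mean vectors are linearly dependent")
    adjoints = np.linalg.pinv(v.T)  # rows satisfy adjoints @ v.T == I
    return PrototypeSet(labels=tuple(classes), prototypes=v, adjoints=adjoints)


def initial_order_parameters(
    feature: SegmentFeature | np.ndarray, protos: PrototypeSet
) -> np.ndarray:
    """xi_k(0) = v_k+ . q, the adjoint projections of the pattern."""
    q = feature.q if isinstance(feature, SegmentFeature) else np.asarray(feature)
    if q.shape[0] != protos.dim:
        raise ValueError(
            f"feature dimension {q.shape[0]} != prototype dimension {protos.dim}"
        )
    return protos.adjoints @ q


def evolve_order_parameters(
    state: OrderParameterState,
) -> tuple[int, np.ndarray, int]:
    """Integrate the order-parameter competition to convergence.

    Returns ``(winner, xi_final, iterations)`` where ``winner`` is the
    index of the largest squared order parameter (lowest index on an
    exact tie).  Competition acts on xi^2, so the sign of an initial
    order parameter is irrelevant to who wins.
    """
    if state.xi is None:
        raise ValueError("state.xi must be set before evolving")
    xi = np.asarray(state.xi, dtype=np.float64).copy()
    if np.all(xi == 0):
        raise NoCompetitionError("all initial order parameters are zero")
    lam = np.asarray(state.lambda_, dtype=np.float64)
    h = state.step_size
    rng = np.random.default_rng(state.seed) if state.noise > 0 else None

    iterations = 0
    for iterations in range(1, state.max_iters + 1):
        total = float(np.dot(xi, xi))
        dxi = lam * xi - state.B * (total - xi**2) * xi - state.C * abs(total) * xi
        step = h * dxi
        if rng is not None:
            step = step + state.noise * np.sqrt(h) * rng.standard_normal(xi.shape)
        xi = xi + step
        if not np.all(np.isfinite(xi)) or np.max(np.abs(xi)) > 1e6:
            raise InstabilityError(
                f"order parameters diverged at iteration {iterations}; "
                f"reduce step_size (currently {h})"
            )
        if np.max(np.abs(step)) < state.tol:
            break
    winner = int(np.argmax(xi**2))
    return winner, xi, iterations


def classify_feature(
    feature: SegmentFeature,
    protos: PrototypeSet,
    dynamics: OrderParameterState | None = None,
) -> str:
    """Run the full competition for one feature and return the winning label."""
    dynamics = dynamics or OrderParameterState()
    xi0 = initial_order_parameters(feature, protos)
    winner, _, _ = evolve_order_parameters(replace(dynamics, xi=xi0))
    return protos.labels[winner]


def partition_segments(
    n: int,
    segment_length: int | None = None,
    n_segments: int | None = None,
) -> list[tuple[int, int]]:
    """The N-equal partition of [0, n): equal-length segments, last one
    possibly shorter and dropped when below MIN_SEGMENT_LENGTH."""
    if n_segments is not None:
        segment_length = max(n // n_segments, 1)
    elif segment_length is None:
        segment_length = DEFAULT_SEGMENT_LENGTH
    if segment_length < 1:
        raise ValueError("segment length must be >= 1")
    bounds = []
    for start in range(0, n, segment_length):
        end = min(start + segment_length, n)
        if end - start >= MIN_SEGMENT_LENGTH:
            bounds.append((start, end))
    return bounds


def detect_initial_intervals(
    seq: NucleotideSequence,
    protos: PrototypeSet,
    params: SpectralParams | None = None,
    segment_length: int | None = None,
    n_segments: int | None = None,
    dynamics: OrderParameterState | None = None,
) -> list[GenomicInterval]:
    """Stage 1: N-equal segmentation + SNN labelling + run merging.

    Each segment is classified exon/intron by the order-parameter
    competition; maximal runs of exon-labelled segments are merged into
    candidate intervals.  Degenerate segments (all-N) and segments whose
    projections are all zero default to intron.
    """
    labels: list[str] = []
    bounds = partition_segments(seq.n, segment_length, n_segments)
    for start, end in bounds:
        iv = GenomicInterval(seq.id, start, end, "candidate")
        try:
            feat = segment_features(seq, iv, params)
            label = classify_feature(feat, protos, dynamics)
        except (DegenerateFeatureError, NoCompetitionError):
            label = "intron"
        labels.append(label)

    out: list[GenomicInterval] = []
    run_start: int | None = None
    for (start, end), label in zip(bounds, labels):
        if label == "exon":
            if run_start is None:
                run_start = start
            run_end = end
        elif run_start is not None:
            out.append(GenomicInterval(seq.id, run_start, run_end, "candidate"))
            run_start = None
    if run_start is not None:
        out.append(GenomicInterval(seq.id, run_start, run_end, "candidate"))
    return out


def training_features(
    seq: NucleotideSequence,
    truth: list[GenomicInterval],
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
    params: SpectralParams | None = None,
) -> tuple[list[SegmentFeature], list[str]]:
    """Chop labelled truth intervals into segment-sized chunks and extract
    features, for prototype training."""
    feats: list[SegmentFeature] = []
    labels: list[str] = []
    for iv in truth:
        if iv.label not in ("exon", "intron"):
            continue
        for start in range(iv.start, iv.end, segment_length):
            end = min(start + segment_length, iv.end)
            if end - start < MIN_SEGMENT_LENGTH:
                continue
            chunk = GenomicInterval(seq.id, start, end, iv.label)
            try:
                feats.append(segment_features(seq, chunk, params))
                labels.append(iv.label)
            except DegenerateFeatureError:
                continue
    return feats, labels


def save_prototypes(protos: PrototypeSet, path) -> None:
    """Serialise a prototype set to a self-describing JSON text file."""
    payload = {
        "format": "exospect-prototypes",
        "dim": protos.dim,
        "labels": list(protos.labels),
        "prototypes": protos.prototypes.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_prototypes(path) -> PrototypeSet:
    """Load a prototype set; adjoints are recomputed from the prototypes."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "exospect-prototypes":
        raise ValueError(f"{path}: not a prototype file")
    v = np.asarray(payload["prototypes"], dtype=np.float64)
    labels = tuple(payload["labels"])
    if np.linalg.matrix_rank(v) < len(labels):
        raise RankError("stored prototypes are linearly dependent")
    adjoints = np.linalg.pinv(v.T)
    return PrototypeSet(labels=labels, prototypes=v, adjoints=adjoints)
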