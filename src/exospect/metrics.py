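"""Recognition accuracy metrics.

Sensitivity S_N = TP / (TP + FN), specificity S_P = TN / (TN + FP), and
the accuracy A_c = (S_N + S_P) / 2 — the score the swarm optimiser
maximises.  Counts can be taken at two resolutions:

* *feature* mode counts whole exons/introns: a true exon is a TP when at
  least ``overlap_fraction`` of its bases are covered by predictions
  (inclusive at the boundary), otherwise an FN; a true intron is a TN
  when less than that fraction is covered, otherwise an FP;
* *nucleotide* mode builds the per-base 2x2 table, so the four counts
  always sum to the sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError
from .intervals import GenomicInterval


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int
    mode: str = "feature"

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.mode not in ("feature", "nucleotide"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if self.mode != other.mode:
            raise ValueError("cannot pool counts of different modes")
        return ConfusionCounts(
            self.tp + other.tp,
            self.fn + other.fn,
            self.tn + other.tn,
            self.fp + other.fp,
            self.mode,
        )


def _validate_truth(truth: list[GenomicInterval], seq_length: int) -> None:
    if not truth:
        raise ValueError("truth annotation is empty")
    ordered = sorted(truth, key=lambda iv: iv.start)
    if ordered[0].start != 0 or ordered[-1].end != seq_length:
        raise ValueError("truth must cover [0, sequence length)")
    for a, b in zip(ordered, ordered[1:]):
        if a.end != b.start:
            raise ValueError(
                f"truth is not a partition: gap/overlap at {a.end} vs {b.start}"
            )
    for iv in ordered:
        if iv.label not in ("exon", "intron"):
            raise ValueError(f"truth labels must be exon/intron, got {iv.label!r}")


def _coverage_mask(pred: list[GenomicInterval], seq_length: int) -> np.ndarray:
    mask = np.zeros(seq_length, dtype=bool)
    last_end = -1
    for iv in sorted(pred, key=lambda p: p.start):
        if iv.start < last_end:
            raise ValueError("predictions overlap")
        if iv.end > seq_length:
            raise ValueError("prediction exceeds sequence bounds")
        mask[iv.start : iv.end] = True
        last_end = iv.end
    return mask


def confusion(
    pred: list[GenomicInterval],
    truth: list[GenomicInterval],
    seq_length: int,
    mode: str = "feature",
    overlap_fraction: float = 0.5,
) -> ConfusionCounts:
    """Confusion counts of a prediction set against a truth partition."""
    _validate_truth(truth, seq_length)
    mask = _coverage_mask(pred, seq_length)

    if mode == "nucleotide":
        exon_mask = np.zeros(seq_length, dtype=bool)
        for iv in truth:
            if iv.label == "exon":
                exon_mask[iv.start : iv.end] = True
        tp = int(np.sum(mask & exon_mask))
        fn = int(np.sum(~mask & exon_mask))
        fp = int(np.sum(mask & ~exon_mask))
        tn = int(np.sum(~mask & ~exon_mask))
        return ConfusionCounts(tp, fn, tn, fp, "nucleotide")

    if mode != "feature":
        raise ValueError(f"unknown mode {mode!r}")
    tp = fn = tn = fp = 0
    for iv in truth:
        frac = float(mask[iv.start : iv.end].mean())
        if iv.label == "exon":
            if frac >= overlap_fraction:
                tp += 1
            else:
                fn += 1
        else:
            if frac < overlap_fraction:
                tn += 1
            else:
                fp += 1
    return ConfusionCounts(tp, fn, tn, fp, "feature")


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("no true exons: sensitivity undefined")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("no true introns: specificity undefined")
    return c.tn / (c.tn + c.fp)


def accuracy(c: ConfusionCounts) -> float:
    """A_c, the arithmetic mean of sensitivity and specificity."""
    return (sensitivity(c) + specificity(c)) / 2.0


def report_table(rows: dict[str, ConfusionCounts]) -> pd.DataFrame:
    """One evaluation row per named sequence set: counts plus S_N, S_P, A_c."""
    records = []
    for name, c in rows.items():
        records.append(
            {
                "set": name,
                "TP": c.tp,
                "FN": c.fn,
                "TN": c.tn,
                "FP": c.fp,
                "S_N": sensitivity(c),
                "S_P": specificity(c),
                "A_c": accuracy(c),
                "mode": c.mode,
            }
        )
    return pd.DataFrame.from_records(records)
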