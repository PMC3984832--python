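"""Genomic intervals and plain-text interval formats (BED, GFF3).

Coordinates are 0-based half-open throughout the package; the GFF3 writer
converts to 1-based inclusive on output.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import OrderingError

_KNOWN_LABELS = {"exon", "intron", "candidate"}


@dataclass(frozen=True)
class GenomicInterval:
    """A labelled half-open interval ``[start, end)`` on one sequence.

    ``score`` carries the mean (smoothed) SNR over the interval once the
    refinement stage has run; before that it is 0.
    """

    seq_id: str
    start: int
    end: int
    label: str = "candidate"
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id!r}"
            )
        if self.label not in _KNOWN_LABELS:
            raise ValueError(f"unknown interval label {self.label!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def check_sorted(intervals: list[GenomicInterval]) -> None:
    """Raise :class:`OrderingError` unless intervals are sorted by start."""
    for a, b in zip(intervals, intervals[1:]):
        if b.start < a.start:
            raise OrderingError(
                f"intervals out of order: {b.start} after {a.start}"
            )


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED file into intervals.

    The name column (4th), when equal to ``exon`` or ``intron``, becomes the
    interval label; anything else maps to ``candidate``.  The score column is
    taken at face value (no rescaling).
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = "candidate"
            score = 0.0
            if len(parts) > 3 and parts[3] in _KNOWN_LABELS:
                label = parts[3]
            if len(parts) > 4:
                try:
                    score = float(parts[4])
                except ValueError:
                    score = 0.0
            out.append(GenomicInterval(chrom, start, end, label, score))
    return out


def write_bed(intervals: list[GenomicInterval], path) -> None:
    """Write 6-column BED; scores are SNR values scaled x100, clipped to 0-1000."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            bed_score = int(min(1000, max(0, round(100 * iv.score))))
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.label}{i + 1}"
                f"\t{bed_score}\t+\n"
            )


def write_gff3(intervals: list[GenomicInterval], path) -> None:
    """Write GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, iv in enumerate(intervals):
            fh.write(
                f"{iv.seq_id}\texospect\texon\t{iv.start + 1}\t{iv.end}\t"
                f"{iv.score:.3f}\t+\t.\tID={iv.label}{i + 1}\n"
            )


def truth_from_exons(
    exons: list[GenomicInterval], seq_length: int, seq_id: str | None = None
) -> list[GenomicInterval]:
    """Complete a list of exon intervals into an exon/intron partition of
    ``[0, seq_length)`` by filling every gap with an intron interval."""
    exons = sorted(exons, key=lambda iv: iv.start)
    check_sorted(exons)
    sid = seq_id or (exons[0].seq_id if exons else "seq")
    out: list[GenomicInterval] = []
    cursor = 0
    for ex in exons:
        if ex.start > cursor:
            out.append(GenomicInterval(sid, cursor, ex.start, "intron"))
        out.append(GenomicInterval(sid, ex.start, ex.end, "exon", ex.score))
        cursor = ex.end
    if cursor < seq_length:
        out.append(GenomicInterval(sid, cursor, seq_length, "intron"))
    return out
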