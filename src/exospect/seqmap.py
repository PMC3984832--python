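"""Sequence ingestion and numeric DNA mappings.

A DNA string over {A, C, G, T, N} is turned into four binary *indicator*
tracks (one per base) and into the three-component *Z-curve* difference
representation.  The Z-curve assigns each base a sign triple on the
purine/amino/weak-strong axes:

    A -> (+1, +1, +1)    C -> (-1, +1, -1)
    G -> (+1, -1, -1)    T -> (-1, -1, +1)

so that the cumulative sums trace a 3-D curve whose increments carry the
same information as the sequence itself.  The ambiguity symbol N maps to
all-zero indicators and a (0, 0, 0) increment: it contributes nothing to
any downstream spectrum but still occupies a position, so track lengths
always equal the sequence length.

All coordinates are 0-based; cumulative tracks use the convention that the
running sum before the first position is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
from Bio import SeqIO

from .errors import FastaFormatError

#: Canonical base order used for all (4, N) stacked tracks.
BASES = "ACGT"

_ALPHABET = set("ACGTN")

# Columns are A, C, G, T; rows are the dx (purine), dy (amino),
# dz (weak-strong) axes.
_ZMATRIX = np.array(
    [
        [1, -1, 1, -1],
        [1, 1, -1, -1],
        [1, -1, -1, 1],
    ],
    dtype=np.int8,
)

_SIGNS_TO_BASE = {tuple(_ZMATRIX[:, j]): BASES[j] for j in range(4)}


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA string over {A, C, G, T, N}.

    Residues are uppercased on construction; lowercase soft-masking is
    treated as the plain base.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError("empty sequence")
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise ValueError(f"invalid symbol(s) {sorted(bad)} in {self.id!r}")

    @property
    def n(self) -> int:
        """Sequence length."""
        return len(self.residues)

    def subsequence(self, start: int, end: int) -> "NucleotideSequence":
        if not (0 <= start < end <= self.n):
            raise ValueError(f"[{start}, {end}) outside [0, {self.n})")
        return NucleotideSequence(f"{self.id}:{start}-{end}", self.residues[start:end])


@dataclass(frozen=True)
class IndicatorTracks:
    """Four binary tracks, stacked as a (4, N) array in A, C, G, T order.

    At each unambiguous position exactly one row is 1; at N positions all
    four rows are 0.
    """

    u: np.ndarray

    @property
    def n(self) -> int:
        return self.u.shape[1]

    def track(self, base: str) -> np.ndarray:
        return self.u[BASES.index(base.upper())]


@dataclass(frozen=True)
class ZCurveTracks:
    """Z-curve increments dx, dy, dz (values in {-1, 0, +1}) and their
    cumulative sums."""

    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray

    @property
    def n(self) -> int:
        return self.dx.shape[0]

    @property
    def cum_x(self) -> np.ndarray:
        return np.cumsum(self.dx)

    @property
    def cum_y(self) -> np.ndarray:
        return np.cumsum(self.dy)

    @property
    def cum_z(self) -> np.ndarray:
        return np.cumsum(self.dz)


def read_fasta(path) -> list[NucleotideSequence]:
    """Read a (multi-record, possibly line-wrapped) FASTA file.

    Returns one record per entry, residues uppercased, input order
    preserved.  An empty file yields an empty list.

    Raises
    ------
    FastaFormatError
        If sequence data precedes any header, or a sequence line contains
        a symbol outside {A, C, G, T, N} (case-insensitive); the message
        names the offending line number.
    """
    with open(path) as fh:
        text = fh.read()

    seen_header = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            seen_header = True
            if len(stripped) == 1:
                raise FastaFormatError(f"line {lineno}: empty FASTA header")
            continue
        if not seen_header:
            raise FastaFormatError(
                f"line {lineno}: sequence data before any '>' header"
            )
        bad = set(stripped.upper()) - _ALPHABET
        if bad:
            raise FastaFormatError(
                f"line {lineno}: invalid symbol(s) {sorted(bad)}"
            )

    return [
        NucleotideSequence(rec.id, str(rec.seq))
        for rec in SeqIO.parse(StringIO(text), "fasta")
    ]


def write_fasta(seqs: list[NucleotideSequence], path, width: int = 70) -> None:
    """Write sequences as wrapped FASTA."""
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, seq.n, width):
                fh.write(seq.residues[i : i + width] + "\n")


def indicator_tracks(seq: NucleotideSequence) -> IndicatorTracks:
    """Binary indicator tracks u_b[n] = 1 iff base b occurs at position n."""
    arr = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    u = np.stack([(arr == ord(b)) for b in BASES]).astype(np.int8)
    return IndicatorTracks(u=u)


def zcurve_map(seq: NucleotideSequence) -> ZCurveTracks:
    """Map a sequence to its Z-curve increment tracks.

    The increments are the linear image of the indicator tracks under the
    sign matrix above: dx = u_A - u_C + u_G - u_T (purine axis),
    dy = u_A + u_C - u_G - u_T (amino axis),
    dz = u_A - u_C - u_G + u_T (weak/strong hydrogen-bond axis).
    """
    u = indicator_tracks(seq).u
    d = (_ZMATRIX.astype(np.int32) @ u.astype(np.int32)).astype(np.int8)
    return ZCurveTracks(dx=d[0], dy=d[1], dz=d[2])


def zcurve_decode(tracks: ZCurveTracks, seq_id: str = "decoded") -> NucleotideSequence:
    """Invert :func:`zcurve_map` — the sign-triple map is injective on
    {A, C, G, T}, and (0, 0, 0) decodes to N."""
    residues = []
    for triple in zip(tracks.dx, tracks.dy, tracks.dz):
        triple = tuple(int(v) for v in triple)
        if triple == (0, 0, 0):
            residues.append("N")
        else:
            try:
                residues.append(_SIGNS_TO_BASE[triple])
            except KeyError:
                raise ValueError(f"not a Z-curve sign triple: {triple}") from None
    return NucleotideSequence(seq_id, "".join(residues))
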