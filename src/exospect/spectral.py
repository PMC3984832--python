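"""Power spectra and 3-base-periodicity signal-to-noise statistics.

Protein-coding DNA shows a statistical period of three along the sequence
(the codon structure), which appears in the discrete Fourier power
spectrum as peaks at k = N/3 and k = 2N/3.  This module computes

* the Z-curve power spectrum  P_z[k] = |DX[k]|^2 + |DY[k]|^2 + |DZ[k]|^2,
  where DX, DY, DZ are the unnormalised DFTs (e^{-j 2 pi n k / N}) of the
  three Z-curve increment tracks;
* the indicator power spectrum, the analogous sum over the four base
  indicator tracks;
* the global signal-to-noise ratio  R = P[N/3] / E  with E the mean
  spectral power, and its gamma-neighbourhood averages R1, R2 around N/3
  and 2N/3;
* a per-position SNR track from a fixed sliding window of odd length M
  divisible by 3, evaluated at the period-3 bin k = M/3.

The sliding track exploits two identities: (i) at k = M/3 the DFT kernel
e^{-j 2 pi i k / M} = e^{-j 2 pi i / 3} has period three in the absolute
position i, so the single-bin coefficient is a windowed sum of
phase-weighted indicators computable by cumulative sums in O(N); and
(ii) by Parseval the mean power of a window's indicator spectrum equals
the number of unambiguous bases in the window, so the local normaliser
needs no FFT either.  Both identities are cross-checked against a direct
FFT oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedSNRError, WindowError
from .seqmap import IndicatorTracks, NucleotideSequence, ZCurveTracks, indicator_tracks


@dataclass
class SpectralParams:
    """Parameters of the spectral front-end.

    Parameters
    ----------
    window_length : int
        Sliding-window length M; must be odd (so the half-width (M-1)/2 is
        integral) and divisible by 3 (so the period-3 bin M/3 is integral).
        Default 351.
    gamma : int
        Half-width of the neighbourhood average around the period-3 bin.
    t0 : float
        SNR decision threshold for the refinement stage.
    r0 : float
        Fixed baseline threshold (the classical fixed-window method uses 2).
    normalization : str
        'local' divides each window's peak power by that window's own mean
        spectral power; 'global' divides by the average of those window
        means over the whole sequence.
    """

    window_length: int = 351
    gamma: int = 3
    t0: float = 2.0
    r0: float = 2.0
    normalization: str = "local"

    def __post_init__(self) -> None:
        m = self.window_length
        if m < 3 or m % 2 == 0 or m % 3 != 0:
            raise ValueError(
                f"window_length must be odd and divisible by 3, got {m}"
            )
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.t0 <= 0 or self.r0 <= 0:
            raise ValueError("thresholds t0 and r0 must be positive")
        if self.normalization not in ("local", "global"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass(frozen=True)
class PowerSpectrum:
    """A DFT power spectrum P[k], k = 0..N-1, of a length-N source."""

    values: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        if len(self.values) != self.source_length:
            raise ValueError("spectrum length must equal source length")
        if np.any(self.values < 0):
            raise ValueError("power spectrum must be non-negative")


@dataclass(frozen=True)
class SNRProfile:
    """Per-position signal-to-noise track from a sliding window.

    ``snr[n]`` is the window-local SNR of the window centred at n; the
    (M-1)/2 positions at either end, which lack full window support,
    carry the value of the nearest fully supported position.
    ``normalizer`` records the mean per-window normalising power.
    """

    snr: np.ndarray
    window_length: int
    normalizer: float
    normalization: str = "local"

    @property
    def n(self) -> int:
        return self.snr.shape[0]


def periodicity_bin(n: int) -> int:
    """The period-3 frequency bin, rounded when N is not divisible by 3.

    For coding sequences whose length is not a multiple of three the
    spectral peak falls next to N/3 rather than on an integer bin, so the
    nearest bin is used.
    """
    return int(round(n / 3))


def power_spectrum_z(tracks: ZCurveTracks) -> PowerSpectrum:
    """Z-curve power spectrum: summed squared DFT magnitudes of dx, dy, dz."""
    fx = np.fft.fft(tracks.dx)
    fy = np.fft.fft(tracks.dy)
    fz = np.fft.fft(tracks.dz)
    values = np.abs(fx) ** 2 + np.abs(fy) ** 2 + np.abs(fz) ** 2
    return PowerSpectrum(values=values, source_length=tracks.n)


def power_spectrum_indicator(tracks: IndicatorTracks) -> PowerSpectrum:
    """Indicator power spectrum: summed squared DFT magnitudes of the four
    base indicator tracks."""
    spec = np.fft.fft(tracks.u, axis=1)
    values = (np.abs(spec) ** 2).sum(axis=0)
    return PowerSpectrum(values=values, source_length=tracks.n)


def global_snr(spec: PowerSpectrum) -> float:
    """Whole-sequence SNR: power at the period-3 bin over mean power."""
    ebar = float(spec.values.mean())
    if ebar == 0.0:
        raise UndefinedSNRError("all-zero spectrum: SNR undefined")
    return float(spec.values[periodicity_bin(spec.source_length)] / ebar)


def neighborhood_snr(spec: PowerSpectrum, gamma: int) -> tuple[float, float]:
    """Average SNR over the bins within +-gamma of N/3 and of 2N/3.

    With gamma = 0 this reduces exactly to :func:`global_snr` (for the
    first component).  The spectral peak of real coding sequence often
    sits beside rather than on the nominal bin, which is what the
    neighbourhood average absorbs.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    n = spec.source_length
    k1 = periodicity_bin(n)
    k2 = int(round(2 * n / 3))
    if k1 - gamma < 0 or k2 + gamma > n - 1:
        raise WindowError(
            f"gamma={gamma} exceeds spectrum bounds for length {n}"
        )
    ebar = float(spec.values.mean())
    if ebar == 0.0:
        raise UndefinedSNRError("all-zero spectrum: SNR undefined")
    width = 2 * gamma + 1
    r1 = float(spec.values[k1 - gamma : k1 + gamma + 1].sum() / (width * ebar))
    r2 = float(spec.values[k2 - gamma : k2 + gamma + 1].sum() / (width * ebar))
    return r1, r2


def _window_sums(x: np.ndarray, m: int) -> np.ndarray:
    """Sliding sums of length m along the last axis (valid positions only)."""
    cs = np.cumsum(x, axis=-1)
    pad = np.zeros(cs.shape[:-1] + (1,), dtype=cs.dtype)
    cs = np.concatenate([pad, cs], axis=-1)
    return cs[..., m:] - cs[..., :-m]


def windowed_snr_track(seq: NucleotideSequence, params: SpectralParams) -> SNRProfile:
    """Per-position SNR from a fixed sliding window of length M.

    For every position with full window support the four indicator tracks
    are Fourier-analysed at the period-3 bin k = M/3 over the window
    centred there; the summed peak power is divided by the window's mean
    spectral power (local mode) or by the sequence-wide average of those
    means (global mode).  Windows consisting entirely of N get SNR 0.
    """
    m = params.window_length
    n = seq.n
    if n < m:
        raise WindowError(
            f"sequence length {n} < window length {m}; use a smaller window"
        )
    half = (m - 1) // 2
    u = indicator_tracks(seq).u.astype(np.float64)

    # e^{-j 2 pi i (M/3) / M} depends only on i mod 3.
    phase = np.exp(-2j * np.pi * (np.arange(n) % 3) / 3)
    coeff = _window_sums(u * phase, m)            # (4, n - m + 1)
    peak_power = (np.abs(coeff) ** 2).sum(axis=0)

    # Parseval: mean indicator-spectrum power of a window == its count of
    # unambiguous bases.
    valid = _window_sums(u.sum(axis=0), m)

    if params.normalization == "local":
        core = np.divide(
            peak_power, valid, out=np.zeros_like(peak_power), where=valid > 0
        )
        normalizer = float(valid.mean())
    else:
        normalizer = float(valid.mean())
        if normalizer == 0.0:
            raise UndefinedSNRError("all-N sequence: SNR undefined")
        core = peak_power / normalizer

    snr = np.empty(n, dtype=np.float64)
    snr[half : n - half] = core
    snr[:half] = core[0]
    snr[n - half :] = core[-1]
    return SNRProfile(
        snr=snr,
        window_length=m,
        normalizer=normalizer,
        normalization=params.normalization,
    )


def window_snr_at(seq: NucleotideSequence, center: int, params: SpectralParams) -> float:
    """Independently recompute the window SNR at one position via a full
    M-point FFT of the window (no incremental updates).

    Used as a spot-check against :func:`windowed_snr_track`; only valid at
    positions with full window support and in local normalisation.
    """
    m = params.window_length
    half = (m - 1) // 2
    if not (half <= center <= seq.n - 1 - half):
        raise WindowError(f"position {center} lacks full window support")
    u = indicator_tracks(seq).u[:, center - half : center + half + 1]
    spec = np.fft.fft(u, axis=1)
    power = (np.abs(spec) ** 2).sum(axis=0)
    ebar = power.mean()
    if ebar == 0.0:
        return 0.0
    return float(power[m // 3] / ebar)


def write_snr_tsv(seq_id: str, profile: SNRProfile, path) -> None:
    """Export an SNR track as a 4-column TSV (id, position, snr, window)."""
    with open(path, "w") as fh:
        fh.write("seq_id\tposition\tsnr\twindow\n")
        for i, v in enumerate(profile.snr):
            fh.write(f"{seq_id}\t{i}\t{v:.6g}\t{profile.window_length}\n")
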