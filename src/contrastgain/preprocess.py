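"""Raw voltage to analog MUA / LFP / chord-binned responses.

Analog multiunit activity (MUA) is used instead of threshold-crossing spike
counts: the recorded voltage is band-passed to the spike band (300-6,000 Hz),
full-wave rectified, low-pass filtered below 6 kHz and resampled to 12 kHz,
yielding a nonnegative envelope in microvolts whose stimulus-driven
modulation tracks population spiking.  Local field potentials are extracted
with an eighth-order Chebyshev Type I low-pass below 300 Hz.  All filters
are applied forward-backward (zero phase) so that response timing is
preserved for 25-ms chord binning.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

MUA_BAND_HZ = (300.0, 6000.0)
MUA_FS_HZ = 12000.0
LFP_CORNER_HZ = 300.0
LFP_CHEBY_ORDER = 8
LFP_CHEBY_RIPPLE_DB = 0.05

__all__ = [
    "RawTrace",
    "AnalogMUATrace",
    "LFPTrace",
    "BinnedResponse",
    "extract_mua",
    "extract_lfp",
    "bin_response",
]


@dataclass(frozen=True)
class RawTrace:
    """Single-channel wideband voltage trace (microvolts)."""

    samples: np.ndarray
    fs: float
    channel_id: int | str | None = None
    depth_um: float | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, float)
        if not np.all(np.isfinite(samples)):
            raise ValueError("raw trace contains non-finite samples")
        object.__setattr__(self, "samples", samples)


@dataclass(frozen=True)
class AnalogMUATrace:
    """Nonnegative analog-MUA envelope at 12 kHz (microvolts)."""

    samples: np.ndarray
    fs: float = MUA_FS_HZ


@dataclass(frozen=True)
class LFPTrace:
    """Low-passed (<300 Hz) field potential (microvolts)."""

    samples: np.ndarray
    fs: float


@dataclass(frozen=True)
class BinnedResponse:
    """Per-chord mean MUA, one value per 25-ms chord (microvolts)."""

    y: np.ndarray
    chord_duration: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "y", np.asarray(self.y, float))

    @property
    def n_chords(self) -> int:
        return len(self.y)


def _resample_fraction(fs_in: float, fs_out: float) -> Fraction:
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return frac


def extract_mua(trace: RawTrace) -> AnalogMUATrace:
    """Extract the analog-MUA envelope from a wideband trace.

    Chain: zero-phase 4th-order Butterworth band-pass 300-6,000 Hz ->
    full-wave rectification -> zero-phase low-pass below 6 kHz ->
    anti-aliased polyphase resampling to 12 kHz.  Output is clipped at zero
    (rectification guarantees nonnegativity up to filter ringing).
    """
    if trace.fs <= MUA_FS_HZ:
        raise ValueError(
            f"sample rate {trace.fs} Hz too low: need > {MUA_FS_HZ:g} Hz to "
            "produce a 12 kHz envelope"
        )
    nyq = trace.fs / 2.0
    lo, hi = MUA_BAND_HZ
    hi = min(hi, 0.99 * nyq)
    sos_bp = signal.butter(4, [lo, hi], btype="bandpass", fs=trace.fs, output="sos")
    band = signal.sosfiltfilt(sos_bp, trace.samples)
    rectified = np.abs(band)
    corner = min(MUA_BAND_HZ[1], 0.99 * nyq)
    sos_lp = signal.butter(4, corner, btype="lowpass", fs=trace.fs, output="sos")
    envelope = signal.sosfiltfilt(sos_lp, rectified)
    frac = _resample_fraction(trace.fs, MUA_FS_HZ)
    resampled = signal.resample_poly(envelope, frac.numerator, frac.denominator)
    return AnalogMUATrace(samples=np.maximum(resampled, 0.0), fs=MUA_FS_HZ)


def extract_lfp(trace: RawTrace, decimate_to: float | None = None) -> LFPTrace:
    """Extract the LFP: zero-phase 8th-order Chebyshev-I low-pass < 300 Hz.

    ``decimate_to`` optionally resamples the filtered signal to a lower rate
    (must still satisfy Nyquist for the 300 Hz corner).
    """
    if trace.fs <= 600.0:
        raise ValueError("sample rate must exceed 600 Hz for a 300 Hz low-pass")
    sos = signal.cheby1(
        LFP_CHEBY_ORDER, LFP_CHEBY_RIPPLE_DB, LFP_CORNER_HZ, btype="lowpass",
        fs=trace.fs, output="sos",
    )
    filtered = signal.sosfiltfilt(sos, trace.samples)
    fs_out = trace.fs
    if decimate_to is not None:
        if decimate_to < 2 * LFP_CORNER_HZ:
            raise ValueError("decimation target below Nyquist for the LFP band")
        frac = _resample_fraction(trace.fs, decimate_to)
        filtered = signal.resample_poly(filtered, frac.numerator, frac.denominator)
        fs_out = decimate_to
    return LFPTrace(samples=filtered, fs=fs_out)


def bin_response(
    mua: AnalogMUATrace,
    n_chords: int,
    chord_duration: float,
    onset: float = 0.0,
) -> BinnedResponse:
    """Average the MUA envelope within each chord's half-open time window.

    Window t covers ``[onset + t*chord_duration, onset + (t+1)*chord_duration)``.
    No latency correction is applied: response latency is absorbed by the
    STRF's 400-ms history kernel.
    """
    n_needed = onset + n_chords * chord_duration
    duration = len(mua.samples) / mua.fs
    if duration + 0.5 / mua.fs < n_needed:
        raise ValueError(
            f"trace of {duration:.4f} s too short for {n_chords} chords "
            f"starting at {onset:.4f} s ({n_needed:.4f} s needed)"
        )
    edges = onset + np.arange(n_chords + 1) * chord_duration
    idx = np.round(edges * mua.fs).astype(int)
    y = np.empty(n_chords)
    for t in range(n_chords):
        y[t] = mua.samples[idx[t]:idx[t + 1]].mean()
    return BinnedResponse(y=y, chord_duration=chord_duration)
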