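"""Dynamic random chord (DRC) stimulus generation.

A DRC is a sequence of chords, each a superposition of pure tones on a fixed
log-spaced frequency grid.  The level of every tone is redrawn independently
for each chord from a uniform distribution; the width of that distribution
sets both the spectral and the temporal contrast of the stimulus.  Two
conditions are used throughout this package: a low-contrast DRC (levels
uniform over a 20-dB range) and a high-contrast DRC (40-dB range), both with
a mean level of 80 dB SPL.

Contrast is summarised two ways: the standard deviation of the tone levels
in dB (sigma_L) and the Weber contrast sigma_P / mu_P of the corresponding
sound-pressure distribution (p proportional to 10**(L/20)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHORD_DURATION_S = 0.025
RAMP_DURATION_S = 0.005

__all__ = [
    "ToneGrid",
    "LevelDistributionSpec",
    "DRCStimulus",
    "ContrastSummary",
    "make_tone_grid",
    "draw_chord_levels",
    "compute_contrast",
    "synthesize_waveform",
    "default_calibration",
]


@dataclass(frozen=True)
class ToneGrid:
    """Log-spaced pure-tone frequency grid.

    Attributes
    ----------
    frequencies : ndarray
        Strictly increasing tone frequencies in Hz; the ratio of consecutive
        entries is constant and equal to ``2**spacing_octaves``.
    spacing_octaves : float
        Fraction of an octave between neighbouring tones.
    """

    frequencies: np.ndarray
    spacing_octaves: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", np.asarray(self.frequencies, float))

    @property
    def n_tones(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class LevelDistributionSpec:
    """Uniform tone-level distribution: mean level and total range in dB."""

    mean_level: float
    range_width: float

    def __post_init__(self) -> None:
        if self.range_width < 0:
            raise ValueError("range_width must be >= 0")

    @property
    def support(self) -> tuple[float, float]:
        half = self.range_width / 2.0
        return (self.mean_level - half, self.mean_level + half)


@dataclass(frozen=True)
class DRCStimulus:
    """A generated DRC: chord-by-tone level matrix plus timing metadata."""

    levels: np.ndarray  # (n_chords, n_tones), dB SPL
    grid: ToneGrid
    chord_duration: float = CHORD_DURATION_S
    ramp_duration: float = RAMP_DURATION_S
    seed: int | None = None
    condition_label: str | None = None
    spec: LevelDistributionSpec | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", np.asarray(self.levels, float))
        if self.levels.ndim != 2:
            raise ValueError("levels must be a 2-D (n_chords, n_tones) matrix")
        if self.levels.shape[1] != self.grid.n_tones:
            raise ValueError(
                f"levels has {self.levels.shape[1]} tone columns but the grid "
                f"has {self.grid.n_tones} frequencies"
            )

    @property
    def n_chords(self) -> int:
        return self.levels.shape[0]

    @property
    def duration(self) -> float:
        return self.n_chords * self.chord_duration


@dataclass(frozen=True)
class ContrastSummary:
    """sigma_L: SD of the dB levels; weber_c: sigma/mu of the pressure distribution."""

    sigma_L: float
    weber_c: float


def make_tone_grid(f_min: float, f_max: float, spacing: float) -> ToneGrid:
    """Build a log-spaced tone grid spanning ``f_min``..``f_max`` inclusive.

    Parameters
    ----------
    f_min, f_max : float
        Endpoint frequencies in Hz.  Both are included in the grid.
    spacing : float
        Spacing between neighbouring tones in octaves.  The octave span
        ``log2(f_max / f_min)`` must be an integer multiple of ``spacing``.

    Raises
    ------
    ValueError
        If the span is not an integral number of spacings, or f_min > f_max.
    """
    if f_min <= 0 or f_max <= 0:
        raise ValueError("frequencies must be positive")
    if f_min > f_max:
        raise ValueError(f"f_min ({f_min}) must not exceed f_max ({f_max})")
    if f_min == f_max:
        return ToneGrid(np.array([float(f_min)]), spacing_octaves=float(spacing))
    if spacing <= 0:
        raise ValueError("spacing must be positive for a multi-tone grid")

    span = np.log2(f_max / f_min)
    n_steps = span / spacing
    n_round = round(n_steps)
    if n_round < 1 or abs(n_steps - n_round) > 1e-9 * max(1.0, abs(n_steps)):
        raise ValueError(
            f"octave span {span:.6g} is not an integer multiple of the "
            f"requested spacing {spacing:.6g}"
        )
    exponents = np.arange(n_round + 1) * spacing
    freqs = f_min * 2.0**exponents
    freqs[-1] = f_max  # exact endpoint despite rounding
    return ToneGrid(freqs, spacing_octaves=float(spacing))


def draw_chord_levels(
    spec: LevelDistributionSpec,
    n_chords: int,
    grid: ToneGrid,
    seed: int,
    *,
    chord_duration: float = CHORD_DURATION_S,
    ramp_duration: float = RAMP_DURATION_S,
    condition_label: str | None = None,
) -> DRCStimulus:
    """Draw i.i.d. uniform tone levels for every chord of a DRC.

    Levels are independent across chords and tones, drawn from the continuous
    uniform distribution on ``spec.support``; the draw is reproducible given
    ``seed``.
    """
    if n_chords <= 0:
        raise ValueError("n_chords must be positive")
    rng = np.random.default_rng(seed)
    lo, hi = spec.support
    levels = rng.uniform(lo, hi, size=(n_chords, grid.n_tones))
    if spec.range_width == 0:
        levels = np.full((n_chords, grid.n_tones), spec.mean_level)
    return DRCStimulus(
        levels=levels,
        grid=grid,
        chord_duration=chord_duration,
        ramp_duration=ramp_duration,
        seed=seed,
        condition_label=condition_label,
        spec=spec,
    )


def compute_contrast(stim: DRCStimulus | np.ndarray) -> ContrastSummary:
    """Contrast summaries of a DRC level matrix.

    ``sigma_L`` is the standard deviation of all level entries (dB).
    ``weber_c`` is sigma/mu of the corresponding pressure values
    ``p = 10**(L/20)``; the proportionality constant cancels.
    """
    levels = stim.levels if isinstance(stim, DRCStimulus) else np.asarray(stim, float)
    if levels.size == 0:
        raise ValueError("empty level matrix")
    sigma_l = float(np.std(levels))
    pressure = 10.0 ** (levels / 20.0)
    mu_p = float(np.mean(pressure))
    weber = float(np.std(pressure) / mu_p)
    return ContrastSummary(sigma_L=sigma_l, weber_c=weber)


def default_calibration(level_db: np.ndarray | float, ref_db: float = 100.0):
    """Map dB SPL to peak sinusoid amplitude: ``10**((L - ref_db) / 20)``.

    ``ref_db`` is the level that maps to unit peak amplitude; it stands in
    for a measured speaker calibration.
    """
    return 10.0 ** ((np.asarray(level_db, float) - ref_db) / 20.0)


def synthesize_waveform(
    stim: DRCStimulus,
    fs: float,
    calibration=default_calibration,
    *,
    phase_seed: int | None = None,
) -> np.ndarray:
    """Render a DRC to an audio waveform.

    Each tone is a constant-frequency sinusoid whose amplitude within a chord
    is set by ``calibration(level_db)``.  Consecutive chords are joined by a
    linear cross-fade of ``stim.ramp_duration``: the outgoing chord ramps
    down while the incoming chord ramps up over the final ramp interval of
    each chord slot, so the total duration is exactly
    ``n_chords * chord_duration``.  Tone phases are drawn once per sequence
    from a seeded generator to avoid onset coherence.

    Raises
    ------
    ValueError
        If ``fs`` is below the Nyquist rate for the highest grid frequency,
        or the ramp does not fit inside a chord.
    """
    freqs = stim.grid.frequencies
    if freqs.size and fs < 2.0 * freqs.max():
        raise ValueError(
            f"sample rate {fs} Hz is below Nyquist for the {freqs.max()} Hz tone"
        )
    if stim.ramp_duration >= stim.chord_duration:
        raise ValueError("ramp_duration must be shorter than chord_duration")

    n_chords, n_tones = stim.levels.shape
    samples_per_chord = int(round(stim.chord_duration * fs))
    n_samples = n_chords * samples_per_chord
    if n_tones == 0:
        return np.zeros(n_samples)

    rng = np.random.default_rng(stim.seed if phase_seed is None else phase_seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_tones)

    t = np.arange(n_samples) / fs
    carriers = np.sin(2.0 * np.pi * freqs[None, :] * t[:, None] + phases[None, :])

    # Per-sample amplitude envelope for each tone: piecewise-constant chord
    # amplitudes with linear cross-fades in the last ramp_duration of each slot.
    amps = calibration(stim.levels)  # (n_chords, n_tones)
    ramp_samples = int(round(stim.ramp_duration * fs))
    env = np.repeat(amps, samples_per_chord, axis=0)  # (n_samples, n_tones)
    if ramp_samples > 1:
        fade = np.linspace(0.0, 1.0, ramp_samples, endpoint=False)[:, None]
        for c in range(n_chords - 1):
            sl = slice((c + 1) * samples_per_chord - ramp_samples,
                       (c + 1) * samples_per_chord)
            env[sl] = amps[c][None, :] * (1.0 - fade) + amps[c + 1][None, :] * fade
    return (env * carriers).sum(axis=1)
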