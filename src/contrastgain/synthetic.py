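"""Synthetic data with known ground truth for every pipeline stage.

Generates linear-nonlinear (LN) model neurons whose sigmoid gain and
threshold depend on stimulus contrast, raw voltage traces carrying spike
wavelets in the 300-6,000 Hz band, laminar potentials produced from a known
CSD forward model, and population tables of per-layer gain changes.  All
generators are pure functions of (spec, seed), so parameter-recovery tests
can compare pipeline estimates against exact ground truth.

An LN unit's response to a DRC is y_t = F_cond[z_t] + noise, where z_t is
the drive of a ground-truth separable STRF (Gaussian frequency bump,
exponentially decaying history kernel) and F_cond the condition-specific
sigmoid.  A unit's true gain change is set directly: a gain change of g%
means 1/d_high = (1 + g/100) / d_low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .csd import CSDProfile, ForwardModel, LaminarLFP
from .gainmodel import SigmoidParams, sigmoid_eval
from .preprocess import RawTrace
from .stimgen import DRCStimulus, ToneGrid, make_tone_grid
from .strf import DesignTensor, SeparableSTRF, predict

#: Per-layer simulation defaults: (n units, mean true gain change %).
#: The layer means and counts mirror the laminar analysis conditions of the
#: study this package models; the within-layer SD is 15 percentage points.
LAYER_DEFAULTS = {
    "2/3": (21, -41.6),
    "4": (39, -54.2),
    "5": (50, -60.6),
    "6": (24, -65.1),
}
LAYER_DEPTH_RANGES_UM = {"2/3": (0.0, 225.0), "4": (225.0, 425.0),
                         "5": (425.0, 675.0), "6": (675.0, 900.0)}
WITHIN_LAYER_SD = 15.0
N_PENETRATIONS = 17
DEFAULT_MEAN_LEVEL_DB = 80.0

__all__ = [
    "SyntheticUnit",
    "SyntheticPopulationSpec",
    "UnitSpec",
    "generate_unit",
    "generate_population",
    "simulate_responses",
    "calibrate_noise_sd",
    "calibrate_noise_sd_realized",
    "simulate_raw_trace",
    "biphasic_wavelet",
    "simulate_laminar_lfp",
    "make_dipole_csd",
    "simulate_gain_change_table",
]


@dataclass(frozen=True)
class UnitSpec:
    """Ground-truth parameters for one LN unit."""

    bf_hz: float = 9500.0
    bw_octaves: float = 0.5  # SD of the Gaussian frequency bump
    tau_ms: float = 40.0  # history-kernel decay constant
    kf_peak: float = 0.6  # uV/dB, peak frequency-kernel coefficient
    baseline: float = 40.0  # uV, sigmoid a
    response_range: float = 30.0  # uV, sigmoid b
    threshold_sd_units: float = 0.5  # c in units of the low-contrast drive SD
    dlow_sd_units: float = 1.0  # d_low in units of the low-contrast drive SD
    gain_change_pct: float = -50.0
    noise_sd: float = 10.0  # uV additive response noise
    depth_um: float = 300.0
    penetration_id: int = 0
    mean_level_db: float = DEFAULT_MEAN_LEVEL_DB
    level_sd_db: float = 20.0 / np.sqrt(12.0)  # low-contrast level SD


@dataclass(frozen=True)
class SyntheticUnit:
    """A generated LN unit: STRF, per-condition sigmoids, noise, location."""

    true_strf: SeparableSTRF
    sigmoid_low: SigmoidParams
    sigmoid_high: SigmoidParams
    noise_sd: float
    depth_um: float
    penetration_id: int
    grid: ToneGrid
    spec: UnitSpec

    @property
    def true_gain_change_pct(self) -> float:
        g_low = 1.0 / self.sigmoid_low.d
        g_high = 1.0 / self.sigmoid_high.d
        return 100.0 * (g_high - g_low) / g_low


@dataclass(frozen=True)
class SyntheticPopulationSpec:
    """Population-level simulation conditions (defaults mirror the study)."""

    layer_n: dict = field(default_factory=lambda: {
        l: n for l, (n, _) in LAYER_DEFAULTS.items()})
    layer_mean_gain_change: dict = field(default_factory=lambda: {
        l: m for l, (_, m) in LAYER_DEFAULTS.items()})
    within_layer_sd: float = WITHIN_LAYER_SD
    penetration_sd: float = 5.0
    n_penetrations: int = N_PENETRATIONS
    noise_sd: float = 10.0


def _gaussian_bump(grid: ToneGrid, bf_hz: float, bw_oct: float, peak: float):
    octaves = np.log2(grid.frequencies / grid.frequencies[0])
    center = octaves[np.argmin(np.abs(grid.frequencies - bf_hz))]
    return peak * np.exp(-0.5 * ((octaves - center) / bw_oct) ** 2)


def generate_unit(
    spec: UnitSpec,
    seed: int,
    grid: ToneGrid | None = None,
    history_steps: int = 16,
    step_s: float = 0.025,
) -> SyntheticUnit:
    """Deterministically generate one LN unit from its spec and a seed.

    The frequency kernel is a Gaussian bump centred on the grid frequency
    nearest ``spec.bf_hz``; the history kernel decays exponentially with
    time constant ``spec.tau_ms`` and is normalised to unit Euclidean norm
    (the package's STRF convention).  The STRF bias is set so the expected
    drive at the stimulus mean level is zero, which keeps the sigmoid
    threshold parameter on the scale of the drive fluctuations.  Sigmoid
    thresholds and inverse slopes are expressed in units of the
    low-contrast drive SD, and the high-contrast inverse slope implements
    the requested true gain change exactly.
    """
    grid = grid if grid is not None else make_tone_grid(1000.0, 64000.0, 0.25)
    k_f = _gaussian_bump(grid, spec.bf_hz, spec.bw_octaves, spec.kf_peak)
    lags_ms = np.arange(history_steps) * step_s * 1e3
    k_h = np.exp(-lags_ms / spec.tau_ms)
    norm = np.linalg.norm(k_h)
    k_h = k_h / norm
    k_f = k_f * norm
    k0 = -float(spec.mean_level_db * k_f.sum() * k_h.sum())
    strf = SeparableSTRF(k0=k0, k_f=k_f, k_h=k_h)

    # drive SD under i.i.d. levels: level SD times the kernel Frobenius norm
    sd_z_low = spec.level_sd_db * float(np.linalg.norm(np.outer(k_f, k_h)))
    c = spec.threshold_sd_units * sd_z_low
    d_low = spec.dlow_sd_units * sd_z_low
    d_high = d_low / (1.0 + spec.gain_change_pct / 100.0)
    sig_low = SigmoidParams(a=spec.baseline, b=spec.response_range, c=c, d=d_low)
    sig_high = SigmoidParams(a=spec.baseline, b=spec.response_range, c=c, d=d_high)
    return SyntheticUnit(
        true_strf=strf, sigmoid_low=sig_low, sigmoid_high=sig_high,
        noise_sd=spec.noise_sd, depth_um=spec.depth_um,
        penetration_id=spec.penetration_id, grid=grid, spec=spec,
    )


def generate_population(
    pop: SyntheticPopulationSpec,
    seed: int,
    grid: ToneGrid | None = None,
) -> list[SyntheticUnit]:
    """Draw a population of LN units with layer-dependent true gain changes."""
    rng = np.random.default_rng(seed)
    pen_offsets = rng.normal(0.0, pop.penetration_sd, pop.n_penetrations)
    units = []
    for layer, n in pop.layer_n.items():
        mean_g = pop.layer_mean_gain_change[layer]
        lo, hi = LAYER_DEPTH_RANGES_UM[layer]
        for _ in range(n):
            pen = int(rng.integers(pop.n_penetrations))
            g = float(rng.normal(mean_g + pen_offsets[pen], pop.within_layer_sd))
            g = float(np.clip(g, -95.0, -1.0))  # keep both gains positive
            spec = UnitSpec(
                bf_hz=float(rng.uniform(2000.0, 45000.0)),
                gain_change_pct=g,
                noise_sd=pop.noise_sd,
                depth_um=float(rng.uniform(lo, hi)),
                penetration_id=pen,
            )
            units.append(generate_unit(spec, seed=int(rng.integers(2**31))))
    return units


def simulate_responses(
    unit: SyntheticUnit,
    design_low: DesignTensor,
    design_high: DesignTensor,
    seed: int,
    noise_sd: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-chord LN responses to both contrast conditions.

    y_t = F_cond[z_t] + eps_t with eps ~ N(0, noise_sd^2), clipped at zero
    to respect the nonnegativity of analog-MUA envelopes.
    """
    rng = np.random.default_rng(seed)
    sd = unit.noise_sd if noise_sd is None else noise_sd
    out = []
    for design, sig in ((design_low, unit.sigmoid_low),
                        (design_high, unit.sigmoid_high)):
        z = predict(unit.true_strf, design)
        y = sigmoid_eval(z, sig) + rng.normal(0.0, sd, design.n_chords)
        out.append(np.maximum(y, 0.0))
    return out[0], out[1]


def calibrate_noise_sd(
    unit: SyntheticUnit,
    design_low: DesignTensor,
    design_high: DesignTensor,
    target_cc: float,
) -> float:
    """Noise SD such that a perfect model would score ``target_cc`` on test data.

    For additive Gaussian noise, the correlation between the noiseless
    signal and the noisy response is sigma_s / sqrt(sigma_s^2 + sigma_n^2);
    inverting gives sigma_n = sigma_s * sqrt(1/cc^2 - 1), with sigma_s the
    SD of the noiseless response over both conditions' usable rows.
    """
    if not 0.0 < target_cc < 1.0:
        raise ValueError("target_cc must lie in (0, 1)")
    sig = []
    for design, s in ((design_low, unit.sigmoid_low),
                      (design_high, unit.sigmoid_high)):
        z = predict(unit.true_strf, design)[design.mask]
        sig.append(sigmoid_eval(z, s))
    sigma_s = float(np.std(np.concatenate(sig)))
    return sigma_s * np.sqrt(1.0 / target_cc**2 - 1.0)


def calibrate_noise_sd_realized(
    unit: SyntheticUnit,
    design_low: DesignTensor,
    design_high: DesignTensor,
    target_cc: float,
    seed: int,
    n_bisect: int = 6,
    n_avg: int = 2,
) -> float:
    """Noise SD at which the *fitted* model's cross-validated test CC hits target.

    :func:`calibrate_noise_sd` gives the CC ceiling of a perfect model; the
    realised test CC of a model estimated from the noisy data is lower
    because of estimation error.  This routine bisects on the noise SD,
    simulating responses and running the 90/10 screening fit at each step
    (averaging the two conditions' test CCs over ``n_avg`` response draws,
    which keeps the calibrated level from chasing single-draw CC noise),
    until the realised CC matches ``target_cc``.
    """
    from .strf import cross_validated_cc  # local import to avoid cycle at module load

    lo = 0.0
    hi = 1.5 * calibrate_noise_sd(unit, design_low, design_high, target_cc)
    for step in range(n_bisect):
        mid = (lo + hi) / 2.0
        ccs = []
        for j in range(n_avg):
            y_low, y_high = simulate_responses(
                unit, design_low, design_high,
                seed=seed + 1009 * step + j, noise_sd=mid)
            _, rep_l = cross_validated_cc(design_low, y_low)
            _, rep_h = cross_validated_cc(design_high, y_high)
            ccs.append((rep_l.cc_test + rep_h.cc_test) / 2.0)
        if float(np.mean(ccs)) > target_cc:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def biphasic_wavelet(fs: float, duration_s: float = 1e-3,
                     amplitude_uv: float = 50.0) -> np.ndarray:
    """One-cycle biphasic spike wavelet (Hann-windowed sine), ~1 ms long."""
    n = max(int(round(duration_s * fs)), 4)
    t = np.arange(n) / n
    return amplitude_uv * np.sin(2.0 * np.pi * t) * np.hanning(n)


def simulate_raw_trace(
    rate_series: np.ndarray,
    fs: float,
    spike_waveform: np.ndarray | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    refractory_s: float = 1e-3,
) -> RawTrace:
    """Wideband voltage with Poisson spike wavelets riding on Gaussian noise.

    Spike times follow an inhomogeneous Poisson process with per-sample
    intensity ``rate_series`` (Hz, one entry per output sample) and a fixed
    refractory period; each spike adds a biphasic 1-ms wavelet.
    """
    if fs < 24000.0:
        raise ValueError("raw-trace simulation requires fs >= 24 kHz")
    rate = np.asarray(rate_series, float)
    rng = np.random.default_rng(seed)
    n = len(rate)
    wave = biphasic_wavelet(fs) if spike_waveform is None else spike_waveform
    trace = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    p_spike = np.clip(rate / fs, 0.0, 1.0)
    draws = rng.random(n) < p_spike
    refr = int(round(refractory_s * fs))
    last = -refr - 1
    for i in np.flatnonzero(draws):
        if i - last <= refr:
            continue
        last = i
        end = min(i + len(wave), n)
        trace[i:end] += wave[: end - i]
    return RawTrace(samples=trace, fs=fs)


def make_dipole_csd(
    n_channels: int,
    n_samples: int,
    sink_channel: int,
    source_channel: int,
    amplitude: float = 1.0,
    onset: int = 0,
    width: int | None = None,
) -> np.ndarray:
    """Ground-truth CSD with one sink and one source sharing a time course."""
    width = n_samples - onset if width is None else width
    profile = np.zeros(n_samples)
    profile[onset:onset + width] = np.hanning(width)
    csd = np.zeros((n_channels, n_samples))
    csd[sink_channel] = -amplitude * profile
    csd[source_channel] = amplitude * profile
    return csd


def simulate_laminar_lfp(
    true_csd: np.ndarray,
    fm: ForwardModel,
    noise_sd: float = 0.0,
    seed: int = 0,
    fs: float | None = None,
) -> LaminarLFP:
    """Forward-project a known CSD through P and add measurement noise."""
    true_csd = np.atleast_2d(np.asarray(true_csd, float))
    if true_csd.shape[0] != fm.P.shape[0]:
        raise ValueError("CSD channel count does not match the forward model")
    phi = fm.P @ true_csd
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        phi = phi + rng.normal(0.0, noise_sd, phi.shape)
    return LaminarLFP(phi=phi, depths_um=fm.depths_um, fs=fs)


def simulate_gain_change_table(
    pop: SyntheticPopulationSpec,
    seed: int,
) -> pd.DataFrame:
    """Draw a per-unit gain-change table directly (no model fitting).

    Used for statistical power studies of the laminar ANOVA: each unit's
    gain change is its layer mean plus a penetration offset plus
    within-layer noise.
    """
    rng = np.random.default_rng(seed)
    pen_offsets = rng.normal(0.0, pop.penetration_sd, pop.n_penetrations)
    rows = []
    for layer, n in pop.layer_n.items():
        mean_g = pop.layer_mean_gain_change[layer]
        for _ in range(n):
            pen = int(rng.integers(pop.n_penetrations))
            rows.append({
                "layer": layer,
                "penetration_id": pen,
                "gain_change_pct": float(
                    rng.normal(mean_g + pen_offsets[pen], pop.within_layer_sd)),
            })
    return pd.DataFrame(rows)
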