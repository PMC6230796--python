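# Methods

## Scientific setting

Neurons in sensory cortex adjust the slope (gain) of their input–output
function to the contrast of the stimulus: when contrast doubles, gain drops
by a compensatory amount, keeping the representation roughly contrast
invariant. `contrastgain` implements the complete analysis used to measure
this *contrast gain control* (CGC) in laminar extracellular recordings from
auditory cortex: dynamic random chord (DRC) stimulus construction with
parametric contrast, analog multiunit-activity (MUA) extraction, separable
spectrotemporal receptive field (STRF) estimation, a dual-condition
sigmoidal output nonlinearity that quantifies gain and threshold changes,
inverse current-source-density (iCSD) layer assignment, and the population
and laminar statistics. A synthetic-data module generates every input with
known ground truth, so the whole pipeline is testable as a
parameter-recovery problem.

## Stimuli

A DRC is a sequence of 25-ms chords built from 25 pure tones log-spaced a
quarter octave apart from 1 to 64 kHz (six octaves). Each tone's level is
redrawn each chord from a continuous uniform distribution with mean 80 dB
SPL and a total range of 20 dB (low contrast) or 40 dB (high contrast).
Consecutive chords are joined by 5-ms linear cross-fades, implemented as an
overlapped down/up ramp inside the final 5 ms of each 25-ms slot so a
1,600-chord sequence lasts exactly 40 s. Tone phases are drawn once per
sequence from the seeded generator.

Contrast is summarised as the SD of the level matrix, σ_L (dB), and as the
Weber contrast σ_P/µ_P of the pressure distribution p ∝ 10^(L/20). For a
continuous uniform distribution these have closed forms: σ_L = width/√12
(5.77 dB and 11.55 dB for the two conditions) and Weber contrasts 0.638 and
1.162 — a contrast ratio of 1.82, "approximately a doubling". Contrast is
computed from the level matrix, not the rendered waveform; ramp-dependent
waveform terms are deliberately excluded.

## Preprocessing

Analog MUA: zero-phase 4th-order Butterworth band-pass 300–6,000 Hz,
full-wave rectification, zero-phase low-pass below 6 kHz, polyphase
resampling to 12 kHz. The result is a nonnegative envelope in µV whose mean
over each 25-ms chord window forms the response vector y_t. LFPs are
extracted with a zero-phase 8th-order Chebyshev Type I low-pass below
300 Hz (0.05 dB ripple). All filters are applied forward–backward so a
symmetric pulse stays symmetric and chord binning needs no group-delay
correction; response latency is absorbed by the STRF's history kernel.

## Encoding model

The stimulus is represented as a design tensor X[t, f, h] (level of tone f
at chord t−h) with 16 history steps of 25 ms (400 ms). The linear drive is

    z_t = k0 + Σ_{f,h} X[t,f,h] · k_fh[f,h],     k_fh = k_f ⊗ k_h,

a rank-1 (separable) STRF. Kernels are estimated by alternating least
squares: each kernel in turn by ordinary least squares with the other held
fixed, iterated until the relative change in the sum-of-squares error drops
below 1e−6 (at most 100 alternations; the error is non-increasing by
construction). Design columns are mean-centred before fitting and the
centring folded back into k0. The scale ambiguity of the outer product is
resolved by ‖k_h‖₂ = 1 with the largest-magnitude element of k_h positive,
so k_f carries the units (µV/dB). On tiny noiseless rank-1 problems the ALS
solution coincides with the best rank-1 approximation of the unconstrained
least-squares kernel — an identity the test suite checks exactly.

The first 40 chords (1 s) are excluded from all fitting and evaluation
(adaptation to the initial contrast; this also guarantees complete history
for every fitted row). Units are screened by fitting to the first 90% of
usable chords and computing the Pearson correlation between prediction and
observation on the final 10% (contiguous partitions avoid temporal leakage
through the history window); a unit is *predictive* when that test CC
exceeds 0.04. The threshold can be re-derived empirically from a null
distribution of circularly shifted responses (`null_cc_distribution`).
Note that a fixed 0.04 threshold admits a sizeable false-positive rate for
a 156-chord test partition (null CC SD ≈ 1/√156 ≈ 0.08); the threshold is
kept as the study's convention, and the synthetic acceptance analyses do
not depend on the false-positive rate.

Tuning metrics: best frequency is the grid frequency of the largest
frequency-kernel coefficient; bandwidth is the half-maximum width of k_f
around that peak in octaves (linear interpolation between bins; for a
negative-going main lobe the positive-peak convention is used); integration
time is the 50%-amplitude width of k_h around its peak within the first
100 ms of history.

## Contrast gain model

Responses are modelled as z_t passed through a static sigmoid

    F[z] = a + b / (1 + exp(−(z − c)/d)),

with baseline a, range b, threshold c and inverse slope d; gain is 1/d. The
dual-condition model shares one STRF and (a, b) across contrast conditions
while (c, d) are free per condition. (The alternative reading, sharing b
and c, is inconsistent with reporting distributions of both threshold and
gain changes per condition; a and b are shared here.) The headline quantity
is the gain change 100·((1/d_high) − (1/d_low))/(1/d_low); negative values
mean gain reduction at high contrast. Threshold changes are reported as
percentage changes in c; baseline changes come from per-condition fully
free sigmoid fits, because a is shared in the dual model.

Sigmoid fits minimise the summed squared error with L-BFGS-B (analytic
gradients, b and d bounded positive), initialised at a = min(y),
b = range(y), c = median(z), d = SD(z)/2 plus five seeded jittered
restarts, keeping the best objective.

**Cross-fitted two-stage estimation.** Estimating the STRF and the sigmoid
on the same chords biases the gain change toward zero at low
signal-to-noise: the STRF stage absorbs stimulus-correlated noise, and that
overfitted component of z_t inflates the apparent low-contrast slope more
than the high-contrast slope (the spurious covariance is equal in absolute
terms in both conditions while the true signal covariance is twice as
large at high contrast). The default estimator therefore cross-fits: the
STRF is estimated on alternate chords and the sigmoid stage on the
complementary chords, then the roles are swapped and the two parameter sets
averaged (arithmetic for a, c; geometric for b, d — the reported gain
change is the geometric mean of the per-fold d-ratios). This removes the
attenuation (recovery is unbiased down to test CC ≈ 0.2) and costs nothing
when noise is low; `crossfit=False` restores the naive same-data fit.

Because the estimated drive is an affine rescaling of the true drive,
absolute values of c and d are only defined up to that scale; ratios
(gain changes) and slope-unit threshold shifts (Δc/d) are scale invariant
and are the quantities compared against ground truth.

## CSD analysis and layers

Laminar LFPs (32 contacts, 50 µm spacing) are inverted with the δ-source
iCSD method: current is assumed to arise in thin disks of radius
R = 125 µm centred on each contact plane in a homogeneous medium with
conductivity σ = 0.3 S/m. The forward matrix is

    P[j,i] = (h / 2σ) · (√((z_j − z_i)² + R²) − |z_j − z_i|),

with h the contact spacing (each disk represents a slab of thickness h),
and the CSD estimate is Ĉ = P⁻¹Φ column-by-column. The per-slab
normalisation fixes absolute units only; σ scales the estimate uniformly
across channels, as the round-trip and scaling tests verify. No spatial
smoothing is applied.

The layer 1–2/3 border is the most superficial adjacent channel pair whose
early-window mean CSD changes sign with both magnitudes above a noise floor
(default 2× the pre-stimulus CSD SD); the border is the midpoint of the
pair. Depths below the border map to layers by half-open intervals:
[0, 225) µm → 2/3, [225, 425) → 4, [425, 675) → 5, ≥ 675 → 6; negative
depths are layer 1 and excluded.

## Population statistics

Paired condition comparisons use the two-sided Wilcoxon signed-rank test
(exact null for n ≤ 25 without ties, normal approximation with continuity
correction otherwise). Outliers are |value − mean| > k·SD per parameter:
k = 1.96 for flagging in tuning comparisons (flagged but retained), k = 3
for exclusion before the laminar ANOVA and the gain–threshold Pearson
correlation. The laminar analysis is a two-factor additive fixed-effects
ANOVA (no interaction) with gain change as response and layer and
penetration as factors, Type II sums of squares by default (the design is
unbalanced; the type is configurable). Pairwise layer contrasts use the
Tukey–Kramer correction on the layer groups (unadjusted for the
penetration blocking factor, which is how pairwise layer-mean comparisons
are conventionally reported). A single-penetration table drops the
penetration factor.

## Synthetic data

Synthetic units are linear–nonlinear neurons: a Gaussian frequency bump
(SD 0.5 octave, peak 0.6 µV/dB), an exponentially decaying history kernel
(τ = 40 ms, unit norm), and per-condition sigmoids. The STRF bias centres
the expected drive at zero, and thresholds/inverse slopes are set in units
of the low-contrast drive SD: c = 0.5 σ_z and d_low = 1.0 σ_z by default,
an operating point where responses are threshold-dominated and rarely
saturate — the regime described for real MUA. Baseline a = 40 µV and range
b = 30 µV are typical analog-MUA envelope values; the baseline sits far
enough above zero that the nonnegativity clip on noisy responses is rarely
active. A true gain change of g% is imposed exactly via
d_high = d_low/(1 + g/100). Additive Gaussian noise on the binned response
(default SD 10 µV, giving screening CCs near 0.5) matches the
sum-of-squares objective; where an analysis requires a specific predictive
power, `calibrate_noise_sd_realized` bisects the noise SD until the fitted
model's cross-validated test CC reaches the target (the analytic
perfect-model formula in `calibrate_noise_sd` gives the CC ceiling, which
overstates the realised CC at high noise).

The default population mirrors the laminar study conditions: layer 2/3,
n = 21, mean gain change −41.6%; layer 4, n = 39, −54.2%; layer 5, n = 50,
−60.6%; layer 6, n = 24, −65.1%; within-layer SD 15 points, 17
penetrations with 5-point penetration offsets, gain changes clipped to
[−95, −1]% so both condition gains stay positive. Raw-trace simulation
drives an inhomogeneous Poisson process (1-ms refractory period, so
wavelet overlaps stay rare and the MUA envelope is approximately linear in
rate) inserting 1-ms biphasic spike wavelets into Gaussian noise; laminar
LFPs are forward-projected from a known CSD through P plus noise.

What the generator does *not* emulate: correlated (non-Gaussian,
non-stationary) recording noise, inseparable or multi-peaked STRFs,
adaptation dynamics within a condition, across-unit noise correlations,
and real cortical geometry beyond the layer depth ranges. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated model class, not performance guarantees on arbitrary real
recordings.

## Problem sizes and numerical choices

Tests and the acceptance script run the study-scale stimulus (1,600 chords
× 25 tones × 16 lags) for single-unit analyses, 20 units for the
low-predictive-power recovery study, the full 134-unit population for the
end-to-end run, and 50 replicates for the laminar power study — sizes
chosen so the whole suite completes in a few minutes on one CPU while
keeping every statistic at the scale the analysis was designed for. ALS
convergence tolerance is 1e−6 relative change in E; sigmoid fits use five
restarts; the iCSD forward matrix is solved directly (condition number is
checked, and a singular matrix is an error). Degenerate inputs — constant
responses, constant drive, all-zero kernels, all-zero paired differences —
are either flagged (b collapsing to its bound warns; an undefined test CC
marks the unit non-predictive) or raise informative errors.

## Known limitations

- Absolute CSD units depend on the per-slab normalisation convention and
  are unvalidated; only spatial pattern and relative scaling are used.
- Absolute sigmoid thresholds are defined up to the affine scale of the
  estimated drive; only scale-invariant summaries should be compared
  across fits.
- The 0.04 screening threshold is kept as a convention; its false-positive
  rate depends on test-partition length.
- Per-unit gain-change estimates at test CC ≈ 0.2 have an SD of roughly
  15–20 percentage points; only medians over ≥ 20 units are meaningful at
  that noise level.
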