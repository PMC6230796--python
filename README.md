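# contrastgain

Analysis pipeline for **contrast gain control (CGC)** in laminar
auditory-cortex recordings. When the contrast of a sound rises, cortical
neurons reduce the gain of their input–output function by a compensatory
amount; this package measures that adjustment from multiunit responses to
dynamic random chord (DRC) stimuli, and localises it across cortical
layers. It is written for systems/computational neuroscientists who want a
tested, reproducible implementation of the full chain — from stimulus
synthesis to laminar statistics — together with a synthetic-data module
that makes every stage verifiable by parameter recovery.

## The model

Responses y_t (analog multiunit activity, µV, binned at the 25-ms chord
rate) are described by a linear–nonlinear model. A separable
spectrotemporal receptive field (STRF) filters the stimulus tensor
X[t, f, h] (tone level at frequency f, h chords in the past, 16 × 25 ms of
history):

    z_t = k0 + Σ_{f,h} X[t,f,h] · (k_f ⊗ k_h)[f,h]

and a static sigmoid maps the drive to the response:

    ŷ_t = F[z_t] = a + b / (1 + exp(−(z_t − c)/d))

with baseline a, range b, threshold c and inverse slope d (gain ≡ 1/d).
Contrast gain control is quantified with a dual-condition fit: one STRF and
one (a, b) shared across the low- and high-contrast conditions, with
(c, d) free per condition. The headline statistic is the percentage gain
change 100·((1/d_high) − (1/d_low))/(1/d_low) — negative when gain drops at
high contrast. Layers are assigned by δ-source inverse current source
density (Ĉ = P⁻¹Φ) from the polarity reversal at the layer 1–2/3 border,
and the laminar profile of gain control is tested with a two-factor
ANOVA (layer × penetration) with Tukey–Kramer pairwise contrasts.

See `docs/methods.md` for the full account of the estimators, including
why the dual-condition model is cross-fitted by default.

## Worked example

Simulate a small population of synthetic units whose true gain changes are
known, run the full pipeline, and summarise:

```python
from contrastgain import RunConfig, run_all

bundle = run_all(RunConfig(seed=4, n_units=6, out_dir="results/demo"))
print(bundle["report"])
```

which prints (numbers from this exact seed):

```
Units: 6
Median gain change: -56.2% (100.0% of units reduced gain)
Median threshold change: -0.52%
Signed-rank gain low vs high: W=0.0, p=0.0312
Gain-threshold correlation: R=0.03, p=0.95
Laminar ANOVA skipped (insufficient data)
```

Every one of the six units was recovered with reduced gain at high
contrast; the median recovered gain change of −56% sits close to the
simulated population median, and the signed-rank test confirms the paired
low-versus-high gain reduction. `results/demo/units.csv` holds the
per-unit table (screening CCs, fitted gains, percentage changes, tuning
metrics, depth/layer/penetration and the ground-truth gain change) and
`manifest.json` the config hash and seeds for reproduction. The laminar
ANOVA needs more than a handful of units per layer; drop `n_units` (or
raise it) to analyse the full default population of 134 units.

The same stages are scriptable from the shell:

```bash
contrastgain stimgen --range-db 40 --n-chords 1600 --seed 3 --out drc.h5
contrastgain run-all --n-units 20 --seed 1 --out results/run1
contrastgain csd-layers --in laminar.h5 --out layers.csv
```

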