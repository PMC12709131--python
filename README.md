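# soxdosim

Singlet-oxygen dosimetry for Type II photodynamic therapy (PDT), built
around liquid-phantom experiments with a benzoporphyrin-derivative (BPD)
photosensitizer excited at 690 nm.

PDT kills tissue through singlet oxygen (¹O₂). Two routes exist to
quantify the delivered ¹O₂ dose:

* **direct luminescence dosimetry** — the weak ¹O₂ emission band at
  ~1270 nm is isolated from the measured near-infrared spectrum
  (1200–1600 nm) by linear unmixing against three fixed basis shapes
  (¹O₂ band, photosensitizer phosphorescence, laser background);
* **explicit (model-based) dosimetry** — a macroscopic kinetic model
  computes the reacted singlet oxygen [¹O₂]rx from the fluence rate ϕ,
  the photosensitizer concentration [S0] and the oxygen concentration
  [³O₂].

This package implements both tracks end to end and quantifies their
linear relationship, exercising everything on synthetic phantom data with
recorded ground truth. It also ships the measured correction-factor grid
for tissue optical properties (μa, μs′) with bilinear interpolation, and a
simplified two-stage Monte Carlo photon-transport model that regenerates
the signal-vs-optical-property trends from first principles.

## The kinetic model

With the oxygen saturation factor f = [³O₂]/([³O₂]+β) and the bleaching
factor g = σ([S0]+δ),

```
[¹O₂]       =  ξ τΔ f ϕ [S0] / (g + 1)          instantaneous, μM
d[S0]/dt    = −ξ f ϕ [S0] · g / (g + 1)          photobleaching
d[³O₂]/dt   = −ξ f ϕ [S0] · (g + k7[A]τΔ) / (g + 1)
d[¹O₂]rx/dt =  ξ f ϕ [S0] / (g + 1)              dose accumulation
```

In-vitro BPD defaults: ξ = 51×10⁻³ cm² mW⁻¹ s⁻¹, β = 11.9 μM, δ = 33 μM,
σ = 1.7×10⁻⁵ μM⁻¹, τΔ = 9.4 μs, [A] = 0. Oxygen can be clamped (shallow
phantom, fast atmospheric re-oxygenation; the default) or integrated.

## Worked example

```python
from soxdosim import ExperimentConfig, NoiseConfig, run_experiment

config = ExperimentConfig(                       # five phantoms, 2-6 mg/L
    noise=NoiseConfig(model="gaussian_scaled", sigma=0.02),
    seed=7,
)
report = run_experiment(config)
print(report.cumulative_fit.summary())
```

prints

```
OLS fit (n=50)
  slope:     497.654 +/- 3.19
  intercept: 0.734085 +/- 0.403
  R^2:       0.998033
```

Each phantom contributes ten acquisitions (every 100 s over a 900 s,
850 mW/cm² irradiation = 765 J/cm²). The slope is the recovered detection
scale in counts per μM·s of cumulative model dose — the generator injected
κ_detect = 500, so the pipeline recovered it to 0.5% through 2% spectral
noise; the intercept is consistent with zero and R² ≈ 1 reflects the
linear tracking between the two dose metrics.

Correction factors and the transport model:

```python
from soxdosim import OpticalProperties, cf_lookup, load_cf_table, mc_detected_signal

table = load_cf_table()
float(cf_lookup(table, OpticalProperties(mua=0.3, musp=10)))   # 1.00 (reference)
float(cf_lookup(table, OpticalProperties(mua=1.0, musp=5)))    # 1.89
signal, se = mc_detected_signal(OpticalProperties(0.3, 10), n_photons=100_000, seed=1)
```

A command-line interface mirrors the library:

```
soxdosim run --outdir out --seed 1        # full experiment + manifest
soxdosim cf --mua 0.5 --musp 15           # correction-factor lookup
soxdosim soed --bpd-mg-per-l 6 --out traj.csv
```

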