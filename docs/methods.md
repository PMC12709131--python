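# Methods

This note records the models implemented by `soxdosim`, the defaults and
their rationale, the numerical choices, and what the synthetic-data tests
do and do not demonstrate about real measurements.

## Kinetic dose model

The explicit-dosimetry model treats Type II PDT in a well-stirred medium
as three coupled ODEs for the ground-state photosensitizer [S0] (μM), the
ground-state oxygen [³O₂] (μM) and the cumulative reacted singlet oxygen
[¹O₂]rx (μM). Writing f = [³O₂]/([³O₂]+β) and g = σ([S0]+δ):

* instantaneous [¹O₂] = ξ τΔ f ϕ [S0]/(g+1);
* d[S0]/dt = −ξ f ϕ [S0]·g/(g+1);
* d[³O₂]/dt = −ξ f ϕ [S0]·(g + k7[A]τΔ)/(g+1);
* d[¹O₂]rx/dt = ξ f ϕ [S0]/(g+1).

Parameters (in-vitro BPD defaults): ξ = 51×10⁻³ cm² mW⁻¹ s⁻¹ (specific
oxygen consumption rate), β = 11.9 μM (oxygen quenching threshold),
δ = 33 μM (low-concentration correction), σ = 1.7×10⁻⁵ μM⁻¹ (specific
photobleaching ratio), τΔ = 9.4×10⁻⁶ s (¹O₂ lifetime), k7 = 0 μM⁻¹ s⁻¹
and [A] = 0 μM (no external acceptors in plain methanol). The fluence
rate ϕ defaults to 850 mW/cm² over 900 s (765 J/cm² total).

Design points:

* **Oxygen modes.** The phantom surface re-oxygenates from air faster
  than PDT consumes oxygen, so the default clamps [³O₂] at its initial
  value (194 μM, from an oxygen-probe reading via 1.295 μM/mmHg). An
  `evolving` mode integrates the oxygen equation as written; note that at
  [A] = 0 that equation coincides with the photobleaching equation, so
  [³O₂] − [S0] is a constant of motion. Both modes are tested.
* **As-printed kinetics.** With these defaults at 850 mW/cm², bleaching
  has an e-folding time of ~44 s at 2–6 mg/L loadings, i.e. the drug is
  essentially consumed within the first quarter of the irradiation. The
  equations and constants are implemented exactly as stated; ξ and σ are
  configurable for studies of slower-bleaching regimes. A consequence is
  that late-time (≥450 s) signals in the synthetic experiment are
  noise-dominated, and cross-phantom regressions evaluated there carry
  very large standard errors.
* **Drug units.** Phantom recipes are in mg/L; the kinetics are molar.
  Conversion uses a configurable molar mass (default 718.8 g/mol for
  BPD/verteporfin). Relative-concentration outputs do not depend on it.
* **Integrator.** `scipy.integrate.solve_ivp` (RK45), rtol 1e-8, atol
  1e-12 μM, integrated piecewise across beam-on/beam-off segments so
  pauses are exact discontinuities of ϕ. States are clipped to zero only
  within absolute tolerance; larger negativity raises an error. The
  integrator is verified against an independent fixed-step Euler oracle
  (dt = 1e-4 s) on a 10 s horizon to 1e-4 relative in every component.

## Spectral unmixing

A measured NIR spectrum is modelled as y = Σᵢ aᵢBᵢ + ε over a common
wavelength grid, with three basis components: the ¹O₂ band, the broad
photosensitizer phosphorescence, and the laser background. Amplitudes are
ordinary least squares computed via the singular-value pseudoinverse with
a relative singular-value cutoff of 1e-12; a basis whose condition number
exceeds 1e10 is rejected as collinear. Non-negativity is optional (off by
default) and uses an active-set solver; negative amplitudes are a useful
model-mismatch diagnostic and are never silently clipped. Amplitude
standard errors are residual-based (homoscedastic), zero for consistent
systems.

The five-point smoother is a centred moving average whose window shrinks
symmetrically at the edges (3 points at the second/penultimate sample,
the raw value at the ends); this keeps boundary samples unbiased for
locally constant spectra and makes the smoother's action exactly
testable.

The quench-difference path (spectrum before minus after chemical
quenching of ¹O₂ with sodium azide) isolates the 1270 nm band without any
fitting and cross-checks the unmixed amplitude.

The visible-window (600–800 nm) fluorescence fit adds the first N
cosine/sine pairs over the window (default one pair) to the
{photosensitizer, background} basis to absorb slowly varying residual
structure; the photosensitizer amplitude divided by its pre-irradiation
value tracks relative [S0] during photobleaching, and the bleaching trend
is summarised by an OLS line, which is adequate over 900 s at these
loadings.

## Synthetic data

The generator emulates the spectrometer output of the phantom bench:

* basis shapes — Gaussian ¹O₂ band (centre 1270 nm, FWHM 20 nm),
  exponential phosphorescence (decay length 250 nm) spanning the
  1200–1600 nm window, sharp exponential background (decay 40 nm) at the
  short-wavelength edge; 256-point grid; all peak-normalised. The true
  band shapes are not parameterised in the source measurements, so all
  shapes are configuration, and the laser-background tail in particular
  is a synthetic stand-in.
* amplitudes — a_o2(t) = κ_detect·[¹O₂](t), a_phos(t) = κ_phos·ϕ·[S0](t),
  a_bg constant. κ_detect (default 500 counts/μM) and κ_phos (default
  2×10⁻⁴ counts per mW cm⁻² μM) are explicit free constants standing for
  everything that makes absolute detected signals setup-dependent
  (detector sensitivity, fiber geometry, coupling). The defaults put the
  ¹O₂ and phosphorescence amplitudes on the same order, as in measured
  mixture spectra, and κ_detect at the order of magnitude of reported
  luminescence-vs-model slopes.
* noise — additive Gaussian, either constant sigma or sigma expressed as
  a fraction of the series' peak intensity ("2% of peak"); a Poisson
  option exists. One seeded generator per simulation call; the seed is
  recorded in all outputs. No detector response curve, wavelength
  calibration error, or solvent evaporation is modelled — passing tests
  demonstrate correctness of the analysis chain under the stated mixture
  model, not robustness to those instrumental effects.

## Correlating the two dose metrics

Per phantom, the instantaneous luminescence amplitude and the
instantaneous model dose are paired on the acquisition grid (every 100 s
by default). Cumulative quantities on *both* sides are cumulative
trapezoid sums of those sampled instantaneous values. Using the
integrator's exact [¹O₂]rx on one side only would compare two different
quadratures of the same fast-decaying signal (they differ by ~40% at a
100 s cadence under the default kinetics) and would break the exact
proportionality that holds between identically sampled tracks; the exact
integral remains available from the trajectory.

"Instantaneous at time t" means the nearest acquisition within half a
cadence step, ties resolved to the earlier acquisition (so t = 450 s maps
to the 400 s acquisition on the default grid). Regressions are unweighted
OLS with intercept (statsmodels); intercepts are estimated, not forced,
because measured comparisons show small non-zero offsets.

## Optical-property correction

The packaged correction-factor table covers μa ∈ {0.1, 0.3, 0.5, 0.7,
1.0} cm⁻¹ × μs′ ∈ {5, 10, 15, 20, 40} cm⁻¹ at 690 nm, normalised to
CF = 1.00 at the reference point (μa = 0.3, μs′ = 10) typical of pleural
tissue. Lookup is exact at nodes, bilinear between nodes, and clamps to
the nearest edge outside the measured hull with a warning flag —
extrapolated CFs are unvalidated. On load the table asserts its
structure: CF strictly increasing in μa at every μs′, and non-increasing
in μs′ over the 5–20 cm⁻¹ range at every μa. The 40 cm⁻¹ row is excluded
from the monotonicity assertion because its printed values sit within
measurement noise of the 20 cm⁻¹ row (at μa = 0.7 they cross by 0.02).

### Monte Carlo transport model

A deliberately simplified two-stage estimator for the detected
luminescence in a semi-infinite homogeneous medium, using the similarity
relation (isotropic scattering with interaction coefficient μa + μs′):

1. *Excitation (690 nm).* Packets launch normally, uniform over the 1 cm²
   beam; each interaction deposits the fraction μa/(μa+μs′) of the packet
   weight into a cylindrical voxel grid (dr = dz = 0.05 cm, r ≤ 2 cm,
   z ≤ 3 cm); survival roulette below weight 1e-4 (survival probability
   0.1). Deposited weight is μa × fluence × volume, so the luminescence
   source strength carries a factor (total deposit)/μa.
2. *Emission (1270 nm).* Sites are sampled proportional to deposited
   weight, emission is isotropic, transport uses the emission-wavelength
   optical pair (defaulting to the excitation pair, since emission-side
   phantom properties are rarely characterised; configurable because
   water absorption at 1270 nm differs materially). Packets crossing the
   top surface inside the fiber core radius (0.075 cm) with polar angle
   within asin(NA/n) — NA = 0.39, n = 1.33 — are scored with their
   weight. The boundary is otherwise matched (no Fresnel reflection).

The reported signal is (total deposit)/(μa·N) × (scored weight)/(M) with
M = 4N emission packets by default: nearly all estimator variance sits in
the rare detections of stage 2, so oversampling the emission stage from
the already-converged deposit map shrinks the error at modest cost. The
quoted standard error is the binomial error of the stage-2 detection
probability propagated to the signal scale; replicate experiments show it
is slightly conservative.

The model's purpose is trend and sign-structure reproduction, not
reproducing the packaged table numerically: it has no anisotropic phase
function, no refractive-index mismatch, no layered structure. It
reproduces the strong decrease of detected signal with μa and the
increase with μs′ from 5 to 20 cm⁻¹. The μs′ effect it predicts at high
absorption (μa ≥ 0.7) is only 1–5%, much weaker than the ~60% in the
measured table; resolving that difference at 3σ would take ~5×10⁷
packets per cell, so statistical tests of the μs′ trend are performed at
the reference absorption column, with "no significant violation" checks
elsewhere.

## Problem sizes

The shipped tests and the acceptance script run five phantoms × ten
acquisitions × 256 wavelengths for the pipeline experiments, 10⁵ packets
per Monte Carlo point for trend grids and 2×10⁶ for the μs′-contrast
pair, and 10 s horizons for integrator-oracle comparisons — sizes chosen
so the full suite completes in a few minutes on one core while every
assertion retains comfortable statistical power. The transport kernels
are numba-compiled per-packet loops, which is what makes multi-million
packet budgets affordable.

## Known limitations

* Absolute signal scales are arbitrary by construction (κ_detect,
  κ_phos); only relative and ratio quantities are meaningful.
* The kinetic parameter set implies much faster photobleaching than
  bench bleaching curves show; the package implements the stated
  constants and exposes them as configuration rather than guessing
  corrected units.
* The transport model's CF magnitudes overshoot the measured table at
  high μa (it is a similarity-relation model with matched boundaries);
  the packaged table is the authoritative source for corrections.
* No instrument-response, wavelength-calibration or evaporation effects
  in the generator; conclusions about real data require the measured
  basis spectra and calibration the bench provides.
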