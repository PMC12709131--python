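"""Synthetic spectrometer output for phantom PDT experiments.

Generates the two data streams the analysis consumes, with full ground
truth recorded:

* near-infrared (1200–1600 nm) luminescence time series — linear mixtures
  of three basis shapes (¹O₂ band at 1270 nm, broad photosensitizer
  phosphorescence, laser background at the short-wavelength edge) whose
  amplitudes follow the explicit-dosimetry kinetics, plus detector noise;
* visible-window (~600–800 nm) fluorescence series used to track
  photobleaching of the ground-state photosensitizer.

The generator's amplitudes follow the minimal physical model: the ¹O₂
amplitude is κ_detect·[¹O₂](t) (κ_detect, counts/μM, absorbs detector
sensitivity, fiber geometry and coupling — everything that makes absolute
signals setup-dependent); the phosphorescence amplitude is
κ_phos·ϕ(t)·[S0](t) (excitation rate times ground-state population); the
laser background is constant.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .soed import (
    IrradiationProtocol,
    PhantomSpec,
    SOEDModel,
    SOEDParameters,
    instantaneous_singlet_oxygen,
)
from .spectra import Spectrum, WavelengthGrid, write_series
from .unmixing import BasisMatrix

__all__ = [
    "BasisShapeConfig",
    "FluorescenceShapeConfig",
    "NoiseConfig",
    "GroundTruth",
    "make_basis",
    "make_fluorescence_basis",
    "simulate_series",
    "simulate_fluorescence_series",
    "simulate_quench_pair",
    "DEFAULT_KAPPA_DETECT",
    "DEFAULT_KAPPA_PHOS",
    "DEFAULT_BACKGROUND_AMPLITUDE",
]

#: Default detection scale, counts per μM of instantaneous [¹O₂]. Chosen at
#: the order of magnitude of the reported MSOLD-vs-SOED slopes so synthetic
#: amplitudes land in a realistic count range; arbitrary otherwise.
DEFAULT_KAPPA_DETECT = 500.0

#: Default phosphorescence scale, counts per (mW/cm² · μM); puts the
#: phosphorescence amplitude on par with the ¹O₂ amplitude as in measured
#: mixture spectra.
DEFAULT_KAPPA_PHOS = 2.0e-4

#: Default constant laser-background amplitude, counts.
DEFAULT_BACKGROUND_AMPLITUDE = 0.5


def _gaussian(wl: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    return np.exp(-4.0 * np.log(2.0) * ((wl - center) / fwhm) ** 2)


@dataclass(frozen=True)
class BasisShapeConfig:
    """Shapes of the three NIR basis components on a common grid.

    The ¹O₂ band is a Gaussian (center/FWHM); phosphorescence is a broad
    exponential decay spanning the window; the laser background is a sharp
    exponential concentrated at the short-wavelength edge. The measured
    band shapes are not parameterised in the source data, so all shapes
    are configurable; each component is peak-normalised to 1.
    """

    o2_center_nm: float = 1270.0
    o2_fwhm_nm: float = 20.0
    phos_decay_nm: float = 250.0
    bg_decay_nm: float = 40.0
    grid: WavelengthGrid = field(default_factory=lambda: WavelengthGrid(1200.0, 1600.0, 256))

    def __post_init__(self) -> None:
        if not (self.grid.start_nm <= self.o2_center_nm <= self.grid.stop_nm):
            raise ValueError("o2_center_nm must lie inside the grid")
        for name in ("o2_fwhm_nm", "phos_decay_nm", "bg_decay_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class FluorescenceShapeConfig:
    """Shapes for the visible-window fluorescence basis (photobleach probe)."""

    ps_center_nm: float = 690.0
    ps_fwhm_nm: float = 30.0
    bg_decay_nm: float = 150.0
    grid: WavelengthGrid = field(default_factory=lambda: WavelengthGrid(600.0, 800.0, 128))


@dataclass(frozen=True)
class NoiseConfig:
    """Detector-noise model for synthetic spectra.

    ``gaussian_constant``: additive N(0, sigma²) per sample, sigma in counts.
    ``gaussian_scaled``: additive Gaussian with sigma = ``sigma`` × the peak
    noiseless intensity of the series (so ``sigma=0.02`` is "2% of peak").
    ``poisson``: counts drawn as ``gain``·Poisson(y/``gain``).
    """

    model: str = "gaussian_constant"
    sigma: float = 0.0
    gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("gaussian_constant", "gaussian_scaled", "poisson"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.model == "gaussian_constant":
            return clean + rng.normal(0.0, self.sigma, clean.shape) if self.sigma else clean.copy()
        if self.model == "gaussian_scaled":
            scale = self.sigma * float(np.max(np.abs(clean))) if clean.size else 0.0
            return clean + rng.normal(0.0, scale, clean.shape) if scale else clean.copy()
        return self.gain * rng.poisson(np.maximum(clean, 0.0) / self.gain)


@dataclass(frozen=True)
class GroundTruth:
    """True mixture amplitudes and kinetic trajectory behind a synthetic series."""

    t_s: np.ndarray
    a_o2: np.ndarray
    a_phos: np.ndarray
    a_bg: np.ndarray
    trajectory: pd.DataFrame
    kappa_detect: float
    kappa_phos: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        traj = self.trajectory.drop_duplicates("t_s")
        interp = lambda col: np.interp(self.t_s, traj["t_s"], traj[col])
        return pd.DataFrame(
            {
                "t_s": self.t_s,
                "a_o2": self.a_o2,
                "a_phos": self.a_phos,
                "a_bg": self.a_bg,
                "S0_uM": interp("S0_uM"),
                "O2_uM": interp("O2_uM"),
                "O2rx_uM": interp("O2rx_uM"),
            }
        )

    def write(self, csv_path, json_path=None, config: dict | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False, float_format="%.12g")
        if json_path is not None:
            sidecar = {"seed": self.seed, "kappa_detect": self.kappa_detect,
                       "kappa_phos": self.kappa_phos}
            if config:
                sidecar["config"] = config
            with open(json_path, "w") as fh:
                json.dump(sidecar, fh, indent=2, default=str)


def make_basis(config: BasisShapeConfig | None = None) -> BasisMatrix:
    """Three unit-peak NIR basis components: ``o2``, ``phosphorescence``, ``background``."""
    cfg = config or BasisShapeConfig()
    wl = cfg.grid.wavelengths
    o2 = _gaussian(wl, cfg.o2_center_nm, cfg.o2_fwhm_nm)
    phos = np.exp(-(wl - wl[0]) / cfg.phos_decay_nm)
    bg = np.exp(-(wl - wl[0]) / cfg.bg_decay_nm)
    cols = np.column_stack([c / c.max() for c in (o2, phos, bg)])
    return BasisMatrix(("o2", "phosphorescence", "background"), wl, cols)


def make_fluorescence_basis(
    config: FluorescenceShapeConfig | None = None,
) -> tuple[Spectrum, Spectrum]:
    """(photosensitizer fluorescence, background) shapes in the visible window."""
    cfg = config or FluorescenceShapeConfig()
    wl = cfg.grid.wavelengths
    ps = _gaussian(wl, cfg.ps_center_nm, cfg.ps_fwhm_nm)
    bg = np.exp(-(wl - wl[0]) / cfg.bg_decay_nm)
    return Spectrum(wl, ps / ps.max()), Spectrum(wl, bg / bg.max())


def _true_amplitudes(
    phantom: PhantomSpec,
    protocol: IrradiationProtocol,
    params: SOEDParameters,
    kappa_detect: float,
    kappa_phos: float,
    background_amplitude: float,
):
    """Kinetics-driven mixture amplitudes at the acquisition times."""
    t_acq = protocol.acquisition_times()
    traj = SOEDModel(phantom, protocol, params).simulate(
        dt_out=protocol.acquisition_period_s
    )
    df = traj.to_frame().drop_duplicates("t_s").reset_index(drop=True)
    inst = np.interp(t_acq, df["t_s"], df["inst_1O2_uM"])
    S0 = np.interp(t_acq, df["t_s"], df["S0_uM"])
    # NIR acquisitions run with the treatment beam on
    a_o2 = kappa_detect * inst
    a_phos = kappa_phos * protocol.phi * S0
    a_bg = np.full_like(a_o2, background_amplitude)
    return t_acq, a_o2, a_phos, a_bg, df


def simulate_series(
    phantom: PhantomSpec,
    protocol: IrradiationProtocol,
    params: SOEDParameters | None = None,
    basis: BasisMatrix | None = None,
    noise: NoiseConfig | None = None,
    kappa_detect: float = DEFAULT_KAPPA_DETECT,
    kappa_phos: float = DEFAULT_KAPPA_PHOS,
    background_amplitude: float = DEFAULT_BACKGROUND_AMPLITUDE,
) -> tuple[list, GroundTruth]:
    """Simulate a noisy NIR luminescence time series for one phantom.

    Returns the list of acquired spectra (one per acquisition time) and the
    :class:`GroundTruth` with true amplitudes and the kinetic trajectory.
    A fixed seed in ``noise`` makes the output bit-reproducible.
    """
    params = params or SOEDParameters()
    basis = basis or make_basis()
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(noise.seed)
    t_acq, a_o2, a_phos, a_bg, traj = _true_amplitudes(
        phantom, protocol, params, kappa_detect, kappa_phos, background_amplitude
    )
    amps = np.column_stack([a_o2, a_phos, a_bg])  # (n_times, 3)
    clean = amps @ basis.matrix.T  # (n_times, n_wl)
    noisy = noise.apply(clean, rng)
    series = [
        Spectrum(
            basis.wavelengths,
            noisy[i],
            exposure_s=protocol.acquisition_exposure_s,
            t_acq_s=float(t),
        )
        for i, t in enumerate(t_acq)
    ]
    gt = GroundTruth(
        t_s=t_acq, a_o2=a_o2, a_phos=a_phos, a_bg=a_bg,
        trajectory=traj, kappa_detect=kappa_detect, kappa_phos=kappa_phos,
        seed=noise.seed,
    )
    return series, gt


def simulate_fluorescence_series(
    phantom: PhantomSpec,
    protocol: IrradiationProtocol,
    params: SOEDParameters | None = None,
    shapes: FluorescenceShapeConfig | None = None,
    noise: NoiseConfig | None = None,
    fluor_scale: float = 100.0,
    background_amplitude: float = 5.0,
) -> tuple[list, pd.DataFrame]:
    """Simulate the visible-window fluorescence series tracking photobleaching.

    Fluorescence is excited by a separate blue source with the treatment
    beam paused, so its amplitude is proportional to [S0](t) alone:
    ``fluor_scale`` counts per unit of relative concentration
    [S0](t)/[S0](0). Returns (spectra, truth frame with ``t_s``,
    ``rel_S0``, ``a_ps``).
    """
    params = params or SOEDParameters()
    shapes = shapes or FluorescenceShapeConfig()
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(noise.seed + 1)
    ps, bg = make_fluorescence_basis(shapes)
    t_acq = protocol.acquisition_times()
    traj = SOEDModel(phantom, protocol, params).simulate(
        dt_out=protocol.acquisition_period_s
    )
    df = traj.to_frame().drop_duplicates("t_s")
    S0 = np.interp(t_acq, df["t_s"], df["S0_uM"])
    rel = S0 / S0[0] if S0[0] > 0 else np.zeros_like(S0)
    a_ps = fluor_scale * rel
    clean = np.outer(a_ps, ps.intensities) + background_amplitude * bg.intensities
    noisy = noise.apply(clean, rng)
    series = [
        Spectrum(ps.wavelengths, noisy[i], t_acq_s=float(t))
        for i, t in enumerate(t_acq)
    ]
    truth = pd.DataFrame({"t_s": t_acq, "rel_S0": rel, "a_ps": a_ps})
    return series, truth


def simulate_quench_pair(
    phantom: PhantomSpec,
    protocol: IrradiationProtocol,
    params: SOEDParameters | None = None,
    basis: BasisMatrix | None = None,
    noise: NoiseConfig | None = None,
    kappa_detect: float = DEFAULT_KAPPA_DETECT,
    kappa_phos: float = DEFAULT_KAPPA_PHOS,
    background_amplitude: float = DEFAULT_BACKGROUND_AMPLITUDE,
    residual_fraction: float = 0.05,
) -> tuple[Spectrum, Spectrum]:
    """(pre-quench, post-quench) spectra at t=0 for an azide-quench experiment.

    Chemical quenching suppresses the ¹O₂ amplitude to ``residual_fraction``
    of its value (imperfect quenching leaves a small residue); the
    phosphorescence and background are untouched, so the pre−post
    difference isolates (1−r)·a_o2·B_o2.
    """
    if not 0.0 <= residual_fraction < 1.0:
        raise ValueError("residual_fraction must be in [0, 1)")
    params = params or SOEDParameters()
    basis = basis or make_basis()
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(noise.seed)
    t_acq, a_o2, a_phos, a_bg, _ = _true_amplitudes(
        phantom, protocol, params, kappa_detect, kappa_phos, background_amplitude
    )
    pre_amp = np.array([a_o2[0], a_phos[0], a_bg[0]])
    post_amp = np.array([residual_fraction * a_o2[0], a_phos[0], a_bg[0]])
    clean = np.vstack([pre_amp, post_amp]) @ basis.matrix.T
    noisy = noise.apply(clean, rng)
    mk = lambda row: Spectrum(basis.wavelengths, row, t_acq_s=0.0)
    return mk(noisy[0]), mk(noisy[1])
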