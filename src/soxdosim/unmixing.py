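"""Spectral unmixing of singlet-oxygen luminescence by SVD least squares.

A measured near-infrared spectrum (1200–1600 nm) is modelled as a linear
mixture of three fixed basis shapes: the ¹O₂ emission band at ~1270 nm,
the broad photosensitizer phosphorescence, and the residual laser
background. The component amplitudes are the least-squares solution,
computed through the singular-value pseudoinverse (relative cutoff 1e-12).
An optional non-negativity constraint uses an active-set solver; it is off
by default — negative amplitudes indicate model mismatch and are reported,
not clipped.

The quench-difference extraction (spectrum before minus after chemical
quenching with sodium azide) isolates the ¹O₂ band without any fitting and
serves as the model-free cross-check on the unmixed ¹O₂ amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .spectra import GridMismatchError, Spectrum, smooth_five_point

__all__ = [
    "BasisMatrix",
    "CollinearityError",
    "UnmixModel",
    "UnmixResults",
    "svd_unmix",
    "quench_difference",
    "unmix_series",
    "fluorescence_unmix",
    "fourier_columns",
]

#: Relative singular-value cutoff for the pseudoinverse solve.
SV_CUTOFF = 1e-12

#: Relative condition-number threshold above which a basis is treated as
#: rank-deficient (two components effectively proportional).
COLLINEAR_COND = 1e10


class CollinearityError(ValueError):
    """Raised when basis components are (numerically) linearly dependent."""


@dataclass(frozen=True)
class BasisMatrix:
    """Named component spectra on a common wavelength grid.

    ``matrix`` is (n_wavelengths, n_components); every column is one
    component shape. Construction asserts a shared grid and full numerical
    rank.
    """

    names: tuple
    wavelengths: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != wl.size:
            raise ValueError("matrix must be (n_wavelengths, n_components)")
        if len(self.names) != m.shape[1]:
            raise ValueError("one name per component required")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "matrix", m)
        sv = np.linalg.svd(m, compute_uv=False)
        if sv[-1] <= 0 or sv[0] / sv[-1] > COLLINEAR_COND:
            raise CollinearityError(
                f"basis is rank-deficient (condition number {sv[0] / max(sv[-1], 1e-300):.3g})"
            )

    @classmethod
    def from_spectra(cls, named_spectra: dict) -> "BasisMatrix":
        names = tuple(named_spectra)
        specs = list(named_spectra.values())
        wl = specs[0].wavelengths
        for s in specs[1:]:
            if not specs[0].same_grid(s):
                raise GridMismatchError("basis spectra must share one grid")
        return cls(names, wl, np.column_stack([s.intensities for s in specs]))

    @property
    def n_components(self) -> int:
        return self.matrix.shape[1]

    @property
    def condition_number(self) -> float:
        sv = np.linalg.svd(self.matrix, compute_uv=False)
        return float(sv[0] / sv[-1])

    def component(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=list(self.names))
        df.insert(0, "wavelength_nm", self.wavelengths)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BasisMatrix":
        names = tuple(c for c in df.columns if c != "wavelength_nm")
        return cls(names, df["wavelength_nm"].to_numpy(float), df[list(names)].to_numpy(float))


class UnmixModel:
    """Linear mixture model of one spectrum over a fixed basis.

    statsmodels-style: the model binds data (the spectrum) to the design
    (the basis); :meth:`fit` returns :class:`UnmixResults` with amplitude
    estimates, their standard errors, and fit diagnostics.
    """

    def __init__(self, spectrum: Spectrum, basis: BasisMatrix):
        if spectrum.wavelengths.size != basis.wavelengths.size or not np.allclose(
            spectrum.wavelengths, basis.wavelengths, atol=1e-9
        ):
            raise GridMismatchError("spectrum and basis are on different grids")
        self.spectrum = spectrum
        self.basis = basis

    def fit(self, nonneg: bool = False) -> "UnmixResults":
        y = self.spectrum.intensities
        B = self.basis.matrix
        U, sv, Vt = np.linalg.svd(B, full_matrices=False)
        keep = sv > SV_CUTOFF * sv[0]
        if not np.all(keep):  # pragma: no cover - guarded at construction
            raise CollinearityError("basis is rank-deficient")
        amps = Vt.T @ ((U.T @ y) / sv)
        if nonneg and np.any(amps < 0):
            amps, _ = nnls(B, y)
        resid = y - B @ amps
        rms = float(np.sqrt(np.mean(resid**2)))
        n, k = B.shape
        dof = max(n - k, 1)
        s2 = float(resid @ resid) / dof
        # Var(a) = s² (BᵀB)⁻¹ = s² V S⁻² Vᵀ
        cov = (Vt.T / sv**2) @ Vt * s2
        return UnmixResults(
            model=self,
            amplitudes=amps,
            bse=np.sqrt(np.diag(cov)),
            residual_rms=rms,
            condition_number=float(sv[0] / sv[-1]),
            nonneg=nonneg,
            df_resid=dof,
        )


@dataclass(frozen=True)
class UnmixResults:
    """Amplitudes (counts) per basis component with uncertainties.

    ``bse`` are residual-based standard errors (valid under the optional
    homoscedastic-noise reading of the fit; with zero residual they are 0).
    """

    model: UnmixModel
    amplitudes: np.ndarray
    bse: np.ndarray
    residual_rms: float
    condition_number: float
    nonneg: bool
    df_resid: int

    @property
    def names(self) -> tuple:
        return self.model.basis.names

    def amplitude(self, name: str) -> float:
        return float(self.amplitudes[self.names.index(name)])

    @property
    def reconstruction(self) -> np.ndarray:
        return self.model.basis.matrix @ self.amplitudes

    def summary(self) -> str:
        head = (
            f"Linear spectral unmixing ({'NNLS' if self.nonneg else 'SVD pseudoinverse'})\n"
            f"{'=' * 52}\n"
            f"grid points: {self.model.basis.wavelengths.size}   "
            f"components: {len(self.names)}   "
            f"cond(B): {self.condition_number:.3g}\n"
            f"residual rms: {self.residual_rms:.6g} counts\n"
        )
        rows = "\n".join(
            f"  {nm:<18s} {a:>14.6g} +/- {se:.3g}"
            for nm, a, se in zip(self.names, self.amplitudes, self.bse)
        )
        return head + rows


def svd_unmix(spectrum: Spectrum, basis: BasisMatrix, nonneg: bool = False) -> UnmixResults:
    """Least-squares amplitudes of ``spectrum`` over ``basis`` (SVD solve)."""
    return UnmixModel(spectrum, basis).fit(nonneg=nonneg)


def quench_difference(pre: Spectrum, post: Spectrum) -> Spectrum:
    """Pointwise (before − after quenching): the isolated ¹O₂ band."""
    if not pre.same_grid(post):
        raise GridMismatchError("pre and post spectra are on different grids")
    return pre.with_intensities(pre.intensities - post.intensities)


def unmix_series(
    series: Sequence[Spectrum],
    basis: BasisMatrix,
    smooth: bool = False,
    nonneg: bool = False,
) -> pd.DataFrame:
    """Unmix a time series of spectra; one row per acquisition.

    Returns a DataFrame sorted by acquisition time with columns ``t_s``,
    one amplitude column per basis component, and ``residual_rms``.
    Five-point smoothing, when requested, is applied before fitting.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    rows = []
    for spec in series:
        s = smooth_five_point(spec) if smooth else spec
        res = svd_unmix(s, basis, nonneg=nonneg)
        row = {"t_s": spec.t_acq_s if spec.t_acq_s is not None else np.nan}
        row.update({nm: a for nm, a in zip(res.names, res.amplitudes)})
        row["residual_rms"] = res.residual_rms
        rows.append(row)
    return pd.DataFrame(rows).sort_values("t_s", kind="stable").reset_index(drop=True)


def fourier_columns(wavelengths: np.ndarray, n_pairs: int) -> tuple[list, list]:
    """First ``n_pairs`` cosine/sine pairs over the wavelength window.

    Periods are the window length L over the harmonic index; used to soak
    up slowly varying residual structure in the fluorescence fit.
    """
    wl = np.asarray(wavelengths, float)
    L = wl[-1] - wl[0]
    x = (wl - wl[0]) / L
    cols, names = [], []
    for k in range(1, n_pairs + 1):
        cols.append(np.cos(2 * np.pi * k * x))
        names.append(f"cos{k}")
        cols.append(np.sin(2 * np.pi * k * x))
        names.append(f"sin{k}")
    return names, cols


def fluorescence_unmix(
    spectrum: Spectrum,
    ps_basis: Spectrum,
    background_basis: Spectrum,
    n_fourier: int = 1,
) -> UnmixResults:
    """Unmix a visible-window fluorescence spectrum (~600–800 nm).

    The basis is {photosensitizer fluorescence, background} plus the first
    ``n_fourier`` cosine/sine pairs over the window. The photosensitizer
    amplitude, referenced to its pre-treatment value, tracks the relative
    ground-state drug concentration during photobleaching.
    """
    if not ps_basis.same_grid(background_basis):
        raise GridMismatchError("fluorescence basis spectra are on different grids")
    names = ["ps_fluorescence", "background"]
    cols = [ps_basis.intensities, background_basis.intensities]
    f_names, f_cols = fourier_columns(ps_basis.wavelengths, n_fourier)
    basis = BasisMatrix(
        tuple(names + f_names),
        ps_basis.wavelengths,
        np.column_stack(cols + f_cols),
    )
    return svd_unmix(spectrum, basis)
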