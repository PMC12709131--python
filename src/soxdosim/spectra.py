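"""Wavelength-resolved spectra: data model, CSV I/O, resampling, smoothing.

Every downstream stage (unmixing, synthetic generation, correlation) works
on :class:`Spectrum` objects sharing a common :class:`WavelengthGrid`.
Wavelengths are always nanometres, times always seconds, intensities are
detector counts in arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "WavelengthGrid",
    "SpectrumFormatError",
    "DuplicateWavelengthError",
    "GridMismatchError",
    "ExtrapolationError",
    "read_spectrum",
    "write_spectrum",
    "write_series",
    "resample",
    "smooth_five_point",
    "shrinking_moving_average",
]


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file does not match the declared dialect."""


class DuplicateWavelengthError(ValueError):
    """Raised when a spectrum contains repeated wavelength samples."""


class GridMismatchError(ValueError):
    """Raised when two spectra expected on one grid have different grids."""


class ExtrapolationError(ValueError):
    """Raised when a resampling grid extends beyond the measured range."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nm."""

    start_nm: float
    stop_nm: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.start_nm < self.stop_nm:
            raise ValueError("start_nm must be < stop_nm")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.start_nm, self.stop_nm, self.n_points)


@dataclass(frozen=True)
class Spectrum:
    """One wavelength-resolved intensity measurement.

    Parameters
    ----------
    wavelengths : array of float
        Strictly ascending wavelengths in nm, length >= 2.
    intensities : array of float
        Detector counts (arbitrary units), same length, all finite.
    exposure_s : float
        Exposure time of the acquisition in seconds.
    t_acq_s : float or None
        Seconds since irradiation start; ``None`` for basis spectra that
        are not tied to a time point.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    exposure_s: float = 5.0
    t_acq_s: float | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelengths must be 1-D with length >= 2")
        if it.shape != wl.shape:
            raise ValueError("intensities must match wavelengths in shape")
        d = np.diff(wl)
        if np.any(d == 0):
            raise DuplicateWavelengthError("duplicate wavelength samples")
        if np.any(d < 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(it)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)

    def __len__(self) -> int:
        return self.wavelengths.size

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return replace(self, intensities=np.asarray(intensities, dtype=float))

    def same_grid(self, other: "Spectrum", rtol: float = 0.0) -> bool:
        return self.wavelengths.size == other.wavelengths.size and np.allclose(
            self.wavelengths, other.wavelengths, rtol=rtol, atol=1e-9
        )


_TWO_COLUMN = ["wavelength_nm", "intensity"]
_LONG_FORMAT = ["t_s", "wavelength_nm", "intensity"]


def read_spectrum(path, dialect: str = "two_column"):
    """Read spectra from CSV.

    ``two_column`` (header ``wavelength_nm,intensity``) yields one
    :class:`Spectrum`; ``long_format`` (header ``t_s,wavelength_nm,intensity``)
    groups rows by ``t_s`` and yields a list of Spectrum ordered by time.
    """
    df = pd.read_csv(path)
    if dialect == "two_column":
        if list(df.columns) != _TWO_COLUMN:
            raise SpectrumFormatError(
                f"expected header {','.join(_TWO_COLUMN)}, got {','.join(df.columns)}"
            )
        return _spectrum_from_frame(df)
    if dialect == "long_format":
        if list(df.columns) != _LONG_FORMAT:
            raise SpectrumFormatError(
                f"expected header {','.join(_LONG_FORMAT)}, got {','.join(df.columns)}"
            )
        out = []
        for t, grp in df.groupby("t_s", sort=True):
            out.append(_spectrum_from_frame(grp[_TWO_COLUMN], t_acq_s=float(t)))
        return out
    raise ValueError(f"unknown dialect {dialect!r}")


def _spectrum_from_frame(df: pd.DataFrame, t_acq_s: float | None = None) -> Spectrum:
    df = df.sort_values("wavelength_nm")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if np.any(np.diff(wl) == 0):
        raise DuplicateWavelengthError("duplicate wavelength samples in file")
    return Spectrum(wl, df["intensity"].to_numpy(dtype=float), t_acq_s=t_acq_s)


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write one spectrum as two-column CSV with 9+ significant digits."""
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "intensity": spectrum.intensities}
    ).to_csv(path, index=False, float_format="%.12g")


def write_series(series: Sequence[Spectrum], path) -> None:
    """Write a time series of spectra as long-format CSV."""
    frames = []
    for s in series:
        if s.t_acq_s is None:
            raise ValueError("all spectra in a series need t_acq_s")
        frames.append(
            pd.DataFrame(
                {
                    "t_s": s.t_acq_s,
                    "wavelength_nm": s.wavelengths,
                    "intensity": s.intensities,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format="%.12g")


def resample(spectrum: Spectrum, grid: WavelengthGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid``.

    The grid must lie within the measured wavelength range; interpolation
    never extrapolates. Grid nodes that coincide with input nodes reproduce
    the input intensity exactly.
    """
    wl = grid.wavelengths
    if wl[0] < spectrum.wavelengths[0] or wl[-1] > spectrum.wavelengths[-1]:
        raise ExtrapolationError(
            f"grid [{wl[0]}, {wl[-1]}] nm extends beyond data "
            f"[{spectrum.wavelengths[0]}, {spectrum.wavelengths[-1]}] nm"
        )
    it = np.interp(wl, spectrum.wavelengths, spectrum.intensities)
    return Spectrum(wl, it, exposure_s=spectrum.exposure_s, t_acq_s=spectrum.t_acq_s)


def smooth_five_point(spectrum: Spectrum) -> Spectrum:
    """Centered 5-point moving average with symmetric shrinking at edges.

    Interior points average 5 neighbours; the window shrinks symmetrically
    near the boundary (3 points at the second/penultimate index, the raw
    value at the ends), so no artificial padding enters the average.
    """
    return spectrum.with_intensities(shrinking_moving_average(spectrum.intensities))


def shrinking_moving_average(y: np.ndarray, half_width: int = 2) -> np.ndarray:
    """Moving average whose window shrinks symmetrically near the edges.

    A single sample is returned unchanged (degenerate window).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    out = np.empty_like(y)
    for i in range(n):
        h = min(half_width, i, n - 1 - i)
        out[i] = y[i - h : i + h + 1].mean()
    return out
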