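"""Optical-property correction for detected singlet-oxygen luminescence.

The luminescence detected by a surface fiber depends strongly on the
absorption (μa) and reduced scattering (μs′) of the medium. This module
provides

* the packaged 5×5 correction-factor (CF) grid measured/simulated over
  μa ∈ {0.1..1.0} cm⁻¹ and μs′ ∈ {5..40} cm⁻¹ at 690 nm, normalised to the
  reference point (μa=0.3, μs′=10) typical of pleural tissue, with
  bilinear interpolation between nodes;
* a simplified two-stage Monte Carlo photon-transport model (isotropic
  scattering under the similarity relation, semi-infinite homogeneous
  medium) that regenerates the signal-vs-(μa, μs′) trends and CF structure
  from first principles.

The packaged table is authoritative data; the Monte Carlo is an
independent model of the same physics, aimed at trend and sign structure,
not at reproducing the table to printed precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "OpticalProperties",
    "CorrectionFactorTable",
    "DetectionGeometry",
    "CFValue",
    "load_cf_table",
    "cf_lookup",
    "apply_cf",
    "compute_cf_from_signals",
    "mc_detected_signal",
    "mc_cf_grid",
    "REFERENCE_MUA",
    "REFERENCE_MUSP",
]

REFERENCE_MUA = 0.3
REFERENCE_MUSP = 10.0

#: μs′ range over which the packaged CF grid is monotone non-increasing at
#: every μa; the 40 cm⁻¹ row sits within measurement noise of the 20 cm⁻¹ row.
MUSP_MONOTONE_MAX = 20.0


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of the medium (cm⁻¹) at the excitation
    wavelength, with an optional separate pair at the emission wavelength."""

    mua: float
    musp: float
    mua_emission: float | None = None
    musp_emission: float | None = None

    def __post_init__(self) -> None:
        if self.mua < 0 or self.musp < 0:
            raise ValueError("mua and musp must be >= 0")

    @property
    def emission_pair(self) -> tuple[float, float]:
        """(μa, μs′) at the emission wavelength; defaults to the excitation pair."""
        mua = self.mua if self.mua_emission is None else self.mua_emission
        musp = self.musp if self.musp_emission is None else self.musp_emission
        return mua, musp


class CFValue(float):
    """A correction factor; ``clamped`` flags lookups outside the grid hull."""

    clamped: bool = False

    def __new__(cls, value: float, clamped: bool = False):
        obj = super().__new__(cls, value)
        obj.clamped = clamped
        return obj


@dataclass(frozen=True)
class CorrectionFactorTable:
    """CF grid over (μs′, μa) with bilinear interpolation semantics."""

    musp_grid: np.ndarray
    mua_grid: np.ndarray
    cf: np.ndarray  # (n_musp, n_mua)

    def __post_init__(self) -> None:
        musp = np.asarray(self.musp_grid, float)
        mua = np.asarray(self.mua_grid, float)
        cf = np.asarray(self.cf, float)
        if cf.shape != (musp.size, mua.size):
            raise ValueError("cf must be (n_musp, n_mua)")
        object.__setattr__(self, "musp_grid", musp)
        object.__setattr__(self, "mua_grid", mua)
        object.__setattr__(self, "cf", cf)
        # structural invariants of the measured grid
        if np.any(np.diff(cf, axis=1) <= 0):
            raise ValueError("CF must be strictly increasing in mua at fixed musp")
        rows = musp <= MUSP_MONOTONE_MAX
        if np.any(np.diff(cf[rows], axis=0) > 0):
            raise ValueError(
                f"CF must be non-increasing in musp (up to {MUSP_MONOTONE_MAX} cm^-1)"
            )
        i = int(np.argmin(np.abs(musp - REFERENCE_MUSP)))
        j = int(np.argmin(np.abs(mua - REFERENCE_MUA)))
        if not (musp[i] == REFERENCE_MUSP and mua[j] == REFERENCE_MUA and cf[i, j] == 1.0):
            raise ValueError("CF at the reference point must be exactly 1.00")

    def lookup(self, op: OpticalProperties) -> CFValue:
        return cf_lookup(self, op)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"musp_cm1": m, "mua_cm1": a, "cf": self.cf[i, j]}
            for i, m in enumerate(self.musp_grid)
            for j, a in enumerate(self.mua_grid)
        ]
        return pd.DataFrame(rows)


def load_cf_table() -> CorrectionFactorTable:
    """Load the packaged correction-factor grid."""
    with resources.files("soxdosim.data").joinpath("correction_factors.csv").open() as fh:
        df = pd.read_csv(fh)
    musp = np.unique(df["musp_cm1"].to_numpy(float))
    mua = np.unique(df["mua_cm1"].to_numpy(float))
    cf = (
        df.pivot(index="musp_cm1", columns="mua_cm1", values="cf")
        .loc[musp, mua]
        .to_numpy(float)
    )
    return CorrectionFactorTable(musp, mua, cf)


def cf_lookup(table: CorrectionFactorTable, op: OpticalProperties) -> CFValue:
    """Bilinear CF interpolation; exact at nodes, clamped outside the hull.

    Outside the measured (μa, μs′) range the nearest edge value is used and
    the result carries ``clamped=True`` (and a warning) — extrapolated CFs
    are unvalidated.
    """
    mua, musp = op.mua, op.musp
    clamped = not (
        table.mua_grid[0] <= mua <= table.mua_grid[-1]
        and table.musp_grid[0] <= musp <= table.musp_grid[-1]
    )
    if clamped:
        warnings.warn(
            f"optical properties (mua={mua}, musp={musp}) outside the CF grid; "
            "clamping to the nearest edge",
            stacklevel=2,
        )
    a = np.clip(mua, table.mua_grid[0], table.mua_grid[-1])
    m = np.clip(musp, table.musp_grid[0], table.musp_grid[-1])
    i = int(np.clip(np.searchsorted(table.musp_grid, m) - 1, 0, table.musp_grid.size - 2))
    j = int(np.clip(np.searchsorted(table.mua_grid, a) - 1, 0, table.mua_grid.size - 2))
    tm = (m - table.musp_grid[i]) / (table.musp_grid[i + 1] - table.musp_grid[i])
    ta = (a - table.mua_grid[j]) / (table.mua_grid[j + 1] - table.mua_grid[j])
    v = (
        table.cf[i, j] * (1 - tm) * (1 - ta)
        + table.cf[i + 1, j] * tm * (1 - ta)
        + table.cf[i, j + 1] * (1 - tm) * ta
        + table.cf[i + 1, j + 1] * tm * ta
    )
    return CFValue(float(v), clamped=clamped)


def apply_cf(signal: float, op: OpticalProperties, table: CorrectionFactorTable) -> float:
    """Correct a detected signal to the reference optical properties."""
    if not np.isfinite(signal):
        raise ValueError("signal must be finite")
    return float(signal) * float(cf_lookup(table, op))


def compute_cf_from_signals(signal: float, reference_signal: float) -> float:
    """CF = reference / signal, so that CF·signal restores the reference scale."""
    if signal <= 0 or reference_signal <= 0:
        raise ValueError("signals must be > 0")
    return reference_signal / signal


@dataclass(frozen=True)
class DetectionGeometry:
    """Surface-contact fiber detection above a semi-infinite slab.

    A flat-cut fiber (core diameter mm, numerical aperture) sits at the
    medium surface on the axis of a uniform beam of ``beam_area_cm2``;
    emission packets exiting the top surface inside the core radius with
    polar angle within asin(NA/n_medium) are scored.
    """

    fiber_core_diameter_mm: float = 1.5
    numerical_aperture: float = 0.39
    beam_area_cm2: float = 1.0
    n_medium: float = 1.33

    def __post_init__(self) -> None:
        if not 0 < self.numerical_aperture < 1:
            raise ValueError("numerical aperture must be in (0, 1)")
        if self.fiber_core_diameter_mm <= 0 or self.beam_area_cm2 <= 0:
            raise ValueError("diameters and areas must be > 0")

    @property
    def fiber_radius_cm(self) -> float:
        return 0.05 * self.fiber_core_diameter_mm

    @property
    def beam_radius_cm(self) -> float:
        return float(np.sqrt(self.beam_area_cm2 / np.pi))

    @property
    def acceptance_cos(self) -> float:
        """cos of the in-medium half-acceptance angle asin(NA/n)."""
        return float(np.cos(np.arcsin(self.numerical_aperture / self.n_medium)))


# voxel grid for the deposited-weight (fluence) map
_DR = 0.05
_DZ = 0.05
_R_MAX = 2.0
_Z_MAX = 3.0
_ROULETTE_W = 1e-4
_ROULETTE_P = 0.1


@njit(cache=True, fastmath=True)
def _excitation_kernel(mua, musp, beam_radius, n, seed, dr, dz, nr, nz):
    """Deposited excitation weight per voxel (∝ μa × fluence × volume).

    Per-packet loop compiled with numba; numba's RNG is seeded once so the
    kernel is deterministic for a given (inputs, seed).
    """
    np.random.seed(seed)
    deposit = np.zeros((nr, nz))
    mut = mua + musp
    loss = mua / mut
    for _ in range(n):
        # launch uniform over the beam disk, straight down
        r0 = beam_radius * np.sqrt(np.random.random())
        phi0 = 2.0 * np.pi * np.random.random()
        x = r0 * np.cos(phi0)
        y = r0 * np.sin(phi0)
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        while True:
            step = -np.log(np.random.random() + 1e-300) / mut
            x += ux * step
            y += uy * step
            z += uz * step
            if z < 0.0:  # escaped through the top surface
                break
            ir = int(np.sqrt(x * x + y * y) / dr)
            iz = int(z / dz)
            if ir < nr and iz < nz:
                deposit[ir, iz] += w * loss
            w *= 1.0 - loss
            if w < _ROULETTE_W:
                if np.random.random() < _ROULETTE_P:
                    w /= _ROULETTE_P
                else:
                    break
            uz = 2.0 * np.random.random() - 1.0
            phi = 2.0 * np.pi * np.random.random()
            s = np.sqrt(max(0.0, 1.0 - uz * uz))
            ux = s * np.cos(phi)
            uy = s * np.sin(phi)
    return deposit


@njit(cache=True, fastmath=True)
def _emission_kernel(cdf, mua, musp, r_fib, cos_acc, n, seed, dr, dz, nz):
    """Mean detected weight per emission packet, sites sampled ∝ deposit."""
    np.random.seed(seed)
    mut = mua + musp
    loss = mua / mut
    scored = 0.0
    for _ in range(n):
        # sample a voxel from the deposit CDF, then uniform-in-volume inside
        idx = np.searchsorted(cdf, np.random.random())
        ir = idx // nz
        iz = idx % nz
        r1 = ir * dr
        r2 = r1 + dr
        r = np.sqrt(np.random.random() * (r2 * r2 - r1 * r1) + r1 * r1)
        phi = 2.0 * np.pi * np.random.random()
        x = r * np.cos(phi)
        y = r * np.sin(phi)
        z = (iz + np.random.random()) * dz
        uz = 2.0 * np.random.random() - 1.0
        ang = 2.0 * np.pi * np.random.random()
        s = np.sqrt(max(0.0, 1.0 - uz * uz))
        ux = s * np.cos(ang)
        uy = s * np.sin(ang)
        w = 1.0
        while True:
            step = -np.log(np.random.random() + 1e-300) / mut
            xn = x + ux * step
            yn = y + uy * step
            zn = z + uz * step
            if zn < 0.0:
                # exact surface crossing point along the segment
                frac = z / (z - zn)
                xs = x + frac * (xn - x)
                ys = y + frac * (yn - y)
                if xs * xs + ys * ys <= r_fib * r_fib and -uz >= cos_acc:
                    scored += w
                break
            x, y, z = xn, yn, zn
            w *= 1.0 - loss
            if w < _ROULETTE_W:
                if np.random.random() < _ROULETTE_P:
                    w /= _ROULETTE_P
                else:
                    break
            uz = 2.0 * np.random.random() - 1.0
            ang = 2.0 * np.pi * np.random.random()
            s = np.sqrt(max(0.0, 1.0 - uz * uz))
            ux = s * np.cos(ang)
            uy = s * np.sin(ang)
    return scored / n


def _excitation_fluence_map(
    mua: float, musp: float, geom: DetectionGeometry, seed: int, n: int
) -> np.ndarray:
    if mua + musp <= 0:
        raise ValueError("mua + musp must be > 0")
    nr = int(round(_R_MAX / _DR))
    nz = int(round(_Z_MAX / _DZ))
    return _excitation_kernel(
        mua, musp, geom.beam_radius_cm, n, seed % (2**31), _DR, _DZ, nr, nz
    )


def _emission_detection(
    deposit: np.ndarray,
    mua: float,
    musp: float,
    geom: DetectionGeometry,
    seed: int,
    n: int,
) -> float:
    p = deposit.ravel()
    total = p.sum()
    if total <= 0:
        return 0.0
    cdf = np.cumsum(p) / total
    cdf[-1] = 1.0
    return _emission_kernel(
        cdf,
        mua,
        musp,
        geom.fiber_radius_cm,
        geom.acceptance_cos,
        n,
        seed % (2**31),
        _DR,
        _DZ,
        deposit.shape[1],
    )


def mc_detected_signal(
    op: OpticalProperties,
    geom: DetectionGeometry | None = None,
    n_photons: int = 100_000,
    seed: int = 0,
    emission_oversampling: int = 4,
) -> tuple[float, float]:
    """Relative detected luminescence signal at given optical properties.

    Two-stage similarity-model Monte Carlo (isotropic scattering with
    interaction coefficient μa+μs′) in a semi-infinite homogeneous medium.
    Stage 1 transports excitation packets from the beam and accumulates
    deposited weight on a cylindrical voxel grid; since deposited weight is
    μa × fluence × volume and the luminescence source follows the local
    fluence, the signal carries a factor (total deposit)/μa. Stage 2 samples
    emission sites from the deposit map, emits isotropically at the emission
    optical pair, and scores packets exiting the surface inside the fiber
    core within the NA acceptance cone.

    Because almost all estimator variance sits in the rare stage-2
    detections, stage 2 launches ``emission_oversampling`` × ``n_photons``
    packets from the (already converged) deposit map; the detection
    probability per packet is unchanged, only its sampling error shrinks.

    Returns ``(signal, standard_error)`` in consistent arbitrary units
    (comparable across optical properties for a fixed geometry and photon
    budget); the standard error is the binomial error of the stage-2
    detection estimate propagated to the signal scale.
    """
    geom = geom or DetectionGeometry()
    if n_photons < 1000:
        raise ValueError("n_photons must be >= 1000")
    if emission_oversampling < 1:
        raise ValueError("emission_oversampling must be >= 1")
    if op.mua <= 0:
        raise ValueError("mua must be > 0 for the fluence normalisation")
    deposit = _excitation_fluence_map(op.mua, op.musp, geom, seed, n_photons)
    fluence_integral = deposit.sum() / (op.mua * n_photons)
    mua_em, musp_em = op.emission_pair
    n_emit = emission_oversampling * n_photons
    p_detect = _emission_detection(
        deposit, mua_em, musp_em, geom, seed + 1000003, n_emit
    )
    signal = fluence_integral * p_detect
    se = fluence_integral * float(
        np.sqrt(max(p_detect * (1.0 - p_detect), 0.0) / n_emit)
    )
    return signal, se


def mc_cf_grid(
    mua_values,
    musp_values,
    geom: DetectionGeometry | None = None,
    n_photons: int = 100_000,
    seed: int = 0,
    reference: tuple[float, float] = (REFERENCE_MUA, REFERENCE_MUSP),
) -> pd.DataFrame:
    """Monte Carlo CF grid: reference signal over signal at each (μa, μs′).

    Returns a frame with columns ``musp_cm1, mua_cm1, signal, signal_se, cf``.
    Seeds are derived per cell so every cell is independently reproducible.
    """
    geom = geom or DetectionGeometry()
    ref_op = OpticalProperties(mua=reference[0], musp=reference[1])
    ref_signal, _ = mc_detected_signal(ref_op, geom, n_photons, seed=seed)
    rows = []
    for i, musp in enumerate(musp_values):
        for j, mua in enumerate(mua_values):
            cell_seed = (seed + 7919 * (i * len(mua_values) + j + 1)) % (2**31)
            s, se = mc_detected_signal(
                OpticalProperties(mua=mua, musp=musp), geom, n_photons, seed=cell_seed
            )
            rows.append(
                {
                    "musp_cm1": musp,
                    "mua_cm1": mua,
                    "signal": s,
                    "signal_se": se,
                    "cf": compute_cf_from_signals(s, ref_signal),
                }
            )
    return pd.DataFrame(rows)
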