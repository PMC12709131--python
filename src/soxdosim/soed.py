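"""Singlet oxygen explicit dosimetry (SOED): macroscopic Type II PDT kinetics.

The model describes benzoporphyrin-derivative (BPD) mediated photodynamic
therapy in a well-stirred medium with three coupled state variables: the
ground-state photosensitizer concentration [S0] (μM), the ground-state
oxygen concentration [³O₂] (μM), and the cumulative reacted singlet oxygen
[¹O₂]rx (μM) — the PDT dose metric. With the oxygen saturation factor
f = [³O₂]/([³O₂]+β) and the bleaching factor g = σ([S0]+δ), the kinetics
under fluence rate ϕ (mW/cm²) are

    [¹O₂]       = ξ τΔ f ϕ [S0] / (g + 1)                 (instantaneous, μM)
    d[S0]/dt    = − ξ f ϕ [S0] · g / (g + 1)
    d[³O₂]/dt   = − ξ f ϕ [S0] · (g + k7 [A] τΔ) / (g + 1)
    d[¹O₂]rx/dt =   ξ f ϕ [S0] / (g + 1)

Two oxygen modes are supported. ``clamped`` holds [³O₂] at its initial
value, matching shallow liquid-phantom measurements where atmospheric
re-oxygenation is fast; ``evolving`` integrates the oxygen equation as
written. Note that at [A]=0 the oxygen and photobleaching equations are
identical, so in evolving mode [³O₂](t) − [S0](t) is conserved; this is a
property of the equations as printed, not a modelling choice made here.

Exposed statsmodels-style: :class:`SOEDModel` holds phantom, protocol and
parameters; :meth:`SOEDModel.simulate` integrates the system and returns a
:class:`SOEDTrajectory` with the state table and derived quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "SOEDParameters",
    "PDTState",
    "IrradiationProtocol",
    "PhantomSpec",
    "SOEDModel",
    "SOEDTrajectory",
    "IntegrationFailure",
    "instantaneous_singlet_oxygen",
    "soed_rhs",
    "integrate_soed",
    "mgL_to_uM",
    "mmHg_to_uM",
    "cumulative_fluence",
    "BPD_MOLECULAR_WEIGHT",
    "OXYGEN_MMHG_TO_UM",
]

#: Default BPD (verteporfin) molar mass, g/mol; overridable in PhantomSpec.
BPD_MOLECULAR_WEIGHT = 718.8

#: Conversion factor from oxygen partial pressure to concentration, μM/mmHg.
OXYGEN_MMHG_TO_UM = 1.295


class IntegrationFailure(RuntimeError):
    """Raised when the ODE solver fails or a state goes negative beyond tolerance."""


@dataclass(frozen=True)
class SOEDParameters:
    """Photophysical constants of the BPD Type II kinetics (in vitro defaults).

    Attributes
    ----------
    xi : float
        Specific oxygen consumption rate ξ, cm² mW⁻¹ s⁻¹.
    beta : float
        Oxygen quenching threshold concentration β, μM.
    delta : float
        Low-concentration correction δ, μM.
    sigma : float
        Specific photobleaching ratio σ, μM⁻¹.
    tau_delta : float
        Singlet oxygen lifetime τΔ, s.
    k7 : float
        Rate constant for ¹O₂ quenching by substrate, μM⁻¹ s⁻¹.
    A : float
        Concentration of oxidisable biomolecular acceptors [A], μM
        (0 in plain methanol phantoms).
    """

    xi: float = 51e-3
    beta: float = 11.9
    delta: float = 33.0
    sigma: float = 1.7e-5
    tau_delta: float = 9.4e-6
    k7: float = 0.0
    A: float = 0.0

    def __post_init__(self) -> None:
        for name in ("xi", "beta", "delta", "sigma", "tau_delta", "k7", "A"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tau_delta <= 0:
            raise ValueError("tau_delta must be > 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")


@dataclass(frozen=True)
class PDTState:
    """State of the PDT system at time t: [S0], [³O₂], cumulative [¹O₂]rx (μM)."""

    t: float
    S0: float
    O2: float
    O2rx: float = 0.0

    def __post_init__(self) -> None:
        if self.S0 < 0 or self.O2 < 0:
            raise ValueError("concentrations must be >= 0")


@dataclass(frozen=True)
class IrradiationProtocol:
    """Irradiation schedule: constant fluence rate with optional dark pauses.

    phi is in mW/cm²; ``pauses`` is a list of (start_s, length_s) windows in
    which the treatment beam is off (ϕ=0), e.g. for contact-probe
    fluorescence reads. ``acquisition_period_s`` sets the spectrometer
    cadence: one ``acquisition_exposure_s`` exposure every period, starting
    at t=0.
    """

    phi: float = 850.0
    duration_s: float = 900.0
    pauses: tuple = ()
    acquisition_period_s: float = 100.0
    acquisition_exposure_s: float = 5.0

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        for start, length in self.pauses:
            if length < 0 or start < 0 or start + length > self.duration_s:
                raise ValueError("pauses must lie within [0, duration_s]")

    def fluence_rate_at(self, t: float) -> float:
        """ϕ(t), zero inside pauses."""
        for start, length in self.pauses:
            if start <= t < start + length:
                return 0.0
        return self.phi

    def acquisition_times(self) -> np.ndarray:
        """Spectrometer acquisition start times, t=0 to duration inclusive."""
        n = int(np.floor(self.duration_s / self.acquisition_period_s + 1e-9)) + 1
        return np.arange(n) * self.acquisition_period_s


@dataclass(frozen=True)
class PhantomSpec:
    """Liquid-phantom recipe: drug loading and oxygenation.

    ``oxygen_mode`` is ``"clamped"`` (oxygen held constant, the phantom
    default — surface layers re-oxygenate from air faster than PDT consumes
    oxygen) or ``"evolving"`` (oxygen follows its rate equation).
    """

    bpd_mg_per_L: float = 6.0
    molecular_weight_g_per_mol: float = BPD_MOLECULAR_WEIGHT
    initial_O2_uM: float = 194.0
    oxygen_mode: str = "clamped"
    label: str = ""

    def __post_init__(self) -> None:
        if self.bpd_mg_per_L < 0 or self.initial_O2_uM < 0:
            raise ValueError("concentrations must be >= 0")
        if self.molecular_weight_g_per_mol <= 0:
            raise ValueError("molecular weight must be > 0")
        if self.oxygen_mode not in ("clamped", "evolving"):
            raise ValueError("oxygen_mode must be 'clamped' or 'evolving'")

    @property
    def S0_uM(self) -> float:
        """Initial photosensitizer concentration in μM."""
        return mgL_to_uM(self.bpd_mg_per_L, self.molecular_weight_g_per_mol)


def mgL_to_uM(c_mg_per_L: float, mw_g_per_mol: float = BPD_MOLECULAR_WEIGHT) -> float:
    """Convert a mass concentration (mg/L) to molar concentration (μM)."""
    if mw_g_per_mol <= 0:
        raise ValueError("molecular weight must be > 0")
    if c_mg_per_L < 0:
        raise ValueError("concentration must be >= 0")
    return 1000.0 * c_mg_per_L / mw_g_per_mol


def mmHg_to_uM(p_mmHg: float) -> float:
    """Convert oxygen partial pressure (mmHg) to dissolved concentration (μM)."""
    if p_mmHg < 0:
        raise ValueError("partial pressure must be >= 0")
    return OXYGEN_MMHG_TO_UM * p_mmHg


def cumulative_fluence(protocol: IrradiationProtocol, t: float) -> float:
    """Delivered fluence ∫₀ᵗ ϕ dt' in J/cm² (pauses contribute zero)."""
    if not 0 <= t <= protocol.duration_s:
        raise ValueError(f"t={t} outside [0, {protocol.duration_s}]")
    paused = 0.0
    for start, length in protocol.pauses:
        paused += max(0.0, min(t, start + length) - start)
    return protocol.phi * (t - paused) / 1000.0


def instantaneous_singlet_oxygen(
    state: PDTState, params: SOEDParameters, phi: float
) -> float:
    """Instantaneous singlet oxygen concentration [¹O₂] in μM.

    [¹O₂] = ξ τΔ · [³O₂]/([³O₂]+β) · ϕ [S0] / (σ([S0]+δ) + 1).
    """
    f = state.O2 / (state.O2 + params.beta)
    g = params.sigma * (state.S0 + params.delta)
    return params.xi * params.tau_delta * f * phi * state.S0 / (g + 1.0)


def soed_rhs(
    state: PDTState,
    params: SOEDParameters,
    phi: float,
    oxygen_mode: str = "evolving",
) -> tuple[float, float, float]:
    """Time derivatives (d[S0]/dt, d[³O₂]/dt, d[¹O₂]rx/dt) in μM/s."""
    f = state.O2 / (state.O2 + params.beta)
    g = params.sigma * (state.S0 + params.delta)
    r0 = params.xi * f * phi * state.S0
    dS0 = -r0 * g / (g + 1.0)
    if oxygen_mode == "clamped":
        dO2 = 0.0
    else:
        dO2 = -r0 * (g + params.k7 * params.A * params.tau_delta) / (g + 1.0)
    dO2rx = r0 / (g + 1.0)
    return dS0, dO2, dO2rx


@dataclass(frozen=True)
class SOEDModel:
    """The explicit-dosimetry kinetic model bound to a phantom and protocol."""

    phantom: PhantomSpec
    protocol: IrradiationProtocol
    params: SOEDParameters = field(default_factory=SOEDParameters)

    def simulate(self, dt_out: float = 1.0) -> "SOEDTrajectory":
        """Integrate the kinetics and return the trajectory.

        Adaptive RK45 with rtol 1e-8 / atol 1e-12 μM, integrated piecewise
        over the beam-on/beam-off segments of the protocol; output on a
        uniform grid of step ``dt_out`` plus the segment boundaries.
        """
        states = integrate_soed(self.phantom, self.protocol, self.params, dt_out)
        return SOEDTrajectory(model=self, states=states)

    def rhs(self, state: PDTState, phi: float) -> tuple[float, float, float]:
        return soed_rhs(state, self.params, phi, self.phantom.oxygen_mode)


def _segment_edges(protocol: IrradiationProtocol) -> list[tuple[float, float, float]]:
    """(t0, t1, phi) segments covering [0, duration] with pauses at phi=0."""
    edges = {0.0, protocol.duration_s}
    for start, length in protocol.pauses:
        edges.add(start)
        edges.add(start + length)
    ts = sorted(edges)
    return [
        (a, b, protocol.fluence_rate_at(0.5 * (a + b)))
        for a, b in zip(ts[:-1], ts[1:])
        if b > a
    ]


def integrate_soed(
    phantom: PhantomSpec,
    protocol: IrradiationProtocol,
    params: SOEDParameters,
    dt_out: float = 1.0,
) -> list[PDTState]:
    """Integrate the SOED system from t=0 to the protocol duration."""
    if dt_out <= 0:
        raise ValueError("dt_out must be > 0")
    clamped = phantom.oxygen_mode == "clamped"
    atol = 1e-12

    def rhs(t, y, phi):
        S0, O2, _ = y
        # the solver may probe slightly negative values; rates vanish there
        S0 = max(S0, 0.0)
        O2 = max(O2, 0.0)
        f = O2 / (O2 + params.beta)
        g = params.sigma * (S0 + params.delta)
        r0 = params.xi * f * phi * S0
        dS0 = -r0 * g / (g + 1.0)
        dO2 = 0.0 if clamped else -r0 * (g + params.k7 * params.A * params.tau_delta) / (g + 1.0)
        return (dS0, dO2, r0 / (g + 1.0))

    t_grid = np.arange(0.0, protocol.duration_s + 0.5 * dt_out, dt_out)
    t_grid = np.minimum(t_grid, protocol.duration_s)
    y = np.array([phantom.S0_uM, phantom.initial_O2_uM, 0.0])
    out_t = [0.0]
    out_y = [y.copy()]
    for t0, t1, phi in _segment_edges(protocol):
        inner = t_grid[(t_grid > t0) & (t_grid < t1)]
        t_eval = np.concatenate([inner, [t1]])
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            t_eval=t_eval,
            args=(phi,),
            method="RK45",
            rtol=1e-8,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationFailure(sol.message)
        if np.any(sol.y[:2] < -1e3 * atol):
            raise IntegrationFailure("negative concentration beyond tolerance")
        for tk, yk in zip(sol.t, sol.y.T):
            out_t.append(tk)
            out_y.append(np.maximum(yk, 0.0))
        y = out_y[-1]
    return [
        PDTState(t=float(t), S0=float(s0), O2=float(o2), O2rx=float(rx))
        for t, (s0, o2, rx) in zip(out_t, out_y)
    ]


@dataclass(frozen=True)
class SOEDTrajectory:
    """Integrated SOED trajectory with derived dosimetric quantities."""

    model: SOEDModel
    states: list

    def to_frame(self) -> pd.DataFrame:
        """State table: t, [S0], [³O₂], [¹O₂]rx, instantaneous [¹O₂], fluence."""
        params = self.model.params
        proto = self.model.protocol
        rows = []
        for st in self.states:
            phi = proto.fluence_rate_at(st.t) if st.t < proto.duration_s else proto.fluence_rate_at(proto.duration_s - 1e-9)
            rows.append(
                {
                    "t_s": st.t,
                    "S0_uM": st.S0,
                    "O2_uM": st.O2,
                    "O2rx_uM": st.O2rx,
                    "inst_1O2_uM": instantaneous_singlet_oxygen(st, params, phi),
                    "fluence_J_cm2": cumulative_fluence(proto, st.t),
                }
            )
        return pd.DataFrame(rows)

    def instantaneous_at(self, times: Sequence[float]) -> np.ndarray:
        """Instantaneous [¹O₂] (μM) interpolated at the given times."""
        df = self.to_frame()
        return np.interp(np.asarray(times, float), df["t_s"], df["inst_1O2_uM"])

    def summary(self) -> str:
        df = self.to_frame()
        ph = self.model.phantom
        lines = [
            "SOED trajectory",
            "=" * 48,
            f"phantom:      {ph.bpd_mg_per_L} mg/L BPD ({ph.S0_uM:.4g} uM), "
            f"O2 {ph.initial_O2_uM} uM ({ph.oxygen_mode})",
            f"protocol:     {self.model.protocol.phi} mW/cm2 x "
            f"{self.model.protocol.duration_s} s "
            f"({df['fluence_J_cm2'].iloc[-1]:.4g} J/cm2)",
            f"final [S0]:   {df['S0_uM'].iloc[-1]:.6g} uM "
            f"({100 * df['S0_uM'].iloc[-1] / ph.S0_uM:.3g}% of initial)"
            if ph.S0_uM > 0
            else "final [S0]:   0 uM",
            f"final [1O2]rx: {df['O2rx_uM'].iloc[-1]:.6g} uM",
            f"peak inst [1O2]: {df['inst_1O2_uM'].max():.6g} uM",
        ]
        return "\n".join(lines)
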