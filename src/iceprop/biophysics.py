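"""Single-cell biophysics during linear cooling.

Deterministic models for one cell in a freezing protocol: Arrhenius membrane
hydraulic conductivity, Mazur-type osmotic water transport, cytoplasm
viscosity (pure-water law plus a crowding correction), freezing-point
depression of the cytosol, the diffusion-limited heterogeneous nucleation
rate ``J_i(T)`` of intracellular ice, and the non-dimensional clock

    tau(t) = integral_0^t J_i dt,

which is the natural time variable of the stochastic ice-propagation model
(see :mod:`iceprop.markov` and :mod:`iceprop.montecarlo`).

Units follow cryobiology convention: volumes in um^3, areas in um^2,
temperatures in K, hydraulic conductivity in m^3 N^-1 s^-1, cooling rates in
K/min, rates in s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid, solve_ivp

__all__ = [
    "ATM_UM3_TO_J",
    "CellParams",
    "CoolingProtocol",
    "CellThermoState",
    "DehydrationTrajectory",
    "TauMap",
    "hydraulic_conductivity",
    "water_viscosity",
    "cytoplasm_viscosity",
    "freezing_point",
    "mole_fraction_water",
    "water_transport_rhs",
    "integrate_dehydration",
    "nucleation_rate",
    "tau_of_time",
]

#: Joules per (um^3 atm): 1e-18 m^3 x 101325 Pa.
ATM_UM3_TO_J = 1.01325e-13

#: Isotonic NaCl concentration used to infer intracellular salt content [mol/L].
ISOTONIC_SALT_MOLARITY = 0.155


class BiophysicsError(ValueError):
    """Invalid input to a single-cell biophysics model."""


@dataclass(frozen=True)
class CellParams:
    """Immutable biophysical constants of a cell type.

    Parameters
    ----------
    A
        Membrane surface area [um^2].
    Lpg
        Hydraulic conductivity at the reference temperature [m^3 N^-1 s^-1].
    ELp
        Activation energy of the water-transport process [J/mol].
    T_R
        Reference temperature (equilibrium freezing point of pure water) [K].
    Tf0
        Freezing point of the cytoplasm at isotonic conditions [K].
    v_w
        Partial molar volume of water [um^3/mol].
    v_s
        Dissociation number for NaCl [-].
    dHf_pv
        Latent heat of fusion of water in pressure-volume units [um^3 atm/mol].
    v_b
        Osmotically inactive volume fraction [-].
    V_iso
        Isotonic cell volume [um^3].
    n_s
        Moles of intracellular dissociated salt [mol].
    Omega0, kappa0
        Kinetic [m^-2 s^-1] and thermodynamic [K^5] coefficients of the
        heterogeneous nucleation model.
    phi_hydro
        Hydrodynamic interaction constant of the crowding viscosity law [-].
    Rgas
        Universal gas constant [J mol^-1 K^-1].
    """

    A: float
    Lpg: float
    ELp: float
    T_R: float
    Tf0: float
    v_w: float
    v_s: float
    dHf_pv: float
    v_b: float
    V_iso: float
    n_s: float
    Omega0: float
    kappa0: float
    phi_hydro: float = 0.609
    Rgas: float = 8.314

    def __post_init__(self) -> None:
        positive = {
            "A": self.A, "Lpg": self.Lpg, "ELp": self.ELp, "T_R": self.T_R,
            "Tf0": self.Tf0, "v_w": self.v_w, "v_s": self.v_s,
            "dHf_pv": self.dHf_pv, "V_iso": self.V_iso, "n_s": self.n_s,
            "Omega0": self.Omega0, "kappa0": self.kappa0,
            "phi_hydro": self.phi_hydro, "Rgas": self.Rgas,
        }
        for name, value in positive.items():
            if not value > 0:
                raise BiophysicsError(f"{name} must be strictly positive, got {value}")
        if not 0 < self.v_b < 1:
            raise BiophysicsError(f"v_b must lie in (0, 1), got {self.v_b}")
        if not self.Tf0 < self.T_R:
            raise BiophysicsError("Tf0 must be below the pure-water reference T_R")

    @property
    def dHf_J(self) -> float:
        """Latent heat of fusion in molar-energy units [J/mol]."""
        return self.dHf_pv * ATM_UM3_TO_J

    @property
    def V_b(self) -> float:
        """Osmotically inactive volume [um^3]."""
        return self.v_b * self.V_iso

    @property
    def V_w_iso(self) -> float:
        """Isotonic osmotically active water volume [um^3]."""
        return (1.0 - self.v_b) * self.V_iso

    @classmethod
    def rat_hepatocyte(cls, **overrides) -> "CellParams":
        """Published rat-hepatocyte parameter set.

        The isotonic volume is that of a 21 um diameter sphere, and the salt
        content follows from isotonic (0.155 M) NaCl in the osmotically
        active water.  The printed surface area is interpreted as um^2.
        """
        V_iso = (4.0 / 3.0) * math.pi * 10.5**3
        defaults = dict(
            A=1.412e3,
            Lpg=1.5e-12,
            ELp=3.42e5,
            T_R=273.15,
            Tf0=272.63,
            v_w=1.8e13,
            v_s=2.0,
            dHf_pv=5.94124e16,
            v_b=0.51,
            V_iso=V_iso,
            n_s=ISOTONIC_SALT_MOLARITY * (1.0 - 0.51) * V_iso * 1e-15,
            Omega0=1.1e10,
            kappa0=1.4e9,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class CoolingProtocol:
    """Linear cooling ramp T(t) = T0 - B*t.

    Attributes
    ----------
    T0 : initial (seeding) temperature [K]
    B : cooling rate [K/min]
    T_end : stop temperature [K]
    """

    T0: float
    B: float
    T_end: float

    def __post_init__(self) -> None:
        if not self.B > 0:
            raise BiophysicsError(f"cooling rate B must be positive, got {self.B}")
        if not self.T_end < self.T0:
            raise BiophysicsError("T_end must be below T0")

    @property
    def B_si(self) -> float:
        """Cooling rate in K/s."""
        return self.B / 60.0

    def temperature(self, t: np.ndarray | float) -> np.ndarray | float:
        """T(t) for t in seconds."""
        return self.T0 - self.B_si * np.asarray(t)

    def time_of(self, T: np.ndarray | float) -> np.ndarray | float:
        """Inverse ramp: t(T) in seconds."""
        return (self.T0 - np.asarray(T)) / self.B_si

    @property
    def duration(self) -> float:
        """Protocol length [s]."""
        return (self.T0 - self.T_end) / self.B_si


@dataclass
class CellThermoState:
    """Thermodynamic state of a single (unfrozen) cell at one instant."""

    V: float       # cell volume [um^3]
    V_w: float     # osmotically active water volume [um^3]
    n_w: float     # moles of water
    x_w: float     # mole fraction of water
    phi_s: float   # volume fraction of non-water intracellular material
    Tf: float      # current cytoplasm freezing temperature [K]
    eta: float     # cytoplasm viscosity
    Ji: float      # spontaneous nucleation rate [1/s]
    tau: float     # non-dimensional time


def hydraulic_conductivity(params: CellParams, T: float | np.ndarray) -> float | np.ndarray:
    """Arrhenius temperature dependence of membrane hydraulic conductivity.

    Lp(T) = Lpg * exp(-(ELp/R) (1/T - 1/T_R)); strictly increasing in T and
    equal to ``Lpg`` at the reference temperature.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise BiophysicsError("temperature must be positive")
    out = params.Lpg * np.exp(-(params.ELp / params.Rgas) * (1.0 / T - 1.0 / params.T_R))
    return out if out.ndim else float(out)


def water_viscosity(T: float | np.ndarray) -> float | np.ndarray:
    """Viscosity of pure supercooled water, eta_w = 0.139 (T/225 - 1)^-1.64.

    The power law diverges as T -> 225 K from above; temperatures at or below
    225 K are outside its domain.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 225.0):
        raise BiophysicsError("water viscosity law requires T > 225 K")
    out = 0.139 * (T / 225.0 - 1.0) ** -1.64
    return out if out.ndim else float(out)


def cytoplasm_viscosity(
    phi_s: float | np.ndarray, T: float | np.ndarray, phi_hydro: float = 0.609
) -> float | np.ndarray:
    """Crowded-cytoplasm viscosity, eta = eta_w exp(2.5 phi_s / (1 - phi*phi_s)).

    ``phi_s`` is the volume fraction of non-water material; ``phi_hydro`` the
    hydrodynamic interaction constant.  Reduces to pure water at phi_s = 0 and
    diverges at phi_s -> 1/phi_hydro.
    """
    phi_s = np.asarray(phi_s, dtype=float)
    if np.any(phi_s < 0) or np.any(phi_s >= 1.0 / phi_hydro):
        raise BiophysicsError(f"phi_s must lie in [0, {1.0 / phi_hydro:.4f})")
    out = water_viscosity(T) * np.exp(2.5 * phi_s / (1.0 - phi_hydro * phi_s))
    return out if np.ndim(out) else float(out)


def freezing_point(params: CellParams, x_w: float | np.ndarray) -> float | np.ndarray:
    """Equilibrium freezing temperature of the cytoplasm.

    Tf = [1/Tf0 - (R/dHf) ln x_w]^-1 with the latent heat in J/mol; equals
    Tf0 for pure water (x_w = 1) and decreases with the water mole fraction.
    """
    x_w = np.asarray(x_w, dtype=float)
    if np.any(x_w <= 0) or np.any(x_w > 1):
        raise BiophysicsError("x_w must lie in (0, 1]")
    out = 1.0 / (1.0 / params.Tf0 - (params.Rgas / params.dHf_J) * np.log(x_w))
    return out if out.ndim else float(out)


def mole_fraction_water(n_w: float | np.ndarray, n_s: float) -> float | np.ndarray:
    """Mole fraction of intracellular water, x_w = n_w / (n_w + 2 n_s).

    The factor 2 accounts for full dissociation of NaCl.
    """
    n_w = np.asarray(n_w, dtype=float)
    if np.any(n_w < 0) or n_s < 0:
        raise BiophysicsError("mole counts must be nonnegative")
    if np.all(n_w == 0) and n_s == 0:
        raise BiophysicsError("n_w and n_s cannot both be zero")
    out = n_w / (n_w + 2.0 * n_s)
    return out if out.ndim else float(out)


def water_transport_rhs(params: CellParams, V: float, T: float, B: float) -> float:
    """Right-hand side of the osmotic water-transport ODE, dV/dT [um^3/K].

    During linear cooling at B [K/min] the cell volume obeys

        dV/dT = (Lp(T) A R T / (B v_w)) [ln x_w + (dHf/R)(1/T - 1/T_R)],

    where the bracket is the (scaled) chemical-potential difference between
    intracellular water and extracellular water in equilibrium with ice.  It
    vanishes at osmotic equilibrium; for a supercooled interior it is
    positive, so the cell shrinks as the temperature falls.
    """
    if T <= 0:
        raise BiophysicsError("temperature must be positive")
    V_b = params.V_b
    if V <= V_b:
        raise BiophysicsError("cell volume at or below the osmotically inactive volume")
    V_w = V - V_b
    ln_xw = math.log(V_w / (V_w + params.v_w * params.v_s * params.n_s))
    bracket = ln_xw + (params.dHf_J / params.Rgas) * (1.0 / T - 1.0 / params.T_R)
    Lp = hydraulic_conductivity(params, T)
    # SI volume flux per K, then back to um^3: A [um^2->m^2], v_w [um^3->m^3].
    pref = Lp * (params.A * 1e-12) * params.Rgas * T / ((params.v_w * 1e-18) * (B / 60.0))
    return pref * bracket * 1e18


@dataclass
class TauMap:
    """Monotone mapping between dimensional time, temperature and tau."""

    t: np.ndarray     # [s], increasing
    T: np.ndarray     # [K], decreasing
    tau: np.ndarray   # nondecreasing, tau[0] = 0

    def tau_at_t(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.interp(t, self.t, self.tau)

    def tau_at_T(self, T: np.ndarray | float) -> np.ndarray | float:
        return np.interp(-np.asarray(T), -self.T, self.tau)

    def t_at_tau(self, tau: np.ndarray | float) -> np.ndarray | float:
        """First time at which the cumulative clock reaches ``tau``.

        Values beyond the final tau map to +inf ("never within protocol").
        """
        tau = np.asarray(tau, dtype=float)
        out = np.interp(tau, self.tau, self.t)
        out = np.where(tau > self.tau[-1], np.inf, out)
        return out if out.ndim else float(out)

    def T_at_tau(self, tau: np.ndarray | float) -> np.ndarray | float:
        tau = np.asarray(tau, dtype=float)
        out = np.interp(tau, self.tau, self.T)
        out = np.where(tau > self.tau[-1], np.nan, out)
        return out if out.ndim else float(out)

    @property
    def tau_final(self) -> float:
        return float(self.tau[-1])


@dataclass
class DehydrationTrajectory:
    """Sampled single-cell dehydration trajectory on a temperature grid."""

    params: CellParams
    protocol: CoolingProtocol
    t: np.ndarray
    T: np.ndarray
    V: np.ndarray
    V_w: np.ndarray
    n_w: np.ndarray
    x_w: np.ndarray
    phi_s: np.ndarray
    Tf: np.ndarray
    eta: np.ndarray
    Ji: np.ndarray
    tau: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t, "T": self.T, "V": self.V, "V_w": self.V_w,
                "x_w": self.x_w, "Tf": self.Tf, "eta": self.eta,
                "Ji": self.Ji, "tau": self.tau,
            }
        )

    def tau_map(self) -> TauMap:
        return TauMap(t=self.t.copy(), T=self.T.copy(), tau=self.tau.copy())

    @property
    def retained_water_fraction(self) -> float:
        """Final water volume over initial water volume (plateau value)."""
        return float(self.V_w[-1] / self.V_w[0])

    def state_at(self, index: int) -> CellThermoState:
        return CellThermoState(
            V=float(self.V[index]), V_w=float(self.V_w[index]),
            n_w=float(self.n_w[index]), x_w=float(self.x_w[index]),
            phi_s=float(self.phi_s[index]), Tf=float(self.Tf[index]),
            eta=float(self.eta[index]), Ji=float(self.Ji[index]),
            tau=float(self.tau[index]),
        )

    def volume_at_time(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.interp(t, self.t, self.V)

    def water_at_time(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.interp(t, self.t, self.V_w)


# Fraction of V_iso below which the residual water is treated as exhausted;
# guards the logarithmic singularity of the transport ODE.
_DEHYDRATION_FLOOR = 1e-6


def nucleation_rate(
    params: CellParams,
    state: CellThermoState | None = None,
    T: float | None = None,
    *,
    eta: float | None = None,
    Tf: float | None = None,
) -> float:
    """Spontaneous intracellular ice nucleation rate J_i(T) [1/s].

    Diffusion-limited heterogeneous nucleation:

        J_i = A Omega0 (eta0/eta) (T/Tf0)^(1/2)
              exp[-kappa0 / (T^3 (Tf - T)^2) * (Tf/Tf0)^4],

    where eta0 is the cytoplasm viscosity at isotonic composition and Tf0,
    and Tf the current freezing point of the (dehydrating) cytoplasm, which
    also plays the role of the melting temperature in the supercooling term.
    Returns 0 when the cell is not supercooled (T >= Tf).

    Either ``state`` (with fields eta and Tf) or the keyword pair
    ``eta``/``Tf`` must be supplied alongside ``T``.
    """
    if state is not None:
        eta, Tf = state.eta, state.Tf
    if T is None or eta is None or Tf is None:
        raise BiophysicsError("nucleation_rate needs T plus (state or eta and Tf)")
    if T >= Tf:
        return 0.0
    eta0 = cytoplasm_viscosity(params.v_b, params.Tf0, params.phi_hydro)
    A_m2 = params.A * 1e-12
    pref = A_m2 * params.Omega0 * (eta0 / eta) * math.sqrt(T / params.Tf0)
    expo = -(params.kappa0 / (T**3 * (Tf - T) ** 2)) * (Tf / params.Tf0) ** 4
    return pref * math.exp(expo)


def integrate_dehydration(
    params: CellParams,
    protocol: CoolingProtocol,
    grid_step: float = 0.05,
    rtol: float = 1e-8,
    atol: float = 1e-6,
) -> DehydrationTrajectory:
    """Integrate the water-transport ODE over a linear cooling protocol.

    The ODE is solved in temperature with an adaptive explicit Runge-Kutta
    scheme and sampled on a uniform temperature grid of ``grid_step`` K.
    Once the residual water volume falls below 1e-6 of the isotonic cell
    volume the cell is considered fully dehydrated and its state is held
    (this guards the logarithmic singularity at V -> V_b).  Derived fields
    (x_w, Tf, eta, J_i) and the cumulative clock tau (composite trapezoid
    over dimensional time) are evaluated on the same grid.
    """
    V_b = params.V_b
    floor = V_b + _DEHYDRATION_FLOOR * params.V_iso

    def rhs(T: float, y: np.ndarray) -> list[float]:
        V = y[0]
        if V <= floor:
            return [0.0]
        return [water_transport_rhs(params, V, T, protocol.B)]

    n = int(math.ceil((protocol.T0 - protocol.T_end) / grid_step)) + 1
    T_grid = np.linspace(protocol.T0, protocol.T_end, n)
    sol = solve_ivp(
        rhs,
        (protocol.T0, protocol.T_end),
        [params.V_iso],
        t_eval=T_grid,
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"dehydration integration failed: {sol.message}")

    V = np.maximum(sol.y[0], floor)
    V_w = V - V_b
    n_w = V_w / params.v_w
    x_w = mole_fraction_water(n_w, params.n_s)
    Tf = freezing_point(params, x_w)
    phi_s = 1.0 - V_w / V
    eta = cytoplasm_viscosity(phi_s, T_grid, params.phi_hydro)

    Ji = np.array(
        [
            nucleation_rate(params, T=float(T_grid[i]), eta=float(eta[i]), Tf=float(Tf[i]))
            for i in range(len(T_grid))
        ]
    )
    t = np.asarray(protocol.time_of(T_grid), dtype=float)
    tau = tau_of_time(t, Ji)

    return DehydrationTrajectory(
        params=params, protocol=protocol, t=t, T=T_grid, V=V, V_w=V_w,
        n_w=n_w, x_w=x_w, phi_s=phi_s, Tf=Tf, eta=eta, Ji=Ji, tau=tau,
    )


def tau_of_time(t: Sequence[float] | np.ndarray, Ji: Sequence[float] | np.ndarray) -> np.ndarray:
    """Cumulative non-dimensional time tau(t) = int_0^t J_i dt.

    Composite trapezoid on the sample points; tau[0] = 0 and the result is
    nondecreasing for nonnegative rates.
    """
    t = np.asarray(t, dtype=float)
    Ji = np.asarray(Ji, dtype=float)
    if t.ndim != 1 or t.shape != Ji.shape:
        raise BiophysicsError("t and Ji must be 1-D arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise BiophysicsError("time samples must be strictly increasing")
    if np.any(Ji < 0):
        raise BiophysicsError("rates must be nonnegative")
    return np.concatenate(([0.0], cumulative_trapezoid(Ji, t)))
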