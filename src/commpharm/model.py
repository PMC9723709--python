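"""Consumer-resource dynamics with passive drug partitioning.

The model tracks ``n`` microbial species competing for a single carbon
source ``C`` while exposed to a bacteriostatic drug. Each species ``j``
carries an internal drug pool ``A_j`` that exchanges with the shared
environmental pool ``A_e`` by Fick's first law in its well-mixed form
(flux proportional to the concentration difference, coefficient
``phi_j`` per unit biomass). Growth follows Monod kinetics on carbon,
scaled by a Hill inhibition factor of the internal drug concentration:

    dS_j/dt = mu_bar_j * C/(K_j + C) * y_j * S_j * 1/(1 + (A_j*kappa_j)**alpha)
    dA_j/dt = -d*A_j + phi_j*(A_e - A_j)*S_j
    dA_e/dt = -d*A_e - sum_j phi_j*(A_e - A_j)*S_j
    dC/dt   = -sum_j mu_bar_j * C/(K_j + C) * S_j

Units: biomass in OD units, carbon in mg/mL, drug in ug/mL, time in h.
``phi`` is an effective per-biomass exchange rate (1/OD/h) so every drug
term is in ug/mL/h. There is no death or lysis term: densities are
nondecreasing,
carbon is nonincreasing, and with drug decay rate ``d`` the total drug
obeys the exact balance ``A_e + sum_j A_j = A_0 * exp(-d*t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SpeciesParams",
    "ExperimentParams",
    "Trajectory",
    "IntegrationError",
    "NegativeStateError",
    "monod_uptake",
    "growth_rate",
    "hill_inhibition",
    "derivatives",
    "simulate",
    "rk4_reference",
]

#: Largest negative excursion (per state component) treated as round-off
#: inside the right-hand side; anything more negative raises.
_NEG_GUARD = 1e-7


class IntegrationError(RuntimeError):
    """The ODE solver failed to converge for the given parameter set."""


class NegativeStateError(ValueError):
    """A state component went negative beyond the round-off guard."""


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species constants.

    Parameters
    ----------
    name : str
        Identifier used in trajectories and output tables.
    mu_bar : float
        Maximal carbon uptake rate, mg/OD/h.
    K : float
        Half-saturation constant for carbon, mg/mL. The affinity of the
        species for carbon is 1/K.
    y : float
        Biomass yield, OD per mg of carbon.
    kappa : float
        Drug affinity, mL/ug. The half-inhibitory internal concentration
        is A_50 = 1/kappa; kappa = 0 encodes total insensitivity.
    phi : float
        Drug diffusion (exchange) coefficient per unit biomass, 1/OD/h.
        Larger phi means faster equilibration of the internal drug pool
        with the environment; the half-exchange time at biomass S is
        ln(2)/(phi*S).
    S0 : float
        Inoculum density, OD.
    """

    name: str
    mu_bar: float
    K: float
    y: float
    kappa: float
    phi: float
    S0: float

    def __post_init__(self) -> None:
        for attr in ("mu_bar", "K", "y", "phi", "S0"):
            if not getattr(self, attr) > 0:
                raise ValueError(f"{self.name}: {attr} must be > 0")
        if self.kappa < 0:
            raise ValueError(f"{self.name}: kappa must be >= 0")

    @property
    def a50(self) -> float:
        """Half-inhibitory internal drug concentration, ug/mL (inf if kappa=0)."""
        return np.inf if self.kappa == 0 else 1.0 / self.kappa


@dataclass(frozen=True)
class ExperimentParams:
    """Shared constants for one culture scenario.

    ``species`` lists the community members (n >= 1); ``d`` is the
    abiotic drug decay rate (1/h), ``alpha`` the Hill coefficient,
    ``A0`` the initial environmental drug (ug/mL), ``C0`` the initial
    carbon (mg/mL) and ``t_end`` the incubation horizon in hours.
    """

    species: tuple[SpeciesParams, ...]
    d: float = 1e-4
    alpha: float = 2.0
    A0: float = 2.0
    C0: float = 2.0
    t_end: float = 24.0

    def __post_init__(self) -> None:
        if isinstance(self.species, SpeciesParams):
            object.__setattr__(self, "species", (self.species,))
        else:
            object.__setattr__(self, "species", tuple(self.species))
        if len(self.species) < 1:
            raise ValueError("at least one species required")
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate species names: {names}")
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if self.A0 < 0:
            raise ValueError("A0 must be >= 0")
        if not self.C0 > 0:
            raise ValueError("C0 must be > 0")
        if not self.t_end > 0:
            raise ValueError("t_end must be > 0")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(sp.name for sp in self.species)

    def with_dose(self, A0: float) -> "ExperimentParams":
        """Same scenario with a different initial drug concentration."""
        return replace(self, A0=A0)

    def subset(self, *names: str) -> "ExperimentParams":
        """Scenario restricted to the named species (e.g. a pure culture)."""
        keep = [sp for sp in self.species if sp.name in names]
        missing = set(names) - {sp.name for sp in keep}
        if missing:
            raise KeyError(f"unknown species: {sorted(missing)}")
        return replace(self, species=tuple(keep))

    def initial_state(self) -> np.ndarray:
        """Packed state [S_1..S_n, A_1..A_n, A_e, C] at t = 0."""
        n = self.n_species
        y0 = np.zeros(2 * n + 2)
        y0[:n] = [sp.S0 for sp in self.species]
        y0[2 * n] = self.A0
        y0[2 * n + 1] = self.C0
        return y0


@dataclass
class Trajectory:
    """Time-indexed solution of one scenario.

    ``S`` and ``A`` have shape (n_species, n_times); ``A_e`` and ``C``
    shape (n_times,). Species order matches ``params.species``.
    """

    times: np.ndarray
    S: np.ndarray
    A: np.ndarray
    A_e: np.ndarray
    C: np.ndarray
    params: ExperimentParams = field(repr=False)

    def species_index(self, name: str) -> int:
        try:
            return self.params.names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def endpoint_density(self, name: str) -> float:
        """Terminal density of one species, OD."""
        return float(self.S[self.species_index(name), -1])

    def drug_mass_error(self) -> float:
        """Max absolute deviation from A_e + sum A_j = A0*exp(-d t)."""
        total = self.A_e + self.A.sum(axis=0)
        expected = self.params.A0 * np.exp(-self.params.d * self.times)
        return float(np.max(np.abs(total - expected)))

    def carbon_biomass_total(self) -> np.ndarray:
        """C(t) + sum_j S_j(t)/y_j, constant when inhibition is absent."""
        ys = np.array([sp.y for sp in self.params.species])
        return self.C + (self.S / ys[:, None]).sum(axis=0)

    def to_frame(self, wide: bool = False):
        """Long (time, variable, species, value) or wide DataFrame."""
        import pandas as pd

        names = self.params.names
        if wide:
            data = {"time_h": self.times}
            for i, nm in enumerate(names):
                data[f"S_{nm}"] = self.S[i]
                data[f"A_{nm}"] = self.A[i]
            data["A_e"] = self.A_e
            data["C"] = self.C
            return pd.DataFrame(data)
        rows = []
        for i, nm in enumerate(names):
            rows.append(pd.DataFrame({"time_h": self.times, "variable": "S",
                                      "species": nm, "value": self.S[i]}))
            rows.append(pd.DataFrame({"time_h": self.times, "variable": "A",
                                      "species": nm, "value": self.A[i]}))
        rows.append(pd.DataFrame({"time_h": self.times, "variable": "A_e",
                                  "species": "", "value": self.A_e}))
        rows.append(pd.DataFrame({"time_h": self.times, "variable": "C",
                                  "species": "", "value": self.C}))
        return pd.concat(rows, ignore_index=True)


def monod_uptake(C, sp: SpeciesParams):
    """Carbon uptake rate mu_bar*C/(K+C), mg/OD/h. Saturating in C."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("carbon concentration must be >= 0")
    out = sp.mu_bar * C / (sp.K + C)
    return float(out) if out.ndim == 0 else out


def growth_rate(C, sp: SpeciesParams):
    """Specific growth rate G(C) = U(C)*y, 1/h."""
    out = np.asarray(monod_uptake(C, sp)) * sp.y
    return float(out) if out.ndim == 0 else out


def hill_inhibition(A_j, kappa: float, alpha: float):
    """Growth inhibition factor 1/(1 + (A_j*kappa)**alpha), in [0, 1].

    Equals 1 at A_j = 0 and 1/2 at the half-inhibitory concentration
    A_50 = 1/kappa. ``kappa = 0`` returns exactly 1 (insensitive).
    """
    A_j = np.asarray(A_j, dtype=float)
    if np.any(A_j < 0):
        raise ValueError("internal drug concentration must be >= 0")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    if kappa == 0:
        out = np.ones_like(A_j)
    else:
        out = 1.0 / (1.0 + (A_j * kappa) ** alpha)
    return float(out) if out.ndim == 0 else out


def _unpack(state: np.ndarray, n: int):
    return state[:n], state[n:2 * n], state[2 * n], state[2 * n + 1]


def derivatives(state: Sequence[float], params: ExperimentParams,
                guard: float = _NEG_GUARD) -> np.ndarray:
    """Time derivatives of the packed state [S_j, A_j, A_e, C].

    Small negative components (|x| <= ``guard``) are treated as zero;
    larger excursions raise :class:`NegativeStateError` rather than
    being silently clipped.
    """
    state = np.asarray(state, dtype=float)
    n = params.n_species
    if state.shape != (2 * n + 2,):
        raise ValueError(
            f"state has shape {state.shape}, expected ({2 * n + 2},) "
            f"for {n} species")
    if np.any(state < -guard):
        worst = float(state.min())
        raise NegativeStateError(
            f"state component {worst:.3e} below -{guard:g}")
    state = np.maximum(state, 0.0)
    S, A, A_e, C = _unpack(state, n)

    mu = np.array([sp.mu_bar for sp in params.species])
    K = np.array([sp.K for sp in params.species])
    y = np.array([sp.y for sp in params.species])
    kap = np.array([sp.kappa for sp in params.species])
    phi = np.array([sp.phi for sp in params.species])

    uptake = mu * C / (K + C)                       # mg/OD/h
    inhib = np.where(kap > 0, 1.0 / (1.0 + (A * kap) ** params.alpha), 1.0)
    flux = phi * (A_e - A) * S                      # ug/mL/h into cells

    dS = uptake * y * S * inhib
    dA = -params.d * A + flux
    dAe = -params.d * A_e - flux.sum()
    dC = -(uptake * S).sum()
    return np.concatenate([dS, dA, [dAe, dC]])


def _grid(params: ExperimentParams, cadence_min: float) -> np.ndarray:
    n_steps = int(round(params.t_end * 60.0 / cadence_min))
    return np.linspace(0.0, params.t_end, n_steps + 1)


def simulate(params: ExperimentParams, *, cadence_min: float = 20.0,
             t_eval: np.ndarray | None = None, method: str = "LSODA",
             rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate the scenario and sample it on a uniform grid.

    The default grid mirrors a plate reader's 20-minute cadence. The
    integrator is adaptive and stiff-capable (LSODA); the dynamics turn
    mildly stiff near carbon exhaustion.
    """
    if t_eval is None:
        t_eval = _grid(params, cadence_min)
    t_eval = np.asarray(t_eval, dtype=float)

    sol = solve_ivp(
        lambda t, y: derivatives(y, params),
        (0.0, params.t_end), params.initial_state(),
        method=method, t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(
            f"integrator failed ({sol.message}) for A0={params.A0}, "
            f"species={params.names}")
    ys = sol.y
    if ys.min() < -_NEG_GUARD:
        raise NegativeStateError(
            f"solution reached {ys.min():.3e} (< -{_NEG_GUARD:g})")
    ys = np.maximum(ys, 0.0)
    n = params.n_species
    return Trajectory(times=sol.t, S=ys[:n], A=ys[n:2 * n],
                      A_e=ys[2 * n], C=ys[2 * n + 1], params=params)


def rk4_reference(params: ExperimentParams, dt: float = 1e-3) -> np.ndarray:
    """Terminal state from a fixed-step classical Runge-Kutta integration.

    Serves as an independent check on the adaptive solver; O(t_end/dt)
    right-hand-side evaluations, so keep ``dt`` moderate.
    """
    n_steps = int(round(params.t_end / dt))
    h = params.t_end / n_steps
    y = params.initial_state()
    f = lambda s: derivatives(s, params, guard=1e-6)
    for _ in range(n_steps):
        k1 = f(y)
        k2 = f(np.maximum(y + 0.5 * h * k1, 0.0))
        k3 = f(np.maximum(y + 0.5 * h * k2, 0.0))
        k4 = f(np.maximum(y + h * k3, 0.0))
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        y = np.maximum(y, 0.0)
    return y
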