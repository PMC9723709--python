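"""Dose-response profiles, IC90 estimation and parameter sweeps.

The IC90 is the drug concentration that inhibits 90% of the growth
observed without drug at the assay endpoint (24 h by default): the
smallest ``A0`` at which the focal species' terminal density, normalised
to the zero-drug terminal density of the *same* culture condition, falls
to 0.10. Grid-based curves interpolate the crossing linearly; model
IC90s can be refined by bisection on the simulator.

Sweeps reproduce the pure-vs-mixed comparisons: the focal species'
IC90 as one growth parameter (K, mu_bar or y) varies, alone and in 1:1
co-culture with a fixed competitor that is either equally drug-sensitive
or drug-tolerant (reduced kappa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import trapezoid

from .model import ExperimentParams, SpeciesParams, Trajectory, simulate

__all__ = [
    "DoseResponse",
    "SweepResult",
    "DrugContent",
    "DegenerateGrowthError",
    "default_gradient",
    "dose_response_curve",
    "ic90",
    "model_ic90",
    "sweep_ic90",
    "inoculum_effect",
    "drug_content_per_cell",
    "carbon_uptake_per_species",
]

INHIBITION_LEVEL = 0.10  # normalised-density threshold defining the IC90


class DegenerateGrowthError(ValueError):
    """Zero-drug growth too small to normalise a dose-response curve."""


@dataclass
class DoseResponse:
    """Endpoint densities of one focal species along a drug gradient."""

    concentrations: np.ndarray
    endpoint_density: np.ndarray
    normalized: np.ndarray
    ic90: float | None = None
    #: True when the normalised curve crosses 0.10 more than once.
    nonmonotone: bool = False
    focal: str = ""

    def density_at(self, concentration: float) -> float:
        """Endpoint density linearly interpolated at a concentration."""
        return float(np.interp(concentration, self.concentrations,
                               self.endpoint_density))


@dataclass
class SweepResult:
    """Focal-species IC90 along one parameter grid, pure vs mixed."""

    parameter: str
    values: np.ndarray
    ic90_pure: np.ndarray
    ic90_mixed: np.ndarray | None
    competitor_mode: str


@dataclass
class DrugContent:
    """Per-cell drug content of the focal species across conditions.

    ``content_*`` is the focal species' internal drug pool divided by
    its density at the endpoint (ug/mL per OD), every condition dosed at
    the same reference concentration. ``difference`` is pure minus
    mixed: positive means more drug per focal cell in pure culture.
    """

    reference_dose: float
    content_pure: float
    content_mixed: float
    difference: float
    dose_policy: str = "pure-ic90"


def default_gradient(kappa: float, n: int = 60, lo_factor: float = 0.01,
                     hi_factor: float = 100.0) -> np.ndarray:
    """Zero plus ``n`` geometric concentrations bracketing A_50 = 1/kappa."""
    if kappa <= 0:
        raise ValueError("default gradient needs kappa > 0")
    a50 = 1.0 / kappa
    return np.concatenate([[0.0],
                           np.geomspace(lo_factor * a50, hi_factor * a50, n)])


def dose_response_curve(params: ExperimentParams, focal: str,
                        gradient: np.ndarray | None = None,
                        refine: bool = False) -> DoseResponse:
    """Simulate the scenario once per gradient concentration.

    The first gradient entry must be 0 (the normalisation reference).
    With ``refine`` the IC90 crossing is sharpened by bisection on the
    simulator instead of linear interpolation alone.
    """
    if gradient is None:
        sp = params.species[[s.name for s in params.species].index(focal)]
        gradient = default_gradient(sp.kappa)
    gradient = np.asarray(gradient, dtype=float)
    if gradient[0] != 0.0:
        raise ValueError("gradient must start at 0 (normalisation reference)")
    if np.any(np.diff(gradient) <= 0):
        raise ValueError("gradient must be strictly increasing")

    endpoint = np.array([
        simulate(params.with_dose(a)).endpoint_density(focal)
        for a in gradient])
    s0_inoc = dict(zip(params.names, (sp.S0 for sp in params.species)))[focal]
    if endpoint[0] <= s0_inoc * (1 + 1e-6):
        raise DegenerateGrowthError(
            f"zero-drug endpoint {endpoint[0]:.3g} did not exceed the "
            f"inoculum {s0_inoc:.3g}; cannot normalise")
    normalized = endpoint / endpoint[0]
    dr = DoseResponse(concentrations=gradient, endpoint_density=endpoint,
                      normalized=normalized, focal=focal)
    dr.ic90 = ic90(dr)
    if refine and dr.ic90 is not None:
        dr.ic90 = model_ic90(params, focal, bracket=_bracket(dr))
    return dr


def _bracket(dr: DoseResponse) -> tuple[float, float]:
    below = np.nonzero(dr.normalized <= INHIBITION_LEVEL)[0]
    i = below[0]
    return float(dr.concentrations[i - 1]), float(dr.concentrations[i])


def ic90(dr: DoseResponse) -> float | None:
    """First crossing of normalised density through 0.10, interpolated.

    Returns None when the curve never reaches 0.10. Multiple crossings
    (non-monotone curve) return the first and set ``dr.nonmonotone``.
    """
    nz = dr.normalized
    below = nz <= INHIBITION_LEVEL
    if not below.any():
        return None
    crossings = np.nonzero(~below[:-1] & below[1:])[0]
    if len(crossings) > 1 or (below[:-1] & ~below[1:]).any():
        dr.nonmonotone = True
        warnings.warn(
            f"dose-response for {dr.focal or 'focal species'} crosses "
            f"{INHIBITION_LEVEL} more than once; using first crossing",
            stacklevel=2)
    i = int(np.nonzero(below)[0][0])
    if i == 0:  # already inhibited at zero drug: degenerate but defined
        return float(dr.concentrations[0])
    c0, c1 = dr.concentrations[i - 1], dr.concentrations[i]
    n0, n1 = nz[i - 1], nz[i]
    if n0 == n1:
        return float(c1)
    return float(c0 + (n0 - INHIBITION_LEVEL) / (n0 - n1) * (c1 - c0))


def model_ic90(params: ExperimentParams, focal: str,
               bracket: tuple[float, float] | None = None,
               tol: float = 1e-4, max_iter: int = 80) -> float | None:
    """IC90 by bisection on the simulator, |normalised - 0.10| < ``tol``.

    Without a bracket the upper bound starts at A_50 of the focal
    species and doubles until the curve is driven below 0.10 (returns
    None past 2^30 * A_50 — effectively uninhibitable).
    """
    s0 = simulate(params.with_dose(0.0)).endpoint_density(focal)
    idx = params.names.index(focal)
    if s0 <= params.species[idx].S0 * (1 + 1e-6):
        raise DegenerateGrowthError("no zero-drug growth to normalise")

    def f(a: float) -> float:
        return simulate(params.with_dose(a)).endpoint_density(focal) / s0

    if bracket is None:
        lo, hi = 0.0, params.species[idx].a50
        if not np.isfinite(hi):
            return None
        n_expand = 0
        while f(hi) > INHIBITION_LEVEL:
            lo, hi = hi, 2.0 * hi
            n_expand += 1
            if n_expand > 30:
                return None
    else:
        lo, hi = bracket
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        v = f(mid)
        if abs(v - INHIBITION_LEVEL) < tol:
            return mid
        if v > INHIBITION_LEVEL:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _with_focal(base: ExperimentParams, focal_sp: SpeciesParams,
                competitor: SpeciesParams | None) -> ExperimentParams:
    species = (focal_sp,) if competitor is None else (focal_sp, competitor)
    return replace(base, species=species)


def _competitor(base: ExperimentParams, mode: str,
                resistant_factor: float) -> SpeciesParams | None:
    """Fixed competitor derived from the scenario's second species."""
    if mode == "none":
        return None
    ref = base.species[1] if base.n_species > 1 else base.species[0]
    comp = replace(ref, name="competitor") if ref.name == base.species[0].name \
        else ref
    if mode == "sensitive":
        return comp
    if mode == "resistant":
        return replace(comp, kappa=comp.kappa * resistant_factor)
    raise ValueError(f"unknown competitor mode {mode!r}")


def sweep_ic90(base: ExperimentParams, parameter: str, grid: np.ndarray,
               competitor_mode: str = "sensitive",
               resistant_factor: float = 0.01) -> SweepResult:
    """Focal-species IC90 as one growth parameter varies.

    The first species of ``base`` is the focal one; the competitor is
    held fixed (its own parameters never swept). ``parameter`` is one of
    ``K``, ``mu_bar``, ``y``. Grid points whose IC90 is undefined are
    recorded as NaN, never interpolated.
    """
    if parameter not in ("K", "mu_bar", "y"):
        raise ValueError(f"cannot sweep {parameter!r}")
    grid = np.asarray(grid, dtype=float)
    focal0 = base.species[0]
    comp = _competitor(base, competitor_mode, resistant_factor)

    pure, mixed = [], []
    for v in grid:
        focal_sp = replace(focal0, **{parameter: float(v)})
        pure.append(model_ic90(_with_focal(base, focal_sp, None),
                               focal_sp.name))
        if comp is not None:
            mixed.append(model_ic90(_with_focal(base, focal_sp, comp),
                                    focal_sp.name))
    to_arr = lambda xs: np.array([np.nan if x is None else x for x in xs])
    return SweepResult(parameter=parameter, values=grid,
                       ic90_pure=to_arr(pure),
                       ic90_mixed=to_arr(mixed) if comp is not None else None,
                       competitor_mode=competitor_mode)


def inoculum_effect(base: ExperimentParams, S0_grid: np.ndarray):
    """Single-species IC90 and endpoint density across inoculum sizes.

    Larger inocula report higher inhibitory concentrations (the inoculum
    effect); the IC90-vs-density profile is direct but non-linear and
    changes if cultures are given time to reach equilibrium.

    Returns (S0_grid, ic90s, densities) where ``densities`` is the
    endpoint density at each inoculum's own IC90.
    """
    if base.n_species != 1:
        raise ValueError("inoculum effect is a single-species diagnostic")
    S0_grid = np.asarray(S0_grid, dtype=float)
    ic90s, densities = [], []
    for s0 in S0_grid:
        params = replace(base, species=(replace(base.species[0], S0=float(s0)),))
        est = model_ic90(params, params.species[0].name)
        ic90s.append(np.nan if est is None else est)
        if est is None:
            densities.append(np.nan)
        else:
            densities.append(simulate(params.with_dose(est))
                             .endpoint_density(params.species[0].name))
    return S0_grid, np.array(ic90s), np.array(densities)


def drug_content_per_cell(params: ExperimentParams, focal: str = "S1",
                          dose_policy: str = "pure-ic90") -> DrugContent:
    """Endpoint drug pool per unit focal biomass, pure vs 1:1 mixed.

    ``params`` describes the mixed scenario (focal species first); the
    pure condition drops the neighbours. Under the default policy both
    conditions are dosed at the focal species' pure-culture IC90, so the
    difference isolates how neighbours redistribute a fixed exposure:
    positive difference = more drug per focal cell in pure culture.
    ``dose_policy="own-ic90"`` doses each condition at its own IC90
    instead.
    """
    if params.n_species < 2:
        raise ValueError("params must include at least one neighbour")
    pure = params.subset(focal)
    ic_pure = model_ic90(pure, focal)
    if ic_pure is None:
        raise DegenerateGrowthError("pure-culture IC90 undefined")
    if dose_policy == "pure-ic90":
        dose_pure = dose_mixed = ic_pure
    elif dose_policy == "own-ic90":
        ic_mixed = model_ic90(params, focal)
        if ic_mixed is None:
            raise DegenerateGrowthError("mixed-culture IC90 undefined")
        dose_pure, dose_mixed = ic_pure, ic_mixed
    else:
        raise ValueError(f"unknown dose policy {dose_policy!r}")

    def content(par: ExperimentParams, dose: float) -> float:
        tr = simulate(par.with_dose(dose))
        i = tr.species_index(focal)
        return float(tr.A[i, -1] / tr.S[i, -1])

    c_pure = content(pure, dose_pure)
    c_mixed = content(params, dose_mixed)
    return DrugContent(reference_dose=dose_pure, content_pure=c_pure,
                       content_mixed=c_mixed, difference=c_pure - c_mixed,
                       dose_policy=dose_policy)


def carbon_uptake_per_species(traj: Trajectory) -> dict[str, float]:
    """Cumulative carbon consumed per species, mg/mL, by quadrature.

    Integrates U_j(C(t)) * S_j(t) on the output grid; the totals sum to
    the carbon depleted, C(0) - C(t_end), within quadrature error.
    """
    params = traj.params
    out = {}
    for i, sp in enumerate(params.species):
        rate = sp.mu_bar * traj.C / (sp.K + traj.C) * traj.S[i]
        out[sp.name] = float(trapezoid(rate, traj.times))
    return out
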