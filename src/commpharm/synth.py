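"""Synthetic plate-reader datasets with known ground truth.

Simulates the community model for every (culture composition, drug
concentration) condition of a plate design, then layers a measurement
model on top: OD600 reads total biomass, each labelled strain's
fluorescence channel reads its own biomass divided by a constant
OD-per-fluorescence ratio, and every reading carries multiplicative
lognormal noise on the biological signal plus an additive Gaussian read
error and a constant blank level. Blank wells contain medium only.

The generator mirrors the assay geometry it emulates: 12 concentrations
(zero plus 11 drug levels, one column each of a 96-well plate) with 8
technical replicates per concentration, read every 20 minutes for 24 h.
Every stochastic call takes an explicit seed; the noise-free truth
(trajectories, model IC90s, calibration ratios) is returned alongside
the plate so each analysis stage can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np

from .model import ExperimentParams, SpeciesParams, Trajectory, simulate
from .plate import PlateTimeSeries, WellMeta
from .scenarios import RESISTANT_KAPPA_FACTOR, table1_species
from . import dose_response as dr_mod

__all__ = [
    "NoiseModel",
    "PlateDesign",
    "GroundTruth",
    "generate_plate",
    "scenario_presets",
    "preset_gradient",
]

#: Default per-channel additive read noise (instrument units).
_SIGMA_ADD = {"OD600": 0.003, "YFP": 5.0, "CFP": 5.0}
#: Default per-channel blank (medium) level.
_BLANK = {"OD600": 0.04, "YFP": 40.0, "CFP": 40.0}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: lognormal on signal, Gaussian read error."""

    sigma_mult: float = 0.05
    sigma_add: Mapping[str, float] = field(
        default_factory=lambda: dict(_SIGMA_ADD))
    blank_level: Mapping[str, float] = field(
        default_factory=lambda: dict(_BLANK))

    def __post_init__(self) -> None:
        if self.sigma_mult < 0 or any(v < 0 for v in self.sigma_add.values()):
            raise ValueError("noise magnitudes must be >= 0")

    def silent(self) -> "NoiseModel":
        """Same blanks, zero noise — for generator-analyser contracts."""
        return replace(self, sigma_mult=0.0,
                       sigma_add={k: 0.0 for k in self.sigma_add})


@dataclass(frozen=True)
class PlateDesign:
    """One synthetic plate: community, gradient, layout and noise."""

    species_a: SpeciesParams
    species_b: SpeciesParams | None
    gradient: tuple[float, ...]
    compositions: tuple[str, ...]           # subset of {pure-A, pure-B, mixed}
    seed: int
    replicates: int = 8
    n_blanks: int = 8
    ratios: Mapping[str, float | None] = field(default_factory=dict)
    noise: NoiseModel = field(default_factory=NoiseModel)
    d: float = 1e-4
    alpha: float = 2.0
    C0: float = 2.0
    duration_h: float = 24.0
    cadence_min: float = 20.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        g = tuple(float(c) for c in self.gradient)
        if not g or g[0] != 0.0 or any(b <= a for a, b in zip(g, g[1:])):
            raise ValueError("gradient must start at 0 and increase")
        object.__setattr__(self, "gradient", g)
        needs_b = {"pure-B", "mixed"} & set(self.compositions)
        if needs_b and self.species_b is None:
            raise ValueError(
                f"compositions {sorted(needs_b)} need a second species")
        unknown = set(self.compositions) - {"pure-A", "pure-B", "mixed"}
        if unknown:
            raise ValueError(f"unknown compositions {sorted(unknown)}")

    def scenario(self, composition: str) -> ExperimentParams:
        species = {"pure-A": (self.species_a,),
                   "pure-B": (self.species_b,),
                   "mixed": (self.species_a, self.species_b)}[composition]
        return ExperimentParams(species=species, d=self.d, alpha=self.alpha,
                                A0=0.0, C0=self.C0, t_end=self.duration_h)

    def strain_for(self, composition: str) -> tuple[str, ...]:
        return tuple(sp.name for sp in self.scenario(composition).species)


@dataclass
class GroundTruth:
    """Noise-free quantities underlying a generated plate."""

    trajectories: dict[tuple[str, float], Trajectory]
    ic90_grid: dict[tuple[str, str], float | None]
    ic90_model: dict[tuple[str, str], float | None]
    ratios: dict[str, float | None]
    design: PlateDesign = field(repr=False)


@lru_cache(maxsize=512)
def _sim(params: ExperimentParams, cadence_min: float) -> Trajectory:
    return simulate(params, cadence_min=cadence_min)


def _truth(design: PlateDesign, refine: bool) -> GroundTruth:
    trajectories: dict[tuple[str, float], Trajectory] = {}
    for comp in design.compositions:
        base = design.scenario(comp)
        for conc in design.gradient:
            trajectories[(comp, conc)] = _sim(base.with_dose(conc),
                                              design.cadence_min)
    grad = np.array(design.gradient)
    ic90_grid: dict[tuple[str, str], float | None] = {}
    ic90_model: dict[tuple[str, str], float | None] = {}
    for comp in design.compositions:
        base = design.scenario(comp)
        for strain in design.strain_for(comp):
            label = ("pure" if comp.startswith("pure") else "mixed")
            end = np.array([trajectories[(comp, c)].endpoint_density(strain)
                            for c in design.gradient])
            curve = dr_mod.DoseResponse(
                concentrations=grad, endpoint_density=end,
                normalized=end / end[0], focal=strain)
            ic90_grid[(strain, label)] = dr_mod.ic90(curve)
            if refine:
                ic90_model[(strain, label)] = dr_mod.model_ic90(base, strain)
    return GroundTruth(trajectories=trajectories, ic90_grid=ic90_grid,
                       ic90_model=ic90_model,
                       ratios=dict(design.ratios), design=design)


def generate_plate(design: PlateDesign,
                   refine_truth: bool = False
                   ) -> tuple[PlateTimeSeries, GroundTruth]:
    """Simulate a plate design and emit measurements plus ground truth.

    With ``refine_truth`` the true model IC90s are additionally sharpened
    by bisection on the simulator (slower); the gradient-interpolated
    truth is always stored. Fixed seed => bit-identical plates.
    """
    truth = _truth(design, refine=refine_truth)
    rng = np.random.default_rng(design.seed)
    noise = design.noise
    times = truth.trajectories[
        (design.compositions[0], design.gradient[0])].times

    channels = ["OD600"]
    strain_channels: dict[str, str] = {}
    labelled = [s for s, r in design.ratios.items() if r is not None]
    for strain, channel in zip(labelled, ("YFP", "CFP")):
        channels.append(channel)
        strain_channels[strain] = channel

    wells, metadata, rows = [], {}, []

    def read(signal: np.ndarray, channel: str) -> np.ndarray:
        out = signal * np.exp(rng.normal(0.0, noise.sigma_mult,
                                         size=signal.shape)) \
            if noise.sigma_mult > 0 else signal.astype(float).copy()
        out += noise.blank_level.get(channel, 0.0)
        sd = noise.sigma_add.get(channel, 0.0)
        if sd > 0:
            out += rng.normal(0.0, sd, size=signal.shape)
        return out

    for comp in design.compositions:
        strains = design.strain_for(comp)
        for ci, conc in enumerate(design.gradient):
            traj = truth.trajectories[(comp, conc)]
            for rep in range(1, design.replicates + 1):
                well = f"{comp}-c{ci:02d}-r{rep}"
                wells.append(well)
                metadata[well] = WellMeta(strains=strains,
                                          concentration=conc,
                                          replicate=rep)
                row = np.empty((len(times), len(channels)))
                row[:, 0] = read(traj.S.sum(axis=0), "OD600")
                for k, ch in enumerate(channels[1:], start=1):
                    strain = next(s for s, c in strain_channels.items()
                                  if c == ch)
                    if strain in strains:
                        i = traj.species_index(strain)
                        signal = traj.S[i] / design.ratios[strain]
                    else:
                        signal = np.zeros(len(times))
                    row[:, k] = read(signal, ch)
                rows.append(row)

    zero = np.zeros(len(times))
    for b in range(1, design.n_blanks + 1):
        well = f"blank-r{b}"
        wells.append(well)
        metadata[well] = WellMeta(strains=(), concentration=None,
                                  replicate=b, blank=True)
        rows.append(np.stack([read(zero, ch) for ch in channels], axis=1))

    plate = PlateTimeSeries(wells=wells, times=times.copy(),
                            channels=channels,
                            values=np.stack(rows), metadata=metadata,
                            strain_channels=strain_channels)
    return plate, truth


def preset_gradient(n: int = 11, lo: float = 15.0,
                    hi: float = 150.0) -> tuple[float, ...]:
    """Zero plus ``n`` geometric drug levels over one decade.

    The decade straddles the anticipated IC90 of the canonical sensitive
    species (a few times its A_50 = 10 ug/mL), the same way assay
    ranges are chosen around an expected inhibitory concentration.
    """
    return (0.0, *np.geomspace(lo, hi, n))


def scenario_presets(seed: int = 0) -> dict[str, PlateDesign]:
    """Named plate designs mirroring the pairwise competition assays.

    - ``equal-sensitivity``: focal labelled strain S1 with an equally
      sensitive unlabelled neighbour S2 (only S1 is tracked in mixed
      wells, via YFP).
    - ``resistant-neighbour``: S2's drug affinity cut 100-fold
      (operationally drug-tolerant); S2 carries CFP.
    - ``pure-only``: the focal strain alone.
    """
    s1 = table1_species("S1")
    s2 = table1_species("S2")
    s2_res = table1_species("S2",
                            kappa=s1.kappa * RESISTANT_KAPPA_FACTOR)
    grad = preset_gradient()
    return {
        "equal-sensitivity": PlateDesign(
            species_a=s1, species_b=s2, gradient=grad,
            compositions=("pure-A", "mixed"), seed=seed,
            ratios={"S1": 1e-4, "S2": None}),
        "resistant-neighbour": PlateDesign(
            species_a=s1, species_b=s2_res, gradient=grad,
            compositions=("pure-A", "pure-B", "mixed"), seed=seed,
            ratios={"S1": 1e-4, "S2": 1e-4}),
        "pure-only": PlateDesign(
            species_a=s1, species_b=None, gradient=grad,
            compositions=("pure-A",), seed=seed,
            ratios={"S1": 1e-4}),
    }
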