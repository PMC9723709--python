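"""Bundled scenarios and scenario-file I/O.

The ``table1`` scenario is the canonical parameterisation used
throughout: two phenotypically identical drug-sensitive species, each
inoculated at 1e-3 OD, competing for 2 mg/mL of carbon under 2 ug/mL of
drug. Scenario files are YAML with a ``species`` list plus the shared
constants, mapping one-to-one onto the parameter dataclasses.
"""

from __future__ import annotations

from dataclasses import asdict, replace
from pathlib import Path

import yaml

from .model import ExperimentParams, SpeciesParams

__all__ = [
    "table1_species",
    "table1",
    "resistant_pair",
    "load_scenario",
    "save_scenario",
]

# Canonical per-species constants: maximal uptake 1.25 mg/OD/h,
# half-saturation 0.5 mg/mL, yield 0.65 OD/mg, drug affinity 0.1 mL/ug
# (A_50 = 10 ug/mL), drug exchange 10 /OD/h, inoculum 1e-3 OD.
_TABLE1 = dict(mu_bar=1.25, K=0.5, y=0.65, kappa=0.1, phi=10.0, S0=1e-3)

#: Affinity fold-reduction encoding a drug-tolerant ("resistant") species.
RESISTANT_KAPPA_FACTOR = 0.01


def table1_species(name: str = "S1", **overrides) -> SpeciesParams:
    """One species with the canonical constants, fields overridable."""
    return SpeciesParams(name=name, **{**_TABLE1, **overrides})


def table1(n_species: int = 2, **overrides) -> ExperimentParams:
    """Canonical scenario: ``n_species`` identical sensitive species.

    Shared constants: drug decay 1e-4 /h, Hill coefficient 2, initial
    drug 2 ug/mL, initial carbon 2 mg/mL, 24 h horizon. Keyword
    overrides apply to the shared constants.
    """
    species = tuple(table1_species(f"S{i + 1}") for i in range(n_species))
    return ExperimentParams(species=species, **overrides)


def resistant_pair(kappa_factor: float = RESISTANT_KAPPA_FACTOR,
                   **overrides) -> ExperimentParams:
    """Sensitive focal species S1 plus a drug-tolerant neighbour S2.

    Tolerance is encoded entirely through a reduced drug affinity
    (kappa_2 = kappa_factor * kappa_1; 0 for ideal insensitivity) —
    no new model terms.
    """
    s1 = table1_species("S1")
    s2 = table1_species("S2", kappa=_TABLE1["kappa"] * kappa_factor)
    return ExperimentParams(species=(s1, s2), **overrides)


def save_scenario(params: ExperimentParams, path: str | Path) -> None:
    doc = {
        "species": [asdict(sp) for sp in params.species],
        "d": params.d, "alpha": params.alpha, "A0": params.A0,
        "C0": params.C0, "t_end": params.t_end,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scenario(path: str | Path) -> ExperimentParams:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "species" not in doc:
        raise ValueError(f"{path}: not a scenario file (no 'species' list)")
    species = tuple(SpeciesParams(**sp) for sp in doc["species"])
    shared = {k: doc[k] for k in ("d", "alpha", "A0", "C0", "t_end")
              if k in doc}
    return ExperimentParams(species=species, **shared)
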