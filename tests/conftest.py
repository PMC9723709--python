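"""Shared fixtures: canonical scenarios, synthetic plates, headline runs."""

from dataclasses import replace

import pytest

from commpharm.dose_response import drug_content_per_cell, model_ic90
from commpharm.plate import blank_correct
from commpharm.scenarios import resistant_pair, table1
from commpharm.synth import generate_plate, scenario_presets


@pytest.fixture(scope="session")
def pure_params():
    return table1(1)


@pytest.fixture(scope="session")
def mixed_params():
    return table1(2)


@pytest.fixture(scope="session")
def resistant_params():
    return resistant_pair()


@pytest.fixture(scope="session")
def headline(pure_params, mixed_params, resistant_params):
    """Model IC90s and per-cell drug contents for the canonical trio.

    One bisection-refined IC90 per condition plus the pure-vs-mixed
    drug-content comparison for both neighbour types; shared across the
    suite because each refinement costs dozens of simulations.
    """
    return {
        "ic90_pure": model_ic90(pure_params, "S1"),
        "ic90_mixed_sensitive": model_ic90(mixed_params, "S1"),
        "ic90_mixed_resistant": model_ic90(resistant_params, "S1"),
        "content_sensitive": drug_content_per_cell(mixed_params, "S1"),
        "content_resistant": drug_content_per_cell(resistant_params, "S1"),
    }


@pytest.fixture(scope="session")
def presets():
    return scenario_presets(seed=7)


@pytest.fixture(scope="session")
def noisy_equal_plate(presets):
    plate, truth = generate_plate(presets["equal-sensitivity"],
                                  refine_truth=True)
    return blank_correct(plate), truth


@pytest.fixture(scope="session")
def silent_equal_plate(presets):
    design = presets["equal-sensitivity"]
    plate, truth = generate_plate(
        replace(design, noise=design.noise.silent()))
    return blank_correct(plate), truth


@pytest.fixture(scope="session")
def silent_resistant_plate(presets):
    design = presets["resistant-neighbour"]
    plate, truth = generate_plate(
        replace(design, noise=design.noise.silent()))
    return blank_correct(plate), truth


@pytest.fixture(scope="session")
def noisy_resistant_plate(presets):
    plate, truth = generate_plate(presets["resistant-neighbour"])
    return blank_correct(plate), truth
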