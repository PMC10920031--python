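import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ottersdm import synth

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_stack():
    """A 40x40 three-covariate landscape shared by modeling tests."""
    return synth.gen_landscape(
        seed=11, n_rows=40, n_cols=40, cell_size=131.0,
        attribute_specs=[("bathymetry", "depth", 4.0),
                         ("shell_litter", "percent_cover", 4.0),
                         ("understory_kelp", "percent_cover", 4.0)])


@pytest.fixture(scope="session")
def small_domain(small_stack):
    return synth.gen_survey_design(small_stack, transect_spacing_cells=4,
                                   transect_width_cells=2)


@pytest.fixture(scope="session")
def small_species(small_stack, small_domain):
    presences, truth = synth.gen_species(
        small_stack, small_domain,
        {"bathymetry": 3.0, "shell_litter": -3.0, "understory_kelp": 0.0},
        n_presences=200, seed=5)
    return presences, truth


@pytest.fixture(scope="session")
def small_background(small_stack, small_domain):
    return synth.sample_background(small_domain, small_stack, n=400, seed=7)


@pytest.fixture(scope="session")
def small_sample(small_stack, small_species, small_background):
    """(presence_X, background_X, names) raw covariate matrices."""
    presences, _ = small_species
    names = small_stack.names
    P = small_stack.values_at_cells(presences.rows, presences.cols, names)
    B = small_stack.values_at_cells(small_background.rows,
                                    small_background.cols, names)
    return P, B, names
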