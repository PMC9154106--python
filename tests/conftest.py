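import numpy as np
import pytest

from hss_screen import EventTable, NormalizedPopulation
from hss_screen.pipeline import run_screen
from hss_screen.synthetic_data import preset_params, simulate_screen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(strain_id, green, orange, red):
    return EventTable(
        strain_id=strain_id,
        green=np.asarray(green, dtype=float),
        orange=np.asarray(orange, dtype=float),
        red=np.asarray(red, dtype=float),
    )


def make_pop(strain_id, green, orange):
    return NormalizedPopulation(
        strain_id=strain_id,
        green_norm=np.asarray(green, dtype=float),
        orange_norm=np.asarray(orange, dtype=float),
    )


@pytest.fixture(scope="session")
def recovery_screen():
    """The planted-hit recovery screen: 400 mutants (20 loss-of-spreading,
    10 gain, 10 nucleation-loss decoys), 3 parent isolates, all strains at
    the 30,000-event acquisition ceiling, seed 0."""
    screen = simulate_screen(
        400,
        seed=0,
        n_parents=3,
        n_planted={
            "loss_of_spreading": 20,
            "gain_of_spreading": 10,
            "loss_of_nucleation": 10,
        },
        params=preset_params("MAT_dREIII", n_cells=30_000),
    )
    result = run_screen(screen.manifest, screen.config, screen.tables)
    return screen, result
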