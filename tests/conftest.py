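import warnings

import numpy as np
import pytest

from fefattn import CellArchetype, TaskDesign, simulate_cell

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def null_cell():
    """A cell with no attention, drug or gain effects and Poisson-like ISIs."""
    arch = CellArchetype(
        name="null", p2t_mean_us=400.0, p2t_sd_us=0.0, base_rate_hz=20.0,
        attention_gain=1.0, drug_gain=1.0, gain_var=0.0, isi_shape=1.0,
    )
    design = TaskDesign(n_trials_per_condition=25)
    return simulate_cell(arch, design, seed=11)


@pytest.fixture(scope="session")
def modulated_cell():
    """A cell with strong attentional gain and drug suppression."""
    arch = CellArchetype(
        name="mod", p2t_mean_us=420.0, p2t_sd_us=0.0, base_rate_hz=20.0,
        attention_gain=1.5, drug_gain=0.7, gain_var=0.1,
        gain_var_attend_scale=0.5, gain_var_drug_scale=1.5, isi_shape=1.0,
    )
    design = TaskDesign(n_trials_per_condition=20)
    return simulate_cell(arch, design, seed=5)
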