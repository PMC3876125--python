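import pandas as pd
import pytest
from hypothesis import settings

import boltzlie as bl

settings.register_profile("suite", deadline=None, max_examples=50,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def noise_free_dataset():
    """10 ligands x 2 conformations x 2 poses x 2 replicates, no noise:
    dG_exp satisfies the Boltzmann-weighted model exactly at (0.42, 0.22)."""
    data = bl.generate(bl.GeneratorSpec(seed=11, replicate_noise_sd=0.0,
                                        obs_noise_sd=0.0))
    return bl.assemble_dataset(data.bound, data.free, data.experimental), \
        data.ground_truth


@pytest.fixture
def noisy_dataset():
    """Same layout with 1 kJ/mol replicate scatter and 0.5 kJ/mol
    observation noise."""
    data = bl.generate(bl.GeneratorSpec(seed=7, replicate_noise_sd=1.0,
                                        obs_noise_sd=0.5))
    return bl.assemble_dataset(data.bound, data.free, data.experimental), \
        data.ground_truth


@pytest.fixture
def tiny_bound():
    return pd.DataFrame([
        {"ligand_id": "L1", "protein_conf": "P70", "pose": "M1",
         "replicate": "S1", "v_el_bound": -120.0, "v_vdw_bound": -80.0},
        {"ligand_id": "L1", "protein_conf": "P70", "pose": "M1",
         "replicate": "S2", "v_el_bound": -110.0, "v_vdw_bound": -90.0},
    ])
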