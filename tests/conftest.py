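import numpy as np
import pandas as pd
import pytest

from tsl2screen import synthio
from tsl2screen.hairpinstruct import HairpinEnsemble


@pytest.fixture(scope="session")
def default_plate():
    """One screening plate at the study defaults (304 compounds, 18%
    binders, 40% mean displacement, CV 5%)."""
    return synthio.gen_plate(synthio.PlateConfig(seed=1))


@pytest.fixture(scope="session")
def two_state_ensemble():
    """Balanced pentaloop/triloop mixture with moderate jitter."""
    return synthio.gen_hairpin_ensemble(
        synthio.HairpinConfig(seed=11, n_frames=400, p_triloop=0.5))


@pytest.fixture()
def toy_ensemble():
    """Hand-built 2-residue, 4-atom ensemble for distance arithmetic."""
    atoms = pd.DataFrame({
        "res_seq": [1, 1, 1, 2],
        "res_name": ["A", "A", "A", "U"],
        "atom_name": ["P", "C1'", "N9", "C1'"],
        "element": ["P", "C", "N", "C"],
        "mass": [30.974, 12.011, 14.007, 12.011],
    })
    coords = np.array([
        [[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [6.0, 0, 0]],
        [[0.0, 1, 0], [1.0, 1, 0], [2.0, 1, 0], [6.0, 1, 0]],
    ])
    return HairpinEnsemble(coords=coords, atoms=atoms)
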