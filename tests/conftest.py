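import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from diverscale.experiment import run_ensemble_and_filter, sobol_design
from diverscale.fixtures import make_multi_island_world


@pytest.fixture(scope="session")
def study_world():
    """The 20x20 archipelago study landscape."""
    return make_multi_island_world()


@pytest.fixture(scope="session")
def study_ensemble(study_world):
    """A 50-run Sobol ensemble over the study landscape.

    Retains every surviving run (the species-count filter is calibrated
    to full-scale ensembles); shared session-wide because it is by far
    the most expensive object in the suite.
    """
    design = sobol_design(50, seed=11)
    return run_ensemble_and_filter(design, study_world, min_species=1, master_seed=100)
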