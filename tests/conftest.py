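import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from fedmorph.design import SurfaceGrid
from fedmorph.simulate import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-site planted cohort shared by read-only tests."""
    design, shards, truth = generate_cohort(
        n_subjects=60,
        grids=SurfaceGrid(8, 12, "left"),
        n_true_patches=3,
        n_sites=2,
        seed=11,
    )
    return design, shards, truth
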