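import numpy as np
import pandas as pd
import pytest

from mirstage.preprocess import CountMatrix
from mirstage.simulate import ProgramSpec, SimConfig


@pytest.fixture
def tiny_cm():
    """3 miRNAs x 4 samples, 2 stages x 2 replicates."""
    counts = pd.DataFrame(
        {"a_r1": [5, 10, 5], "b_r1": [2, 8, 0], "a_r2": [6, 12, 6], "b_r2": [3, 9, 1]},
        index=["mir-1", "mir-2", "mir-3"],
    )
    samples = pd.DataFrame(
        {"stage": ["A", "B", "A", "B"], "replicate": ["r1", "r1", "r2", "r2"]},
        index=counts.columns,
    )
    return CountMatrix(counts, samples)


def small_config(**kw):
    """A fast 4-program config used across recovery tests."""
    defaults = dict(
        stages=("MEF", "Thy1-", "SSEA1+", "Oct4-GFP+"),
        programs=[
            ProgramSpec("down_up", 20, (0.0, -3.0, -1.5, -0.2)),
            ProgramSpec("spike", 10, (0.0, 0.0, 4.0, 0.5)),
            ProgramSpec("ramp", 10, (0.0, 1.0, 2.5, 6.0)),
            ProgramSpec("null", 60, (0.0, 0.0, 0.0, 0.0)),
        ],
        lib_sizes=(1e6, 1.5e6),
        dispersion=0.05,
        batch_logfc_sd=0.2,
        seed=11,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
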