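import numpy as np
import pandas as pd
import pytest

from devostate import reference, simulate
from devostate.io_formats import CountMatrix


@pytest.fixture(scope="session")
def small_reference():
    """Small annotated synthetic reference: 4 states (2 fetal / 2 adult)."""
    counts, annotations, truth = simulate.simulate_reference(
        n_fetal_states=2, n_adult_states=2, n_genes=400,
        n_cells_per_state=40, n_markers_per_state=12, marker_fc=8.0,
        seed=101)
    return counts, annotations, truth


@pytest.fixture(scope="session")
def small_signature(small_reference):
    """Signature built from the small reference with relaxed QC thresholds."""
    counts, annotations, _ = small_reference
    return reference.build_signature(
        counts, annotations, min_umi=50, min_cells=10, top_n=60, seed=202)


@pytest.fixture()
def toy_counts():
    """3 genes x 4 cells with easily hand-checked sums."""
    df = pd.DataFrame(
        [[1, 0, 5, 0],
         [2, 5, 5, 0],
         [0, 3, 10, 600]],
        index=["gA", "gB", "gC"],
        columns=["c1", "c2", "c3", "c4"],
    )
    return CountMatrix(df)


@pytest.fixture()
def rng():
    return np.random.default_rng(4242)
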