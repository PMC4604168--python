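import numpy as np
import pandas as pd
import pytest

import synscape as syn


def sorted_measurements(ds: syn.ScreenDataset) -> pd.DataFrame:
    return (
        ds.measurements.sort_values(list(ds.measurements.columns))
        .reset_index(drop=True)
    )


def assert_datasets_equal(a: syn.ScreenDataset, b: syn.ScreenDataset) -> None:
    """Equality up to row order."""
    assert a.panel == b.panel
    assert a.lines == b.lines
    pd.testing.assert_frame_equal(
        sorted_measurements(a), sorted_measurements(b), check_dtype=False
    )


@pytest.fixture(scope="session")
def small_screen():
    """Auto-planted landscape: 24 drugs (276 pairs), 8 lines, two tiers."""
    return syn.generate_screen(syn.SimulationConfig(n_drugs=24, n_lines=8, seed=3))


@pytest.fixture(scope="session")
def small_scores(small_screen):
    ds, _ = small_screen
    return syn.score_dataset(ds)


@pytest.fixture(scope="session")
def null_screen():
    """Noise-free Bliss-null screen, small geometry."""
    return syn.generate_screen(syn.null_config(n_drugs=12, n_lines=6, seed=5))


@pytest.fixture(scope="session")
def noisy_null_screen():
    """Null screen (no planted effects) with measurement noise on."""
    ds, _ = syn.generate_screen(
        syn.SimulationConfig(
            n_drugs=16,
            n_lines=24,
            seed=9,
            planted_synergies=[],
            broad_sensitizer=None,
            planted_cparp_outliers=[],
        )
    )
    return ds
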