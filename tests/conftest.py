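import numpy as np
import pandas as pd
import pytest

import twinmeth as tm


@pytest.fixture(scope="session")
def small_cfg():
    """Small but fully structured study configuration for shared fixtures."""
    return tm.SimConfig(seed=11, n_probes=3000, n_acquired_truth=30,
                        n_celltype_truth=60, noise_sd=0.01)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return tm.generate_twin_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return tm.generate_reference_panel(small_cfg)


def toy_cohort(categories, deltas=None, dfos=None, ages=None):
    """Hand-built cohort frame: one row per pair.

    ``deltas`` may contain NaN (unknown pairs); DfO is split around a fixed
    center so milder twins score higher.
    """
    n = len(categories)
    deltas = deltas if deltas is not None else [np.nan] * n
    dfos = dfos if dfos is not None else [500.0] * n
    ages = ages if ages is not None else [20.0] * n
    rows = []
    for i, cat in enumerate(categories):
        d = deltas[i]
        known = np.isfinite(d) if d is not None else False
        rows.append({
            "pair_id": f"p{i + 1}", "sample_mild": f"s{i + 1}m",
            "sample_severe": f"s{i + 1}s", "category": cat,
            "delta": d if known else np.nan,
            "dfo_mild": dfos[i] + d / 2 if known else np.nan,
            "dfo_severe": dfos[i] - d / 2 if known else np.nan,
            "age": ages[i], "sex": "female"})
    return pd.DataFrame(rows)
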