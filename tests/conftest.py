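"""Shared fixtures: templates, small simulated walks, synthetic cohort tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from plantarstat.gait import MeanPeakPressureMap
from plantarstat.io import AreaTable, RegularGrid
from plantarstat.simulate import VariabilityModel, default_foot_template


@pytest.fixture(scope="session")
def template():
    return default_foot_template()


@pytest.fixture(scope="session")
def study_variability():
    """The moderate-variability condition used for recovery checks."""
    return VariabilityModel(amplitude_cv=0.1, jitter_sd_mm=2.0, seed=0)


@pytest.fixture
def tiny_grid():
    return RegularGrid((0.0, 0.0), 5.0, 4, 3)


def make_mppm(mean, sd, n, cell_size=5.0):
    mean = np.atleast_2d(np.asarray(mean, dtype=float))
    sd = np.atleast_2d(np.asarray(sd, dtype=float))
    grid = RegularGrid((0.0, 0.0), cell_size, *mean.shape)
    return MeanPeakPressureMap(grid, mean, sd, n)


def synthetic_cohort_table(
    n_subjects: int = 30, seed: int = 11, optimal_rate: float = 0.35
) -> AreaTable:
    """Synthetic 60-foot R-ROI area table for three insole conditions.

    Emulates the structure of a per-foot supplementary data set: flat-insole
    (FI) areas around 20 cm² with wide spread, custom insoles (TCCI,
    CADCAM) strongly reduced with a substantial fraction of complete
    removals (area exactly 0), CADCAM slightly better than TCCI.  This is a
    synthetic stand-in, not the published data set.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(1, n_subjects + 1):
        for side in ("left", "right"):
            fi = max(rng.normal(20.6, 12.9), 0.75)
            optimal = rng.uniform() < optimal_rate
            if optimal:
                tcci = cadcam = 0.0
            else:
                tcci = max(fi * rng.uniform(0.15, 0.75), 0.25)
                cadcam = max(tcci - abs(rng.normal(1.6, 1.2)), 0.25)
            rows.append(
                {"subject": f"S{s:02d}", "side": side,
                 "FI": round(fi, 2), "TCCI": round(tcci, 2),
                 "CADCAM": round(cadcam, 2)}
            )
    df = pd.DataFrame(rows).set_index(["subject", "side"])
    return AreaTable(df)


@pytest.fixture(scope="session")
def cohort_table():
    return synthetic_cohort_table()
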