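"""Shared fixtures and small synthetic-table builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cardiodnp.acquisition import AcquisitionParams

GROUPS = (("sham", "chow"), ("sham", "wd"), ("aab", "chow"), ("aab", "wd"))


@pytest.fixture
def acq() -> AcquisitionParams:
    """Protocol acquisition: TR 1 s, 5 deg, 13 593 Hz, 2048 pts, 60 reps."""
    return AcquisitionParams()


@pytest.fixture
def acq_small() -> AcquisitionParams:
    """Reduced acquisition for fast fitting tests."""
    return AcquisitionParams(n_points=1024, n_repetitions=30)


def make_cohort_table(
    means=(0.0, 0.0, 0.0, 0.0),
    sds=(1.0, 1.0, 1.0, 1.0),
    ns=(8, 8, 8, 8),
    week: int = 4,
    measure: str = "m",
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Factorial cohort table with one value per animal, groups in the order
    sham-chow, sham-wd, aab-chow, aab-wd."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    rows = []
    for (surgery, diet), mean, sd, n in zip(GROUPS, means, sds, ns):
        for i in range(n):
            rows.append(
                (
                    f"{surgery}-{diet}-{i:02d}",
                    surgery,
                    diet,
                    week,
                    measure,
                    mean + sd * rng.standard_normal(),
                )
            )
    return pd.DataFrame(
        rows, columns=["animal_id", "surgery", "diet", "week", "measure", "value"]
    )
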