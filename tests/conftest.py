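import numpy as np
import pandas as pd
import pytest

from transgen_scan import AncestorStratum, CohortConfig, generate_cohort


def make_stratum(
    n: int,
    n_cases: int,
    rng: np.random.Generator,
    coord_scale: float = 100.0,
    years=(2000, 2005),
    role: str = "mother",
    window: str = "birth",
) -> AncestorStratum:
    """A small random stratum with integer-valued coordinates (exact floats),
    guaranteed to contain at least two distinct years."""
    year = rng.integers(years[0], years[1] + 1, n)
    while len(np.unique(year)) < 2:
        year = rng.integers(years[0], years[1] + 1, n)
    labels = np.zeros(n, dtype=bool)
    labels[rng.choice(n, size=n_cases, replace=False)] = True
    return AncestorStratum(
        role=role,
        window=window,
        subject_ids=np.array([f"s{i:03d}" for i in range(n)], dtype=object),
        x=rng.integers(0, int(coord_scale) + 1, n).astype(float),
        y=rng.integers(0, int(coord_scale) + 1, n).astype(float),
        year=year.astype(int),
        is_case=labels,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A fully linked 10-case cohort (30 children, 540 records)."""
    cfg = CohortConfig(n_case_children=10, p_link=1.0)
    return generate_cohort(cfg, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231118)
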