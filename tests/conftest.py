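"""Shared fixtures and helpers for the metamech test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metamech.kinetics import TimeCourse


def make_timecourse(times, values, kind, series_id="s", replicate=1, meta=None):
    """One-replicate time course from parallel arrays."""
    return TimeCourse(
        series_id=series_id,
        kind=kind,
        data=pd.DataFrame({
            "time": np.asarray(times, dtype=float),
            "value": np.asarray(values, dtype=float),
            "replicate": replicate,
        }),
        meta=meta or {},
    )


def random_simplex(rng: np.random.Generator, size: int) -> np.ndarray:
    """Uniform random point on the probability simplex."""
    x = rng.dirichlet(np.ones(size))
    return x / x.sum()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
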