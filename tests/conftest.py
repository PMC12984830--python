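"""Shared fixtures: a full-scale paired phantom study computed once."""

from __future__ import annotations

import numpy as np
import pytest

from octaquant import ImageSpec
from octaquant.pipeline import RunConfig, run_simulate_and_quantify

STUDY_SEED = 11
STUDY_PARTICIPANTS = 25


@pytest.fixture(scope="session")
def spec512() -> ImageSpec:
    return ImageSpec()


@pytest.fixture(scope="session")
def study():
    """25-participant / 50-eye paired phantom study at full scan scale.

    Device A uses the low-noise preset, device B the high-noise preset;
    quantification and quality metrics run with identical settings on both.
    Session-scoped because the 100 image quantifications take a few minutes.
    """
    return run_simulate_and_quantify(
        RunConfig(n_participants=STUDY_PARTICIPANTS, seed=STUDY_SEED)
    )


@pytest.fixture(scope="session")
def study_merged(study):
    m, q = study["metrics"], study["quality"]
    return m.merge(q, on=["participant", "eye", "device", "plexus"])


@pytest.fixture(scope="session")
def paired(study_merged):
    """Return a function giving per-eye paired (A, B) values for a metric."""

    def _pivot(metric: str):
        wide = study_merged.pivot_table(index="eye", columns="device", values=metric)
        wide = wide.dropna()
        return wide["A"].to_numpy(float), wide["B"].to_numpy(float)

    return _pivot


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
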