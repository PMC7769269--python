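import warnings

import numpy as np
import pandas as pd
import pytest

from femgpipe.pipeline import analyze_recordings
from femgpipe.synthetic import SimulationConfig, simulate_cohort
from femgpipe.types import EMOTIONS


@pytest.fixture(scope="session")
def study_cohort():
    """A clean (artifact-free) cohort at the study's scale: 30 per group."""
    cfg = SimulationConfig(n_per_group=30, seed=42, artifact_rate=0.0)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def study_bundle(study_cohort):
    """Full pipeline results for the clean study-scale cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_recordings(
            [(p.recording, p.events) for p in study_cohort.participants],
            osi=study_cohort.osi, isas=study_cohort.isas,
        )


@pytest.fixture(scope="session")
def small_cohort():
    """A 2-per-group cohort for smoke tests."""
    cfg = SimulationConfig(n_per_group=2, seed=7, artifact_rate=0.0)
    return simulate_cohort(cfg)


def make_binned_frame(y: np.ndarray, n_per_group: int,
                      muscle: str = "corrugator") -> pd.DataFrame:
    """Long-format binned table from a subjects x emotions x bins array,
    first ``n_per_group`` subjects labelled hnssi, the rest control."""
    n, E, T = y.shape
    recs = []
    for i in range(n):
        g = "hnssi" if i < n_per_group else "control"
        for e in range(E):
            for b in range(T):
                recs.append((f"P{i:03d}", g, muscle, EMOTIONS[e], b, y[i, e, b]))
    return pd.DataFrame(recs, columns=["participant", "group", "muscle",
                                       "emotion", "bin", "amplitude"])
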