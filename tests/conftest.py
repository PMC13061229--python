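"""Shared fixtures: small synthetic experiments and helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from apparency import RunConfig, SimulationParams, simulate_experiment
from apparency.pipeline import score_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """Six participants, both periods, default response model."""
    return simulate_experiment(SimulationParams(n_participants=6, seed=11))


@pytest.fixture(scope="session")
def small_scored(small_experiment):
    """Scored measurements frame for the six-participant experiment."""
    from apparency.aggregate import interpolate_bathing_hour

    scored = score_experiment(small_experiment, RunConfig(seed=11))
    return interpolate_bathing_hour(scored, small_experiment.layout)


def make_measurements(rows) -> pd.DataFrame:
    """Build a minimal measurements frame from (pid, sound, period, segment, label)
    tuples, assigning distinct in-segment onsets automatically."""
    from apparency.protocol import DEFAULT_LAYOUT

    counters: dict = {}
    recs = []
    for pid, sound, period, segment, label in rows:
        seg = DEFAULT_LAYOUT.segments[segment]
        key = (pid, segment)
        i = counters.get(key, 0)
        counters[key] = i + 1
        recs.append(
            {
                "participant_id": pid,
                "sound_code": sound,
                "period": period,
                "segment": segment,
                "onset_ms": seg.start_ms + 1000.0 * (i + 1),
                "m1_ms": 800.0,
                "m2_ms": 790.0,
                "sd_ms": 10.0,
                "or_value": 1.0 if label == "unnoticed" else (3.0 if label == "acceleration" else -3.0),
                "label": label,
            }
        )
    df = pd.DataFrame(recs)
    if (df["label"] == "invalid").any():
        df.loc[df["label"] == "invalid", ["m1_ms", "m2_ms", "sd_ms", "or_value"]] = np.nan
    return df
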