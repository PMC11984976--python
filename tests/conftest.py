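"""Shared fixtures: compact schedules and feature-space cohort builders.

Most evaluation-logic tests operate on synthetic feature tables built
directly in feature space (Gaussian clusters per condition); full signal
simulation is exercised where the signal model itself is under test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from myofuse.features import feature_columns
from myofuse.synthetic_data import (
    CONTRACTION_S,
    GESTURES,
    REST_S,
    ConditionLabel,
    TrialEvent,
    all_conditions,
)


def make_schedule(conditions, reps: int = 3) -> list[TrialEvent]:
    """Contiguous 3 s + 3 s schedule over the given conditions, reps consecutive."""
    events = []
    t = 0.0
    for cond in conditions:
        for r in range(1, reps + 1):
            events.append(
                TrialEvent(
                    condition=cond,
                    repetition=r,
                    contraction_onset_s=t,
                    contraction_offset_s=t + CONTRACTION_S,
                    rest_offset_s=t + CONTRACTION_S + REST_S,
                )
            )
            t += CONTRACTION_S + REST_S
    return events


def feature_cohort(
    rng: np.random.Generator,
    participant_id: str = "P00",
    conditions=None,
    n_windows: int = 5,
    cluster_fn=None,
    noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Feature table drawn from Gaussian clusters, one per condition.

    ``cluster_fn(condition) -> (48,) mean vector`` sets the cluster
    centres; the default places every condition at a distinct corner so
    all 160 classes are perfectly separable.
    """
    conditions = list(conditions) if conditions is not None else all_conditions()
    cols = feature_columns()
    if cluster_fn is None:
        def cluster_fn(cond):  # noqa: ANN001
            i = cond.canonical_index
            out = np.zeros(len(cols))
            out[i % len(cols)] = 10.0 + 3.0 * (i // len(cols))
            out[(i * 7 + 3) % len(cols)] += -10.0 - 2.0 * (i // len(cols))
            return out

    rows, blocks = [], []
    for cond in conditions:
        centre = np.asarray(cluster_fn(cond), dtype=float)
        for rep in (1, 2, 3):
            x = centre + rng.normal(0.0, noise_sd, (n_windows, len(cols)))
            blocks.append(x)
            g, l, p = cond.as_tuple()
            rows.append(
                pd.DataFrame(
                    {
                        "participant_id": participant_id,
                        "gesture": g,
                        "load_g": l,
                        "position": p,
                        "repetition": rep,
                        "window_index": np.arange(n_windows),
                    }
                )
            )
    meta = pd.concat(rows, ignore_index=True)
    values = pd.DataFrame(np.vstack(blocks), columns=cols)
    return pd.concat([meta, values], axis=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
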