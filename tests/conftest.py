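"""Shared fixtures: session-scoped micro-curve sets at the study conditions.

Micro-curves (pair strain rate and crosslinking probability on the default
16-point [ATP] grid) are expensive enough to share: one set per valency,
5 seeds x 1000 simulated seconds, built once per session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from actonem.pipeline import SweepConfig, build_micro_curves


@pytest.fixture(scope="session")
def study_config() -> SweepConfig:
    """Default sweep configuration (packaged rates, 5 seeds, 1000 s)."""
    return SweepConfig(total_time=1000.0)


@pytest.fixture(scope="session")
def micro_curves(study_config):
    """{valency: (seed-mean MicroCurve, per-seed DataFrame)} for 3, 4, 8."""
    return {v: build_micro_curves(study_config, v) for v in (3, 4, 8)}


def sem_by_atp(df: pd.DataFrame) -> np.ndarray:
    """Standard errors of (epsilon, p_crosslink) across seeds per grid point."""
    return df.groupby("atp")[["epsilon", "p_crosslink"]].sem().to_numpy()
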