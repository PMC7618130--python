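"""Shared fixtures: a default synthetic study computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from nrfage.pipeline import derive_study
from nrfage.synthetic import CohortSpec, Event, Recording, generate_cohort

#: the default study conditions: 30 infants, snr 2, fixed seed
DEFAULT_SPEC = CohortSpec(n_infants=30, snr=2.0, seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    recordings, truth = generate_cohort(DEFAULT_SPEC)
    return recordings, truth


@pytest.fixture(scope="session")
def default_study(default_cohort):
    recordings, _ = default_cohort
    return derive_study(recordings, n_permutations_model=99, n_bootstrap=2000, seed=7)


def make_recording(signals: dict[str, np.ndarray], sfreq: float,
                   events: list[tuple[str, float]], *, infant_id: str = "sub-001",
                   session_id: str = "sub-001_ses-01", pma_days: int = 240) -> Recording:
    """Small hand-built recording for unit tests."""
    channels = list(signals)
    data = np.stack([np.asarray(signals[c], dtype=np.float32) for c in channels])
    evs = [Event(kind, onset) for kind, onset in events]
    return Recording(infant_id, session_id, pma_days, channels, sfreq, data, evs)
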