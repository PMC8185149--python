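"""Shared fixtures: the default synthetic study (40 samples) and the
5-replicate variant used where differential-expression power matters."""

import pytest

from droughtlnc import SyntheticConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: 20 condition codes x 2 replicates."""
    return simulate_study(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def study5():
    """Same design with 5 replicates per code (DE power tests)."""
    return simulate_study(SyntheticConfig(seed=42, n_samples_per_code=5))


@pytest.fixture(scope="session")
def transcript_map(study):
    return {t.transcript_id: t for t in study.transcripts}
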