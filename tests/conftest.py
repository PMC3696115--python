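import numpy as np
import pytest

from nirsconn.cohort import ArtifactSpec, CohortSpec, generate_cohort
from nirsconn.hemodynamics import mbll_inverse
from nirsconn.layout import default_layout


@pytest.fixture(scope="session")
def layout94():
    return default_layout(94)


@pytest.fixture(scope="session")
def layout16():
    return default_layout(16)


def make_cohort(seed=0, n_channels=16, n_preterm=2, n_fullterm=2, duration_s=300.0,
                artifact_rate=0.0, coupling=-0.4, **kwargs):
    """Small synthetic cohort helper used across test modules."""
    spec = CohortSpec(
        n_preterm=n_preterm,
        n_fullterm=n_fullterm,
        n_channels=n_channels,
        duration_s=duration_s,
        oxy_deoxy_coupling=coupling,
        artifact_spec=ArtifactSpec(rate_per_recording=artifact_rate),
        seed=seed,
        **kwargs,
    )
    return spec, generate_cohort(spec, default_layout(n_channels))


def make_clean_series(seed=0, n_channels=16, duration_s=300.0, coupling=-0.4):
    """One artifact-free hemoglobin series recovered through the full OD path."""
    _, (_, recordings, _, _) = make_cohort(
        seed=seed, n_channels=n_channels, duration_s=duration_s, coupling=coupling
    )
    return mbll_inverse(recordings[0])


@pytest.fixture(scope="session")
def clean_series():
    return make_clean_series(seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230628)
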