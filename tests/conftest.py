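from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from connlearn.synthetic import CohortConfig, generate_cohort

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


def path_edges(n_edges: int, offset: int = 0) -> tuple[tuple[int, int], ...]:
    """A connected path subnetwork of ``n_edges`` edges."""
    return tuple((offset + i, offset + i + 1) for i in range(n_edges))


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with a strongly implanted 20-edge connected subnetwork."""
    cfg = CohortConfig(
        n_subjects=40,
        n_nodes=40,
        n_frames=200,
        base_correlation=0.2,
        implanted_edges=path_edges(20),
        effect_beta=0.25,
        edge_noise_sd=0.02,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no implanted skill effect (effect_beta = 0)."""
    cfg = CohortConfig(
        n_subjects=40,
        n_nodes=40,
        n_frames=200,
        base_correlation=0.2,
        implanted_edges=path_edges(20),
        effect_beta=0.0,
        edge_noise_sd=0.02,
        seed=12,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_matrices(effect_cohort):
    from connlearn.connectome import correlation_matrix

    return np.stack(
        [correlation_matrix(ts).values for ts in effect_cohort.timeseries]
    )


@pytest.fixture(scope="session")
def null_matrices(null_cohort):
    from connlearn.connectome import correlation_matrix

    return np.stack([correlation_matrix(ts).values for ts in null_cohort.timeseries])
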