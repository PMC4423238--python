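import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sersband as sb

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_spectra_set(matrix, labels, grid=None, ids=None):
    """Small helper to assemble a SpectraSet from raw arrays."""
    matrix = np.asarray(matrix, dtype=float)
    if grid is None:
        grid = sb.WavenumberGrid(np.linspace(400.0, 1800.0, matrix.shape[1]))
    if ids is None:
        ids = np.array([f"s{i}" for i in range(matrix.shape[0])], dtype=object)
    return sb.SpectraSet(grid=grid, matrix=matrix,
                         labels=np.array(labels, dtype=object),
                         ids=np.asarray(ids, dtype=object))


def tiny_synthetic_config(**overrides):
    """A small, fast generator config for operator-level GA tests.

    100-point grid (20 five-variable segments), strong effects, light noise:
    the band-selection problem is easy, so short GA runs behave predictably.
    """
    defaults = dict(
        n_normal=12,
        n_cancer=14,
        n_points=100,
        peaks=(
            sb.PeakSpec(center=600.0, width=25.0, base_amplitude=1.0, class_effect=-0.4),
            sb.PeakSpec(center=1000.0, width=25.0, base_amplitude=1.0, class_effect=0.4),
            sb.PeakSpec(center=1500.0, width=25.0, base_amplitude=1.0, class_effect=0.0),
        ),
        noise_sd=0.03,
        seed=0,
    )
    defaults.update(overrides)
    return sb.SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def default_clean():
    """Preprocessed default six-band cohort (55 cancer + 36 normal), shared."""
    cfg = sb.six_band_config(seed=7)
    clean, _ = sb.preprocess_set(sb.simulate_dataset(cfg))
    return cfg, clean


@pytest.fixture(scope="session")
def segment_index_1270():
    return sb.build_segment_index(1270, 5)
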