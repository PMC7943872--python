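import numpy as np
import pytest

from pacemap.ecg import EcgBeat, PacingSite
from pacemap.synthetic import SyntheticConfig, forward_ecg, make_dataset

NOISELESS_AFFINE = SyntheticConfig(
    n_sites=12, beats_per_site=1, beat_noise_sd=0.0, mode="affine", seed=3
)


@pytest.fixture(scope="session")
def affine_dataset():
    """12 noiseless affine-mode sites: the algebraic oracle dataset."""
    return make_dataset(NOISELESS_AFFINE)


@pytest.fixture(scope="session")
def make_affine_site():
    """Factory: a noiseless affine-mode site at an arbitrary position."""

    def _make(site_id: str, position) -> PacingSite:
        pos = np.asarray(position, dtype=float)
        return PacingSite(
            site_id=site_id, position=pos, beats=forward_ecg(pos, NOISELESS_AFFINE)
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_beat(rng, n_samples=256, sampling_rate=1000.0) -> EcgBeat:
    return EcgBeat(
        voltages=rng.standard_normal((12, n_samples)), sampling_rate=sampling_rate
    )


@pytest.fixture(scope="session")
def position_only_site():
    """Factory for geometry-only sites (one tiny placeholder beat)."""

    def _make(site_id: str, position) -> PacingSite:
        beat = EcgBeat(voltages=np.zeros((12, 160)), sampling_rate=1000.0)
        return PacingSite(site_id=site_id, position=np.asarray(position, float), beats=[beat])

    return _make
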