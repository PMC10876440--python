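import numpy as np
import pytest

from ciliakit import kymo
from ciliakit.synthetic import IFTSimConfig, simulate_ift_movie


def straight_path(stack):
    """Horizontal path through the centre row, base at x = 0."""
    ny, nx = stack.data.shape[1:]
    return kymo.CiliumPath(np.array([[(ny - 1) / 2, 0.0], [(ny - 1) / 2, nx - 1.0]]))


def analyze_movie(stack):
    """Movie -> kymograph -> directional split -> tracks -> encounters."""
    km = kymo.build_kymograph(stack, straight_path(stack))
    dk = kymo.separate_directions(km)
    tracks = kymo.extract_tracks(dk)
    encounters = kymo.find_encounters(tracks)
    return km, dk, tracks, encounters


def single_train_config(**overrides):
    """Config whose seed is known to inject exactly one anterograde train."""
    defaults = dict(
        seed=1,
        antero_injection_rate_hz=0.02,
        retro_injection_rate_hz=0.0,
        n_frames=300,
        length_spread_nm=1e-9,
    )
    defaults.update(overrides)
    return IFTSimConfig(**defaults)


@pytest.fixture(scope="session")
def single_train():
    cfg = single_train_config()
    stack, truth = simulate_ift_movie(cfg)
    assert len(truth.true_tracks) == 1
    assert truth.true_tracks[0].direction == "anterograde"
    return cfg, stack, truth
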