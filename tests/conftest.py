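import numpy as np
import pytest

from chromemo import locus as locus_mod
from chromemo import simulate


@pytest.fixture(scope="session")
def screen_model():
    measurements = locus_mod.synthetic_measurements()
    return locus_mod.fit_screen_model(measurements)


@pytest.fixture(scope="session")
def default_intensity(screen_model):
    axis_max = min(locus_mod.total_intensity(screen_model, np.eye(3)[k] * 255)
                   for k in range(3))
    return 0.6 * axis_max


@pytest.fixture(scope="session")
def color_locus(screen_model, default_intensity):
    return locus_mod.build_locus(screen_model, default_intensity, n_colors=743)


@pytest.fixture(scope="session")
def targets32():
    return simulate.default_targets(32)


@pytest.fixture()
def null_responses(targets32):
    profile = simulate.make_profile("unbiased", sigma0=0.17)
    return simulate.simulate_responses(profile, targets32, 15, seed=42,
                                       player_id="nullfix")


def player_summaries(rs):
    """Per-target arrays (t, y, w, eps2) ready for the fitting machinery."""
    from chromemo.circstats import wrap_angle

    s = rs.summaries()
    t = s["target_rad"].to_numpy()
    n = s["n"].to_numpy()
    eps = s["sd_rad"].to_numpy()
    w = eps / np.sqrt(n)
    y = wrap_angle(s["mean_rad"].to_numpy() - t)
    return t, y, w, eps**2
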