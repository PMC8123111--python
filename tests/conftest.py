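import numpy as np
import pytest

from wcdetect import NoiseConfig, SurveyConfig, TargetSpec, generate_survey
from wcdetect.simulate import FanGeometry, PingFan


@pytest.fixture(scope="session")
def small_config():
    """Shallow, narrow-fan survey: fast to generate, easy to reason about."""
    return SurveyConfig(
        water_depth=20.0,
        area_side=60.0,
        n_transects=2,
        transect_spacing=20.0,
        vessel_speed=2.0,
        pings_per_transect=30,
        n_beams_per_transducer=48,
        seed=7,
    )


@pytest.fixture(scope="session")
def empty_survey(small_config):
    return generate_survey(small_config, [])


@pytest.fixture(scope="session")
def fish_target():
    return TargetSpec(
        "FISH", anchor=(15.0, 20.0, 12.0), dims=(6.0, 4.0, 3.0),
        sv_offset=15.0, velocity=(1.0, 0.0, 0.0),
    )


@pytest.fixture(scope="session")
def fish_survey(small_config, fish_target):
    return generate_survey(small_config, [fish_target])


def make_fan(sv, range_bin=1.0, nav=(0.0, 0.0, 90.0), ping_id=0, time=0.0,
             angles=None):
    """Wrap a raw (2, beams, bins) array into a PingFan for unit tests."""
    sv = np.asarray(sv, dtype=np.float32)
    nt, nb, nr = sv.shape
    if angles is None:
        angles = np.linspace(-30, 30, nt * nb).reshape(nt, nb)
    ranges = (np.arange(nr) + 0.5) * range_bin
    theta = np.radians(angles)[:, :, None]
    geom = FanGeometry(
        beam_angles=angles, ranges=ranges, range_bin=range_bin,
        across=np.sin(theta) * ranges[None, None, :],
        depth=np.cos(theta) * ranges[None, None, :],
    )
    return PingFan(
        ping_id=ping_id, time=time, nav=nav, geometry=geom, sv=sv,
        ground_truth=np.zeros_like(sv, dtype=np.uint8),
        seafloor_depth=np.full((nt, nb), np.inf),
    )
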