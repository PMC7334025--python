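"""Shared fixtures: small deterministic recordings, events, configs."""

import numpy as np
import pandas as pd
import pytest

import auriclab as al
from auriclab.synthetic import reduced_analysis, reduced_sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim():
    """Reduced-scale exogenous generator (480 Hz, one muscle pair, ~30 s)."""
    return reduced_sim(fs=480.0, carrier_band=(20.0, 90.0))


@pytest.fixture
def small_cfg():
    """Analysis config matched to the 480 Hz reduced generator."""
    return reduced_analysis(480.0, 2)


@pytest.fixture
def pam_pair():
    return [
        al.ChannelInfo(al.Muscle.PAM, al.Side.LEFT),
        al.ChannelInfo(al.Muscle.PAM, al.Side.RIGHT),
    ]


@pytest.fixture
def tiny_recording(rng, pam_pair):
    data = rng.normal(0.0, 5.0, (9600, 2))
    return al.Recording(data, 9600.0, pam_pair, "s01", "exo")


def make_events(rows):
    df = pd.DataFrame(rows)
    for col in al.io_core.EVENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return al.EventTable(df)


@pytest.fixture
def exo_events():
    return make_events(
        [
            dict(onset=5.0 + 10 * i, duration=2.0, speaker_azimuth=az,
                 stimulus_type="dog_barking", experiment="exogenous")
            for i, az in enumerate([-30, 30, -120, 120])
        ]
    )
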