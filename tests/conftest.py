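import numpy as np
import pytest

import polarflip as pf
from polarflip.events import RegionActivitySeries
from polarflip.synthetic import track_region_traces


@pytest.fixture(scope="session")
def acq():
    return pf.AcquisitionParams()


@pytest.fixture(scope="session")
def reversed_track(acq):
    return pf.simulate_cell_track(pf.default_kinetics("reversed"), acq, n_frames=51)


def series_from_track(track, noise_sd=0.0, velocity_noise_sd=0.0, seed=0):
    """Trace-level region series + signed velocity from a ground-truth track."""
    t, front, rear, vel = track_region_traces(
        track, noise_sd=noise_sd, velocity_noise_sd=velocity_noise_sd, seed=seed
    )
    series = RegionActivitySeries(
        time_s=t, front=front, rear=rear, middle=(front + rear) / 2,
        whole=(front + rear) / 2,
    )
    return series, vel
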