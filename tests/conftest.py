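import numpy as np
import pandas as pd
import pytest

from copstab import synthetic_cohort as sc
from copstab.cop_metrics import CoPRecording, DEVICE_SAMPLE_RATE


def make_recording(ap, ml, rate=DEVICE_SAMPLE_RATE, subject_id="s1", condition="OE"):
    ap = np.asarray(ap, dtype=float)
    ml = np.asarray(ml, dtype=float)
    t = np.arange(len(ap)) / rate
    return CoPRecording(subject_id=subject_id, condition=condition,
                        sample_rate=rate, t=t, ml=ml, ap=ap)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (fixed-margin endpoint mode)."""
    return sc.generate_cohort(sc.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def sway_recording():
    """A realistic 60 s sway-like recording at the device rate."""
    return sc.generate_trajectory(12.12, 12.12, duration=60.0, seed=7)
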