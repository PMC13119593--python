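import numpy as np
import pytest

from liversep import AcquisitionParams, CohortSpec, build_specimen, simulate_mgre
from dataclasses import replace


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def nofat_spec():
    """Cohort spec with fat switched off (clean relaxometry conditions)."""
    return replace(CohortSpec(), fat_fraction_range=((0.0, 0.0),) * 5)


@pytest.fixture(scope="session")
def noiseless_specimen(nofat_spec, acq):
    """One noiseless fat-free stage-2 specimen with its echo series."""
    truth = build_specimen((48, 48, 32), 2, nofat_spec, seed=3)
    series = simulate_mgre(truth, acq, noise_sd=0.0, seed=0)
    return truth, series


@pytest.fixture(scope="session")
def fatty_specimen(acq):
    """Noiseless stage-3 specimen with fat present."""
    truth = build_specimen((48, 48, 32), 3, CohortSpec(), seed=5)
    series = simulate_mgre(truth, acq, noise_sd=0.0, seed=0)
    return truth, series
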