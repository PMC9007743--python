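"""Shared fixtures: the rho/opsin registry and synthetic instrument factories."""

import numpy as np
import pytest

from photocascade.instrument import InstrumentModel
from photocascade.quant import ChargeSeries
from photocascade.spectra import RETINYLIDENE_DELTA, LightSchedule, SpeciesDef

RHO_BASE_MASS = 39965.0  # fixture constant (order-of-magnitude, not a measurement)


@pytest.fixture
def rho_opsin_registry():
    return {
        "rho": SpeciesDef("rho", RHO_BASE_MASS, RETINYLIDENE_DELTA, 6, 10, 8.0),
        "opsin": SpeciesDef("opsin", RHO_BASE_MASS, 0.0, 6, 10, 8.0),
    }


@pytest.fixture
def rho_opsin_series(rho_opsin_registry):
    return [ChargeSeries(rho_opsin_registry["rho"]), ChargeSeries(rho_opsin_registry["opsin"])]


def make_instrument(noise_sd: float = 0.0, mz_min: float = 3900.0, mz_max: float = 7000.0,
                    mz_step: float = 0.25, **kw) -> InstrumentModel:
    """Instrument with envelopes centered mid-range; noisy runs get a 5σ noise floor."""
    env = kw.pop("charge_envelope", {"rho": (8.0, 1.0), "opsin": (8.0, 1.0)})
    baseline = kw.pop("baseline", 5.0 * noise_sd)
    return InstrumentModel(mz_min=mz_min, mz_max=mz_max, mz_step=mz_step,
                           charge_envelope=env, noise_sd=noise_sd, baseline=baseline, **kw)


@pytest.fixture
def continuous_light():
    return LightSchedule.continuous(0.0)


@pytest.fixture
def scan_times():
    return np.arange(0.0, 120.0 + 1.0, 2.0)
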