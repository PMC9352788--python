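import numpy as np
import pytest

import mvitc as mv

# Fitted parameters of the two study cases (bivalent and trivalent
# lectin / glycomacromolecule titrations); used as realistic study
# conditions throughout the suite.
BIVALENT_RATES = mv.MicroRates(s=2, k_on=(136.4185, 33.4088), k_off=(2.3716, 18.5925))
BIVALENT_N = 0.3208
BIVALENT_DH = -73.4629

TRIVALENT_RATES = mv.MicroRates(
    s=3, k_on=(559.1484, 489.7665, 1056.7834), k_off=(1844.5886, 81.966, 1338.633)
)
TRIVALENT_N = 0.3624
TRIVALENT_DH = -115.1639


@pytest.fixture(scope="session")
def bivalent_schedule():
    return mv.bivalent_schedule()


@pytest.fixture(scope="session")
def trivalent_schedule():
    return mv.trivalent_schedule()


@pytest.fixture(scope="session")
def bivalent_conc(bivalent_schedule):
    return mv.total_concentrations(bivalent_schedule)


@pytest.fixture(scope="session")
def trivalent_conc(trivalent_schedule):
    return mv.total_concentrations(trivalent_schedule)


@pytest.fixture(scope="session")
def bivalent_qc_truth():
    return mv.QcParams(rates=BIVALENT_RATES, n=BIVALENT_N, dH=BIVALENT_DH)


@pytest.fixture(scope="session")
def bivalent_qc_heats(bivalent_schedule, bivalent_qc_truth):
    """Noise-free heats generated by the per-step-K forward model."""
    spec = mv.SimulationSpec(schedule=bivalent_schedule, truth=bivalent_qc_truth)
    return mv.simulate_heats(spec)


def random_micro_rates(rng, s=None, low=1e-1, high=1e3):
    s = int(rng.choice([1, 2, 3])) if s is None else s
    return mv.MicroRates(
        s=s,
        k_on=10 ** rng.uniform(np.log10(low), np.log10(high), s),
        k_off=10 ** rng.uniform(np.log10(low), np.log10(high), s),
    )
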