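import numpy as np
import pytest

from hapsched.dynamics import RateFunctions
from hapsched.microenvironment import build_compartment_model
from hapsched.rate_models import default_calibration
from hapsched.schedule import table3_schedules


@pytest.fixture(scope="session")
def compartment_model():
    return build_compartment_model()


@pytest.fixture(scope="session")
def rate_model(compartment_model):
    return default_calibration(compartment_model)


@pytest.fixture(scope="session")
def schedules():
    return table3_schedules()


def exact_mutation_rates(rates_tuple, u):
    """Constant rates adjusted so the analytic means describe the simulated
    process exactly: sensitive divisions occur at rate lam_X but only a
    fraction (1-u) adds a sensitive cell, so the sensitive net rate uses
    lam_X*(1-u) while the mutant influx keeps the full division rate
    (equivalent to using u/(1-u) with the thinned birth rate)."""
    lx, mx, ly, my = rates_tuple
    return RateFunctions.constant(lx * (1.0 - u), mx, ly, my), u / (1.0 - u)


def exact_mutation_rates_piecewise(bounds, rate_rows, u):
    rows = [(lx * (1.0 - u), mx, ly, my) for lx, mx, ly, my in rate_rows]
    return RateFunctions.piecewise_constant(bounds, rows), u / (1.0 - u)


def combine_compartment_sims(summaries):
    """Replicate-wise sum of independent per-compartment simulations."""
    S = sum(s.sensitive for s in summaries)
    R = sum(s.resistant for s in summaries)
    trunc = np.zeros(S.shape[0], dtype=bool)
    for s in summaries:
        trunc |= s.truncated
    from hapsched.branching_sim import SimSummary

    return SimSummary(times=summaries[0].times, sensitive=S, resistant=R, truncated=trunc)
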