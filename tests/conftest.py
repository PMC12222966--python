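"""Shared fixtures: the seeded standard population and small helpers."""

import numpy as np
import pytest

from glycodmd import (
    OscillatorParams,
    PopulationSpec,
    population_analytic_spectrum,
    simulate_population,
)

STANDARD_SEED = 7


@pytest.fixture(scope="session")
def standard_population():
    """100-cell heterogeneous population under the default study
    conditions (influx median 14.5 mM/min, 1 Hz sampling, 10 min)."""
    base = OscillatorParams()
    spec = PopulationSpec(seed=STANDARD_SEED, base=base)
    f6p, f16bp, v = simulate_population(spec)
    params_list = [base.with_(v=float(vv)) for vv in v]
    analytic = population_analytic_spectrum(params_list, f6p.dt)
    return {"f6p": f6p, "f16bp": f16bp, "v": v,
            "params_list": params_list, "analytic": analytic,
            "base": base, "spec": spec}


@pytest.fixture()
def rotation_data():
    """Planar rotation by 0.3 rad per step: eigenvalues exp(+-0.3i)."""
    theta = 0.3
    A = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    X = np.empty((2, 60))
    X[:, 0] = [1.0, 0.25]
    for k in range(59):
        X[:, k + 1] = A @ X[:, k]
    return X, theta
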