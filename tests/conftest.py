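"""Shared fixtures: small simulated measurements with the standard analysis
pipeline applied.  All randomness is seeded; session-scoped fixtures keep
the suite fast by reusing expensive simulations."""

import numpy as np
import pytest

from smburst import background as bg_mod
from smburst import burstsearch, corrections, phcore
from smburst import simulate as sim


def run_standard_pipeline(measurement, m=10, F=6.0, window_s=30.0):
    """alternation (if ALEX) -> background -> search -> corrections."""
    if measurement.is_alex and not measurement.alternation_applied:
        measurement = phcore.apply_alternation(measurement)
    bg_mod.estimate_background(measurement, window_s=window_s)
    burstsearch.burst_search(measurement, m=m, F=F)
    corrections.apply_corrections(measurement)
    return measurement


@pytest.fixture(scope="session")
def alex_static():
    """120 s ALEX simulation, one static population E=0.6, pipeline run."""
    cfg = sim.SimConfig(duration_s=120.0, seed=11,
                        populations=(sim.Population(fraction=1.0, E=0.6,
                                                    S=0.5),))
    measurement, truth = sim.simulate_measurement(cfg)
    measurement = run_standard_pipeline(measurement)
    return measurement, truth


@pytest.fixture(scope="session")
def alex_three_pop():
    """FRET + donor-only + acceptor-only mixture (ALEX), pipeline run."""
    pops = (sim.Population(fraction=0.4, E=0.6, S=0.5),
            sim.Population(fraction=0.3, E=0.05, S=1.0),   # D-only
            sim.Population(fraction=0.3, E=1.0, S=0.0))    # A-only
    cfg = sim.SimConfig(duration_s=150.0, seed=21, populations=pops)
    measurement, truth = sim.simulate_measurement(cfg)
    measurement = run_standard_pipeline(measurement)
    return measurement, truth


@pytest.fixture(scope="session")
def single_laser():
    """300 s non-ALEX simulation (the stated acceptance world): 2 kcps
    background, 1 burst/s at 100 kcps, E=0.5."""
    cfg = sim.SimConfig(duration_s=300.0, seed=1,
                        alternation=phcore.NO_ALTERNATION,
                        bg_rates=dict(sim.DEFAULT_BG_RATES_SINGLE),
                        populations=(sim.Population(fraction=1.0, E=0.5),))
    measurement, truth = sim.simulate_measurement(cfg)
    bg_mod.estimate_background(measurement, window_s=30.0)
    burstsearch.burst_search(measurement, m=10, F=6.0)
    return measurement, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
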