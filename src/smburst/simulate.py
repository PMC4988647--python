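"""Synthetic smFRET photon-stream generator with ground truth.

The simulator emulates exactly the statistical structure the analysis
assumes:

- background photons are independent homogeneous Poisson processes, one per
  canonical photon stream, so inter-photon delays have exponential tails;
- molecule transits ("bursts") arrive as a Poisson process; each burst is a
  photon cluster with a constant within-burst rate over an
  exponentially-distributed transit duration (rectangular transit profile —
  a deliberate simplification of the diffusion profile);
- each burst photon falls in a donor- or acceptor-excitation period with
  probability given by the population stoichiometry; donor-excitation
  photons split donor/acceptor binomially with success probability E_p,
  optionally contaminated by per-photon leakage and direct-excitation
  misassignment so correction round trips have exact ground truth;
- for μs-ALEX, each photon's timestamp is placed at a uniformly random
  phase inside the ON range of its excitation period, reproducing the
  alternation histogram structure;
- optional two-state dynamics: within each burst the emitting state follows
  a continuous-time Markov chain and each photon uses the current state's E.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import phcore
from .phcore import (AlternationSpec, Measurement, PhotonData,
                     ValidationError)

__all__ = [
    "Population", "TwoStateDynamics", "SimConfig", "GroundTruth",
    "simulate_measurement", "simulate_two_state",
    "default_alex_alternation", "DEFAULT_BG_RATES_ALEX",
    "DEFAULT_BG_RATES_SINGLE",
]


def default_alex_alternation() -> AlternationSpec:
    """50 μs alternation at 12.5 ns/tick: period 4000 ticks,
    D_ON=(2100, 3900), A_ON=(100, 1900)."""
    return AlternationSpec(mode="us_alex", period=4000,
                           d_on=(2100, 3900), a_on=(100, 1900))


#: default background rates (counts/s), 2 kcps total
DEFAULT_BG_RATES_ALEX = {"DexDem": 700.0, "DexAem": 600.0,
                         "AexAem": 600.0, "AexDem": 100.0}
DEFAULT_BG_RATES_SINGLE = {"Dem": 1000.0, "Aem": 1000.0}


@dataclass(frozen=True)
class Population:
    """One molecular species: occurrence fraction, FRET efficiency E_p,
    stoichiometry S_p (fraction of burst photons emitted in
    donor-excitation periods), within-burst photon rate and mean transit
    duration."""

    fraction: float
    E: float
    S: float = 0.5
    rate_cps: float = 100e3
    transit_s: float = 1e-3


@dataclass(frozen=True)
class TwoStateDynamics:
    """Two-state interconversion: efficiencies E_a/E_b and exchange rates
    k_ab (a→b) and k_ba (b→a), per second."""

    E_a: float
    E_b: float
    k_ab: float
    k_ba: float


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults are the package's stated world
    (300 s, 2 kcps background, 1 burst/s at 100 kcps, 1 ms transits)."""

    duration_s: float = 300.0
    timestamps_unit: float = 12.5e-9
    alternation: AlternationSpec = field(
        default_factory=default_alex_alternation)
    bg_rates: dict = None
    populations: tuple = (Population(fraction=1.0, E=0.5),)
    dynamics: Optional[TwoStateDynamics] = None
    burst_arrival_rate: float = 1.0
    leakage: float = 0.0
    dir_ex: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.bg_rates is None:
            rates = DEFAULT_BG_RATES_ALEX if self.alternation.is_alex \
                else DEFAULT_BG_RATES_SINGLE
            object.__setattr__(self, "bg_rates", dict(rates))
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be > 0")
        if abs(sum(p.fraction for p in self.populations) - 1.0) > 1e-9:
            raise ValidationError("population fractions must sum to 1")
        for p in self.populations:
            if not 0 <= p.E <= 1 or not 0 <= p.S <= 1:
                raise ValidationError("E and S must be in [0, 1]")
            if p.rate_cps <= 0 or p.transit_s <= 0:
                raise ValidationError("rates and transit times must be > 0")
        if any(r < 0 for r in self.bg_rates.values()):
            raise ValidationError("background rates must be >= 0")
        if self.burst_arrival_rate < 0:
            raise ValidationError("burst_arrival_rate must be >= 0")


@dataclass
class GroundTruth:
    """Injected-burst records: intervals (s), population id, true E, and
    photon count per burst."""

    t_start: np.ndarray
    t_stop: np.ndarray
    population: np.ndarray
    E: np.ndarray
    n_photons: np.ndarray

    @property
    def n_bursts(self) -> int:
        return len(self.t_start)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t_start": self.t_start, "t_stop": self.t_stop,
                             "population": self.population, "E": self.E,
                             "n_photons": self.n_photons})


# stream label codes used internally while assembling the photon record
_DEXDEM, _DEXAEM, _AEXDEM, _AEXAEM = 0, 1, 2, 3
_STREAM_NAME = {0: "DexDem", 1: "DexAem", 2: "AexDem", 3: "AexAem"}


def _poisson_times(rng, rate, duration):
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def _assign_ticks(rng, times_s, streams, config: SimConfig) -> np.ndarray:
    """Timestamps in clock ticks consistent with each photon's excitation
    period (μs-ALEX) or plain quantization (no alternation)."""
    unit = config.timestamps_unit
    alt = config.alternation
    if not alt.is_alex:
        return np.round(times_s / unit).astype(np.int64)
    period_s = alt.period * unit
    period_idx = np.floor(times_s / period_s).astype(np.int64)
    is_dex = streams < _AEXDEM
    lo = np.where(is_dex, alt.d_on[0], alt.a_on[0])
    hi = np.where(is_dex, alt.d_on[1], alt.a_on[1])
    phase = rng.integers(lo, hi)
    return period_idx * alt.period + phase


def _burst_photon_streams(rng, n_ph, E, config: SimConfig, S):
    """Stream label for each burst photon: excitation by S, then the
    donor-excitation binomial D/A split at efficiency E (scalar or
    per-photon), then leakage / direct-excitation misassignment."""
    is_dex = rng.random(n_ph) < S if config.alternation.is_alex \
        else np.ones(n_ph, dtype=bool)
    streams = np.full(n_ph, _AEXAEM, dtype=np.int8)
    acceptor = rng.random(n_ph) < E
    if config.dir_ex > 0:
        acceptor |= rng.random(n_ph) < config.dir_ex
    donor = ~acceptor
    if config.leakage > 0:
        # the leakage coefficient is na_leak/nd (ratio to *detected* donor
        # counts), so the per-photon misassignment probability is lk/(1+lk)
        p_mis = config.leakage / (1.0 + config.leakage)
        leaked = donor & (rng.random(n_ph) < p_mis)
        acceptor |= leaked
        donor &= ~leaked
    streams[is_dex & donor] = _DEXDEM
    streams[is_dex & acceptor] = _DEXAEM
    return streams


def _two_state_E(rng, times, dyn: TwoStateDynamics):
    """Per-photon E along a two-state CTMC trajectory over the burst,
    initialized from the stationary distribution."""
    k_tot = dyn.k_ab + dyn.k_ba
    p_a = dyn.k_ba / k_tot if k_tot > 0 else 0.5
    t0 = times[0] if len(times) else 0.0
    state = 0 if rng.random() < p_a else 1
    rates = (dyn.k_ab, dyn.k_ba)
    Es = (dyn.E_a, dyn.E_b)
    out = np.empty(len(times))
    t = t0
    next_jump = t + rng.exponential(1.0 / rates[state]) \
        if rates[state] > 0 else np.inf
    for i, tp in enumerate(times):
        while tp >= next_jump:
            t = next_jump
            state = 1 - state
            next_jump = t + rng.exponential(1.0 / rates[state]) \
                if rates[state] > 0 else np.inf
        out[i] = Es[state]
    return out


def simulate_measurement(config: SimConfig):
    """Simulate one spot and return ``(Measurement, GroundTruth)``.

    The measurement holds the photon record *before* alternation is
    applied (as a file loader would produce it); ground truth records
    every injected burst.  Bit-identical for identical configs.
    """
    rng = np.random.default_rng(config.seed)
    all_times = []
    all_streams = []

    # background: independent Poisson processes per configured stream
    name_to_code = {"DexDem": _DEXDEM, "DexAem": _DEXAEM,
                    "AexDem": _AEXDEM, "AexAem": _AEXAEM,
                    "Dem": _DEXDEM, "Aem": _DEXAEM}
    for name, rate in sorted(config.bg_rates.items()):
        if rate == 0:
            continue
        if name not in name_to_code:
            raise ValidationError(f"unknown background stream {name!r}")
        t = _poisson_times(rng, rate, config.duration_s)
        all_times.append(t)
        all_streams.append(np.full(len(t), name_to_code[name], dtype=np.int8))

    # bursts: Poisson arrivals, rectangular transit profile
    arrivals = _poisson_times(rng, config.burst_arrival_rate,
                              config.duration_s)
    fractions = np.array([p.fraction for p in config.populations])
    pop_ids = rng.choice(len(config.populations), size=len(arrivals),
                         p=fractions)
    gt_start, gt_stop, gt_pop, gt_E, gt_n = [], [], [], [], []
    for t0, ipop in zip(arrivals, pop_ids):
        pop = config.populations[ipop]
        dur = rng.exponential(pop.transit_s)
        t1 = min(t0 + dur, config.duration_s)
        n_ph = rng.poisson(pop.rate_cps * (t1 - t0))
        times = np.sort(rng.uniform(t0, t1, size=n_ph))
        if config.dynamics is not None:
            E = _two_state_E(rng, times, config.dynamics)
            true_E = np.nan  # interconverting: no single E
        else:
            E = pop.E
            true_E = pop.E
        streams = _burst_photon_streams(rng, n_ph, E, config, pop.S)
        all_times.append(times)
        all_streams.append(streams)
        gt_start.append(t0)
        gt_stop.append(t1)
        gt_pop.append(ipop)
        gt_E.append(true_E)
        gt_n.append(n_ph)

    times = np.concatenate(all_times) if all_times else np.empty(0)
    streams = np.concatenate(all_streams) if all_streams \
        else np.empty(0, dtype=np.int8)
    ticks = _assign_ticks(rng, times, streams, config)
    order = np.argsort(ticks, kind="stable")
    ticks, streams = ticks[order], streams[order]
    detectors = np.where(np.isin(streams, (_DEXAEM, _AEXAEM)),
                         phcore.ACCEPTOR, phcore.DONOR).astype(np.int8)

    spot = PhotonData(timestamps=ticks,
                      timestamps_unit=config.timestamps_unit,
                      detectors=detectors,
                      alternation=config.alternation)
    measurement = Measurement(spots=[spot],
                              metadata={"simulated": "true",
                                        "seed": str(config.seed)})
    truth = GroundTruth(t_start=np.asarray(gt_start),
                        t_stop=np.asarray(gt_stop),
                        population=np.asarray(gt_pop, dtype=np.int64),
                        E=np.asarray(gt_E),
                        n_photons=np.asarray(gt_n, dtype=np.int64))
    return measurement, truth


def simulate_two_state(config: SimConfig):
    """Simulate with two-state interconversion (``config.dynamics`` set)."""
    if config.dynamics is None:
        raise ValidationError("config.dynamics must be set")
    return simulate_measurement(config)
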