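"""Sliding-window burst search vs a brute-force oracle, AND-gate search and
index remapping."""

import numpy as np
import pytest

from smburst import burstsearch as bs
from smburst import corrections, phcore
from smburst import simulate as sim
from smburst.burstsearch import (SearchParams, and_gate_search, burst_search,
                                 recompute_index, sliding_window_search)
from smburst.phcore import StateError, ValidationError
from tests.conftest import run_standard_pipeline


def brute_force_bursts(ts, m, rate_of):
    """Independent oracle: enumerate every m-photon window, keep windows
    with span <= m/rate, merge windows sharing at least one photon."""
    bursts = []
    for i in range(len(ts) - m + 1):
        if ts[i + m - 1] - ts[i] <= m / rate_of(ts[i]):
            if bursts and i <= bursts[-1][1]:
                bursts[-1][1] = i + m - 1
            else:
                bursts.append([i, i + m - 1])
    return [tuple(b) for b in bursts]


class TestSlidingWindow:
    def test_two_cluster_example(self):
        """Two 4-photon clusters 96 ms apart with Δt = 5 ms stay separate
        bursts even though the window index ranges touch."""
        ts = np.array([0, 1, 2, 3, 100, 101, 102, 103]) * 1e-3
        out = sliding_window_search(ts, m=4, threshold_rate_fn=4 / 5e-3)
        assert out == [(0, 3), (4, 7)]
        assert out == brute_force_bursts(ts, 4, lambda t: 4 / 5e-3)

    def test_below_threshold_rate_no_bursts(self, rng):
        """Uniform photons well below the threshold rate: no false
        positives over a long run.  (At m=10 a window of Poisson photons
        at half the threshold still beats it ~7% of the time, so the
        false-positive probe needs a wide margin: 10x here, expected
        false positives ~0.05 over 5e4 windows.)"""
        ts = np.sort(rng.uniform(0, 100.0, size=50000))  # 500 cps
        assert sliding_window_search(ts, 10, 5000.0) == []

    def test_fewer_than_m_photons(self):
        assert sliding_window_search(np.array([0.0, 1.0]), 5, 100.0) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_randomized(self, seed):
        """Exact match with the brute-force enumerator on random instances
        with random m and threshold."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 3000))
        # mixture of background and clustered photons
        ts = np.sort(np.concatenate([
            rng.uniform(0, 1.0, size=n),
            (rng.uniform(0, 1.0, size=1) + rng.uniform(0, 1e-3, size=200)),
        ]))
        m = int(rng.integers(3, 20))
        rate = float(rng.uniform(2, 20) * n)
        fast = sliding_window_search(ts, m, rate)
        assert fast == brute_force_bursts(ts, m, lambda t: rate)

    def test_oracle_equivalence_time_varying_threshold(self, rng):
        """Equivalence also holds with a time-dependent threshold."""
        ts = np.sort(rng.uniform(0, 10.0, size=5000))

        def rate_fn(t):
            return np.where(np.asarray(t) < 5.0, 2000.0, 500.0)

        fast = sliding_window_search(ts, 8, rate_fn)
        assert fast == brute_force_bursts(ts, 8, lambda t: rate_fn(t))

    def test_windows_satisfy_rate_condition(self, single_laser):
        """Post-hoc audit: every burst contains at least one valid window
        and every window inside a burst that triggered it satisfies the
        rate condition."""
        measurement, _ = single_laser
        bset = measurement.bursts[0]
        bg = measurement.background[0]
        ts = measurement.spots[0].times_s
        m = bset.params.m
        from smburst.background import background_rates
        rates = background_rates(bg, phcore.ALL)
        for istart, istop in zip(bset.istart[:50], bset.istop[:50]):
            ok = False
            for i in range(istart, istop - m + 2):
                thr = 6.0 * rates[bg.period_of(ts[i])]
                if ts[i + m - 1] - ts[i] <= m / thr:
                    ok = True
            assert ok

    def test_concatenation_away_from_cut(self, rng):
        """Searching two halves separately equals the full search when no
        burst spans the cut."""
        ts = np.sort(rng.uniform(0, 2.0, size=2000))
        cut = 1.0
        full = sliding_window_search(ts, 10, 5000.0)
        left_ts = ts[ts < cut]
        right_ts = ts[ts >= cut]
        left = sliding_window_search(left_ts, 10, 5000.0)
        right = [(a + len(left_ts), b + len(left_ts))
                 for a, b in sliding_window_search(right_ts, 10, 5000.0)]
        spanning = [b for b in full
                    if ts[b[0]] < cut <= ts[b[1]]]
        if not spanning:
            assert full == left + right


class TestSearchParams:
    def test_exclusive_threshold_modes(self):
        with pytest.raises(ValidationError):
            SearchParams(m=10, F=6.0, min_rate_cps=5e4)
        with pytest.raises(ValidationError):
            SearchParams(m=10)
        with pytest.raises(ValidationError):
            SearchParams(m=1, F=6.0)


class TestBurstSearch:
    def test_recovers_injected_bursts(self, single_laser):
        """>= 90% of injected bursts at 50x background are recovered
        (interval overlap with ground truth)."""
        measurement, truth = single_laser
        bset = measurement.bursts[0]
        hits = 0
        for t0, t1, nph in zip(truth.t_start, truth.t_stop, truth.n_photons):
            if nph < 20:      # too dim to be detectable in principle
                continue
            overlap = (bset.t_start <= t1) & (bset.t_stop >= t0)
            hits += overlap.any()
        n_detectable = np.sum(truth.n_photons >= 20)
        assert hits / n_detectable >= 0.90

    def test_min_size_is_m(self, single_laser):
        measurement, _ = single_laser
        bset = measurement.bursts[0]
        assert bset.counts_raw[phcore.ALL].min() >= 10

    def test_sbr_guarantee(self, single_laser):
        """Every burst's triggering window rate >= F x local background."""
        measurement, _ = single_laser
        bset = measurement.bursts[0]
        bg = measurement.background[0]
        ts = measurement.spots[0].times_s
        m = bset.params.m
        min_ratio = np.inf
        for istart, istop in zip(bset.istart, bset.istop):
            for i in range(istart, istop - m + 2):
                dt = ts[i + m - 1] - ts[i]
                bgr = bg.rates[phcore.ALL][bg.period_of(ts[i])]
                if dt <= m / (6.0 * bgr):
                    min_ratio = min(min_ratio, (m / dt) / bgr)
        assert min_ratio >= 6.0

    def test_L_filter(self, single_laser):
        measurement, truth = single_laser
        bs.burst_search(measurement, m=10, F=6.0, L=40)
        assert measurement.bursts[0].counts_raw[phcore.ALL].min() >= 40
        bs.burst_search(measurement, m=10, F=6.0)   # restore fixture state
        corrections.apply_corrections(measurement)

    def test_min_rate_mode_equivalence(self, single_laser):
        """A fixed min_rate_cps equal to F x (flat background) reproduces
        the F-mode search."""
        measurement, _ = single_laser
        bg = measurement.background[0]
        # impose a flat background so the two modes are exactly comparable
        flat = float(bg.rates[phcore.ALL].mean())
        saved = bg.rates[phcore.ALL].copy()
        bg.rates[phcore.ALL][:] = flat
        try:
            by_F = bs.burst_search(measurement, m=10, F=6.0)[0]
            by_rate = bs.burst_search(measurement, m=10,
                                      min_rate_cps=6.0 * flat)[0]
            assert np.array_equal(by_F.istart, by_rate.istart)
            assert np.array_equal(by_F.istop, by_rate.istop)
        finally:
            bg.rates[phcore.ALL][:] = saved
            bs.burst_search(measurement, m=10, F=6.0)
            corrections.apply_corrections(measurement)

    def test_F_mode_requires_background(self):
        cfg = sim.SimConfig(duration_s=1.0, seed=9,
                            alternation=phcore.NO_ALTERNATION,
                            bg_rates=dict(sim.DEFAULT_BG_RATES_SINGLE))
        measurement, _ = sim.simulate_measurement(cfg)
        with pytest.raises(StateError):
            bs.burst_search(measurement, m=10, F=6.0)

    def test_bursts_non_overlapping_sorted(self, single_laser):
        measurement, _ = single_laser
        bset = measurement.bursts[0]
        assert np.all(np.diff(bset.t_start) > 0)
        assert np.all(bset.t_start[1:] > bset.t_stop[:-1])

    def test_reference_count_definitional(self, single_laser):
        measurement, _ = single_laser
        bset = measurement.bursts[0]
        assert np.array_equal(bset.counts_raw[phcore.ALL],
                              bset.istop - bset.istart + 1)


@pytest.fixture(scope="module")
def dcbs_setup():
    """FRET + donor-only mixture, ALEX; AND-gate removes donor-only."""
    pops = (sim.Population(fraction=0.5, E=0.6, S=0.5),
            sim.Population(fraction=0.5, E=0.05, S=1.0))  # donor-only
    cfg = sim.SimConfig(duration_s=120.0, seed=31, populations=pops)
    measurement, truth = sim.simulate_measurement(cfg)
    measurement = phcore.apply_alternation(measurement)
    from smburst.background import estimate_background
    estimate_background(measurement, window_s=30.0)
    return measurement, truth


class TestAndGate:
    def test_subset_of_both_searches(self, dcbs_setup):
        measurement, _ = dcbs_setup
        b1 = burst_search(measurement, m=10, F=6.0, sel=phcore.DEX_ALL)[0]
        b2 = burst_search(measurement, m=10, F=6.0, sel=phcore.AEX_AEM)[0]
        bag = and_gate_search(measurement, m=10, F=6.0)[0]
        for t0, t1 in zip(bag.t_start, bag.t_stop):
            assert np.any((b1.t_start <= t0) & (b1.t_stop >= t1))
            assert np.any((b2.t_start <= t0) & (b2.t_stop >= t1))

    def test_removes_donor_only_population(self, dcbs_setup):
        """Bursts from the donor-only population survive the single-stream
        Dex search but not the AND gate."""
        measurement, truth = dcbs_setup
        single = burst_search(measurement, m=10, F=6.0,
                              sel=phcore.DEX_ALL)[0]
        gated = and_gate_search(measurement, m=10, F=6.0)[0]

        def hits(bset, mask):
            n = 0
            for t0, t1, nph in zip(truth.t_start[mask], truth.t_stop[mask],
                                   truth.n_photons[mask]):
                if nph >= 50 and np.any((bset.t_start <= t1)
                                        & (bset.t_stop >= t0)):
                    n += 1
            return n

        donly = truth.population == 1
        fret = truth.population == 0
        assert hits(single, donly) > 0.5 * np.sum(
            donly & (truth.n_photons >= 50))
        assert hits(gated, donly) < 0.2 * np.sum(
            donly & (truth.n_photons >= 50))
        assert hits(gated, fret) > 0.8 * np.sum(
            fret & (truth.n_photons >= 50))

    def test_symmetric_in_stream_order(self, dcbs_setup):
        measurement, _ = dcbs_setup
        ab = and_gate_search(measurement, m=10, F=6.0,
                             sel1=phcore.DEX_ALL, sel2=phcore.AEX_AEM)[0]
        ba = and_gate_search(measurement, m=10, F=6.0,
                             sel1=phcore.AEX_AEM, sel2=phcore.DEX_ALL)[0]
        np.testing.assert_allclose(ab.t_start, ba.t_start)
        np.testing.assert_allclose(ab.t_stop, ba.t_stop)


class TestRecomputeIndex:
    def test_identity_on_reference(self, single_laser):
        measurement, _ = single_laser
        bset = measurement.bursts[0]
        out = recompute_index(bset, measurement.spots[0].times_s)
        assert np.array_equal(out.istart, bset.istart)
        assert np.array_equal(out.istop, bset.istop)
        assert not out.empty_mask.any()

    def test_brute_force_position(self, single_laser):
        measurement, _ = single_laser
        spot = measurement.spots[0]
        bset = measurement.bursts[0]
        target = phcore.stream_timestamps(spot, phcore.DEM) \
            * spot.timestamps_unit
        out = recompute_index(bset, target)
        for b in range(min(out.n_bursts, 30)):
            inside = np.flatnonzero((target >= bset.t_start[b])
                                    & (target <= bset.t_stop[b]))
            if len(inside):
                assert out.istart[b] == inside[0]
                assert out.istop[b] == inside[-1]
            else:
                assert out.empty_mask[b]

    def test_count_consistency(self, single_laser):
        measurement, _ = single_laser
        spot = measurement.spots[0]
        bset = measurement.bursts[0]
        target = phcore.stream_timestamps(spot, phcore.DEM) \
            * spot.timestamps_unit
        out = recompute_index(bset, target)
        ok = ~out.empty_mask
        assert np.array_equal(out.istop[ok] - out.istart[ok] + 1,
                              bset.counts_raw[phcore.DEM][ok])


def test_dataframe_export(single_laser):
    measurement, _ = single_laser
    df = bs.bursts_to_dataframe(measurement)
    assert {"istart", "istop", "t_start", "t_stop", "width_ms",
            "n_all", "nd_raw", "na_raw"} <= set(df.columns)
    assert len(df) == measurement.bursts[0].n_bursts
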