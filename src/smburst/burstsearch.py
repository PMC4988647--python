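"""Sliding-window burst search.

A burst is a region of a photon stream where the local count rate — measured
over ``m`` consecutive photons — exceeds a threshold rate.  Photon index
``i`` starts a valid window when ``t[i+m-1] - t[i] <= m / rate_threshold``,
with the threshold evaluated at the window's first photon.  Overlapping
valid windows (sharing at least one photon) merge into a single burst, so
the minimum burst size is effectively ``m``.

The threshold is either a fixed rate (``min_rate_cps``) or ``F`` times the
local background rate, which guarantees every burst a signal-to-background
ratio of at least ``F - 1``.  The dual-channel AND-gate search (DCBS when
used with its default streams) intersects the burst intervals of two
independent searches, suppressing donor-only/acceptor-only artifacts such
as blinking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from . import phcore
from .phcore import Measurement, PhotonStream, StateError, ValidationError

__all__ = [
    "SearchParams", "BurstSet", "sliding_window_search", "burst_search",
    "and_gate_search", "recompute_index", "bursts_to_dataframe",
]


@dataclass(frozen=True)
class SearchParams:
    """Burst-search parameters: exactly one of ``F`` (threshold multiplier
    over the local background rate) or ``min_rate_cps`` (fixed threshold)."""

    m: int = 10
    F: Optional[float] = None
    min_rate_cps: Optional[float] = None
    L: int = 0
    stream: PhotonStream = phcore.ALL
    stream2: Optional[PhotonStream] = None   # set for AND-gate searches

    def __post_init__(self):
        if self.m < 2:
            raise ValidationError("m must be >= 2")
        if (self.F is None) == (self.min_rate_cps is None):
            raise ValidationError("specify exactly one of F and min_rate_cps")
        if self.F is not None and self.F <= 1:
            raise ValidationError("F must be > 1")
        if self.min_rate_cps is not None and self.min_rate_cps <= 0:
            raise ValidationError("min_rate_cps must be > 0")
        if self.L < 0:
            raise ValidationError("L must be >= 0")


@dataclass
class BurstSet:
    """Bursts of one spot, as index intervals into a reference stream.

    ``istart``/``istop`` are 0-based inclusive indices into the reference
    stream's timestamp array; ``t_start``/``t_stop`` are in seconds.
    ``counts_raw`` maps each canonical stream to the photons counted in
    ``[t_start, t_stop]``.  ``counts`` (corrected, real-valued) is filled
    by the corrections stage.
    """

    istart: np.ndarray
    istop: np.ndarray
    t_start: np.ndarray
    t_stop: np.ndarray
    params: SearchParams
    reference: PhotonStream
    spot: int = 0
    counts_raw: dict = field(default_factory=dict)
    counts: object = None                 # corrections.BurstCounts (full)
    counts_bg: object = None              # background-corrected only
    empty_mask: Optional[np.ndarray] = None  # recompute_index: no target photon

    def __post_init__(self):
        self.istart = np.asarray(self.istart, dtype=np.int64)
        self.istop = np.asarray(self.istop, dtype=np.int64)
        self.t_start = np.asarray(self.t_start, dtype=float)
        self.t_stop = np.asarray(self.t_stop, dtype=float)

    @property
    def n_bursts(self) -> int:
        return len(self.istart)

    @property
    def width(self) -> np.ndarray:
        """Burst durations in seconds."""
        return self.t_stop - self.t_start

    def take(self, index) -> "BurstSet":
        """New BurstSet holding the bursts selected by ``index`` (mask or
        integer indices); photon data is shared, not copied."""
        out = replace(
            self,
            istart=self.istart[index], istop=self.istop[index],
            t_start=self.t_start[index], t_stop=self.t_stop[index],
            counts_raw={k: v[index] for k, v in self.counts_raw.items()},
        )
        if self.counts is not None:
            out.counts = self.counts.take(index)
        if self.counts_bg is not None:
            out.counts_bg = self.counts_bg.take(index)
        if self.empty_mask is not None:
            out.empty_mask = self.empty_mask[index]
        return out


def sliding_window_search(ts_s: np.ndarray, m: int,
                          threshold_rate_fn: Union[float, Callable]):
    """Core sliding-window search on timestamps in seconds.

    ``threshold_rate_fn`` is a scalar rate (counts/s) or a vectorized
    callable mapping window-start times to threshold rates.  Returns a list
    of inclusive index intervals ``(istart, istop)``; fewer than ``m``
    photons yields no bursts.
    """
    ts_s = np.asarray(ts_s, dtype=float)
    n = len(ts_s)
    if n < m:
        return []
    starts_t = ts_s[: n - m + 1]
    if callable(threshold_rate_fn):
        rates = np.asarray(threshold_rate_fn(starts_t), dtype=float)
        rates = np.broadcast_to(rates, starts_t.shape)
    else:
        rates = np.full(starts_t.shape, float(threshold_rate_fn))
    dt_max = m / rates
    valid = (ts_s[m - 1:] - starts_t) <= dt_max
    starts = np.flatnonzero(valid)
    if len(starts) == 0:
        return []
    # windows overlap (share >= 1 photon) iff next start <= start + m - 1
    breaks = np.flatnonzero(np.diff(starts) > m - 1)
    first = np.concatenate(([0], breaks + 1))
    last = np.concatenate((breaks, [len(starts) - 1]))
    return [(int(starts[f]), int(starts[l]) + m - 1)
            for f, l in zip(first, last)]


def _burst_set_from_intervals(spot_data, intervals, params, reference,
                              ispot, is_alex):
    ts_ref_s = phcore.stream_timestamps(spot_data, reference) \
        * spot_data.timestamps_unit
    if intervals:
        istart = np.array([iv[0] for iv in intervals], dtype=np.int64)
        istop = np.array([iv[1] for iv in intervals], dtype=np.int64)
        t_start = ts_ref_s[istart]
        t_stop = ts_ref_s[istop]
    else:
        istart = istop = np.empty(0, dtype=np.int64)
        t_start = t_stop = np.empty(0)
    bset = BurstSet(istart=istart, istop=istop, t_start=t_start,
                    t_stop=t_stop, params=params, reference=reference,
                    spot=ispot)
    _fill_counts_raw(bset, spot_data, is_alex)
    return bset


def _fill_counts_raw(bset: BurstSet, spot_data, is_alex: bool):
    """Count photons of every canonical stream inside [t_start, t_stop]
    (both ends inclusive); the reference stream count is definitional."""
    streams = phcore.canonical_streams(is_alex)
    if is_alex:
        streams = streams + [phcore.DEX_ALL]
    for sel in streams:
        ts_s = phcore.stream_timestamps(spot_data, sel) \
            * spot_data.timestamps_unit
        lo = np.searchsorted(ts_s, bset.t_start, side="left")
        hi = np.searchsorted(ts_s, bset.t_stop, side="right")
        bset.counts_raw[sel] = (hi - lo).astype(np.int64)
    bset.counts_raw[bset.reference] = bset.istop - bset.istart + 1


def burst_search(measurement: Measurement, m: int = 10,
                 F: Optional[float] = None,
                 min_rate_cps: Optional[float] = None,
                 sel: PhotonStream = phcore.ALL,
                 L: int = 0) -> list[BurstSet]:
    """Burst search on stream ``sel`` for every spot.

    In ``F`` mode the threshold rate at time ``t`` is ``F`` times the local
    background rate of ``sel`` (background must have been estimated); in
    ``min_rate_cps`` mode it is fixed.  Bursts with fewer than ``L``
    reference-stream photons are dropped.  Results are stored on
    ``measurement.bursts`` and returned.
    """
    params = SearchParams(m=m, F=F, min_rate_cps=min_rate_cps, L=L, stream=sel)
    if F is not None and measurement.background is None:
        raise StateError("F-mode burst search requires background estimation")
    out = []
    for ispot, spot_data in enumerate(measurement.spots):
        ts_s = phcore.stream_timestamps(spot_data, sel) \
            * spot_data.timestamps_unit
        if F is not None:
            bg = measurement.background[ispot]
            from .background import background_rates
            period_rates = background_rates(bg, sel)

            def thr(t, _bg=bg, _r=period_rates):
                idx = np.clip(np.searchsorted(_bg.edges_s, t, side="right") - 1,
                              0, _bg.n_periods - 1)
                return F * _r[idx]
        else:
            thr = float(min_rate_cps)
        intervals = sliding_window_search(ts_s, m, thr)
        bset = _burst_set_from_intervals(spot_data, intervals, params, sel,
                                         ispot, measurement.is_alex)
        if L > 0:
            bset = bset.take(bset.counts_raw[sel] >= L)
        out.append(bset)
    measurement.bursts = out
    return out


def _intersect_intervals(a_start, a_stop, b_start, b_stop):
    """Pairwise intersection of two sorted, non-overlapping interval lists.

    Returns arrays (start, stop) of the nonempty intersections
    [max(starts), min(stops)], in time order."""
    starts, stops = [], []
    i = j = 0
    while i < len(a_start) and j < len(b_start):
        lo = max(a_start[i], b_start[j])
        hi = min(a_stop[i], b_stop[j])
        if lo <= hi:
            starts.append(lo)
            stops.append(hi)
        if a_stop[i] < b_stop[j]:
            i += 1
        else:
            j += 1
    return np.asarray(starts), np.asarray(stops)


def and_gate_search(measurement: Measurement, m: int = 10, F: float = 6.0,
                    sel1: PhotonStream = phcore.DEX_ALL,
                    sel2: PhotonStream = phcore.AEX_AEM,
                    min_rate_cps=None) -> list[BurstSet]:
    """Dual-channel AND-gate burst search (DCBS with the default streams).

    Runs independent searches on ``sel1`` and ``sel2``; output bursts are
    the nonempty time-interval intersections, index-mapped onto the
    all-photons stream with counts recomputed on the intersected
    intervals.
    """
    bursts1 = burst_search(measurement, m=m, F=F, min_rate_cps=min_rate_cps,
                           sel=sel1)
    bursts2 = burst_search(measurement, m=m, F=F, min_rate_cps=min_rate_cps,
                           sel=sel2)
    params = SearchParams(m=m, F=F, min_rate_cps=min_rate_cps,
                          stream=sel1, stream2=sel2)
    out = []
    for ispot, (b1, b2) in enumerate(zip(bursts1, bursts2)):
        spot_data = measurement.spots[ispot]
        t_start, t_stop = _intersect_intervals(b1.t_start, b1.t_stop,
                                               b2.t_start, b2.t_stop)
        ts_all_s = spot_data.times_s
        istart = np.searchsorted(ts_all_s, t_start, side="left")
        istop = np.searchsorted(ts_all_s, t_stop, side="right") - 1
        bset = BurstSet(istart=istart, istop=istop, t_start=t_start,
                        t_stop=t_stop, params=params, reference=phcore.ALL,
                        spot=ispot)
        _fill_counts_raw(bset, spot_data, measurement.is_alex)
        out.append(bset)
    measurement.bursts = out
    return out


def recompute_index(bursts: BurstSet, target_ts_s: np.ndarray) -> BurstSet:
    """Re-express burst intervals as indices into a (sub-)stream.

    ``target_ts_s`` are the target stream's timestamps in seconds (a subset
    of the reference stream's photons).  ``istart``/``istop`` become the
    first/last target photon inside ``[t_start, t_stop]``; bursts with no
    target photon are flagged in ``empty_mask`` (istart > istop there).
    """
    target_ts_s = np.asarray(target_ts_s, dtype=float)
    istart = np.searchsorted(target_ts_s, bursts.t_start, side="left")
    istop = np.searchsorted(target_ts_s, bursts.t_stop, side="right") - 1
    out = replace(bursts, istart=istart, istop=istop)
    out.empty_mask = istop < istart
    out.counts = bursts.counts
    out.counts_raw = dict(bursts.counts_raw)
    return out


def bursts_to_dataframe(measurement: Measurement) -> pd.DataFrame:
    """Burst table: one row per burst with raw per-stream counts."""
    if measurement.bursts is None:
        raise StateError("no burst search has been run")
    frames = []
    is_alex = measurement.is_alex
    for bset in measurement.bursts:
        df = pd.DataFrame({
            "spot": bset.spot,
            "istart": bset.istart, "istop": bset.istop,
            "t_start": bset.t_start, "t_stop": bset.t_stop,
            "width_ms": bset.width * 1e3,
            "n_all": bset.counts_raw[phcore.ALL],
        })
        if is_alex:
            df["nd_raw"] = bset.counts_raw[phcore.DEX_DEM]
            df["na_raw"] = bset.counts_raw[phcore.DEX_AEM]
            df["naa_raw"] = bset.counts_raw[phcore.AEX_AEM]
            df["nda_raw"] = bset.counts_raw[phcore.AEX_DEM]
        else:
            df["nd_raw"] = bset.counts_raw[phcore.DEM]
            df["na_raw"] = bset.counts_raw[phcore.AEM]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
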