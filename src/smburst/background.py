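"""Background-rate estimation from the exponential tail of inter-photon delays.

The timestamp record mixes two Poisson-like processes: a low-rate background
(dark counts, scattering, out-of-focus molecules) and short high-rate bursts
from single molecules crossing the excitation volume.  In the inter-photon
delay distribution the background shows up as an exponential tail; delays
above a threshold ``tail_min`` are modeled as a left-truncated exponential
and the background rate is its inverse time constant.

Rates are tracked over time by splitting the acquisition into consecutive
constant-duration *background periods* (default 30 s) and estimating one
rate per photon stream per period.  Downstream, the burst search uses these
local rates to set time-dependent detection thresholds and the corrections
stage uses them to subtract background counts from bursts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import phcore
from .phcore import Measurement, PhotonStream, StateError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "BackgroundEstimate", "interphoton_delays", "mle_tail_rate",
    "lsq_tail_rate", "auto_tail_threshold", "estimate_background",
    "background_rate_at", "background_to_dataframe", "default_streams",
]

#: minimum number of tail delays required by the estimators (configurable)
MIN_TAIL_DELAYS = 10


@dataclass
class BackgroundEstimate:
    """Per-stream background rates in consecutive time windows.

    ``rates[stream]`` and ``thresholds[stream]`` are arrays of length
    ``n_periods`` (rate in counts/s, tail threshold actually used in s);
    ``edges_s`` are the ``n_periods + 1`` window boundaries in seconds.
    """

    window_s: float
    n_periods: int
    edges_s: np.ndarray
    rates: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    n_tail: dict = field(default_factory=dict)
    method: str = "mle"

    def __post_init__(self):
        for name in ("rates", "thresholds"):
            for sel, arr in getattr(self, name).items():
                if len(arr) != self.n_periods:
                    raise ValidationError(
                        f"{name}[{sel}] has length {len(arr)} != n_periods")

    @property
    def streams(self):
        return list(self.rates.keys())

    def period_of(self, t: float) -> int:
        """Index of the window containing time ``t`` (seconds).

        A boundary time belongs to the later window; times beyond the last
        edge (merged partial window) map to the last period.
        """
        idx = int(np.searchsorted(self.edges_s, t, side="right") - 1)
        return min(max(idx, 0), self.n_periods - 1)


def interphoton_delays(ts: np.ndarray, unit: float) -> np.ndarray:
    """Waiting times between subsequent timestamps, in seconds."""
    ts = np.asarray(ts)
    if len(ts) < 2:
        raise ValidationError("need at least 2 photons to compute delays")
    return np.diff(ts) * unit


def mle_tail_rate(delays, tail_min: float, min_tail=MIN_TAIL_DELAYS):
    """Maximum-likelihood rate of the exponential tail of a delay sample.

    For delays ``d_i >= tail_min`` modeled as a left-truncated exponential,
    the MLE of the rate is ``1 / (mean(d_i | d_i >= tail_min) - tail_min)``.

    Returns ``(rate_cps, n_tail)``.
    """
    delays = np.asarray(delays, dtype=float)
    tail = delays[delays >= tail_min]
    if len(tail) < min_tail:
        raise ValidationError(
            f"only {len(tail)} delays >= tail_min={tail_min:g}; need {min_tail}")
    excess = tail.mean() - tail_min
    if excess <= 1e-12 * tail.mean():
        raise ValidationError("mean tail delay equals tail_min (zero excess)")
    return 1.0 / excess, len(tail)


def lsq_tail_rate(delays, tail_min: float, bin_width: float,
                  min_tail=MIN_TAIL_DELAYS):
    """Tail rate from linear least squares of log(histogram) vs delay.

    The delay histogram above ``tail_min`` decays as ``exp(-λ d)``, so the
    slope of ``log(counts)`` over the nonzero tail bins is ``-λ``.

    Returns ``(rate_cps, n_tail)``.
    """
    delays = np.asarray(delays, dtype=float)
    tail = delays[delays >= tail_min]
    if len(tail) < min_tail:
        raise ValidationError(
            f"only {len(tail)} delays >= tail_min={tail_min:g}; need {min_tail}")
    n_bins = max(int(np.ceil((tail.max() - tail_min) / bin_width)), 1)
    edges = tail_min + np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(tail, bins=edges)
    centers = edges[:-1] + bin_width / 2
    nz = counts > 0
    if nz.sum() < 3:
        raise ValidationError("fewer than 3 nonzero tail bins for least squares")
    slope, _ = np.polyfit(centers[nz], np.log(counts[nz]), 1)
    if slope >= 0:
        raise ValidationError("non-decaying tail histogram")
    return -slope, len(tail)


def auto_tail_threshold(delays, c: float = 3.0, rel_tol: float = 0.01,
                        max_iter: int = 100, min_tail=MIN_TAIL_DELAYS):
    """Heuristic tail threshold for background fitting.

    Iterates ``T_0 = 10 median(delays)``, ``λ_k = MLE(delays, T_k)``,
    ``T_{k+1} = c / λ_k`` until the rate changes by less than ``rel_tol``
    (or ``max_iter`` iterations, then an error carrying the iterate
    history).  The fixed point puts the threshold ``c`` mean background
    delays out, so burst photons are excluded from the tail.
    """
    delays = np.asarray(delays, dtype=float)
    if len(delays) < 100:
        raise ValidationError("auto threshold requires at least 100 delays")
    # cap: keep at least 2*min_tail delays in the tail at any iterate
    T_cap = float(np.sort(delays)[-2 * min_tail])
    T = min(10.0 * float(np.median(delays)), T_cap)
    rate_prev = None
    history = []
    for _ in range(max_iter):
        rate, _ = mle_tail_rate(delays, T, min_tail=min_tail)
        history.append((T, rate))
        if rate_prev is not None and abs(rate - rate_prev) / rate_prev < rel_tol:
            return T
        rate_prev = rate
        T = min(c / rate, T_cap)
    raise ValidationError(
        f"auto tail threshold did not converge in {max_iter} iterations; "
        f"history={history[-5:]}")


def default_streams(measurement: Measurement) -> list[PhotonStream]:
    """Streams estimated by default: all + the signal-carrying canonical
    streams (plus the all-Dex union for ALEX data)."""
    if measurement.is_alex:
        return [phcore.ALL, phcore.DEX_DEM, phcore.DEX_AEM,
                phcore.AEX_AEM, phcore.DEX_ALL]
    return [phcore.ALL, phcore.DEM, phcore.AEM]


def _window_edges(duration_s: float, window_s: float) -> np.ndarray:
    """Window boundaries covering [0, duration]; a final partial window
    shorter than window_s/2 is merged into the previous one."""
    if window_s >= duration_s:
        return np.array([0.0, duration_s])
    n_full = int(duration_s // window_s)
    edges = list(np.arange(n_full + 1) * window_s)
    remainder = duration_s - edges[-1]
    if remainder > 0:
        if remainder < window_s / 2 and n_full >= 1:
            edges[-1] = duration_s          # merge into previous window
        else:
            edges.append(duration_s)
    return np.asarray(edges)


def estimate_background(measurement: Measurement, window_s: float = 30.0,
                        tail_min="auto", method: str = "mle",
                        streams=None, lsq_bin_width: float = 1e-4,
                        min_tail=MIN_TAIL_DELAYS) -> list[BackgroundEstimate]:
    """Estimate per-stream background rates in ``window_s`` windows.

    ``tail_min`` is ``'auto'`` (per-stream heuristic threshold, computed on
    the whole acquisition and reused in each window), a scalar in seconds,
    or a dict mapping stream to threshold.  ``method`` is ``'mle'``
    (truncated-exponential MLE) or ``'lsq'`` (log-histogram least squares).

    Windows with too few photons inherit the previous (else next) window's
    rate with a logged warning.  Results are stored on
    ``measurement.background`` and returned.
    """
    if method not in ("mle", "lsq"):
        raise ValueError(f"unknown method {method!r}")
    estimates = []
    for ispot, spot in enumerate(measurement.spots):
        sels = streams if streams is not None else default_streams(measurement)
        edges = _window_edges(spot.duration_s, window_s)
        n_periods = len(edges) - 1
        bg = BackgroundEstimate(window_s=window_s, n_periods=n_periods,
                                edges_s=edges, method=method)
        for sel in sels:
            ts = phcore.stream_timestamps(spot, sel)
            t_s = ts * spot.timestamps_unit
            all_delays = interphoton_delays(ts, spot.timestamps_unit)
            if tail_min == "auto":
                thr = auto_tail_threshold(all_delays, min_tail=min_tail)
            elif isinstance(tail_min, dict):
                thr = tail_min[sel]
            else:
                thr = float(tail_min)
            rates = np.full(n_periods, np.nan)
            n_tails = np.zeros(n_periods, dtype=int)
            pending = []
            for k in range(n_periods):
                in_win = (t_s >= edges[k]) & (t_s < edges[k + 1])
                if k == n_periods - 1:  # merged tail: include last edge
                    in_win = (t_s >= edges[k]) & (t_s <= edges[k + 1])
                win_ts = ts[in_win]
                try:
                    delays = interphoton_delays(win_ts, spot.timestamps_unit)
                    if method == "mle":
                        rates[k], n_tails[k] = mle_tail_rate(
                            delays, thr, min_tail=min_tail)
                    else:
                        rates[k], n_tails[k] = lsq_tail_rate(
                            delays, thr, lsq_bin_width, min_tail=min_tail)
                except ValidationError:
                    if k > 0 and np.isfinite(rates[k - 1]):
                        rates[k] = rates[k - 1]
                        logger.warning(
                            "spot %d stream %s window %d: too few photons; "
                            "using previous window's rate", ispot, sel, k)
                    else:
                        pending.append(k)
            for k in pending:  # leading windows fall back to the next estimate
                nxt = next((j for j in range(k + 1, n_periods)
                            if np.isfinite(rates[j])), None)
                if nxt is None:
                    raise ValidationError(
                        f"stream {sel}: no window has enough photons")
                rates[k] = rates[nxt]
                logger.warning("spot %d stream %s window %d: too few photons; "
                               "using next window's rate", ispot, sel, k)
            bg.rates[sel] = rates
            bg.thresholds[sel] = np.full(n_periods, thr)
            bg.n_tail[sel] = n_tails
        estimates.append(bg)
    measurement.background = estimates
    return estimates


def background_rate_at(bg: BackgroundEstimate, sel: PhotonStream,
                       t: float) -> float:
    """Background rate (counts/s) of stream ``sel`` in the window holding
    ``t``.  Streams not estimated directly are decomposed into canonical
    components and their rates summed."""
    return float(background_rates(bg, sel)[bg.period_of(t)])


def background_rates(bg: BackgroundEstimate, sel: PhotonStream) -> np.ndarray:
    """Per-period rates for ``sel``, via direct lookup or sum of
    single-channel component streams."""
    if sel in bg.rates:
        return bg.rates[sel]
    total = np.zeros(bg.n_periods)
    for period_attr, chans in (("dex", sel.dex), ("aex", sel.aex)):
        for chan in chans:
            comp = PhotonStream(**{period_attr: chan})
            if comp not in bg.rates:
                raise ValidationError(
                    f"stream {sel} not estimated and component {comp} missing")
            total = total + bg.rates[comp]
    return total


def background_to_dataframe(measurement: Measurement) -> pd.DataFrame:
    """Tabulate background results: one row per (spot, stream, period)."""
    if measurement.background is None:
        raise StateError("background not estimated")
    rows = []
    for ispot, bg in enumerate(measurement.background):
        for sel in bg.streams:
            for k in range(bg.n_periods):
                rows.append({
                    "spot": ispot, "stream": str(sel), "period": k,
                    "t_start": bg.edges_s[k], "t_stop": bg.edges_s[k + 1],
                    "rate_cps": bg.rates[sel][k],
                    "tail_min_us": bg.thresholds[sel][k] * 1e6,
                    "n_tail": bg.n_tail[sel][k],
                })
    return pd.DataFrame(rows)
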