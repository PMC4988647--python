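"""Burst variance analysis (BVA).

BVA detects FRET dynamics on the diffusion timescale by comparing, within
each burst, the empirical spread of sub-burst proximity ratios to the
shot-noise expectation.  Each burst's donor-excitation photons are divided
into consecutive chunks of exactly ``n`` photons (trailing remainder
dropped); the chunk PR is the acceptor fraction, and for a static molecule
the acceptor count per chunk is binomial B(n, E_p), so the chunk PR has
standard deviation

    Std(E_sub) = sqrt(E_p (1 - E_p) / n).

A burst whose sub-burst PR standard deviation ``s_E`` lies above this curve
(evaluated at the burst's mean sub-burst PR) indicates interconversion
between FRET states during the transit; a static mixture scatters
symmetrically about the curve.  Background counts inside chunks are
neglected — they are a small fraction of burst counts.

``s_E`` is the population standard deviation (denominator = number of
chunks); bursts with fewer than 2 chunks are excluded (and logged) rather
than reported as degenerate zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import phcore
from .burstsearch import BurstSet, recompute_index
from .phcore import Measurement, StateError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["BvaResult", "shot_noise_std", "bva_analysis", "bva_dynamic_flag"]


@dataclass
class BvaResult:
    """Per-burst BVA quantities for bursts with >= 2 sub-bursts.

    ``burst_index`` maps each row back to the input BurstSet.
    """

    n: int
    burst_index: np.ndarray
    E_avg: np.ndarray
    s_E: np.ndarray
    n_chunks: np.ndarray

    @property
    def n_bursts(self) -> int:
        return len(self.E_avg)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"burst_id": self.burst_index,
                             "E_avg": self.E_avg, "s_E": self.s_E,
                             "n_chunks": self.n_chunks})


def shot_noise_std(E_p, n: int):
    """Shot-noise-limited standard deviation of a sub-burst PR:
    ``sqrt(E_p(1-E_p)/n)`` for chunks of ``n`` photons."""
    E_p = np.asarray(E_p, dtype=float)
    out = np.sqrt(E_p * (1.0 - E_p) / n)
    return out if out.ndim else float(out)


def bva_analysis(measurement: Measurement, bursts: BurstSet,
                 n: int = 7, spot: int = 0) -> BvaResult:
    """Sub-burst PR standard deviation per burst.

    Bursts are index-mapped onto the donor-excitation photon stream; each
    is split into consecutive chunks of exactly ``n`` donor-excitation
    photons starting at the burst's first photon, the chunk PR is the
    fraction of acceptor-channel photons, and ``s_E`` is the population
    standard deviation of the chunk PRs.
    """
    if n < 2:
        raise ValidationError("chunk size n must be >= 2")
    spot_data = measurement.spots[spot]
    if spot_data.excitation is None:
        raise StateError("BVA requires alternation to be applied")
    dex_mask = phcore.stream_mask(spot_data, phcore.DEX_ALL)
    aem_mask = phcore.stream_mask(spot_data, phcore.DEX_AEM)
    # acceptor mask reduced onto the donor-excitation sub-stream
    aem_mask_d = aem_mask[dex_mask]
    ph_d_s = spot_data.timestamps[dex_mask] * spot_data.timestamps_unit
    bursts_d = recompute_index(bursts, ph_d_s)

    idx, e_avg, s_e, n_chunks = [], [], [], []
    n_excluded = 0
    for b in range(bursts_d.n_bursts):
        if bursts_d.empty_mask[b]:
            n_excluded += 1
            continue
        istart, istop = bursts_d.istart[b], bursts_d.istop[b]
        n_ph = istop - istart + 1
        k = n_ph // n
        if k < 2:
            n_excluded += 1
            continue
        chunk = aem_mask_d[istart:istart + k * n].reshape(k, n)
        e_sub = chunk.sum(axis=1) / n
        idx.append(b)
        e_avg.append(e_sub.mean())
        s_e.append(e_sub.std())        # population std (denominator k)
        n_chunks.append(k)
    if n_excluded:
        logger.info("BVA: excluded %d bursts with < 2 chunks of %d photons",
                    n_excluded, n)
    return BvaResult(n=n, burst_index=np.asarray(idx, dtype=np.int64),
                     E_avg=np.asarray(e_avg), s_E=np.asarray(s_e),
                     n_chunks=np.asarray(n_chunks, dtype=np.int64))


def bva_dynamic_flag(result: BvaResult) -> np.ndarray:
    """Indicator for bursts above the shot-noise curve:
    ``s_E > sqrt(E_avg(1-E_avg)/n)``.

    The fraction flagged is ~0.5 for a static population (symmetric
    fluctuation about the curve) and approaches 1 for dynamics on the
    transit timescale.  This simple rule is a pragmatic summary, not a
    calibrated hypothesis test.
    """
    if result.n_bursts == 0:
        return np.zeros(0, dtype=bool)
    return result.s_E > shot_noise_std(result.E_avg, result.n)
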