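"""Burst-count corrections and derived FRET quantities.

Raw burst counts are corrected in three steps:

1. **Background**: subtract ``rate × width`` per stream, using the local
   background rate of the period containing the burst start.
2. **Leakage / direct excitation**: the acceptor count during donor
   excitation contains donor photons leaking into the acceptor channel
   (fraction ``lk`` of ``nd``) and acceptor photons from direct excitation
   by the donor laser (proportional to ``naa``):
   ``na ← na − lk·nd − dir·naa``.
3. **γ factor**: compensates unequal quantum yields and detection
   efficiencies of the two channels when combining donor and acceptor
   counts.

γ-corrected burst sizes are ``n_dex = na + γ·nd`` (donor-excitation
photons) and ``n_t = na + γ·nd + naa`` (all photons).  The proximity ratio
``E_pr = na/(na+nd)`` is deliberately left uncorrected — detected counts
partition binomially with success probability equal to the PR — and the
recommended workflow corrects fitted *population-level* PR values with the
closed forms :func:`correct_E_population` / :func:`correct_S_population`
rather than distorting per-burst histograms.

The closed-form population correction expresses direct excitation in the
*total-size convention*: a coefficient ``d_T`` such that the subtracted
count is ``d_T·(γ·nd + na_corr)``.  The per-burst link to the counts-level
``naa`` convention is ``d_T = dir·naa / (γ·nd + na_corr)``
(:func:`dir_ex_total_convention`); the two paths agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from . import phcore
from .phcore import Measurement, StateError, ValidationError

__all__ = [
    "CorrectionCoeffs", "BurstCounts", "background_correct",
    "leakage_direx_correct", "burst_size", "proximity_ratio",
    "stoichiometry", "correct_E_population", "correct_S_population",
    "uncorrect_E_population", "corrected_E",
    "dir_ex_total_convention", "apply_corrections",
    "corrected_bursts_to_dataframe",
]


@dataclass(frozen=True)
class CorrectionCoeffs:
    """γ factor, donor leakage and acceptor direct-excitation coefficients.

    Defaults (γ=1, lk=0, dir=0) make every correction the identity.
    """

    gamma: float = 1.0
    leakage: float = 0.0
    dir_ex: float = 0.0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValidationError("gamma must be > 0")
        if not 0 <= self.leakage < 1:
            raise ValidationError("leakage must be in [0, 1)")
        if not 0 <= self.dir_ex < 1:
            raise ValidationError("dir_ex must be in [0, 1)")


@dataclass
class BurstCounts:
    """Corrected (real-valued) per-stream burst counts.

    ``nda`` (donor emission during acceptor excitation) is carried along but
    normally neglected: it contains only background.  Background
    subtraction may leave counts slightly negative; they are never clamped
    during computation.
    """

    nd: np.ndarray
    na: np.ndarray
    naa: np.ndarray
    nda: np.ndarray

    def take(self, index) -> "BurstCounts":
        return BurstCounts(nd=self.nd[index], na=self.na[index],
                           naa=self.naa[index], nda=self.nda[index])


def background_correct(bursts, bg) -> BurstCounts:
    """Subtract expected background counts from the raw burst counts.

    For each burst and stream: ``n = raw − rate(period of t_start) × width``.
    """
    from .background import background_rates

    def stream_rates(sel):
        try:
            return background_rates(bg, sel)
        except ValidationError:
            if sel == phcore.AEX_DEM and phcore.ALL in bg.rates:
                # residual: nda carries only background, rarely estimated
                # directly; infer its rate from the total minus the others
                rest = sum(background_rates(bg, s) for s in
                           (phcore.DEX_DEM, phcore.DEX_AEM, phcore.AEX_AEM))
                return np.clip(bg.rates[phcore.ALL] - rest, 0, None)
            raise

    def corrected(sel):
        if sel not in bursts.counts_raw:
            return np.zeros(bursts.n_bursts)
        periods = np.clip(
            np.searchsorted(bg.edges_s, bursts.t_start, side="right") - 1,
            0, bg.n_periods - 1)
        rate = stream_rates(sel)[periods]
        return bursts.counts_raw[sel] - rate * bursts.width

    if phcore.AEX_AEM in bursts.counts_raw:
        return BurstCounts(nd=corrected(phcore.DEX_DEM),
                           na=corrected(phcore.DEX_AEM),
                           naa=corrected(phcore.AEX_AEM),
                           nda=corrected(phcore.AEX_DEM))
    return BurstCounts(nd=corrected(phcore.DEM), na=corrected(phcore.AEM),
                       naa=np.zeros(bursts.n_bursts),
                       nda=np.zeros(bursts.n_bursts))


def leakage_direx_correct(counts: BurstCounts,
                          coeffs: CorrectionCoeffs) -> BurstCounts:
    """Correct ``na`` for donor leakage and acceptor direct excitation:
    ``na ← na − lk·nd − dir·naa``; ``nd`` and ``naa`` are unchanged."""
    na = counts.na - coeffs.leakage * counts.nd - coeffs.dir_ex * counts.naa
    return BurstCounts(nd=counts.nd, na=na, naa=counts.naa, nda=counts.nda)


def burst_size(counts: BurstCounts, gamma: float = 1.0,
               add_naa: bool = False) -> np.ndarray:
    """γ-corrected burst size: ``na + γ·nd`` (donor-excitation photons) or
    ``na + γ·nd + naa`` with ``add_naa=True`` (all photons)."""
    size = counts.na + gamma * counts.nd
    if add_naa:
        size = size + counts.naa
    return size


def proximity_ratio(counts: BurstCounts) -> np.ndarray:
    """Uncorrected FRET estimator ``E_pr = na/(na+nd)``.

    γ/leakage/direct-excitation are *not* applied (PR by definition).
    Bursts with ``na + nd <= 0`` are returned as NaN (undefined).
    """
    den = counts.na + counts.nd
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, counts.na / np.where(den == 0, np.nan, den),
                       np.nan)
    return out


def stoichiometry(counts: BurstCounts, gamma: float = 1.0) -> np.ndarray:
    """Stoichiometry ``S = (γ·nd + na)/(γ·nd + na + naa)``.

    Raw S uses γ=1.  D-only bursts sit near S=1, A-only near S=0, FRET
    species mid-range.  Zero denominator → NaN.
    """
    dex = gamma * counts.nd + counts.na
    den = dex + counts.naa
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, dex / np.where(den == 0, np.nan, den), np.nan)


def dir_ex_total_convention(counts: BurstCounts,
                            coeffs: CorrectionCoeffs) -> np.ndarray:
    """Per-burst direct-excitation coefficient in the total-size convention.

    ``counts`` must be background-corrected but NOT yet leakage/dir
    corrected.  Returns ``d_T`` such that ``dir·naa = d_T·(γ·nd +
    na_corr)``, the convention the population-level closed form uses.
    """
    na_corr = (counts.na - coeffs.leakage * counts.nd
               - coeffs.dir_ex * counts.naa)
    size = coeffs.gamma * counts.nd + na_corr
    with np.errstate(invalid="ignore", divide="ignore"):
        return coeffs.dir_ex * counts.naa / size


def correct_E_population(E_pr, gamma: float = 1.0, leakage: float = 0.0,
                         dir_ex_t: float = 0.0):
    """Population-level FRET efficiency from a (background-corrected)
    proximity-ratio value.

    ``dir_ex_t`` is the direct-excitation coefficient in the total-size
    convention (see :func:`dir_ex_total_convention`).  Reduces to
    ``E_pr/(E_pr(1−γ)+γ)`` when lk=dir=0 and to the identity when
    additionally γ=1.  A zero denominator yields NaN.
    """
    E_pr = np.asarray(E_pr, dtype=float)
    lk, g, d = leakage, gamma, dir_ex_t
    num = E_pr * (lk + d * g + 1) - lk - d * g
    den = E_pr * (lk - g + 1) - lk + g
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den != 0, num / np.where(den == 0, np.nan, den), np.nan)
    return out if out.ndim else float(out)


def uncorrect_E_population(E, gamma: float = 1.0, leakage: float = 0.0,
                           dir_ex_t: float = 0.0):
    """Forward map: proximity ratio produced by a population of true
    efficiency ``E`` under the counts model (inverse of
    :func:`correct_E_population`)."""
    E = np.asarray(E, dtype=float)
    lk, g, d = leakage, gamma, dir_ex_t
    # normalize corrected size to 1: na_c = E, gamma*nd = 1-E
    na = E + lk * (1 - E) / g + d
    nd = (1 - E) / g
    out = na / (na + nd)
    return out if out.ndim else float(out)


def correct_S_population(E_pr, S_raw, gamma: float = 1.0,
                         leakage: float = 0.0, dir_ex_t: float = 0.0):
    """Corrected stoichiometry from raw population-level (E_pr, S_raw).

    Applies the counts-level corrections algebraically: with the
    donor-excitation counts normalized to ``na + nd = 1``, ``naa``
    reconstructs as ``1/S_raw − 1`` and the corrected S follows from the
    corrected counts.  Identity at γ=1, lk=dir=0.
    """
    E_pr = np.asarray(E_pr, dtype=float)
    S_raw = np.asarray(S_raw, dtype=float)
    lk, g, d = leakage, gamma, dir_ex_t
    nd = 1.0 - E_pr
    with np.errstate(invalid="ignore", divide="ignore"):
        naa = 1.0 / S_raw - 1.0
        na_c = (E_pr - lk * nd - d * g * nd) / (1.0 + d)
        dex = g * nd + na_c
        den = dex + naa
        out = np.where(den != 0, dex / np.where(den == 0, np.nan, den), np.nan)
    return out if out.ndim else float(out)


def apply_corrections(measurement: Measurement,
                      coeffs: CorrectionCoeffs = None) -> list[BurstCounts]:
    """Background + leakage/direct-excitation correction for every spot's
    bursts; stores the result on each BurstSet (``bursts.counts``)."""
    if measurement.bursts is None:
        raise StateError("no burst search has been run")
    if measurement.background is None:
        raise StateError("background not estimated")
    if coeffs is not None:
        measurement.coeffs = coeffs
    coeffs = measurement.coeffs
    out = []
    for bset, bg in zip(measurement.bursts, measurement.background):
        counts_bg = background_correct(bset, bg)
        counts = leakage_direx_correct(counts_bg, coeffs)
        bset.counts_bg = counts_bg      # background-corrected only (raw PR)
        bset.counts = counts            # + leakage/direct-excitation on na
        out.append(counts)
    return out


def corrected_E(counts: BurstCounts, gamma: float = 1.0) -> np.ndarray:
    """Counts-level corrected FRET efficiency ``na/(na + γ·nd)`` for
    counts whose ``na`` has already been leakage/dir corrected."""
    den = counts.na + gamma * counts.nd
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den != 0,
                        counts.na / np.where(den == 0, np.nan, den), np.nan)


def corrected_bursts_to_dataframe(measurement: Measurement) -> pd.DataFrame:
    """Burst table extended with corrected counts, sizes, E and S.

    ``E_pr``/``S_raw`` come from background-corrected counts only; the
    fully corrected ``E_corr``/``S_corr`` use the counts-level path.
    """
    from .burstsearch import bursts_to_dataframe

    df = bursts_to_dataframe(measurement)
    coeffs = measurement.coeffs
    parts = []
    for bset in measurement.bursts:
        if bset.counts is None:
            raise StateError("corrections not applied")
        c = bset.counts
        c_bg = getattr(bset, "counts_bg", c)
        parts.append(pd.DataFrame({
            "nd": c.nd, "na": c.na, "naa": c.naa,
            "size_dex": burst_size(c, coeffs.gamma, add_naa=False),
            "size_all": burst_size(c, coeffs.gamma, add_naa=True),
            "E_pr": proximity_ratio(c_bg),
            "S_raw": stoichiometry(c_bg, gamma=1.0),
            "E_corr": corrected_E(c, coeffs.gamma),
            "S_corr": stoichiometry(c, coeffs.gamma),
        }))
    extra = pd.concat(parts, ignore_index=True)
    return pd.concat([df, extra], axis=1)
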