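"""Composable post-search burst filtering.

Each rule computes one statistic per burst and keeps bursts with the
statistic inside ``[th1, th2]`` (bounds inclusive, ``th2`` defaults to
+∞).  Rules:

``size``
    γ-corrected burst size ``na + γ·nd`` (optionally ``+ naa`` with
    ``add_naa=True``).  Selecting on the γ-corrected size avoids
    under-representing sub-populations with unequal dye brightness.
``naa``
    corrected acceptor count during acceptor excitation — removes the
    donor-only population.
``width``
    burst duration in seconds.
``ES``
    joint rectangular region on (E_pr, S_raw); ALEX only.

Rules compose sequentially: ``size(th1=15)`` then ``naa(th1=15)`` first
removes the acceptor-only, then the donor-only population, isolating the
FRET species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .burstsearch import BurstSet
from .corrections import burst_size, proximity_ratio, stoichiometry
from .phcore import StateError, ValidationError

__all__ = ["SelectionRule", "selection_mask", "select", "select_chain"]

_RULES = ("size", "naa", "width", "ES")


@dataclass(frozen=True)
class SelectionRule:
    """One burst-selection criterion.

    For the ``ES`` rule ``th1``/``th2`` bound E_pr and ``S1``/``S2`` bound
    S_raw; the region is the closed rectangle.
    """

    name: str
    th1: float = -np.inf
    th2: float = np.inf
    gamma: float = 1.0
    add_naa: bool = False
    S1: float = -np.inf
    S2: float = np.inf

    def __post_init__(self):
        if self.name not in _RULES:
            raise ValidationError(
                f"unknown selection rule {self.name!r}; choose from {_RULES}")
        if self.th1 > self.th2 or self.S1 > self.S2:
            raise ValidationError("lower bound exceeds upper bound")


def _statistic(bursts: BurstSet, rule: SelectionRule):
    if rule.name == "width":
        return bursts.width
    if bursts.counts is None:
        raise StateError(f"rule {rule.name!r} requires corrected counts; "
                         "run corrections first")
    if rule.name == "size":
        return burst_size(bursts.counts, gamma=rule.gamma,
                          add_naa=rule.add_naa)
    if rule.name == "naa":
        return bursts.counts.naa
    # ES
    counts_bg = bursts.counts_bg if bursts.counts_bg is not None \
        else bursts.counts
    return proximity_ratio(counts_bg), stoichiometry(counts_bg, gamma=1.0)


def selection_mask(bursts: BurstSet, rule: SelectionRule) -> np.ndarray:
    """Boolean mask, true for bursts passing the rule."""
    if rule.name == "ES":
        from . import phcore
        if phcore.AEX_AEM not in bursts.counts_raw:
            raise ValidationError("ES rule requires ALEX data")
        E, S = _statistic(bursts, rule)
        with np.errstate(invalid="ignore"):
            return ((E >= rule.th1) & (E <= rule.th2)
                    & (S >= rule.S1) & (S <= rule.S2))
    stat = _statistic(bursts, rule)
    with np.errstate(invalid="ignore"):
        return (stat >= rule.th1) & (stat <= rule.th2)


def select(bursts: BurstSet, rule: SelectionRule) -> BurstSet:
    """New BurstSet with exactly the bursts passing ``rule`` (photon data
    shared with the input)."""
    return bursts.take(selection_mask(bursts, rule))


def select_chain(bursts: BurstSet, rules) -> BurstSet:
    """Apply rules sequentially (equivalent to AND of the masks)."""
    for rule in rules:
        bursts = select(bursts, rule)
    return bursts
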