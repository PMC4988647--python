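"""Photon data model for diffusion-based single-molecule FRET measurements.

A measurement is one or more *spots*, each holding a sorted array of integer
photon timestamps (in clock ticks of ``timestamps_unit`` seconds) with a
per-photon detector label (donor or acceptor emission channel).  With
alternating-laser excitation (ALEX) every photon additionally belongs to a
donor- or acceptor-excitation period; the alternation is *defined* by an
:class:`AlternationSpec` and *applied* by :func:`apply_alternation`, which
labels photons by their phase and discards photons outside both excitation
windows.

Subsets of photons — "photon streams" — are selected by emission channel and
excitation period through :class:`PhotonStream`.  Non-ALEX data has 3
canonical streams (all, Dem, Aem); ALEX data has 5 (all, DexDem, DexAem,
AexDem, AexAem), and arbitrary unions are allowed.

The module also reads/writes a minimal HDF5 layout (a small subset of the
Photon-HDF5 conventions): per-spot groups ``/photon_data`` (or
``/photon_dataN``) with ``timestamps``, ``detectors``,
``timestamps_specs/timestamps_unit``, optional ``nanotimes``, a two-code
spectral-channel map and the alternation metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import h5py
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DONOR", "ACCEPTOR", "DEX", "AEX",
    "FormatError", "ValidationError", "StateError",
    "PhotonStream", "AlternationSpec", "PhotonData", "Measurement",
    "ALL", "NONE", "DEM", "AEM",
    "DEX_DEM", "DEX_AEM", "AEX_DEM", "AEX_AEM", "DEX_ALL", "AEX_ALL",
    "canonical_streams",
    "load_photon_hdf5", "write_photon_hdf5",
    "alternation_histogram", "apply_alternation",
    "stream_mask", "stream_timestamps",
]

# integer detector / excitation codes used in the in-memory arrays
DONOR = 0      # donor emission channel (Dem)
ACCEPTOR = 1   # acceptor emission channel (Aem)
DEX = 0        # donor excitation period
AEX = 1        # acceptor excitation period


class FormatError(ValueError):
    """A file does not contain a mandatory group/field."""


class ValidationError(ValueError):
    """Data violates a structural invariant (e.g. unsorted timestamps)."""


class StateError(RuntimeError):
    """Operation invalid in the current pipeline state."""


# --------------------------------------------------------------------------
# Photon streams
# --------------------------------------------------------------------------

_CHANNELS = frozenset({"Dem", "Aem"})


def _parse_channels(spec) -> frozenset:
    if spec is None:
        return frozenset()
    if isinstance(spec, str):
        mapping = {"Dem": {"Dem"}, "Aem": {"Aem"}, "DAem": {"Dem", "Aem"}}
        if spec not in mapping:
            raise ValueError(f"unknown channel spec {spec!r}; use 'Dem', 'Aem' or 'DAem'")
        return frozenset(mapping[spec])
    chans = frozenset(spec)
    if not chans <= _CHANNELS:
        raise ValueError(f"unknown channels {sorted(chans - _CHANNELS)}")
    return chans


@dataclass(frozen=True)
class PhotonStream:
    """Selection of photons by emission channel and excitation period.

    ``dex`` / ``aex`` are the emission channels selected during donor /
    acceptor excitation periods.  They accept ``'Dem'``, ``'Aem'``,
    ``'DAem'`` or an iterable of channel names.  The empty selection (both
    empty) is the explicit "none" sentinel, :data:`NONE`.
    """

    dex: frozenset = frozenset()
    aex: frozenset = frozenset()

    def __init__(self, dex=None, aex=None):
        object.__setattr__(self, "dex", _parse_channels(dex))
        object.__setattr__(self, "aex", _parse_channels(aex))

    # -- predicates --------------------------------------------------------
    @property
    def is_none(self) -> bool:
        return not self.dex and not self.aex

    @property
    def is_all(self) -> bool:
        return self.dex == _CHANNELS and self.aex == _CHANNELS

    @property
    def period_specific(self) -> bool:
        """True when the selection distinguishes excitation periods."""
        return self.dex != self.aex

    def __or__(self, other: "PhotonStream") -> "PhotonStream":
        return PhotonStream(dex=self.dex | other.dex, aex=self.aex | other.aex)

    def __str__(self) -> str:
        if self.is_all:
            return "all"
        if self.is_none:
            return "none"
        parts = []
        for period, chans in (("Dex", self.dex), ("Aex", self.aex)):
            if chans:
                parts.append(period + ("DAem" if chans == _CHANNELS
                                       else next(iter(chans))))
        return "+".join(parts)


ALL = PhotonStream(dex="DAem", aex="DAem")
NONE = PhotonStream()
DEX_DEM = PhotonStream(dex="Dem")
DEX_AEM = PhotonStream(dex="Aem")
AEX_DEM = PhotonStream(aex="Dem")
AEX_AEM = PhotonStream(aex="Aem")
DEX_ALL = PhotonStream(dex="DAem")        # all photons during donor excitation
AEX_ALL = PhotonStream(aex="DAem")
# For non-ALEX data the donor-excitation channels are the only meaningful ones.
DEM = DEX_DEM
AEM = DEX_AEM

_STREAM_NAMES = {
    "all": ALL, "none": NONE,
    "Dem": DEM, "Aem": AEM,
    "DexDem": DEX_DEM, "DexAem": DEX_AEM,
    "AexDem": AEX_DEM, "AexAem": AEX_AEM,
    "DexDAem": DEX_ALL, "AexDAem": AEX_ALL,
}


def stream_from_name(name: str) -> PhotonStream:
    """Resolve a stream by its conventional name (e.g. ``'DexAem'``).

    Unions are written with ``+``: ``'DexDAem+AexAem'``.
    """
    sel = NONE
    for part in name.split("+"):
        part = part.strip()
        if part not in _STREAM_NAMES:
            raise ValueError(f"unknown photon stream name {part!r}")
        sel = sel | _STREAM_NAMES[part]
    return sel


def canonical_streams(alex: bool) -> list[PhotonStream]:
    """The canonical photon streams: 3 for non-ALEX data, 5 for ALEX."""
    if alex:
        return [ALL, DEX_DEM, DEX_AEM, AEX_DEM, AEX_AEM]
    return [ALL, DEM, AEM]


# --------------------------------------------------------------------------
# Alternation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AlternationSpec:
    """Definition of the laser alternation scheme.

    For ``us_alex`` the phase of a photon is its timestamp modulo ``period``
    (clock ticks); for ``ns_alex`` it is the TCSPC nanotime (TDC bins, with
    ``period`` the nanotime histogram span).  ``d_on``/``a_on`` are half-open
    integer ranges ``[start, stop)`` of phases assigned to donor/acceptor
    excitation; they must not overlap.
    """

    mode: str = "none"                       # none | us_alex | ns_alex
    period: int = 0
    d_on: tuple[int, int] = (0, 0)
    a_on: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if self.mode not in ("none", "us_alex", "ns_alex"):
            raise ValidationError(f"unknown alternation mode {self.mode!r}")
        if self.mode == "none":
            return
        if self.period <= 0:
            raise ValidationError("alternation period must be > 0")
        for name, (start, stop) in (("D_ON", self.d_on), ("A_ON", self.a_on)):
            if not (0 <= start < stop <= self.period):
                raise ValidationError(
                    f"{name}={start, stop} must satisfy 0 <= start < stop <= period"
                )
        lo, hi = sorted([self.d_on, self.a_on])
        if hi[0] < lo[1]:
            raise ValidationError("D_ON and A_ON ranges overlap")

    @property
    def is_alex(self) -> bool:
        return self.mode != "none"


NO_ALTERNATION = AlternationSpec()


# --------------------------------------------------------------------------
# Photon data containers
# --------------------------------------------------------------------------

@dataclass
class PhotonData:
    """Per-spot photon arrays.

    ``timestamps`` are sorted 64-bit integers, 0-based at acquisition start;
    ``timestamps_unit`` is seconds per clock tick (typically 10-50 ns).
    ``excitation`` (codes :data:`DEX`/:data:`AEX`) exists only after
    :func:`apply_alternation`.
    """

    timestamps: np.ndarray
    timestamps_unit: float
    detectors: np.ndarray
    nanotimes: Optional[np.ndarray] = None
    alternation: AlternationSpec = NO_ALTERNATION
    excitation: Optional[np.ndarray] = None
    alternation_applied: bool = False

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.detectors = np.asarray(self.detectors, dtype=np.int8)
        if self.nanotimes is not None:
            self.nanotimes = np.asarray(self.nanotimes, dtype=np.int64)
        if self.timestamps_unit <= 0:
            raise ValidationError("timestamps_unit must be > 0")
        if self.timestamps.ndim != 1:
            raise ValidationError("timestamps must be a 1-D array")
        n = len(self.timestamps)
        for name in ("detectors", "nanotimes", "excitation"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValidationError(f"{name} length {len(arr)} != timestamps length {n}")
        if n > 1 and np.any(np.diff(self.timestamps) < 0):
            raise ValidationError("timestamps are not sorted")
        bad = ~np.isin(self.detectors, (DONOR, ACCEPTOR))
        if bad.any():
            raise ValidationError(
                f"unknown detector codes {sorted(set(self.detectors[bad].tolist()))}"
            )

    @property
    def n_photons(self) -> int:
        return len(self.timestamps)

    @property
    def times_s(self) -> np.ndarray:
        """Timestamps in seconds."""
        return self.timestamps * self.timestamps_unit

    @property
    def duration_s(self) -> float:
        if self.n_photons == 0:
            return 0.0
        return float(self.timestamps[-1]) * self.timestamps_unit


@dataclass
class Measurement:
    """Aggregate container: spots plus downstream analysis results.

    ``background`` / ``bursts`` are per-spot lists filled in by the
    background and burst-search stages; ``coeffs`` holds the correction
    coefficients (γ, leakage, direct excitation).
    """

    spots: list
    metadata: dict = field(default_factory=dict)
    background: Optional[list] = None
    bursts: Optional[list] = None
    coeffs: object = None

    def __post_init__(self):
        if self.coeffs is None:
            from .corrections import CorrectionCoeffs
            self.coeffs = CorrectionCoeffs()
        for name in ("background", "bursts"):
            val = getattr(self, name)
            if val is not None and len(val) != self.n_spots:
                raise ValidationError(f"{name} list length != number of spots")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def alternation_applied(self) -> bool:
        return all(spot.alternation_applied for spot in self.spots)

    @property
    def is_alex(self) -> bool:
        return any(spot.alternation.is_alex for spot in self.spots)


# --------------------------------------------------------------------------
# HDF5 subset I/O
# --------------------------------------------------------------------------

_MODE_TO_TYPE = {"none": "smFRET", "us_alex": "smFRET-usALEX", "ns_alex": "smFRET-nsALEX"}
_TYPE_TO_MODE = {v: k for k, v in _MODE_TO_TYPE.items()}

# detector integer codes used on disk (mapped through the spectral-channel map)
_FILE_DONOR_CODE = 0
_FILE_ACCEPTOR_CODE = 1


def write_photon_hdf5(measurement: Measurement, path) -> None:
    """Write a Measurement to the minimal HDF5 layout read by
    :func:`load_photon_hdf5`.

    One group per spot (``/photon_data`` for single-spot files,
    ``/photon_dataN`` otherwise). Round trip preserves timestamps,
    detectors, unit, nanotimes and alternation metadata exactly.
    """
    if measurement.n_spots == 0:
        raise ValidationError("measurement has no spots")
    for i, spot in enumerate(measurement.spots):
        if spot.n_photons == 0:
            raise ValidationError(f"spot {i} has no photons")
    with h5py.File(path, "w") as f:
        for i, spot in enumerate(measurement.spots):
            name = "photon_data" if measurement.n_spots == 1 else f"photon_data{i}"
            g = f.create_group(name)
            g.create_dataset("timestamps", data=spot.timestamps, dtype=np.int64)
            g.create_dataset("detectors", data=spot.detectors.astype(np.int8))
            g.create_dataset("timestamps_specs/timestamps_unit",
                             data=float(spot.timestamps_unit))
            if spot.nanotimes is not None:
                g.create_dataset("nanotimes", data=spot.nanotimes, dtype=np.int64)
            ds = g.create_group("detectors_specs")
            ds.create_dataset("spectral_ch1", data=_FILE_DONOR_CODE)
            ds.create_dataset("spectral_ch2", data=_FILE_ACCEPTOR_CODE)
            ms = g.create_group("measurement_specs")
            alt = spot.alternation
            ms.create_dataset(
                "measurement_type",
                data=np.bytes_(_MODE_TO_TYPE[alt.mode]))
            if alt.is_alex:
                ms.create_dataset("alex_period", data=int(alt.period))
                ms.create_dataset("alex_excitation_period1",
                                  data=np.asarray(alt.d_on, dtype=np.int64))
                ms.create_dataset("alex_excitation_period2",
                                  data=np.asarray(alt.a_on, dtype=np.int64))
        meta = f.create_group("identity")
        for key, val in measurement.metadata.items():
            try:
                meta.create_dataset(key, data=np.bytes_(str(val)))
            except TypeError:  # pragma: no cover - non-serializable metadata
                logger.warning("skipping non-serializable metadata key %r", key)


def _require(group, name, path):
    if name not in group:
        raise FormatError(f"missing mandatory field '{path}/{name}'")
    return group[name]


def load_photon_hdf5(path) -> Measurement:
    """Load a Measurement from the HDF5 subset layout.

    Alternation metadata is loaded but NOT applied; call
    :func:`apply_alternation` to label and filter photons.  Detector codes
    are mapped to donor/acceptor through the file's spectral-channel map;
    any other code raises :class:`ValidationError`.
    """
    with h5py.File(path, "r") as f:
        names = sorted(k for k in f.keys() if k.startswith("photon_data"))
        known = set(names) | {"identity"}
        for k in f.keys():
            if k not in known:
                logger.warning("ignoring unknown HDF5 group '/%s'", k)
        if not names:
            raise FormatError("missing mandatory group '/photon_data'")
        spots = []
        for name in names:
            g = f[name]
            ts = _require(g, "timestamps", name)[()]
            det_raw = _require(g, "detectors", name)[()]
            tspecs = _require(g, "timestamps_specs", name)
            unit = float(_require(tspecs, "timestamps_unit",
                                  f"{name}/timestamps_specs")[()])
            nanotimes = g["nanotimes"][()] if "nanotimes" in g else None

            dspecs = _require(g, "detectors_specs", name)
            ch_d = int(_require(dspecs, "spectral_ch1", f"{name}/detectors_specs")[()])
            ch_a = int(_require(dspecs, "spectral_ch2", f"{name}/detectors_specs")[()])
            detectors = np.full(len(det_raw), -1, dtype=np.int8)
            detectors[det_raw == ch_d] = DONOR
            detectors[det_raw == ch_a] = ACCEPTOR
            if (detectors < 0).any():
                bad = sorted(set(det_raw[detectors < 0].tolist()))
                raise ValidationError(f"unmapped detector codes {bad} in '{name}'")

            alt = NO_ALTERNATION
            if "measurement_specs" in g:
                ms = g["measurement_specs"]
                mtype = _require(ms, "measurement_type",
                                 f"{name}/measurement_specs")[()]
                mode = _TYPE_TO_MODE.get(
                    mtype.decode() if isinstance(mtype, bytes) else str(mtype))
                if mode is None:
                    raise FormatError(f"unknown measurement_type {mtype!r}")
                if mode != "none":
                    period = int(_require(ms, "alex_period",
                                          f"{name}/measurement_specs")[()])
                    d_on = tuple(int(x) for x in ms["alex_excitation_period1"][()])
                    a_on = tuple(int(x) for x in ms["alex_excitation_period2"][()])
                    alt = AlternationSpec(mode=mode, period=period,
                                          d_on=d_on, a_on=a_on)
            spots.append(PhotonData(timestamps=ts, timestamps_unit=unit,
                                    detectors=detectors, nanotimes=nanotimes,
                                    alternation=alt))
        metadata = {}
        if "identity" in f:
            for key, ds in f["identity"].items():
                val = ds[()]
                metadata[key] = val.decode() if isinstance(val, bytes) else val
    return Measurement(spots=spots, metadata=metadata)


# --------------------------------------------------------------------------
# Alternation application
# --------------------------------------------------------------------------

def _phases(spot: PhotonData) -> np.ndarray:
    alt = spot.alternation
    if alt.mode == "us_alex":
        return spot.timestamps % alt.period
    if alt.mode == "ns_alex":
        if spot.nanotimes is None:
            raise ValidationError("ns-ALEX data requires nanotimes")
        return spot.nanotimes
    raise StateError("no alternation defined")


def alternation_histogram(spot: PhotonData, n_bins: int = 100):
    """Histogram of photon phases, one count array per detector channel.

    For μs-ALEX the phase is the timestamp modulo the alternation period;
    for ns-ALEX it is the nanotime.  Returns ``(bin_edges, counts)`` with
    ``counts`` a dict ``{'Dem': array, 'Aem': array}``.
    """
    phases = _phases(spot)
    edges = np.linspace(0, spot.alternation.period, n_bins + 1)
    counts = {}
    for label, code in (("Dem", DONOR), ("Aem", ACCEPTOR)):
        counts[label], _ = np.histogram(phases[spot.detectors == code], bins=edges)
    return edges, counts


def apply_alternation(measurement: Measurement) -> Measurement:
    """Label photons by excitation period and drop photons outside both.

    A photon whose phase falls in ``D_ON`` gets the donor-excitation label,
    in ``A_ON`` the acceptor-excitation label; all other photons are
    removed.  Returns a new Measurement flagged as applied; applying twice
    raises :class:`StateError` (the file must be reloaded to change the
    period definitions).
    """
    if measurement.alternation_applied:
        raise StateError("alternation already applied; "
                         "the data file will need to be reloaded")
    new_spots = []
    for spot in measurement.spots:
        phases = _phases(spot)
        alt = spot.alternation
        d_mask = (phases >= alt.d_on[0]) & (phases < alt.d_on[1])
        a_mask = (phases >= alt.a_on[0]) & (phases < alt.a_on[1])
        keep = d_mask | a_mask
        excitation = np.where(d_mask, DEX, AEX).astype(np.int8)[keep]
        new_spots.append(replace(
            spot,
            timestamps=spot.timestamps[keep],
            detectors=spot.detectors[keep],
            nanotimes=None if spot.nanotimes is None else spot.nanotimes[keep],
            excitation=excitation,
            alternation_applied=True,
        ))
    return Measurement(spots=new_spots, metadata=dict(measurement.metadata),
                       coeffs=measurement.coeffs)


# --------------------------------------------------------------------------
# Stream selection
# --------------------------------------------------------------------------

def stream_mask(spot: PhotonData, sel: PhotonStream) -> np.ndarray:
    """Boolean mask over the spot's photons matching the stream selection.

    For non-alternated data only the donor-excitation channels of ``sel``
    are meaningful; a period-specific selection raises
    :class:`StateError`.
    """
    n = spot.n_photons
    if sel.is_none:
        return np.zeros(n, dtype=bool)
    if sel.is_all:
        return np.ones(n, dtype=bool)
    det = spot.detectors
    if spot.excitation is None:
        if spot.alternation.is_alex and sel.period_specific:
            raise StateError(
                f"stream {sel} is excitation-period specific but alternation "
                "has not been applied")
        if not spot.alternation.is_alex and sel.aex and sel.aex != sel.dex:
            raise StateError(
                f"stream {sel} selects acceptor-excitation photons but the "
                "data has no alternation")
        # non-ALEX (or pre-alternation, non-period-specific): the
        # donor-excitation channels are the emission-channel selection
        mask = np.zeros(n, dtype=bool)
        if "Dem" in sel.dex:
            mask |= det == DONOR
        if "Aem" in sel.dex:
            mask |= det == ACCEPTOR
        return mask
    exc = spot.excitation
    mask = np.zeros(n, dtype=bool)
    for chans, code in ((sel.dex, DEX), (sel.aex, AEX)):
        if "Dem" in chans:
            mask |= (exc == code) & (det == DONOR)
        if "Aem" in chans:
            mask |= (exc == code) & (det == ACCEPTOR)
    return mask


def stream_timestamps(spot: PhotonData, sel: PhotonStream) -> np.ndarray:
    """Timestamps (clock ticks) of the photons selected by ``sel``."""
    return spot.timestamps[stream_mask(spot, sel)]
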