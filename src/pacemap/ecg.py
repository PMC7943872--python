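"""Core ECG containers and waveform operations for pace mapping.

A pace-mapping dataset is a set of endocardial pacing sites, each with a
known 3-D catheter position (mm) and a stack of paced 12-lead ECG beats
(mV).  Every localization model downstream works either on the averaged
*representative beat* of a site or on its *splice vector* — the 12
per-lead 150-ms windows, centered on the maximum of the 12-lead composite
signal and concatenated in canonical lead order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LEAD_ORDER",
    "EcgBeat",
    "SpliceVector",
    "PacingSite",
    "PatientDataset",
    "average_beats",
    "composite_signal",
    "extract_splice",
]

#: Canonical 12-lead order used throughout: limb, augmented, precordial.
LEAD_ORDER: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

N_LEADS = 12

#: Default splice window length (ms) around the composite-signal maximum.
DEFAULT_WINDOW_MS = 150.0


class ShapeError(ValueError):
    """Raised when ECG arrays have inconsistent or invalid shapes."""


class BoundaryError(ValueError):
    """Raised when a requested window does not fit inside the recording."""


@dataclass(frozen=True)
class EcgBeat:
    """One 12-lead ECG beat.

    Parameters
    ----------
    voltages:
        ``(12, T)`` array of lead voltages in mV, rows in :data:`LEAD_ORDER`.
    sampling_rate:
        Sampling rate in Hz (> 0).
    """

    voltages: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, dtype=float)
        if v.ndim != 2 or v.shape[0] != N_LEADS:
            raise ShapeError(
                f"expected a (12, T) voltage matrix, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("beat voltages must be finite")
        if not (self.sampling_rate > 0 and np.isfinite(self.sampling_rate)):
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        object.__setattr__(self, "voltages", v)

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]


@dataclass(frozen=True)
class SpliceVector:
    """Concatenated per-lead windows of one beat (the waveform vector W).

    ``values`` has length ``12 * window_samples``: lead I's window first,
    then lead II, ... in :data:`LEAD_ORDER`.  ``center_index`` is the
    sample index, in the source beat, of the composite-signal maximum the
    windows were centered on.
    """

    values: np.ndarray
    window_samples: int
    center_index: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != N_LEADS * self.window_samples:
            raise ShapeError(
                f"splice length {v.size} != 12 * window_samples "
                f"({N_LEADS * self.window_samples})"
            )
        object.__setattr__(self, "values", v)

    def lead(self, i: int) -> np.ndarray:
        """Return the window of lead ``i`` (0-based in canonical order)."""
        w = self.window_samples
        return self.values[i * w:(i + 1) * w]

    def by_lead(self) -> np.ndarray:
        """Return the splice reshaped to ``(12, window_samples)``."""
        return self.values.reshape(N_LEADS, self.window_samples)


@dataclass
class PacingSite:
    """A pacing site: position, raw beats, and derived waveforms.

    ``representative`` (beat average) and ``splice`` are computed lazily on
    first access and cached.
    """

    site_id: str
    position: np.ndarray
    beats: Sequence[EcgBeat]
    _representative: EcgBeat | None = field(default=None, repr=False)
    _splice: SpliceVector | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float)
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise ValueError(f"site {self.site_id}: position must be a finite 3-vector")
        self.position = p
        if len(self.beats) < 1:
            raise ValueError(f"site {self.site_id}: at least one beat required")
        sr = self.beats[0].sampling_rate
        t = self.beats[0].n_samples
        for b in self.beats:
            if b.sampling_rate != sr or b.n_samples != t:
                raise ShapeError(
                    f"site {self.site_id}: beats must share sampling rate and length"
                )

    @property
    def representative(self) -> EcgBeat:
        if self._representative is None:
            self._representative = average_beats(self.beats)
        return self._representative

    @property
    def splice(self) -> SpliceVector:
        if self._splice is None:
            self._splice = extract_splice(self.representative)
        return self._splice


@dataclass
class PatientDataset:
    """All pacing sites of one patient, in one Cartesian frame (mm)."""

    patient_id: str
    sites: list[PacingSite]

    def __post_init__(self) -> None:
        if len(self.sites) < 2:
            raise ValueError("a dataset needs at least 2 pacing sites")
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("site_ids must be unique")

    def site(self, site_id: str) -> PacingSite:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    def positions(self) -> np.ndarray:
        return np.stack([s.position for s in self.sites])


def average_beats(beats: Sequence[EcgBeat]) -> EcgBeat:
    """Element-wise mean of beats: the site's representative beat.

    All beats must share shape and sampling rate.
    """
    if len(beats) == 0:
        raise ValueError("cannot average an empty beat sequence")
    sr = beats[0].sampling_rate
    shape = beats[0].voltages.shape
    for b in beats:
        if b.voltages.shape != shape or b.sampling_rate != sr:
            raise ShapeError("beats must share shape and sampling rate")
    mean = np.mean([b.voltages for b in beats], axis=0)
    return EcgBeat(voltages=mean, sampling_rate=sr)


def composite_signal(beat: EcgBeat) -> np.ndarray:
    """Per-sample sum of absolute voltages across the 12 leads.

    Used as the single alignment signal: its maximum marks the splice
    center, and QRS onset is searched on it.  Summing magnitudes avoids
    sign cancellation between leads of opposite polarity.
    """
    return np.sum(np.abs(beat.voltages), axis=0)


def window_samples(sampling_rate: float, window_ms: float = DEFAULT_WINDOW_MS) -> int:
    """Window length in samples for ``window_ms`` at ``sampling_rate``."""
    w = int(round(window_ms * sampling_rate / 1000.0))
    if w < 1:
        raise ValueError("window shorter than one sample")
    return w


def extract_splice(beat: EcgBeat, window_ms: float = DEFAULT_WINDOW_MS) -> SpliceVector:
    """Extract the 12 concatenated ``window_ms`` windows centered on the
    composite-signal maximum.

    The window covers samples ``[c - w//2, c - w//2 + w)`` where ``c`` is
    the composite argmax (earliest sample on ties).  A window that would
    overrun either edge of the recording raises :class:`BoundaryError`
    rather than padding silently.
    """
    w = window_samples(beat.sampling_rate, window_ms)
    if beat.n_samples < w:
        raise BoundaryError(
            f"beat has {beat.n_samples} samples, window needs {w}"
        )
    comp = composite_signal(beat)
    center = int(np.argmax(comp))  # argmax returns the earliest tie
    start = center - w // 2
    stop = start + w
    if start < 0 or stop > beat.n_samples:
        raise BoundaryError(
            f"window [{start}, {stop}) overruns the beat extent "
            f"[0, {beat.n_samples}) — composite maximum too close to an edge"
        )
    values = beat.voltages[:, start:stop].reshape(-1)
    return SpliceVector(values=values, window_samples=w, center_index=center)
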