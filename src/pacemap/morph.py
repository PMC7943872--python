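"""Morphology-domain quantities compared between pacing sites.

Four quantities drive the localizers:

* the initial 120-ms QRS integrals of leads III, V2 and V6 (regression
  predictors),
* ``e12`` — the sum over leads of the per-lead RMS voltage difference
  between two splice vectors (a morphology distance),
* ``corr12`` — the mean per-lead Pearson correlation (a similarity),
* ``wave_diff`` — the raw waveform-difference vector dw between two
  splice vectors (the morphological counterpart of the spatial
  position-difference dp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ecg import EcgBeat, ShapeError, SpliceVector, composite_signal

__all__ = [
    "QrsIntTriple",
    "WaveDiff",
    "detect_qrs_onset",
    "qrs_integrals",
    "e12",
    "corr12",
    "wave_diff",
]

#: Leads whose initial QRS integrals act as regression predictors
#: (0-based indices of III, V2, V6 in the canonical lead order).
QRS_INT_LEADS: tuple[int, int, int] = (2, 7, 11)

QRS_INT_WINDOW_MS = 120.0

#: Fraction of the composite-signal maximum used as the onset threshold.
ONSET_THRESHOLD_FRACTION = 0.05


class DegenerateLeadError(ValueError):
    """Raised when a correlation is undefined on every lead."""


@dataclass(frozen=True)
class QrsIntTriple:
    """Initial 120-ms QRS integrals of leads III, V2, V6 (mV*ms), signed."""

    values: np.ndarray
    integration_window_ms: float = QRS_INT_WINDOW_MS

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (3,) or not np.all(np.isfinite(v)):
            raise ValueError("QRS integrals must be a finite 3-vector")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class WaveDiff:
    """Waveform-difference vector dw = W(to) - W(from), antisymmetric."""

    values: np.ndarray
    from_id: str
    to_id: str


def detect_qrs_onset(beat: EcgBeat) -> int:
    """Automated QRS-onset estimate on the composite signal.

    Starting from the composite-signal argmax, scan backward and return
    the first sample of the contiguous run on which the composite exceeds
    5% of its maximum.  Deterministic for a fixed beat.

    Raises
    ------
    ValueError
        If the beat is flat (no deflection to anchor an onset on).
    """
    comp = composite_signal(beat)
    peak = float(comp.max())
    if peak <= 0.0:
        raise ValueError("flat beat: no QRS onset detectable")
    threshold = ONSET_THRESHOLD_FRACTION * peak
    idx = int(np.argmax(comp))
    onset = idx
    while onset > 0 and comp[onset - 1] > threshold:
        onset -= 1
    return onset


def qrs_integrals(
    beat: EcgBeat,
    onset: int,
    window_ms: float = QRS_INT_WINDOW_MS,
) -> QrsIntTriple:
    """Signed trapezoidal integrals of leads III, V2, V6 over the initial
    ``window_ms`` from QRS onset, in mV*ms.

    Signed (not rectified) integrals are required: the downstream
    regression uses them as linear predictors of position.
    """
    n_win = int(round(window_ms * beat.sampling_rate / 1000.0))
    stop = onset + n_win + 1  # inclusive right edge: integral spans the full window
    if onset < 0 or stop > beat.n_samples:
        raise ValueError(
            f"integration window [{onset}, {stop}) overruns the beat "
            f"extent [0, {beat.n_samples})"
        )
    dt_ms = 1000.0 / beat.sampling_rate
    segment = beat.voltages[list(QRS_INT_LEADS), onset:stop]
    vals = np.trapezoid(segment, dx=dt_ms, axis=1)
    return QrsIntTriple(values=vals, integration_window_ms=window_ms)


def _check_compatible(a: SpliceVector, b: SpliceVector) -> None:
    if a.window_samples != b.window_samples or a.values.size != b.values.size:
        raise ShapeError("splice vectors differ in length or window size")


def e12(a: SpliceVector, b: SpliceVector) -> float:
    """Morphology distance: sum over the 12 leads of the per-lead RMS
    voltage difference, in mV.

    For each lead the RMS difference is ``sqrt(mean((Va - Vb)^2))`` over
    the window; the 12 per-lead values are summed.  Symmetric, zero iff
    the splices are identical, and a true metric (each term is a scaled
    Euclidean norm of the per-lead difference).
    """
    _check_compatible(a, b)
    diff = a.by_lead() - b.by_lead()
    return float(np.sum(np.sqrt(np.mean(diff**2, axis=1))))


def corr12(a: SpliceVector, b: SpliceVector) -> float:
    """Mean per-lead Pearson correlation between two splices, in [-1, 1].

    A lead whose window is constant in either input has no defined
    correlation; such leads are dropped and the mean taken over the
    remaining ones.  If every lead is degenerate a
    :class:`DegenerateLeadError` is raised.
    """
    _check_compatible(a, b)
    xa = a.by_lead()
    xb = b.by_lead()
    da = xa - xa.mean(axis=1, keepdims=True)
    db = xb - xb.mean(axis=1, keepdims=True)
    sa = np.sqrt(np.sum(da**2, axis=1))
    sb = np.sqrt(np.sum(db**2, axis=1))
    valid = (sa > 0) & (sb > 0)
    if not np.any(valid):
        raise DegenerateLeadError("all 12 leads are constant: correlation undefined")
    num = np.sum(da[valid] * db[valid], axis=1)
    r = num / (sa[valid] * sb[valid])
    return float(np.clip(r, -1.0, 1.0).mean())


def wave_diff(a: SpliceVector, b: SpliceVector, from_id: str = "", to_id: str = "") -> WaveDiff:
    """Waveform-difference vector dw(a -> b) = W_b - W_a."""
    _check_compatible(a, b)
    return WaveDiff(values=b.values - a.values, from_id=from_id, to_id=to_id)
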