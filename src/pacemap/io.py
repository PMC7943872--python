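"""Dataset containers on disk.

Native format: HDF5 with one group per site::

    /                     attrs: patient_id, position_units, voltage_units
    /sites/<site_id>/position   (3,)  float64, mm
    /sites/<site_id>/beats      (n_beats, 12, T) float64, mV
                          attrs: sampling_rate_hz

Sites are written in sorted site-id order and datasets are created with
HDF5 timestamps disabled, so writing the same dataset twice produces
byte-identical files.

A best-effort adapter for MATLAB-container exports (as distributed by
public electrocardiographic-imaging repositories) is provided; field
layouts vary by contributing lab, so the adapter is optional and the
expected field names are documented on :func:`read_mat_dataset`.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .ecg import EcgBeat, PacingSite, PatientDataset

__all__ = ["read_dataset", "write_dataset", "read_mat_dataset", "FormatError"]


class FormatError(ValueError):
    """A container file violates the expected layout."""


def write_dataset(dataset: PatientDataset, path: str | Path) -> None:
    """Write a dataset to the native HDF5 container (deterministic bytes)."""
    path = Path(path)
    with h5py.File(path, "w", track_order=False) as f:
        f.attrs["patient_id"] = dataset.patient_id
        f.attrs["position_units"] = "mm"
        f.attrs["voltage_units"] = "mV"
        grp = f.create_group("sites")
        for site in sorted(dataset.sites, key=lambda s: s.site_id):
            g = grp.create_group(site.site_id)
            g.create_dataset("position", data=site.position, track_times=False)
            beats = np.stack([b.voltages for b in site.beats])
            d = g.create_dataset("beats", data=beats, track_times=False)
            d.attrs["sampling_rate_hz"] = float(site.beats[0].sampling_rate)


def read_dataset(path: str | Path) -> PatientDataset:
    """Read a native HDF5 container into a validated :class:`PatientDataset`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sites = []
    with h5py.File(path, "r") as f:
        if "sites" not in f:
            raise FormatError(f"{path}: missing /sites group")
        patient_id = str(f.attrs.get("patient_id", path.stem))
        for site_id in sorted(f["sites"]):
            g = f["sites"][site_id]
            if "position" not in g:
                raise FormatError(f"{path}: site {site_id} has no position")
            if "beats" not in g:
                raise FormatError(f"{path}: site {site_id} has no beats")
            beats_ds = g["beats"]
            if "sampling_rate_hz" not in beats_ds.attrs:
                raise FormatError(
                    f"{path}: site {site_id}: sampling_rate_hz attribute missing"
                )
            sr = float(beats_ds.attrs["sampling_rate_hz"])
            arr = np.asarray(beats_ds, dtype=float)
            if arr.ndim != 3 or arr.shape[1] != 12:
                raise FormatError(
                    f"{path}: site {site_id}: beats must be (n, 12, T), "
                    f"got {arr.shape}"
                )
            position = np.asarray(g["position"], dtype=float)
            beats = [EcgBeat(voltages=b, sampling_rate=sr) for b in arr]
            sites.append(PacingSite(site_id=site_id, position=position, beats=beats))
    return PatientDataset(patient_id=patient_id, sites=sites)


def read_mat_dataset(
    path: str | Path,
    position_key: str = "positions",
    beats_key: str = "beats",
    sampling_rate_key: str = "sampling_rate",
    patient_id: str | None = None,
) -> PatientDataset:
    """Best-effort adapter for MATLAB containers.

    Expects ``positions`` (n_sites, 3) in mm, ``beats`` either an
    (n_sites,) object array of (n_beats, 12, T) arrays or a single
    (n_sites, n_beats, 12, T) array in mV, and a scalar
    ``sampling_rate`` in Hz.  Field names are overridable because
    repository layouts differ per contributing lab; confirm against the
    actual download before relying on this reader.
    """
    from scipy.io import loadmat

    raw = loadmat(str(path), squeeze_me=True)
    for key in (position_key, beats_key, sampling_rate_key):
        if key not in raw:
            raise FormatError(f"{path}: field {key!r} not found in MAT container")
    positions = np.atleast_2d(np.asarray(raw[position_key], dtype=float))
    sr = float(raw[sampling_rate_key])
    beats_raw = raw[beats_key]
    sites = []
    for i, pos in enumerate(positions):
        arr = np.asarray(
            beats_raw[i] if isinstance(beats_raw, np.ndarray) and beats_raw.dtype == object
            else beats_raw[i],
            dtype=float,
        )
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3 or arr.shape[1] != 12:
            raise FormatError(
                f"{path}: site {i}: beats must be (n, 12, T), got {arr.shape}"
            )
        beats = [EcgBeat(voltages=b, sampling_rate=sr) for b in arr]
        sites.append(PacingSite(site_id=f"M{i:03d}", position=pos, beats=beats))
    return PatientDataset(patient_id=patient_id or Path(path).stem, sites=sites)
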