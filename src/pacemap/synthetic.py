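"""Synthetic paced-ECG generator for pace-mapping experiments.

Emulates the structure of a clinical endocardial-pacing dataset: ~25
pacing sites on a ventricular-like ellipsoid shell, each with ~28 noisy
12-lead beats, and a forward model mapping catheter position to waveform.

Two forward modes are provided:

``affine``
    Each lead's waveform is ``b_l(t) + G * Phi(t) R_l p`` — a fixed
    common QRS bump plus a position part built from three orthonormal
    temporal shapes ``Phi`` rotated per lead.  The construction makes
    every downstream model's core assumption *exactly* true: QRS
    integrals are affine in position, the per-lead position encoding is
    an isometry (so the E12 morphology distance is exactly proportional
    to Euclidean distance), and the splice map is globally affine (so the
    transfer-matrix model is algebraically exact).  This mode is a
    non-physiological calibration standard, not a heart model.

``isotropic``
    A traveling-wavefront dipole model: the depolarization spreads from
    the pacing site at a fixed conduction velocity (default 0.7 m/s);
    each surface patch, on activation, contributes a dipole oriented
    along the local propagation direction, projected onto 12 fixed lead
    vectors.  Nonlinear in position — exercises the models off their
    assumptions.

Determinism: a fixed config (including ``seed``) reproduces the dataset
bit for bit.  Beat noise is drawn as ``sd * standard_normal`` from a
stream that depends on the seed but not on ``sd``, so datasets differing
only in noise level share the same underlying noise realization, scaled.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .ecg import EcgBeat, PacingSite, PatientDataset

__all__ = [
    "SyntheticConfig",
    "make_geometry",
    "forward_ecg",
    "make_dataset",
    "dataset_digest",
    "affine_components",
    "activation_time_ms",
]

SAMPLING_RATE_HZ = 1000.0
N_SAMPLES = 400

# --- affine-mode waveform constants (samples at 1000 Hz) -------------------

#: Common QRS bump: sin^2 on [160, 240], peak (value 1) at sample 200.
_BUMP_START, _BUMP_STOP, _BUMP_PEAK = 160, 240, 200

#: Per-lead amplitudes (mV) of the common bump.  aVR is inverted, as on a
#: real ECG; magnitudes are what matter for alignment.
_LEAD_AMPLITUDES = np.array(
    [1.2, 1.5, 1.4, -1.3, 1.1, 1.6, 1.8, 2.0, 1.9, 1.7, 1.5, 1.3]
)

#: Gain of the position-dependent part, mV per mm.  Small enough that the
#: composite-signal argmax and the QRS onset stay pinned by the common
#: bump for any position on the shell (|p| <= ~70 mm).
_WAVE_GAIN = 0.02

#: Supports of the three orthonormal temporal shapes (half-sine bumps).
#: Disjoint, inside the 150-ms splice window, zero around the composite
#: peak (sample 200), and fully inside the 120-ms QRS-integral window.
_SHAPE_SUPPORTS = ((170, 191), (210, 231), (245, 266))


def _temporal_shapes(n_samples: int) -> np.ndarray:
    """The (T, 3) orthonormal temporal shape matrix Phi."""
    phi = np.zeros((n_samples, 3))
    for k, (a, b) in enumerate(_SHAPE_SUPPORTS):
        t = np.arange(a, b)
        bump = np.sin(np.pi * (t - a) / (b - 1 - a))
        phi[a:b, k] = bump / np.linalg.norm(bump)
    return phi


def _lead_rotations() -> np.ndarray:
    """Fixed (12, 3, 3) orthogonal matrices mixing the temporal shapes.

    Leads III, V2 and V6 (indices 2, 7, 11) are built from the basis
    {(1,1,1)/sqrt3, (1,-1,0)/sqrt2, (1,1,-2)/sqrt6} so that their QRS
    integrals respond to orthogonal spatial directions — the integral of
    each temporal shape is identical, so a column ordering that puts the
    all-ones direction in slots x, y, z respectively yields a perfectly
    conditioned integral-to-position map.  The remaining leads get fixed
    pseudo-random rotations (seeded constant) for variety.
    """
    u1 = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
    u2 = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)
    u3 = np.array([1.0, 1.0, -2.0]) / np.sqrt(6)
    rng = np.random.default_rng(20210224)
    rots = np.empty((12, 3, 3))
    for i in range(12):
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rots[i] = q
    rots[2] = np.column_stack([u1, u2, u3])   # lead III -> x
    rots[7] = np.column_stack([u2, u1, u3])   # lead V2  -> y
    rots[11] = np.column_stack([u2, u3, u1])  # lead V6  -> z
    return rots


_PHI = _temporal_shapes(N_SAMPLES)
_ROTS = _lead_rotations()


def affine_components(n_samples: int = N_SAMPLES) -> tuple[np.ndarray, np.ndarray]:
    """Return (A, b) of the affine forward map: voltages = b + A @ p.

    ``A`` has shape (12, T, 3) (mV per mm) and ``b`` shape (12, T) (mV).
    Exposed so tests can treat the generator as an algebraic oracle.
    """
    phi = _temporal_shapes(n_samples) if n_samples != N_SAMPLES else _PHI
    a = _WAVE_GAIN * np.einsum("tk,lkj->ltj", phi, _ROTS)
    t = np.arange(n_samples)
    g = np.zeros(n_samples)
    rise = (t >= _BUMP_START) & (t < _BUMP_STOP)
    g[rise] = np.sin(np.pi * (t[rise] - _BUMP_START) / (_BUMP_STOP - _BUMP_START)) ** 2
    b = _LEAD_AMPLITUDES[:, None] * g[None, :]
    return a, b


# --- isotropic-conduction mode ---------------------------------------------

#: Fixed unit lead vectors: frontal-plane limb leads (x = patient left,
#: y = inferior) and horizontal-plane precordials (z = anterior).
#: Approximate textbook axes; hard-coded for reproducibility.
_LEAD_VECTORS = np.array(
    [
        [1.000, 0.000, 0.000],    # I
        [0.500, 0.866, 0.000],    # II
        [-0.500, 0.866, 0.000],   # III
        [-0.866, -0.500, 0.000],  # aVR
        [0.866, -0.500, 0.000],   # aVL
        [0.000, 1.000, 0.000],    # aVF
        [-0.342, 0.000, 0.940],   # V1
        [-0.174, 0.000, 0.985],   # V2
        [0.174, 0.000, 0.985],    # V3
        [0.500, 0.000, 0.866],    # V4
        [0.766, 0.000, 0.643],    # V5
        [0.985, 0.000, 0.174],    # V6
    ]
)

_N_PATCHES = 256
_PULSE_SIGMA_MS = 8.0
_ACTIVATION_DELAY_MS = 80.0
_DIPOLE_GAIN_MV = 30.0  # scales the summed dipole projection to mV range
#: Distance scale (mm) of the near-field weighting 1 / (1 + (d/scale)^2):
#: sources close to the pacing site dominate the early QRS, which keeps the
#: detectable onset close to the true activation start.
_NEARFIELD_SCALE_MM = 30.0


def activation_time_ms(distance_mm: float, conduction_velocity: float) -> float:
    """Activation delay of a patch ``distance_mm`` from the pacing site at
    ``conduction_velocity`` m/s (mm / (m/s) = ms)."""
    if conduction_velocity <= 0:
        raise ValueError("conduction velocity must be positive")
    return distance_mm / conduction_velocity


def _fibonacci_shell(n: int, semi_axes: np.ndarray) -> np.ndarray:
    """Quasi-uniform points on the ellipsoid via a Fibonacci sphere."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = 1 - 2 * (i + 0.5) / n
    r = np.sqrt(1 - z**2)
    phi = 2 * np.pi * i / golden
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts * semi_axes


# --- configuration ----------------------------------------------------------

Mode = Literal["affine", "isotropic"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters for one synthetic patient.

    Defaults mirror a typical clinical pacing dataset: 25 distinct sites,
    28 beats per site, 0.7 m/s conduction.
    """

    n_sites: int = 25
    semi_axes: tuple[float, float, float] = (30.0, 35.0, 50.0)
    mode: Mode = "affine"
    conduction_velocity: float = 0.7
    beats_per_site: int = 28
    beat_noise_sd: float = 0.05
    min_spacing: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 6:
            raise ValueError("n_sites must be >= 6")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")
        if self.mode not in ("affine", "isotropic"):
            raise ValueError(f"unknown forward mode {self.mode!r}")
        if self.conduction_velocity <= 0:
            raise ValueError("conduction_velocity must be positive")
        if self.beats_per_site < 1:
            raise ValueError("beats_per_site must be >= 1")
        if self.beat_noise_sd < 0:
            raise ValueError("beat_noise_sd must be >= 0")


def make_geometry(config: SyntheticConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Sample ``n_sites`` positions on the ellipsoid shell with a minimum
    pairwise spacing, by rejection.  Returns an (n, 3) array in mm."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    axes = np.asarray(config.semi_axes)
    points: list[np.ndarray] = []
    max_tries = 4000 * config.n_sites
    tries = 0
    while len(points) < config.n_sites:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {config.n_sites} sites with spacing "
                f">= {config.min_spacing} mm on the shell"
            )
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        p = u * axes
        if all(np.linalg.norm(p - q) >= config.min_spacing for q in points):
            points.append(p)
    return np.stack(points)


def _base_waveform(position: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Noise-free (12, T) waveform for a pacing position."""
    p = np.asarray(position, dtype=float)
    if config.mode == "affine":
        a, b = affine_components()
        return b + a @ p
    # isotropic traveling wavefront
    patches = _fibonacci_shell(_N_PATCHES, np.asarray(config.semi_axes))
    deltas = patches - p
    dists = np.linalg.norm(deltas, axis=1)
    live = dists > 1e-9
    deltas, dists = deltas[live], dists[live]
    directions = deltas / dists[:, None]
    weights = 1.0 / (1.0 + (dists / _NEARFIELD_SCALE_MM) ** 2)
    t_act = _ACTIVATION_DELAY_MS + dists / config.conduction_velocity
    t = np.arange(N_SAMPLES) * 1000.0 / SAMPLING_RATE_HZ
    pulses = weights[:, None] * np.exp(
        -0.5 * ((t[None, :] - t_act[:, None]) / _PULSE_SIGMA_MS) ** 2
    )
    projections = directions @ _LEAD_VECTORS.T  # (patches, 12)
    return _DIPOLE_GAIN_MV / float(weights.sum()) * (projections.T @ pulses)


def forward_ecg(
    position: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> list[EcgBeat]:
    """Simulate ``beats_per_site`` paced beats at ``position``.

    Noise is additive i.i.d. Gaussian per sample, ``beat_noise_sd`` mV,
    drawn as ``sd * standard_normal`` so that the realization depends on
    the RNG state but not on the noise level.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    base = _base_waveform(position, config)
    beats = []
    for _ in range(config.beats_per_site):
        noise = config.beat_noise_sd * rng.standard_normal(base.shape)
        beats.append(EcgBeat(voltages=base + noise, sampling_rate=SAMPLING_RATE_HZ))
    return beats


def make_dataset(
    config: SyntheticConfig,
    patient_id: str = "synthetic",
    site_prefix: str = "S",
) -> PatientDataset:
    """Generate a full patient dataset: geometry plus paced beats per site.

    ``site_prefix`` lets multi-patient studies keep site ids globally
    unique when traces are pooled.
    """
    rng = np.random.default_rng(config.seed)
    positions = make_geometry(config, rng)
    sites = [
        PacingSite(
            site_id=f"{site_prefix}{idx:03d}",
            position=pos,
            beats=forward_ecg(pos, config, rng),
        )
        for idx, pos in enumerate(positions)
    ]
    return PatientDataset(patient_id=patient_id, sites=sites)


def dataset_digest(dataset: PatientDataset) -> str:
    """SHA-256 over site ids, positions and raw beat voltages — a compact
    equality check for determinism tests."""
    h = hashlib.sha256()
    for s in dataset.sites:
        h.update(s.site_id.encode())
        h.update(np.ascontiguousarray(s.position).tobytes())
        for b in s.beats:
            h.update(np.ascontiguousarray(b.voltages).tobytes())
    return h.hexdigest()
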