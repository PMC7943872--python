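"""The four pace-mapping origin predictors.

QIM — QRS-integral regression.  Each coordinate of the pacing position is
fitted by ordinary least squares on the three initial 120-ms QRS
integrals (leads III, V2, V6) plus an intercept; prediction is a direct
application of the fitted coefficients.

DEM / DCM — scalar morphology-distance models.  A through-origin slope k
maps a pairwise morphology quantity (E12, or 1 - Corr) to Euclidean
distance; the estimated distances from every modeling site to the
unknown site are then intersected by multilateration, minimizing

    J(x) = sum_i (||x - a_i|| - d_i)^2 .

DDM — the transfer-matrix (dp-dw) model.  Waveform differences between
modeling-site pairs form a basis [dW]; the waveform differences from each
modeling site to the unknown site, [dW*], are expressed in that basis by
least squares (transfer matrix theta), and the same theta is applied to
the spatial position differences [dP] to estimate the position
differences to the unknown site.  The prediction averages, over modeling
sites i, the site position plus its estimated offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .ecg import PacingSite, SpliceVector
from .morph import QrsIntTriple, corr12, e12

__all__ = [
    "QimFit",
    "ScalarDistanceFit",
    "Prediction",
    "fit_qim",
    "predict_qim",
    "fit_scalar_distance",
    "multilaterate",
    "predict_dem",
    "predict_dcm",
    "predict_ddm",
    "predict_with_model",
    "MODEL_NAMES",
    "MIN_SITES",
]

MODEL_NAMES = ("QIM", "DEM", "DCM", "DDM")

#: Minimum number of modeling sites per model (5 for the regression
#: model to avoid a singular 4-column design; 3 for the others).
MIN_SITES = {"QIM": 5, "DEM": 3, "DCM": 3, "DDM": 3}

#: Relative ridge added when a least-squares system is rank deficient.
RIDGE_REL = 1e-8


class InsufficientDataError(ValueError):
    """Raised when fewer modeling sites are supplied than a model needs."""


@dataclass(frozen=True)
class QimFit:
    """QRS-integral regression coefficients: 3 coordinates x (intercept + 3)."""

    coefficients: np.ndarray  # (3, 4)
    rank_deficient: bool = False


@dataclass(frozen=True)
class ScalarDistanceFit:
    """Through-origin slope mapping a morphology metric to distance (mm/unit)."""

    k: float
    metric_kind: str  # "E12" | "one-minus-Corr"


@dataclass(frozen=True)
class Prediction:
    """A predicted origin with solver diagnostics."""

    position: np.ndarray
    model_name: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float)
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise ValueError("prediction position must be a finite 3-vector")
        object.__setattr__(self, "position", p)


def _lstsq_ridge(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, bool]:
    """Least squares with pseudo-inverse semantics.

    Rank-deficient systems (frequent with near-collinear site sets, and
    structural for the all-pairs difference basis, whose m-th column is a
    combination of the others) get the SVD minimum-norm solution and a
    diagnostics flag.  If the SVD itself fails to converge, fall back to
    a small relative ridge.
    """
    try:
        x, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
        return x, bool(rank < min(a.shape))
    except np.linalg.LinAlgError:
        scale = float(np.linalg.norm(a, ord=2)) or 1.0
        lam = RIDGE_REL * scale
        ata = a.T @ a + (lam**2) * np.eye(a.shape[1])
        return np.linalg.solve(ata, a.T @ b), True


# ---------------------------------------------------------------------------
# QIM: QRS-integral regression
# ---------------------------------------------------------------------------

def fit_qim(sites: Sequence[PacingSite], integrals: Sequence[QrsIntTriple]) -> QimFit:
    """Fit each coordinate on [1, I_III, I_V2, I_V6] by least squares.

    At least 5 sites are required to determine the 4-column design.
    """
    if len(sites) < MIN_SITES["QIM"]:
        raise InsufficientDataError(
            f"QIM needs at least {MIN_SITES['QIM']} sites, got {len(sites)}"
        )
    if len(integrals) != len(sites):
        raise ValueError("one QrsIntTriple per site required")
    design = np.column_stack(
        [np.ones(len(sites))] + [np.array([q.values[j] for q in integrals]) for j in range(3)]
    )
    targets = np.stack([s.position for s in sites])  # (n, 3)
    coef, deficient = _lstsq_ridge(design, targets)
    return QimFit(coefficients=coef.T, rank_deficient=deficient)


def predict_qim(fit: QimFit, integrals: QrsIntTriple) -> Prediction:
    """Apply the fitted coefficient matrix to [1, I_III, I_V2, I_V6]."""
    x = np.concatenate([[1.0], integrals.values])
    pos = fit.coefficients @ x
    return Prediction(
        position=pos,
        model_name="QIM",
        diagnostics={"rank_deficient": fit.rank_deficient},
    )


# ---------------------------------------------------------------------------
# Scalar distance models (DEM / DCM)
# ---------------------------------------------------------------------------

def fit_scalar_distance(
    pairs: Sequence[tuple[float, float]], metric_kind: str = "E12"
) -> ScalarDistanceFit:
    """Through-origin least-squares slope k of distance on metric:

        k = sum(dist * metric) / sum(metric^2)

    Raises a degenerate-data error when every metric value is zero.
    """
    m = np.array([p[0] for p in pairs], dtype=float)
    d = np.array([p[1] for p in pairs], dtype=float)
    if m.size == 0 or not np.any(m != 0.0):
        raise ValueError("all metric values are zero: slope undefined")
    k = float(np.sum(d * m) / np.sum(m**2))
    return ScalarDistanceFit(k=k, metric_kind=metric_kind)


def multilaterate(
    anchors: np.ndarray,
    distances: np.ndarray,
    model_name: str = "multilateration",
) -> Prediction:
    """Locate a point from estimated distances to known anchors.

    Minimizes ``J(x) = sum_i (||x - a_i|| - d_i)^2``.  J is nonconvex
    (three coplanar anchors have two mirror minima), so a multi-start
    strategy is used: the distance-weighted centroid of the anchors plus
    one start per anchor (each nudged off the anchor itself, where the
    residual is not differentiable); the start with the lowest final J
    wins.  Needs at least 3 anchors.
    """
    anchors = np.asarray(anchors, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if anchors.ndim != 2 or anchors.shape[1] != 3:
        raise ValueError("anchors must be (n, 3)")
    if anchors.shape[0] != distances.shape[0]:
        raise ValueError("one distance per anchor required")
    if anchors.shape[0] < 3:
        raise InsufficientDataError(
            f"multilateration needs >= 3 anchors, got {anchors.shape[0]}"
        )
    if np.any(distances < 0):
        raise ValueError("distances must be nonnegative")

    def residuals(x: np.ndarray) -> np.ndarray:
        return np.linalg.norm(anchors - x, axis=1) - distances

    scale = max(float(np.ptp(anchors)), 1.0)
    w = 1.0 / (distances + 1e-3 * scale)
    starts = [np.average(anchors, axis=0, weights=w)]
    centroid = anchors.mean(axis=0)
    for a in anchors:
        # nudge toward the centroid so no start sits exactly on an anchor
        offset = centroid - a
        nrm = np.linalg.norm(offset)
        nudge = offset / nrm * (1e-6 * scale) if nrm > 0 else np.array([1e-6 * scale, 0, 0])
        starts.append(a + nudge)

    best_x: np.ndarray | None = None
    best_j = np.inf
    for x0 in starts:
        sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        j = float(np.sum(sol.fun**2))
        if j < best_j:
            best_j = j
            best_x = sol.x
    assert best_x is not None
    return Prediction(
        position=best_x,
        model_name=model_name,
        diagnostics={"cost_J": best_j, "n_anchors": int(anchors.shape[0])},
    )


def _predict_scalar(
    modeling: Sequence[PacingSite],
    target_splice: SpliceVector,
    metric: Callable[[SpliceVector, SpliceVector], float],
    metric_kind: str,
    model_name: str,
) -> Prediction:
    if len(modeling) < MIN_SITES[model_name]:
        raise InsufficientDataError(
            f"{model_name} needs at least {MIN_SITES[model_name]} modeling sites"
        )
    pairs = [
        (metric(si.splice, sj.splice), float(np.linalg.norm(si.position - sj.position)))
        for si, sj in combinations(modeling, 2)
    ]
    fit = fit_scalar_distance(pairs, metric_kind=metric_kind)
    est = np.array([fit.k * metric(s.splice, target_splice) for s in modeling])
    est = np.clip(est, 0.0, None)  # a negative estimated distance is meaningless
    anchors = np.stack([s.position for s in modeling])
    pred = multilaterate(anchors, est, model_name=model_name)
    pred.diagnostics["k"] = fit.k
    pred.diagnostics["estimated_distances"] = est
    return pred


def predict_dem(modeling: Sequence[PacingSite], target_splice: SpliceVector) -> Prediction:
    """dis-E12 model: distances estimated as k1 * E12, then multilaterated."""
    return _predict_scalar(modeling, target_splice, e12, "E12", "DEM")


def predict_dcm(modeling: Sequence[PacingSite], target_splice: SpliceVector) -> Prediction:
    """dis-Corr model: distances estimated as k2 * (1 - Corr), then multilaterated."""
    metric = lambda a, b: 1.0 - corr12(a, b)  # noqa: E731
    return _predict_scalar(modeling, target_splice, metric, "one-minus-Corr", "DCM")


# ---------------------------------------------------------------------------
# DDM: transfer-matrix (dp-dw) model
# ---------------------------------------------------------------------------

def predict_ddm(modeling: Sequence[PacingSite], target_splice: SpliceVector) -> Prediction:
    """Transfer-matrix predictor mapping waveform differences to position
    differences.

    With m modeling sites, the basis holds all C(m, 2) ordered pairs
    (i < j): columns of [dW] are W_j - W_i and the matching columns of
    [dP] are P_j - P_i.  The columns of [dW*] are W_target - W_i for each
    modeling site.  theta solves [dW] theta ~= [dW*] in least squares;
    [dP] theta estimates the offsets P_target - P_i, and the prediction
    is the uniform mean over i of P_i + offset_i.
    """
    if len(modeling) < MIN_SITES["DDM"]:
        raise InsufficientDataError(
            f"DDM needs at least {MIN_SITES['DDM']} modeling sites"
        )
    splices = [s.splice for s in modeling]
    length = target_splice.values.size
    for sp in splices:
        if sp.values.size != length:
            raise ValueError("all splice vectors must share the target's length")
    positions = np.stack([s.position for s in modeling])

    pair_idx = list(combinations(range(len(modeling)), 2))
    dw = np.column_stack([splices[j].values - splices[i].values for i, j in pair_idx])
    dp = np.column_stack([positions[j] - positions[i] for i, j in pair_idx])
    dw_star = np.column_stack([target_splice.values - sp.values for sp in splices])

    theta, deficient = _lstsq_ridge(dw, dw_star)  # (n_pairs, m)
    dp_star = dp @ theta  # (3, m) estimated offsets P_target - P_i
    pos = np.mean(positions.T + dp_star, axis=1)
    resid = float(np.linalg.norm(dw @ theta - dw_star))
    return Prediction(
        position=pos,
        model_name="DDM",
        diagnostics={"rank_deficient": deficient, "dw_residual_norm": resid},
    )


def predict_with_model(
    model: str, modeling: Sequence[PacingSite], target: PacingSite
) -> Prediction:
    """Dispatch by model name.

    Only the target's ECG is consumed: QIM extracts the target's QRS
    integrals from its representative beat, the morphology models use its
    splice vector.  The target's stored position is never read here.
    """
    if model == "QIM":
        from .morph import detect_qrs_onset, qrs_integrals

        ints = [
            qrs_integrals(s.representative, detect_qrs_onset(s.representative))
            for s in modeling
        ]
        fit = fit_qim(modeling, ints)
        rep = target.representative
        return predict_qim(fit, qrs_integrals(rep, detect_qrs_onset(rep)))
    if model == "DEM":
        return predict_dem(modeling, target.splice)
    if model == "DCM":
        return predict_dcm(modeling, target.splice)
    if model == "DDM":
        return predict_ddm(modeling, target.splice)
    raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
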