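"""Emulation of the clinical pace-mapping procedure.

A *target* plays the role of the PVC whose origin is sought: its ECG is
known, its position is hidden from the localizer and used only to emulate
the operator's distance judgements (hit check, credibility check), which
in a real procedure come from the electroanatomic map.

Target selection schemes
------------------------
``hitrate``  — a site qualifies as a target if at least 5 other sites lie
strictly between 15 and 35 mm from it; those neighbors form its potential
modeling set.  ``range`` — at least 5 other sites within 35 mm
(inclusive).

Iterative loop (per target, per model)
--------------------------------------
1. Initialize with the 3 farthest potential sites from the target (5 for
   the regression model, which needs a determined design).
2. Fit the model on the current modeling sites; predict.
3. Terminate on a hit (prediction within 15 mm of the target) or when no
   unused potential sites remain.
4. If the prediction is more than 35 mm from the target it is not
   credible: go to 6.
5. Otherwise take the unused site nearest the prediction, if within
   15 mm of it; else go to 6.
6. Fallback: take the unused site farthest from the geometric center of
   the current modeling sites (maximum new spatial information).
Back to 2.

The ``fixed`` variant replaces steps 4-6 with a model-independent rule:
each round add the unused site farthest from the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

from .ecg import PacingSite, PatientDataset
from .localizers import MIN_SITES, Prediction, predict_with_model

__all__ = [
    "TargetCase",
    "ProtocolRound",
    "ProtocolTrace",
    "select_targets",
    "run_protocol",
    "geometric_center",
    "HIT_RADIUS_MM",
    "CREDIBLE_RADIUS_MM",
]

HIT_RADIUS_MM = 15.0
CREDIBLE_RADIUS_MM = 35.0

Scheme = Literal["hitrate", "range"]
Variant = Literal["adaptive", "fixed"]

#: Model name -> callable(modeling_sites, target_site) -> Prediction.
Predictor = Callable[[Sequence[PacingSite], PacingSite], Prediction]


class InsufficientCaseError(ValueError):
    """Raised when a target case has too few potential sites for a model."""


@dataclass(frozen=True)
class TargetCase:
    """One emulated localization problem."""

    target: PacingSite
    potential_modeling: tuple[PacingSite, ...]
    scheme: Scheme

    @property
    def initial_radius(self) -> float:
        """Maximum distance from the target to a potential modeling site
        (the initial target range)."""
        return max(
            float(np.linalg.norm(s.position - self.target.position))
            for s in self.potential_modeling
        )


@dataclass(frozen=True)
class ProtocolRound:
    """State after one fit/predict round."""

    modeling_site_ids: tuple[str, ...]
    prediction: Prediction
    estimated_error_mm: float
    min_modeling_distance_mm: float


@dataclass(frozen=True)
class ProtocolTrace:
    """Complete record of one target under one model."""

    target_id: str
    model_name: str
    variant: Variant
    rounds: tuple[ProtocolRound, ...]
    termination: Literal["hit", "exhausted"]

    @property
    def errors(self) -> np.ndarray:
        return np.array([r.estimated_error_mm for r in self.rounds])

    @property
    def n_sites_used(self) -> int:
        return len(self.rounds[-1].modeling_site_ids)


def geometric_center(positions: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Arithmetic mean of a nonempty set of 3-D positions."""
    arr = np.asarray(positions, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric center of an empty set is undefined")
    return arr.reshape(-1, 3).mean(axis=0)


def select_targets(dataset: PatientDataset, scheme: Scheme) -> list[TargetCase]:
    """Every site whose neighborhood satisfies the scheme becomes a target,
    with exactly its qualifying neighbors as potential modeling sites."""
    if scheme not in ("hitrate", "range"):
        raise ValueError(f"unknown scheme {scheme!r}")
    cases = []
    for site in dataset.sites:
        neighbors = []
        for other in dataset.sites:
            if other.site_id == site.site_id:
                continue
            d = float(np.linalg.norm(other.position - site.position))
            if scheme == "hitrate":
                ok = HIT_RADIUS_MM < d < CREDIBLE_RADIUS_MM
            else:
                ok = d <= CREDIBLE_RADIUS_MM
            if ok:
                neighbors.append(other)
        if len(neighbors) >= 5:
            cases.append(
                TargetCase(
                    target=site,
                    potential_modeling=tuple(neighbors),
                    scheme=scheme,
                )
            )
    return cases


def _dist(site: PacingSite, point: np.ndarray) -> float:
    return float(np.linalg.norm(site.position - point))


def _pop_extreme(
    unused: list[PacingSite], point: np.ndarray, farthest: bool
) -> PacingSite:
    """Remove and return the unused site farthest from / nearest to a
    point; ties broken by lexicographic site_id for determinism."""
    sign = -1.0 if farthest else 1.0
    best = min(unused, key=lambda s: (sign * _dist(s, point), s.site_id))
    unused.remove(best)
    return best


def run_protocol(
    case: TargetCase,
    model: str,
    variant: Variant = "adaptive",
    predictor: Predictor | None = None,
) -> ProtocolTrace:
    """Run the iterative modeling/prediction loop for one target.

    ``predictor`` overrides the model dispatch (used for stub models in
    tests); ``model`` still controls the initial modeling-set size unless
    it is not a known model name, in which case 3 is used.
    """
    if predictor is None:
        pred_fn: Predictor = lambda sites, tgt: predict_with_model(model, sites, tgt)  # noqa: E731
    else:
        pred_fn = predictor
    n_init = MIN_SITES.get(model, 3)
    if len(case.potential_modeling) < n_init:
        raise InsufficientCaseError(
            f"{model} needs {n_init} initial sites; case has "
            f"{len(case.potential_modeling)} potential modeling sites"
        )
    target = case.target
    unused = sorted(case.potential_modeling, key=lambda s: s.site_id)
    modeling: list[PacingSite] = []

    # Step 1: the n_init farthest potential sites from the target.
    for _ in range(n_init):
        modeling.append(_pop_extreme(unused, target.position, farthest=True))

    rounds: list[ProtocolRound] = []
    termination: str | None = None
    while termination is None:
        # Step 2: fit and predict.
        prediction = pred_fn(modeling, target)
        err = float(np.linalg.norm(prediction.position - target.position))
        min_d = min(_dist(s, target.position) for s in modeling)
        rounds.append(
            ProtocolRound(
                modeling_site_ids=tuple(s.site_id for s in modeling),
                prediction=prediction,
                estimated_error_mm=err,
                min_modeling_distance_mm=min_d,
            )
        )
        # Step 3: termination judgment.
        if err <= HIT_RADIUS_MM:
            termination = "hit"
            break
        if not unused:
            termination = "exhausted"
            break
        if variant == "fixed":
            modeling.append(_pop_extreme(unused, target.position, farthest=True))
            continue
        # Step 4: credibility of the prediction.
        next_site: PacingSite | None = None
        if err <= CREDIBLE_RADIUS_MM:
            # Step 5: nearest unused site to the prediction, if within 15 mm.
            candidate = min(
                unused, key=lambda s: (_dist(s, prediction.position), s.site_id)
            )
            if _dist(candidate, prediction.position) <= HIT_RADIUS_MM:
                unused.remove(candidate)
                next_site = candidate
        if next_site is None:
            # Step 6: farthest from the geometric center of current sites.
            center = geometric_center([s.position for s in modeling])
            next_site = _pop_extreme(unused, center, farthest=True)
        modeling.append(next_site)

    return ProtocolTrace(
        target_id=target.site_id,
        model_name=model,
        variant=variant,
        rounds=tuple(rounds),
        termination=termination,  # type: ignore[arg-type]
    )
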