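"""Outcome classification and evaluation summaries for protocol traces.

Outcomes
--------
A trace is a *hit* when the loop terminated by the 15-mm rule.  A trace
that exhausted its candidate sites is an *early termination* if its final
round still improved the estimated error (the search was interrupted
while converging), otherwise a *miss*.  The early-termination rule is an
operational reading of a qualitative clinical notion and is flagged as
such in emitted reports.

Curves
------
``error_curve`` applies the hold-at-minimum convention: once a trace has
reached its minimum estimated error, later rounds report that minimum.
``reduced_distance`` (minimum modeling-site distance minus estimated
error, positive = the search region shrank) excludes rounds after the
trace's minimum error was reached.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import ProtocolTrace

__all__ = [
    "classify_outcome",
    "OutcomeSummary",
    "summarize_outcomes",
    "error_curve",
    "reduced_distance",
    "RangeTable",
    "range_table",
]


def classify_outcome(trace: ProtocolTrace) -> str:
    """Classify a completed trace as ``hit``, ``miss`` or
    ``early_termination`` (see module docstring for the rule)."""
    if trace.termination == "hit":
        return "hit"
    errs = trace.errors
    if len(errs) >= 2 and errs[-1] < errs[-2]:
        return "early_termination"
    return "miss"


@dataclass(frozen=True)
class OutcomeSummary:
    """Per-model outcome counts plus per-round hit/miss accumulation."""

    model_name: str
    hits: int
    misses: int
    early_terminations: int
    #: hit_accumulation[k] = hits achieved with <= k+1 rounds
    hit_accumulation: tuple[int, ...]

    @property
    def n_traces(self) -> int:
        return self.hits + self.misses + self.early_terminations


def summarize_outcomes(traces: Sequence[ProtocolTrace]) -> OutcomeSummary:
    """Counts and accumulation curve for one model's traces."""
    if not traces:
        raise ValueError("no traces to summarize")
    names = {t.model_name for t in traces}
    if len(names) != 1:
        raise ValueError(f"traces mix models: {sorted(names)}")
    outcomes = [classify_outcome(t) for t in traces]
    max_rounds = max(len(t.rounds) for t in traces)
    acc = []
    for k in range(1, max_rounds + 1):
        acc.append(
            sum(
                1
                for t, o in zip(traces, outcomes)
                if o == "hit" and len(t.rounds) <= k
            )
        )
    return OutcomeSummary(
        model_name=names.pop(),
        hits=outcomes.count("hit"),
        misses=outcomes.count("miss"),
        early_terminations=outcomes.count("early_termination"),
        hit_accumulation=tuple(acc),
    )


def error_curve(
    traces: Sequence[ProtocolTrace], max_rounds: int | None = None
) -> list[list[float]]:
    """Per-round estimated-error samples with hold-at-minimum.

    Returns a list of length ``max_rounds``; entry ``k`` collects, from
    every trace, the running minimum of its estimated errors up to round
    ``k`` (traces shorter than ``k`` rounds contribute their overall
    minimum — the error stays at its minimum once reached).
    """
    if max_rounds is None:
        max_rounds = max(len(t.rounds) for t in traces)
    series: list[list[float]] = [[] for _ in range(max_rounds)]
    for t in traces:
        running = np.minimum.accumulate(t.errors)
        for k in range(max_rounds):
            series[k].append(float(running[min(k, len(running) - 1)]))
    return series


def reduced_distance(trace: ProtocolTrace, round_index: int) -> float | None:
    """Minimum modeling-site-to-target distance minus the estimated error
    at ``round_index`` (0-based); ``None`` for rounds after the trace
    first reached its minimum estimated error (those samples are not
    counted)."""
    if not 0 <= round_index < len(trace.rounds):
        raise IndexError(f"round {round_index} outside trace of {len(trace.rounds)}")
    errs = trace.errors
    first_min = int(np.argmin(errs))
    if round_index > first_min:
        return None
    r = trace.rounds[round_index]
    return r.min_modeling_distance_mm - r.estimated_error_mm


@dataclass(frozen=True)
class RangeTable:
    """Target-range statistics per model plus pairwise paired t-tests."""

    summary: pd.DataFrame  # rows: model; cols: statistic
    error_pvalues: pd.DataFrame  # pairwise p-values on final errors
    sites_pvalues: pd.DataFrame  # pairwise p-values on modeling-site counts


def _mean_std_mid(x: np.ndarray) -> tuple[float, float, float]:
    std = float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
    return float(np.mean(x)), std, float(np.median(x))


def _paired_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired t-test p-value; 1.0 when the difference vector is
    identically zero (the test statistic is undefined but the samples are
    indistinguishable)."""
    if np.allclose(a, b):
        return 1.0
    res = stats.ttest_rel(a, b)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def range_table(
    traces_by_model: Mapping[str, Sequence[ProtocolTrace]],
    initial_radius: Mapping[str, float],
) -> RangeTable:
    """Target-range narrowing statistics over a shared target set.

    ``initial_radius`` maps target id to the maximum potential-site
    distance (``TargetCase.initial_radius``).  For each model:
    mean/std/median of the initial radius, of the final (minimum)
    estimated error, and of the number of modeling sites used; pairwise
    two-sided *paired* t-tests between models on final errors and on site
    counts (paired — every model ran the identical targets).
    """
    target_ids: list[str] | None = None
    final_err: dict[str, np.ndarray] = {}
    n_sites: dict[str, np.ndarray] = {}
    init_radius: np.ndarray | None = None
    rows = []
    for model, traces in traces_by_model.items():
        ids = [t.target_id for t in traces]
        if target_ids is None:
            target_ids = ids
            init_radius = np.array([initial_radius[i] for i in ids])
        elif ids != target_ids:
            raise ValueError(f"model {model} ran a different target set")
        final_err[model] = np.array([float(t.errors.min()) for t in traces])
        n_sites[model] = np.array([t.n_sites_used for t in traces], dtype=float)
        r_m, r_s, r_mid = _mean_std_mid(init_radius)
        e_m, e_s, e_mid = _mean_std_mid(final_err[model])
        s_m, s_s, s_mid = _mean_std_mid(n_sites[model])
        rows.append(
            {
                "model": model,
                "radius_mean": r_m, "radius_std": r_s, "radius_mid": r_mid,
                "error_mean": e_m, "error_std": e_s, "error_mid": e_mid,
                "sites_mean": s_m, "sites_std": s_s, "sites_mid": s_mid,
            }
        )
    summary = pd.DataFrame(rows).set_index("model")
    models = list(traces_by_model)
    pe = pd.DataFrame(np.nan, index=models, columns=models)
    ps = pd.DataFrame(np.nan, index=models, columns=models)
    for a, b in combinations(models, 2):
        pe.loc[a, b] = pe.loc[b, a] = _paired_p(final_err[a], final_err[b])
        ps.loc[a, b] = ps.loc[b, a] = _paired_p(n_sites[a], n_sites[b])
    return RangeTable(summary=summary, error_pvalues=pe, sites_pvalues=ps)
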