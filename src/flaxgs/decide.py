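"""Check-based advancement decisions.

A benchmark check cultivar grown alongside the candidates sets two
thresholds: its observed value (phenotypic-selection space) and its predicted
value (genomic-selection space).  A candidate is advanced when its predicted
value strictly exceeds the predicted-space threshold; it is observed-superior
when its observed value strictly exceeds the observed-space threshold.  The
report carries the four quadrant counts, the trial-size reduction achieved by
advancing only the predicted winners, and the retention of observed-superior
lines among them.  Percentages round to the nearest integer, half away from
zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DecisionError(ValueError):
    pass


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def standardize(values) -> np.ndarray:
    """z-scores (population SD); reporting aid for scatter output."""
    v = np.asarray(values, dtype=float)
    sd = v.std()
    if sd == 0:
        raise DecisionError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


def reduction_percent(n_total: int, n_advanced: int) -> int:
    """Percent reduction in trial size when only n_advanced of n_total go on."""
    if n_total <= 0 or not 0 <= n_advanced <= n_total:
        raise DecisionError(f"invalid counts ({n_total}, {n_advanced})")
    return _round_half_away(100.0 * (n_total - n_advanced) / n_total)


def retention_percent(n_retained: int, n_superior: int) -> int:
    """Percent of observed-superior lines kept by the genomic decision."""
    if n_superior <= 0 or not 0 <= n_retained <= n_superior:
        raise DecisionError(f"invalid counts ({n_retained}, {n_superior})")
    return _round_half_away(100.0 * n_retained / n_superior)


@dataclass
class CheckSpec:
    check_ids: tuple[str, ...]
    benchmark: str

    def __post_init__(self) -> None:
        if self.benchmark not in self.check_ids:
            raise DecisionError("benchmark must be one of the check ids")


@dataclass
class DecisionReport:
    n_total: int
    threshold_observed: float
    threshold_predicted: float
    advanced: list[str]
    superior_observed: list[str]
    quadrants: dict[str, int]  # both_above, predicted_only, observed_only, both_below
    reduction_percent: int
    retention_percent: int | None  # None when no observed-superior lines
    missed_superior: pd.DataFrame  # line, observed, observed_rank
    per_line: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "threshold_observed": self.threshold_observed,
            "threshold_predicted": self.threshold_predicted,
            "n_advanced": len(self.advanced),
            "n_superior_observed": len(self.superior_observed),
            "quadrants": self.quadrants,
            "reduction_percent": self.reduction_percent,
            "retention_percent": self.retention_percent,
            "missed_superior": self.missed_superior.to_dict("records"),
        }


def check_based_selection(
    observed: pd.Series,
    predicted: pd.Series,
    checks: CheckSpec,
    candidates: list[str] | None = None,
) -> DecisionReport:
    """Advancement decision against the benchmark check.

    ``observed`` and ``predicted`` are line-indexed series covering the
    candidates and the benchmark check.  Candidates default to all indexed
    lines minus the checks.  Comparisons are strict (a tie with the check is
    not advanced).
    """
    for name, s in (("observed", observed), ("predicted", predicted)):
        if checks.benchmark not in s.index:
            raise DecisionError(f"benchmark {checks.benchmark!r} missing a {name} value")
    if candidates is None:
        candidates = [i for i in observed.index if i not in set(checks.check_ids)]
    missing = [c for c in candidates if c not in observed.index or c not in predicted.index]
    if missing:
        raise DecisionError(f"candidates missing values: {missing[:5]}")
    thr_obs = float(observed[checks.benchmark])
    thr_pred = float(predicted[checks.benchmark])
    obs = observed[candidates].astype(float)
    pred = predicted[candidates].astype(float)
    above_pred = pred > thr_pred
    above_obs = obs > thr_obs
    advanced = list(obs.index[above_pred])
    superior = list(obs.index[above_obs])
    quad = {
        "both_above": int((above_pred & above_obs).sum()),
        "predicted_only": int((above_pred & ~above_obs).sum()),
        "observed_only": int((~above_pred & above_obs).sum()),
        "both_below": int((~above_pred & ~above_obs).sum()),
    }
    n_total = len(candidates)
    red = reduction_percent(n_total, len(advanced))
    ret = (
        retention_percent(quad["both_above"], len(superior)) if superior else None
    )
    obs_rank = obs.rank(ascending=False, method="min").astype(int)
    missed = [l for l in superior if l not in set(advanced)]
    missed_df = pd.DataFrame(
        {
            "line": missed,
            "observed": obs[missed].to_numpy(),
            "observed_rank": obs_rank[missed].to_numpy(),
        }
    )
    per_line = pd.DataFrame(
        {
            "line": list(obs.index),
            "observed": obs.to_numpy(),
            "predicted": pred.to_numpy(),
            "advanced": above_pred.to_numpy(),
            "superior_observed": above_obs.to_numpy(),
        }
    )
    return DecisionReport(
        n_total=n_total,
        threshold_observed=thr_obs,
        threshold_predicted=thr_pred,
        advanced=advanced,
        superior_observed=superior,
        quadrants=quad,
        reduction_percent=red,
        retention_percent=ret,
        missed_superior=missed_df,
        per_line=per_line,
    )
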