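"""Reliability filtering, ranking and the experiment-order protocol.

Two reaction-independent-plus-reaction-specific reliability indices decide
which database ligands get a trustworthy prediction:

* ``l_min`` — descriptor-space residual of the ligand's virtual-ligand fit
  (how much of the real ligand the VL model cannot represent at all);
* ``||dp'||`` — range-normalized deviation of the ligand's VL parameters
  from the surrogate's reference point ``p*`` (how far the quadratic model
  is being extrapolated).

Ligands passing both thresholds (strict inequalities) are ranked by the
surrogate prediction, best first; the trial-order protocol then asks at
which position the truly best ligand would have been tried.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .vl_model import ParamBounds

__all__ = [
    "delta_p_norm",
    "FilterSpec",
    "STRICT_FILTER",
    "LOOSE_FILTER",
    "apply_filter",
    "rank",
    "RankingReport",
    "TrialOutcome",
    "trial_order",
]


def delta_p_norm(p, p_star, bounds: ParamBounds) -> float:
    """Range-normalized deviation ``sqrt(sum_i ((p_i - p*_i) / width_i)^2)``.

    Each component is scaled by the accessible range of that parameter (the
    same range the barrier function enforces), making the metric
    dimensionless and comparable across parameters of different character.
    """
    p = np.asarray(p, dtype=float)
    p_star = np.asarray(p_star, dtype=float)
    w = bounds.width
    if np.any(w <= 0):
        raise ValueError("bounds must have positive width")
    return float(np.linalg.norm((p - p_star) / w))


@dataclass(frozen=True)
class FilterSpec:
    """Reliability thresholds; a ligand passes iff both indices are below."""

    l_min_max: float
    dp_norm_max: float
    name: str = "filter"

    def __post_init__(self):
        if self.l_min_max < 0 or self.dp_norm_max < 0:
            raise ValueError("filter thresholds must be nonnegative")


#: The two threshold sets used throughout the phosphine validations.
STRICT_FILTER = FilterSpec(2.0, 0.75, name="strict")
LOOSE_FILTER = FilterSpec(2.5, 1.0, name="loose")


def _indices(record, p_star, bounds):
    return record.l_min, delta_p_norm(record.p.as_array(), p_star, bounds)


def apply_filter(db, p_star, bounds: ParamBounds, filt: FilterSpec) -> list:
    """Subset of records with ``l_min < l_min_max`` and ``||dp'|| < dp_norm_max``.

    Comparisons are strict: a ligand sitting exactly on a threshold fails.
    """
    if not db:
        raise ValueError("empty ligand database")
    out = []
    for rec in db:
        l_min, dpn = _indices(rec, p_star, bounds)
        if l_min < filt.l_min_max and dpn < filt.dp_norm_max:
            out.append(rec)
    return out


@dataclass
class RankingReport:
    """Per-ligand predictions, reliability indices, filter flags and ranks."""

    table: pd.DataFrame
    sense: str
    p_star: np.ndarray
    filters: tuple

    def passing(self, filter_name: str) -> pd.DataFrame:
        """Rows passing the named filter, in rank order."""
        col = f"pass_{filter_name}"
        if col not in self.table.columns:
            raise KeyError(f"unknown filter {filter_name!r}")
        sub = self.table[self.table[col]]
        return sub.sort_values(f"rank_{filter_name}")

    def counts(self) -> dict:
        return {
            f.name: int(self.table[f"pass_{f.name}"].sum()) for f in self.filters
        }

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.17g")

    def summary(self) -> str:
        lines = [f"ligands: {len(self.table)}", f"sense: {self.sense}"]
        for f in self.filters:
            sub = self.passing(f.name)
            top = ", ".join(sub["id"].head(5))
            lines.append(
                f"filter {f.name} (l_min < {f.l_min_max}, "
                f"||dp'|| < {f.dp_norm_max}): {len(sub)} ligands; top: {top}"
            )
        return "\n".join(lines)


def rank(
    db,
    predict: Callable[[np.ndarray], float],
    sense: str = "minimize",
    p_star=None,
    bounds: Optional[ParamBounds] = None,
    filters=(STRICT_FILTER, LOOSE_FILTER),
) -> RankingReport:
    """Score every record with ``predict`` and rank within each filter.

    Ordering is ascending prediction for ``minimize``, descending for
    ``maximize``; ties are broken by smaller ``||dp'||``, then by id.
    """
    if sense not in ("minimize", "maximize"):
        raise ValueError("sense must be 'minimize' or 'maximize'")
    p_star = np.asarray(p_star, dtype=float)
    rows = []
    for rec in db:
        l_min, dpn = _indices(rec, p_star, bounds)
        rows.append(
            {
                "id": rec.id,
                "name": rec.name,
                "predicted": float(predict(rec.p.as_array())),
                "l_min": l_min,
                "dp_norm": dpn,
            }
        )
    df = pd.DataFrame(rows)
    sign = 1.0 if sense == "minimize" else -1.0
    order_key = df.assign(_key=sign * df["predicted"]).sort_values(
        ["_key", "dp_norm", "id"]
    ).index
    for f in filters:
        df[f"pass_{f.name}"] = (df["l_min"] < f.l_min_max) & (
            df["dp_norm"] < f.dp_norm_max
        )
        ranks = np.full(len(df), np.nan)
        pos = 0
        for idx in order_key:
            if df.loc[idx, f"pass_{f.name}"]:
                pos += 1
                ranks[df.index.get_loc(idx)] = pos
        df[f"rank_{f.name}"] = ranks
    return RankingReport(df, sense, p_star, tuple(filters))


@dataclass
class TrialOutcome:
    """Where the truly best ligand sits in the ranked trial order."""

    best_id: str
    position: Optional[int]      # 1-based; None when filtered out
    filtered_out: bool


def trial_order(
    report: RankingReport, true_values: dict, filter_name: str
) -> TrialOutcome:
    """Position of the true-best ligand within the named filtered ranking.

    ``true_values`` maps ligand id to the true objective; the best is the
    minimum or maximum according to the report's sense.  A true-best ligand
    excluded by the filter yields ``filtered_out=True``.
    """
    pick = min if report.sense == "minimize" else max
    best_id = pick(true_values, key=lambda k: true_values[k])
    sub = report.passing(filter_name)
    match = sub[sub["id"] == best_id]
    if match.empty:
        return TrialOutcome(best_id, None, True)
    return TrialOutcome(
        best_id, int(match[f"rank_{filter_name}"].iloc[0]), False
    )
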