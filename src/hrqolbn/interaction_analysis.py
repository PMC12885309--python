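"""Pairwise joint interventions and additive/relative interaction measures.

For two risk factors coded to binary levels (1 = higher-risk quartile), let
``p_ab = P(outcome | do(Var1=a, Var2=b))``.  The additive interaction is

    interaction = p11 - p10 - p01 + p00            (synergy > 0, antagonism < 0)
    total       = p11 - p00
    relative    = interaction / total

All three live on the probability (risk-difference) scale; the narrative
percentage-point figures are these values times 100.

Exposures with three analysis levels are dichotomized at the 75th percentile
(level 1 = top quartile) except activity volume — and BMI when the outcome is
mental quality of life — where the *low* quartile is the risk side (cut at
the 25th).  The merged level 0 spans two categories and is intervened as a
restricted-marginal stochastic policy (see
:func:`hrqolbn.interventional_inference.do_probability`); because both
variables of a pair are intervened simultaneously, all arcs into both nodes —
including any arc between them — are removed, so a pair's grid is invariant
to the orientation of an arc joining its two members.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .interventional_inference import FittedBn, do_probability

__all__ = [
    "BinaryCoding", "InteractionGrid", "InteractionMeasures",
    "interaction_coding", "joint_do_grid", "interaction_measures",
    "relative_interaction", "interaction_scan", "OUTCOME_EVENTS",
]

#: outcome label -> (target node, tail level in the three-level coding)
OUTCOME_EVENTS = {
    "poor_PCS": ("PCS", "Low"),
    "good_PCS": ("PCS", "High"),
    "poor_MCS": ("MCS", "Low"),
    "good_MCS": ("MCS", "High"),
}

#: adverse (risk) side of the binary lifestyle/demographic variables
ADVERSE_BINARY = {"EXER": "No", "MARRY": "No", "JOB": "No", "DRINK": "Yes", "SMOKE": "Yes"}


@dataclass(frozen=True)
class BinaryCoding:
    """Dichotomization of one exposure; level 1 is the higher-risk side."""

    var: str
    cut_percentile: float          # 75 (risk = high tail) or 25 (risk = low tail)
    level1: tuple[str, ...]        # risk categories
    level0: tuple[str, ...]

    def levels(self, a: int):
        lv = self.level1 if a == 1 else self.level0
        return lv[0] if len(lv) == 1 else set(lv)


def interaction_coding(table: pd.DataFrame, var: str, outcome: str) -> BinaryCoding:
    """Risk-side dichotomization rule for ``var`` against a given outcome target.

    ``outcome`` is the target node name (``"PCS"`` or ``"MCS"``) or one of
    the labels in :data:`OUTCOME_EVENTS`.
    """
    target = OUTCOME_EVENTS[outcome][0] if outcome in OUTCOME_EVENTS else outcome
    col = table[var]
    cats = list(col.cat.categories) if isinstance(col.dtype, pd.CategoricalDtype) \
        else sorted(col.dropna().unique())
    observed = col.dropna().unique()
    if len(observed) < 2:
        raise ValueError(f"variable {var} is constant; cannot dichotomize")
    if set(cats) <= {"Yes", "No"} or len(cats) == 2:
        risk = ADVERSE_BINARY.get(var, cats[-1])
        other = [c for c in cats if c != risk]
        return BinaryCoding(var, 50.0, (risk,), tuple(other))
    low_is_risk = var in ("ACT", "INCOME") or (var == "BMI" and target == "MCS")
    if set(cats) != {"Low", "Mid", "High"}:
        # other ordered categoricals (e.g. age bands): extreme category is level 1
        if len(cats) < 3:
            raise ValueError(f"no dichotomization rule for {var} with levels {cats}")
        risk = cats[0] if low_is_risk else cats[-1]
        return BinaryCoding(var, 25.0 if low_is_risk else 75.0, (risk,),
                            tuple(c for c in cats if c != risk))
    if low_is_risk:
        return BinaryCoding(var, 25.0, ("Low",), ("Mid", "High"))
    return BinaryCoding(var, 75.0, ("High",), ("Low", "Mid"))


@dataclass
class InteractionGrid:
    """The 2x2 joint-interventional outcome probabilities for one pair."""

    var1: str
    var2: str
    coding1: BinaryCoding
    coding2: BinaryCoding
    outcome: str
    p00: float
    p01: float
    p10: float
    p11: float

    def validate(self) -> None:
        for p in (self.p00, self.p01, self.p10, self.p11):
            if not 0.0 <= p <= 1.0:
                raise ValueError("grid probability outside [0, 1]")

    def swapped(self) -> "InteractionGrid":
        return InteractionGrid(self.var2, self.var1, self.coding2, self.coding1,
                               self.outcome, self.p00, self.p10, self.p01, self.p11)


@dataclass(frozen=True)
class InteractionMeasures:
    additive: float
    total: float
    relative: float | None


def joint_do_grid(bn: FittedBn, var1: str, var2: str, event,
                  coding1: BinaryCoding, coding2: BinaryCoding) -> InteractionGrid:
    """Evaluate ``p_ab`` for the four joint interventions on one network."""
    p = {}
    for a in (0, 1):
        for b in (0, 1):
            p[a, b] = do_probability(
                bn, {var1: coding1.levels(a), var2: coding2.levels(b)}, event
            )
    outcome = f"{event[0]}={event[1]}"
    grid = InteractionGrid(var1, var2, coding1, coding2, outcome,
                           p[0, 0], p[0, 1], p[1, 0], p[1, 1])
    grid.validate()
    return grid


def relative_interaction(additive: float, total: float, tol: float = 1e-12) -> float | None:
    return None if abs(total) < tol else additive / total


def interaction_measures(grid: InteractionGrid) -> InteractionMeasures:
    """Additive and relative interaction plus total effect from a 2x2 grid."""
    additive = grid.p11 - grid.p10 - grid.p01 + grid.p00
    total = grid.p11 - grid.p00
    return InteractionMeasures(additive, total, relative_interaction(additive, total))


def interaction_scan(
    bns,
    table: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    outcomes=("poor_PCS", "good_PCS", "poor_MCS", "good_MCS"),
    report_threshold: float = 0.01,
    weight_a: float = 0.56,
    sensitive_pair: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Scan variable pairs for additive interactions on each tail outcome.

    Parameters
    ----------
    bns:
        A single :class:`FittedBn`, or a pair ``(bn_a, bn_b)`` differing only
        in the orientation of the arc between ``sensitive_pair``; estimates
        from the two networks are then combined with weight ``weight_a`` on
        the first.  Pairs intervening on both or neither endpoint of the
        sensitive arc are direction-invariant and computed once.
    table:
        The categorical analysis table (used for the coding rules).
    pairs:
        Exposure pairs; defaults to all pairs of non-target variables.
    report_threshold:
        Keep rows with ``|interaction| > threshold`` AND ``|total| > threshold``
        (the 1-percentage-point reporting rule); ``None`` disables filtering.
    """
    if isinstance(bns, FittedBn):
        bn_a, bn_b = bns, None
    else:
        bn_a, bn_b = bns
    targets = {t for t, _ in OUTCOME_EVENTS.values()}
    if pairs is None:
        exposures = [v for v in bn_a.dag.nodes if v not in targets]
        pairs = list(combinations(exposures, 2))
    rows = []
    for outcome in outcomes:
        target, tail = OUTCOME_EVENTS[outcome]
        event = (target, tail)
        for var1, var2 in pairs:
            c1 = interaction_coding(table, var1, target)
            c2 = interaction_coding(table, var2, target)
            grid_a = joint_do_grid(bn_a, var1, var2, event, c1, c2)
            endpoints = set(sensitive_pair or ())
            sensitive = bn_b is not None and len({var1, var2} & endpoints) == 1
            if sensitive:
                grid_b = joint_do_grid(bn_b, var1, var2, event, c1, c2)
                grids = [grid_a, grid_b]
                w = (weight_a, 1.0 - weight_a)
            else:
                grids = [grid_a]
                w = (1.0,)
            meas = [interaction_measures(g) for g in grids]
            inter = float(np.dot(w, [m.additive for m in meas]))
            total = float(np.dot(w, [m.total for m in meas]))
            rows.append({
                "outcome": outcome, "var1": var1, "var2": var2,
                "p00": float(np.dot(w, [g.p00 for g in grids])),
                "p01": float(np.dot(w, [g.p01 for g in grids])),
                "p10": float(np.dot(w, [g.p10 for g in grids])),
                "p11": float(np.dot(w, [g.p11 for g in grids])),
                "interaction": inter,
                "interaction_min": min(m.additive for m in meas),
                "interaction_max": max(m.additive for m in meas),
                "total": total,
                "total_min": min(m.total for m in meas),
                "total_max": max(m.total for m in meas),
                "relative": relative_interaction(inter, total),
                "direction_sensitive": sensitive,
            })
    out = pd.DataFrame(rows)
    if report_threshold is not None and len(out):
        out = out[(out["interaction"].abs() > report_threshold)
                  & (out["total"].abs() > report_threshold)].reset_index(drop=True)
    return out
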