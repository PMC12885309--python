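"""SF-12 composite scoring, MET activity volume, and cohort discretization.

The SF-12 yields Physical and Mental Component Summary scores (PCS, MCS) as
weighted sums of standardized item scores, reported on a T-score scale
(location 50, scale 10).  The published factor-score coefficients weight all
twelve items for each component, with negative cross-weights that decorrelate
the two summaries.  The per-item norm means/SDs of the 1998 U.S. reference
population are proprietary tables; by default items are standardized against
the analyzed cohort itself, and externally supplied norms are accepted via
:class:`ScoringWeights`.

Downstream structure learning works on categorical data, so this module also
owns every discretization convention: fixed bins for age and income,
empirical 25th/75th-percentile Low/Mid/High cuts for the continuous scales,
count bins for the morbidity tally, and the quartile tail events on PCS/MCS.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

#: Canonical item order: general health, physical functioning, role-physical,
#: bodily pain, vitality, social functioning, role-emotional, mental health.
SF12_ITEMS = (
    "GH", "PF1", "PF2", "RP1", "RP2", "BP",
    "VT", "SF", "RE1", "RE2", "MH1", "MH2",
)

#: Likert response ranges; PF1/PF2 are 3-point, the rest 5-point.
SF12_ITEM_RANGES = {item: (1, 3) if item in ("PF1", "PF2") else (1, 5) for item in SF12_ITEMS}

#: Published factor-score coefficients for the physical component.
PCS_WEIGHTS = {
    "GH": 0.42402, "PF1": 0.35119, "PF2": 0.48907,
    "RP1": 0.15714, "RP2": 0.17835, "BP": 0.28343,
    "VT": -0.09731, "SF": -0.04695, "RE1": -0.00753,
    "RE2": 0.01553, "MH1": -0.20963, "MH2": -0.10531,
}

#: Published factor-score coefficients for the mental component.
MCS_WEIGHTS = {
    "GH": -0.22999, "PF1": -0.10337, "PF2": -0.09731,
    "RP1": -0.01483, "RP2": -0.11454, "BP": -0.07311,
    "VT": 0.23534, "SF": 0.26876, "RE1": 0.21060,
    "RE2": 0.18602, "MH1": 0.48581, "MH2": 0.43407,
}

#: MET intensity weights for (sedentary, very light, light, moderate, vigorous) hours.
ACT_MET_WEIGHTS = (1.0, 1.5, 2.5, 4.5, 7.0)

ACT_DURATION_COLUMNS = (
    "ACT_SEDENTARY_H", "ACT_VERYLIGHT_H", "ACT_LIGHT_H",
    "ACT_MODERATE_H", "ACT_VIGOROUS_H",
)

LMH = ("Low", "Mid", "High")

#: Variables whose larger values are the health-favorable side.  Ties landing
#: exactly on a percentile cut are assigned to the lower-risk category, so
#: this orientation decides interval closure per variable.  BMI is grouped
#: with the higher-favorable scales (in this age band low BMI tracks frailty).
HIGHER_IS_BETTER = frozenset({"ACT", "BMI", "PCS", "MCS"})


@dataclass
class ScoringWeights:
    """Factor-score coefficients plus standardization/T-transform parameters.

    ``norm_params`` maps item -> (mean, sd) used to standardize raw
    responses.  ``None`` means the inputs are taken as already standardized
    (the within-sample default is filled in by :class:`SF12Scorer.fit`).
    ``polarity`` optionally flags reverse-scored items (-1 flips the item
    within its Likert range before standardization).
    """

    pcs_weights: dict[str, float] = field(default_factory=lambda: dict(PCS_WEIGHTS))
    mcs_weights: dict[str, float] = field(default_factory=lambda: dict(MCS_WEIGHTS))
    norm_params: dict[str, tuple[float, float]] | None = None
    t_location: float = 50.0
    t_scale: float = 10.0
    polarity: dict[str, int] = field(default_factory=lambda: {i: 1 for i in SF12_ITEMS})

    def validate(self) -> None:
        for name, w in (("pcs_weights", self.pcs_weights), ("mcs_weights", self.mcs_weights)):
            if set(w) != set(SF12_ITEMS):
                raise ValueError(f"{name} must supply exactly the 12 item coefficients")
        if self.norm_params is not None and set(self.norm_params) != set(SF12_ITEMS):
            raise ValueError("norm_params must cover all 12 items")


def _standardize_items(items: dict[str, float], weights: ScoringWeights) -> dict[str, float]:
    z = {}
    for item in SF12_ITEMS:
        if item not in items:
            raise ValueError(f"missing SF-12 item: {item}")
        x = items[item]
        if x is None or (isinstance(x, float) and np.isnan(x)):
            raise ValueError(f"missing SF-12 item: {item}")
        if weights.norm_params is not None:
            lo, hi = SF12_ITEM_RANGES[item]
            if not lo <= x <= hi:
                raise ValueError(f"SF-12 item {item} out of range [{lo}, {hi}]: {x}")
            if weights.polarity.get(item, 1) < 0:
                x = (lo + hi) - x
            mean, sd = weights.norm_params[item]
            z[item] = (x - mean) / sd
        else:
            z[item] = float(x)
    return z


def score_sf12(items: dict[str, float], weights: ScoringWeights | None = None) -> tuple[float, float]:
    """Score one SF-12 response vector into (PCS, MCS) T-scores.

    With ``weights.norm_params is None`` the inputs are interpreted as
    standardized item scores, so an all-zero vector maps to exactly
    (50.0, 50.0) and the transform is affine in the inputs.
    """
    weights = weights or ScoringWeights()
    weights.validate()
    z = _standardize_items(items, weights)
    pcs_agg = sum(weights.pcs_weights[i] * z[i] for i in SF12_ITEMS)
    mcs_agg = sum(weights.mcs_weights[i] * z[i] for i in SF12_ITEMS)
    return (
        weights.t_location + weights.t_scale * pcs_agg,
        weights.t_location + weights.t_scale * mcs_agg,
    )


def compute_act(durations) -> float:
    """MET-weighted daily activity volume from the five intensity durations.

    ``ACT = 1.0*sedentary + 1.5*very_light + 2.5*light + 4.5*moderate + 7.0*vigorous``
    with all durations in hours/day.
    """
    d = np.asarray(durations, dtype=float)
    if d.shape[-1] != 5:
        raise ValueError("expected 5 activity durations (hours/day)")
    if np.any(d < 0):
        raise ValueError("activity durations must be nonnegative")
    if np.any(d.sum(axis=-1) > 24 + 1e-9):
        raise ValueError("activity durations exceed 24 hours/day")
    return float(d @ np.asarray(ACT_MET_WEIGHTS)) if d.ndim == 1 else d @ np.asarray(ACT_MET_WEIGHTS)


class SF12Scorer(TransformerMixin, BaseEstimator):
    """Transformer adding PCS/MCS T-score columns to a cohort table.

    Parameters
    ----------
    weights:
        Optional :class:`ScoringWeights`; if its ``norm_params`` is ``None``
        (the default), per-item means/SDs are estimated from the fitted
        cohort (within-sample standardization).
    item_prefix:
        Column-name prefix of the item responses, e.g. ``SF12_GH``.
    """

    def __init__(self, weights: ScoringWeights | None = None, item_prefix: str = "SF12_"):
        self.weights = weights
        self.item_prefix = item_prefix

    def fit(self, X: pd.DataFrame, y=None) -> "SF12Scorer":
        base = self.weights or ScoringWeights()
        base.validate()
        if base.norm_params is None:
            norms = {}
            for item in SF12_ITEMS:
                col = X[self.item_prefix + item].astype(float)
                lo, hi = SF12_ITEM_RANGES[item]
                if base.polarity.get(item, 1) < 0:
                    col = (lo + hi) - col
                sd = float(col.std(ddof=1))
                if sd == 0:
                    raise ValueError(f"SF-12 item {item} is constant; cannot standardize")
                norms[item] = (float(col.mean()), sd)
            self.weights_ = ScoringWeights(
                dict(base.pcs_weights), dict(base.mcs_weights), norms,
                base.t_location, base.t_scale, dict(base.polarity),
            )
        else:
            self.weights_ = base
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        w = self.weights_
        z = np.empty((len(X), len(SF12_ITEMS)))
        for k, item in enumerate(SF12_ITEMS):
            col = X[self.item_prefix + item].astype(float).to_numpy()
            lo, hi = SF12_ITEM_RANGES[item]
            bad = ~np.isnan(col) & ((col < lo) | (col > hi))
            if bad.any():
                raise ValueError(f"SF-12 item {item} out of range in {int(bad.sum())} rows")
            if w.polarity.get(item, 1) < 0:
                col = (lo + hi) - col
            mean, sd = w.norm_params[item]
            z[:, k] = (col - mean) / sd
        pcs_w = np.array([w.pcs_weights[i] for i in SF12_ITEMS])
        mcs_w = np.array([w.mcs_weights[i] for i in SF12_ITEMS])
        out = X.copy()
        out["PCS"] = w.t_location + w.t_scale * (z @ pcs_w)
        out["MCS"] = w.t_location + w.t_scale * (z @ mcs_w)
        return out


# fixed bins: label -> [lower, upper) on the last bin upper-inclusive by +inf
AGE_BINS = (("50-54", 50.0, 55.0), ("55-69", 55.0, 70.0), ("70-81", 70.0, 82.0))
INCOME_BINS = (("Low", -np.inf, 1.0), ("Mid", 1.0, 4.0), ("High", 4.0, np.inf))


@dataclass
class DiscretizationRules:
    """All cut points and labels used to produce the categorical analysis table."""

    age_bins: tuple = AGE_BINS
    income_bins: tuple = INCOME_BINS
    #: var -> (25th, 75th percentile) for Low/Mid/High coding
    continuous_cuts: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: target -> (25th, 75th percentile) defining poor/good tail events
    tail_cuts: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for var, (lo, hi) in {**self.continuous_cuts, **self.tail_cuts}.items():
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
                raise ValueError(f"invalid cut points for {var}: ({lo}, {hi})")

    def to_json(self) -> str:
        return json.dumps(
            {
                "age_bins": [list(b) for b in self.age_bins],
                "income_bins": [[lbl, lo if np.isfinite(lo) else None, hi if np.isfinite(hi) else None]
                                for lbl, lo, hi in self.income_bins],
                "continuous_cuts": {k: list(v) for k, v in self.continuous_cuts.items()},
                "tail_cuts": {k: list(v) for k, v in self.tail_cuts.items()},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DiscretizationRules":
        d = json.loads(text)
        income = tuple(
            (lbl, -np.inf if lo is None else lo, np.inf if hi is None else hi)
            for lbl, lo, hi in d["income_bins"]
        )
        return cls(
            age_bins=tuple(tuple(b) for b in d["age_bins"]),
            income_bins=income,
            continuous_cuts={k: tuple(v) for k, v in d["continuous_cuts"].items()},
            tail_cuts={k: tuple(v) for k, v in d["tail_cuts"].items()},
        )


def _cut_lmh(x: np.ndarray, q25: float, q75: float, higher_is_better: bool) -> np.ndarray:
    """Three-level cut with boundary values assigned to the lower-risk side."""
    out = np.full(len(x), "Mid", dtype=object)
    if higher_is_better:
        out[x < q25] = "Low"
        out[x >= q75] = "High"
    else:
        out[x <= q25] = "Low"
        out[x > q75] = "High"
    return out


def _cut_bins(x: np.ndarray, bins) -> np.ndarray:
    out = np.full(len(x), None, dtype=object)
    for i, (label, lo, hi) in enumerate(bins):
        last = i == len(bins) - 1
        mask = (x >= lo) & ((x <= hi) if last else (x < hi))
        out[mask] = label
    if any(v is None for v in out):
        raise ValueError("values outside the declared bins")
    return out


class QuantileDiscretizer(TransformerMixin, BaseEstimator):
    """Learn empirical quartile cuts on a scored cohort and emit the categorical table.

    ``fit`` expects a table that already carries ACT, PCS and MCS columns
    (see :class:`SF12Scorer` and :func:`compute_act`).  ``transform`` returns
    the 15-variable categorical analysis table with ordered categories; the
    fitted :class:`DiscretizationRules` live in ``rules_`` and every cut
    point is logged.
    """

    QUARTILE_VARS = ("BMI", "ACT", "INSOMNIA", "PSS", "PCS", "MCS")

    def __init__(self, tail_percentiles: tuple[float, float] = (25.0, 75.0)):
        self.tail_percentiles = tail_percentiles

    def fit(self, X: pd.DataFrame, y=None) -> "QuantileDiscretizer":
        lo_p, hi_p = self.tail_percentiles
        cuts = {}
        for var in self.QUARTILE_VARS:
            col = X[var].astype(float).to_numpy()
            cuts[var] = (float(np.percentile(col, lo_p)), float(np.percentile(col, hi_p)))
            logger.info("discretization cut %s: 25th=%.4f 75th=%.4f", var, *cuts[var])
        self.rules_ = DiscretizationRules(
            continuous_cuts=cuts,
            tail_cuts={t: cuts[t] for t in ("PCS", "MCS")},
        )
        self.rules_.validate()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        rules = self.rules_
        out = pd.DataFrame(index=X.index)
        out["SEX"] = pd.Categorical(X["SEX"], categories=["Male", "Female"])
        out["AGE"] = pd.Categorical(
            _cut_bins(X["AGE"].astype(float).to_numpy(), rules.age_bins),
            categories=[b[0] for b in rules.age_bins], ordered=True,
        )
        for var in ("MARRY", "JOB", "EXER", "DRINK", "SMOKE"):
            out[var] = pd.Categorical(X[var], categories=["Yes", "No"])
        out["INCOME"] = pd.Categorical(
            _cut_bins(X["INCOME"].astype(float).to_numpy(), rules.income_bins),
            categories=list(LMH), ordered=True,
        )
        for var in self.QUARTILE_VARS:
            q25, q75 = rules.continuous_cuts[var]
            out[var] = pd.Categorical(
                _cut_lmh(X[var].astype(float).to_numpy(), q25, q75, var in HIGHER_IS_BETTER),
                categories=list(LMH), ordered=True,
            )
        ncncd = X["NCNCD"].astype(int).to_numpy()
        if ncncd.min() < 0 or ncncd.max() > 4:
            raise ValueError("NCNCD must lie in 0..4")
        lab = np.where(ncncd == 0, "Low", np.where(ncncd == 1, "Mid", "High"))
        out["nCNCD"] = pd.Categorical(lab, categories=list(LMH), ordered=True)
        return out


def discretize_cohort(table: pd.DataFrame, rules: DiscretizationRules) -> pd.DataFrame:
    """Apply previously fitted :class:`DiscretizationRules` to a scored cohort."""
    for var in QuantileDiscretizer.QUARTILE_VARS:
        if var not in rules.continuous_cuts:
            raise ValueError(f"no discretization rule for variable {var}")
    disc = QuantileDiscretizer()
    disc.rules_ = rules
    return disc.transform(table)


def complete_case_filter(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Drop rows with any missing analysis value; the removal count is logged."""
    cols = list(columns) if columns is not None else list(table.columns)
    kept = table.dropna(subset=cols)
    removed = len(table) - len(kept)
    if len(kept) == 0:
        logger.warning("complete-case filter removed every row")
    logger.info("complete-case filter removed %d of %d rows", removed, len(table))
    return kept
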