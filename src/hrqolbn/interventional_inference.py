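"""Discrete Bayesian-network parameter fitting and do-interventional queries.

A fitted network is the Markov factorization P(X1..Xp) = prod_i P(Xi | Pa_i)
with multinomial CPTs estimated by (optionally Laplace-smoothed) counts.  An
intervention do(X = x) severs X from its parents and clamps its value; the
probability of a tail event under the mutilated network is then computed
exactly by variable elimination, so no Monte-Carlo noise enters the effect
estimates.  A forward sampler over the (mutilated) network is provided as an
independent stochastic oracle for testing.

Interventions may also set a variable to a *merged* level (a set of base
categories): the intervened node then follows its observational marginal
restricted to that set, renormalized — a stochastic policy used by the
interaction analysis when quartile-coded exposures merge two categories.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exact import Factor, eliminate
from .structure_learning import Dag

logger = logging.getLogger(__name__)

__all__ = [
    "FittedBn", "fit_cpts", "do_probability", "effect_table",
    "direction_weighted_average", "flip_arc", "sample_from_bn",
    "DEFAULT_REFERENCE_LEVELS",
]

#: Most-favorable category per variable, the RR = 1 reference convention.
DEFAULT_REFERENCE_LEVELS = {
    "INSOMNIA": "Low", "PSS": "Low", "ACT": "High", "BMI": "Mid",
    "nCNCD": "Low", "EXER": "Yes", "DRINK": "No", "SMOKE": "No",
    "MARRY": "Yes", "JOB": "Yes", "INCOME": "High",
    "SEX": "Male", "AGE": "50-54",
}


@dataclass
class FittedBn:
    """A DAG plus per-node CPTs ``P(node | parents)``.

    ``cpts[v]`` has shape ``(*parent cardinalities, |domain(v)|)`` with parent
    axes following ``dag.parents[v]`` order; each row sums to 1.
    """

    dag: Dag
    domains: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray]
    n: int = 0
    pseudo_count: float = 0.0
    _marginals: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def validate(self) -> None:
        self.dag.validate()
        for v in self.dag.nodes:
            dom = self.domains[v]
            if len(dom) == 0:
                raise ValueError(f"empty domain for {v}")
            t = self.cpts[v]
            want = tuple(len(self.domains[p]) for p in self.dag.parents[v]) + (len(dom),)
            if t.shape != want:
                raise ValueError(f"CPT shape mismatch for {v}: {t.shape} != {want}")
            if np.any(t < 0):
                raise ValueError(f"negative probability in CPT of {v}")
            if not np.allclose(t.sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows of {v} do not sum to 1")

    def factor(self, v: str) -> Factor:
        return Factor(tuple(self.dag.parents[v]) + (v,), self.cpts[v])

    def level_index(self, v: str, level: str) -> int:
        try:
            return self.domains[v].index(level)
        except ValueError:
            raise ValueError(f"unknown level {level!r} for variable {v}") from None

    def marginal(self, v: str) -> np.ndarray:
        """Exact observational marginal of ``v`` (cached)."""
        if v not in self._marginals:
            f = eliminate([self.factor(u) for u in self.dag.nodes], (v,))
            t = f.table / f.table.sum()
            self._marginals[v] = t
        return self._marginals[v]

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "nodes": list(self.dag.nodes),
            "parents": {v: list(ps) for v, ps in self.dag.parents.items()},
            "domains": {v: list(d) for v, d in self.domains.items()},
            "cpts": {v: self.cpts[v].tolist() for v in self.dag.nodes},
            "n": self.n,
            "pseudo_count": self.pseudo_count,
        })

    @classmethod
    def from_json(cls, text: str) -> "FittedBn":
        d = json.loads(text)
        dag = Dag(tuple(d["nodes"]), {v: tuple(ps) for v, ps in d["parents"].items()})
        bn = cls(
            dag,
            {v: tuple(dom) for v, dom in d["domains"].items()},
            {v: np.asarray(t, dtype=float) for v, t in d["cpts"].items()},
            int(d["n"]), float(d["pseudo_count"]),
        )
        bn.validate()
        return bn


def fit_cpts(dag: Dag, data: pd.DataFrame, pseudo_count: float = 1.0) -> FittedBn:
    """Estimate CPTs on ``dag`` from a categorical table.

    Each entry is ``(count + pseudo_count) / (stratum_total + pseudo_count * |domain|)``;
    a parent stratum with zero observations and no smoothing falls back to the
    uniform distribution (logged).
    """
    if pseudo_count < 0:
        raise ValueError("pseudo_count must be nonnegative")
    missing = [v for v in dag.nodes if v not in data.columns]
    if missing:
        raise ValueError(f"data lacks columns for nodes: {missing}")
    domains: dict[str, tuple[str, ...]] = {}
    codes: dict[str, np.ndarray] = {}
    for v in dag.nodes:
        col = data[v]
        cat = col if isinstance(col.dtype, pd.CategoricalDtype) else pd.Categorical(col)
        if isinstance(col.dtype, pd.CategoricalDtype):
            cat = col.cat
        domains[v] = tuple(str(c) for c in cat.categories)
        cd = cat.codes if isinstance(cat.codes, np.ndarray) else cat.codes.to_numpy()
        if (cd < 0).any():
            raise ValueError(f"missing values in column {v}")
        codes[v] = np.asarray(cd, dtype=np.int64)
    cpts = {}
    for v in dag.nodes:
        ps = dag.parents[v]
        k = len(domains[v])
        pcards = [len(domains[p]) for p in ps]
        idx = np.zeros(len(data), dtype=np.int64)
        for p in ps:
            idx = idx * len(domains[p]) + codes[p]
        idx = idx * k + codes[v]
        counts = np.bincount(idx, minlength=int(np.prod(pcards, dtype=int)) * k)
        counts = counts.reshape(*pcards, k).astype(float)
        totals = counts.sum(axis=-1, keepdims=True)
        if pseudo_count == 0:
            empty = totals[..., 0] == 0
            if empty.any():
                logger.info("uniform fallback for %d empty strata of %s", int(empty.sum()), v)
            with np.errstate(invalid="ignore", divide="ignore"):
                t = counts / totals
            t[np.broadcast_to((totals == 0), t.shape)] = 1.0 / k
        else:
            t = (counts + pseudo_count) / (totals + pseudo_count * k)
        cpts[v] = t
    bn = FittedBn(dag, domains, cpts, len(data), pseudo_count)
    bn.validate()
    return bn


def _policy_vector(bn: FittedBn, var: str, value) -> np.ndarray:
    """Intervention distribution over domain(var) for a level, set, or dict."""
    k = len(bn.domains[var])
    if isinstance(value, str):
        vec = np.zeros(k)
        vec[bn.level_index(var, value)] = 1.0
        return vec
    if isinstance(value, dict):
        vec = np.zeros(k)
        for lvl, w in value.items():
            vec[bn.level_index(var, lvl)] = float(w)
        s = vec.sum()
        if s <= 0:
            raise ValueError(f"degenerate intervention distribution for {var}")
        return vec / s
    # a set of levels -> restricted, renormalized observational marginal
    levels = list(value)
    marg = bn.marginal(var)
    vec = np.zeros(k)
    for lvl in levels:
        vec[bn.level_index(var, lvl)] = marg[bn.level_index(var, lvl)]
    s = vec.sum()
    if s <= 0:
        raise ValueError(f"intervention levels {levels} for {var} have zero support")
    return vec / s


def _event_levels(bn: FittedBn, event) -> tuple[str, list[int]]:
    target, levels = event
    if isinstance(levels, str):
        levels = (levels,)
    return target, [bn.level_index(target, lvl) for lvl in levels]


def do_probability(bn: FittedBn, interventions: dict, event) -> float:
    """Exact ``P(event | do(interventions))`` by truncated factorization.

    ``interventions`` maps variable -> level (hard do), set of levels
    (restricted-marginal policy), or dict level -> weight.  ``event`` is
    ``(target, level-or-levels)``.
    """
    target, lv_idx = _event_levels(bn, event)
    for v in interventions:
        if v not in bn.dag.parents:
            raise ValueError(f"unknown intervention variable {v}")
    factors = []
    for v in bn.dag.nodes:
        if v in interventions:
            vec = _policy_vector(bn, v, interventions[v])
            # positivity check against the observational marginal
            marg = bn.marginal(v)
            if np.any((vec > 0) & (marg <= 1e-12)):
                warnings.warn(
                    f"positivity violation: intervened level of {v} has zero "
                    "observational support", stacklevel=2,
                )
            factors.append(Factor((v,), vec))
        else:
            factors.append(bn.factor(v))
    f = eliminate(factors, (target,))
    t = f.table / f.table.sum()
    return float(t[lv_idx].sum())


def effect_table(
    bn: FittedBn,
    event,
    variables: list[str] | None = None,
    reference: dict[str, str] | None = None,
    negligible_threshold: float = 0.005,
) -> pd.DataFrame:
    """Single-variable interventional probabilities and risk ratios for a tail event.

    One row per (variable, level) with the do-probability of the event, the RR
    against the variable's reference level, and a flag for variables whose
    probabilities are nearly identical across levels (max - min below
    ``negligible_threshold``).
    """
    target = event[0]
    variables = list(variables) if variables is not None else [
        v for v in bn.dag.nodes if v != target
    ]
    reference = {**DEFAULT_REFERENCE_LEVELS, **(reference or {})}
    rows = []
    for var in variables:
        ref = reference.get(var, bn.domains[var][0])
        probs = {lvl: do_probability(bn, {var: lvl}, event) for lvl in bn.domains[var]}
        p_ref = probs[ref]
        spread = max(probs.values()) - min(probs.values())
        for lvl in bn.domains[var]:
            if p_ref <= 0:
                warnings.warn(f"reference probability 0 for {var}; RR undefined", stacklevel=2)
                rr = np.nan
            else:
                rr = probs[lvl] / p_ref
            rows.append({
                "variable": var, "level": lvl, "probability": probs[lvl],
                "rr": rr, "is_reference": lvl == ref,
                "negligible": spread < negligible_threshold,
            })
    return pd.DataFrame(rows)


def direction_weighted_average(
    est_a: pd.DataFrame, est_b: pd.DataFrame, weight_a: float
) -> pd.DataFrame:
    """Blend two effect tables from rival arc orientations.

    Probabilities are averaged cell-wise with weight ``weight_a`` on the first
    table; RRs are recomputed from the averaged probabilities and each cell
    keeps its (min, max) across the two orientations.
    """
    if not 0 <= weight_a <= 1:
        raise ValueError("weight_a must lie in [0, 1]")
    key = ["variable", "level"]
    a = est_a.set_index(key).sort_index()
    b = est_b.set_index(key).sort_index()
    if not a.index.equals(b.index):
        raise ValueError("effect tables cover different (variable, level) sets")
    out = a.copy()
    pa, pb = a["probability"].to_numpy(), b["probability"].to_numpy()
    out["probability"] = weight_a * pa + (1 - weight_a) * pb
    out["prob_min"] = np.minimum(pa, pb)
    out["prob_max"] = np.maximum(pa, pb)
    out = out.reset_index()
    # recompute RR against each variable's reference within the averaged table
    for var, grp in out.groupby("variable", sort=False):
        ref_rows = grp[grp["is_reference"]]
        p_ref = float(ref_rows["probability"].iloc[0]) if len(ref_rows) else np.nan
        out.loc[grp.index, "rr"] = (
            grp["probability"] / p_ref if p_ref and p_ref > 0 else np.nan
        )
    return out


def flip_arc(dag: Dag, a: str, b: str) -> Dag:
    """Return a DAG identical to ``dag`` but with arc a->b reversed to b->a."""
    if a not in dag.parents[b]:
        raise ValueError(f"no arc {a}->{b} to flip")
    parents = {v: list(ps) for v, ps in dag.parents.items()}
    parents[b].remove(a)
    parents[a].append(b)
    out = Dag(dag.nodes, {v: tuple(sorted(ps)) for v, ps in parents.items()})
    out.validate()
    return out


def sample_from_bn(
    bn: FittedBn, n: int, rng: np.random.Generator, interventions: dict | None = None
) -> pd.DataFrame:
    """Forward ancestral sampling from the (optionally mutilated) network.

    Serves as the Monte-Carlo oracle against which exact variable-elimination
    answers are tested.
    """
    import networkx as nx

    interventions = interventions or {}
    order = list(nx.topological_sort(bn.dag.to_networkx()))
    cols: dict[str, np.ndarray] = {}
    for v in order:
        k = len(bn.domains[v])
        if v in interventions:
            vec = _policy_vector(bn, v, interventions[v])
            probs = np.broadcast_to(vec, (n, k))
        else:
            ps = bn.dag.parents[v]
            if ps:
                idx = np.zeros(n, dtype=np.int64)
                for p in ps:
                    idx = idx * len(bn.domains[p]) + cols[p]
                probs = bn.cpts[v].reshape(-1, k)[idx]
            else:
                probs = np.broadcast_to(bn.cpts[v], (n, k))
        u = rng.random(n)
        cols[v] = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1).clip(0, k - 1)
    return pd.DataFrame({
        v: pd.Categorical.from_codes(cols[v], list(bn.domains[v])) for v in bn.dag.nodes
    })
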