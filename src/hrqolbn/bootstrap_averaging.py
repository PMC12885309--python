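"""Bagged structure learning: arc strength/direction and consensus networks.

Structure estimates from a single sample are unstable, so the learner is run
on B bootstrap resamples (sampling with replacement, each a fraction of the
original rows).  For every variable pair the *arc strength* is the fraction
of replicates in which the pair is connected in either orientation, and the
*arc direction* is the fraction of those pair-containing replicates carrying
a specific orientation (the two directions of a pair therefore sum to 1).
A consensus network keeps pairs whose strength exceeds a threshold, oriented
by majority direction; majority frequencies inside the uncertainty band
(default [0.5, 0.6)) are flagged as directionally unstable and exported as
undirected (dashed) edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .structure_learning import (
    Blacklist, Cpdag, Dag, _encode, _g2_from_codes, _orient_cpdag,
    _skeleton_from_codes, extend_to_dag,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ArcConfidenceTable", "ConsensusNetwork", "bootstrap_structures",
    "arc_confidence", "averaged_network", "threshold_grid", "BootstrapArcStrength",
]


@dataclass
class ArcConfidenceTable:
    """Bootstrap presence and orientation frequencies per variable pair."""

    strength: dict[frozenset, float]
    direction: dict[tuple[str, str], float]   # conditional on presence
    B: int
    resample_fraction: float

    def validate(self) -> None:
        for pair, s in self.strength.items():
            if not 0 <= s <= 1:
                raise ValueError("strength outside [0, 1]")
            a, b = sorted(pair)
            if s > 0:
                da, db = self.direction.get((a, b), 0.0), self.direction.get((b, a), 0.0)
                if abs(da + db - 1.0) > 1e-9:
                    raise ValueError(f"directions of {a}-{b} do not sum to 1")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pair in sorted(self.strength, key=lambda p: tuple(sorted(p))):
            a, b = sorted(pair)
            s = self.strength[pair]
            for u, v in ((a, b), (b, a)):
                rows.append({"from": u, "to": v, "strength": s,
                             "direction": self.direction.get((u, v), 0.0)})
        return pd.DataFrame(rows, columns=["from", "to", "strength", "direction"])


def bootstrap_structures(
    data: pd.DataFrame,
    B: int,
    fraction: float = 0.8,
    alpha: float = 0.05,
    blacklist: Blacklist | None = None,
    seed: int = 0,
    resample: bool = True,
    min_avg_count: float = 5.0,
    max_cond: int | None = None,
) -> list[Dag]:
    """Learn B DAGs, each on an independent with-replacement row resample.

    Each replicate runs the full PC-stable -> orientation -> extension chain.
    Replicates whose resample degenerates (a constant column) or admits no
    consistent extension are skipped and logged.  With ``resample=False`` the
    learner runs B times on the original rows (useful for reduction tests).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    codes, cards, nodes = _encode(data)
    n = codes.shape[0]
    m = max(int(np.floor(fraction * n)), 1)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(B)
    dags: list[Dag] = []
    skipped = 0
    for b in range(B):
        if resample:
            rng = np.random.default_rng(child_seeds[b])
            idx = rng.integers(0, n, size=m)
            sub = codes[idx]
        else:
            sub = codes
        if any(len(np.unique(sub[:, j])) < 2 for j in range(sub.shape[1])):
            skipped += 1
            logger.warning("replicate %d skipped: constant column in resample", b)
            continue
        try:
            skel = _skeleton_from_codes(sub, cards, nodes, blacklist, alpha,
                                        min_avg_count, max_cond)
            jidx = {v: i for i, v in enumerate(nodes)}

            def check(x, y, s, sub=sub):  # conservative collider confirmation
                _, _, p = _g2_from_codes(
                    sub, cards, jidx[x], jidx[y], [jidx[c] for c in s], min_avg_count
                )
                return p <= alpha

            cp = _orient_cpdag(skel, blacklist, check, alpha)
            dags.append(extend_to_dag(cp, blacklist))
        except ValueError as err:
            skipped += 1
            logger.warning("replicate %d skipped: %s", b, err)
    logger.info("bootstrap complete: %d structures, %d skipped", len(dags), skipped)
    if not dags:
        raise ValueError("every bootstrap replicate was skipped")
    return dags


def arc_confidence(structures: list[Dag], resample_fraction: float = 0.8) -> ArcConfidenceTable:
    """Presence and orientation frequencies across learned structures."""
    if not structures:
        raise ValueError("need at least one structure")
    B = len(structures)
    present: dict[frozenset, int] = {}
    directed: dict[tuple[str, str], int] = {}
    nodes = structures[0].nodes
    for dag in structures:
        for a, b in dag.arcs():
            present[frozenset((a, b))] = present.get(frozenset((a, b)), 0) + 1
            directed[(a, b)] = directed.get((a, b), 0) + 1
    strength = {p: c / B for p, c in present.items()}
    for a in nodes:
        for b in nodes:
            if a < b:
                strength.setdefault(frozenset((a, b)), 0.0)
    direction = {}
    for pair, cnt in present.items():
        a, b = sorted(pair)
        direction[(a, b)] = directed.get((a, b), 0) / cnt
        direction[(b, a)] = directed.get((b, a), 0) / cnt
    table = ArcConfidenceTable(strength, direction, B, resample_fraction)
    table.validate()
    return table


@dataclass
class ConsensusNetwork:
    """Threshold-filtered model average with per-arc confidence metadata."""

    dag: Dag
    arcs: pd.DataFrame            # from,to,strength,direction,uncertain
    strength_threshold: float
    direction_band: tuple[float, float]
    dropped_for_cycles: list[tuple[str, str]] = field(default_factory=list)

    def uncertain_pairs(self) -> list[tuple[str, str]]:
        sub = self.arcs[self.arcs["uncertain"]]
        return [tuple(r) for r in sub[["from", "to"]].itertuples(index=False)]


def averaged_network(
    confidences: ArcConfidenceTable,
    strength_threshold: float = 0.3,
    direction_band: tuple[float, float] = (0.5, 0.6),
    nodes: tuple[str, ...] | None = None,
) -> ConsensusNetwork:
    """Consensus graph: arcs with strength > threshold, majority orientation.

    Majority direction frequencies inside ``direction_band`` are flagged
    uncertain.  If the retained arcs contain a directed cycle, the weakest
    arcs on cycles are dropped (and logged) until acyclic.
    """
    if not 0 <= strength_threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    rows = []
    for pair, s in confidences.strength.items():
        if s <= strength_threshold or s == 0:
            continue
        a, b = sorted(pair)
        da = confidences.direction.get((a, b), 0.0)
        u, v = (a, b) if (da > 0.5 or (da == 0.5 and a < b)) else (b, a)
        dmaj = max(da, 1.0 - da)
        rows.append({"from": u, "to": v, "strength": s, "direction": dmaj,
                     "uncertain": direction_band[0] <= dmaj < direction_band[1]})
    arcs = pd.DataFrame(rows, columns=["from", "to", "strength", "direction", "uncertain"])
    arcs = arcs.sort_values(["from", "to"]).reset_index(drop=True)
    g = nx.DiGraph()
    if nodes:
        g.add_nodes_from(nodes)
    for r in arcs.itertuples(index=False):
        g.add_edge(r[0], r[1], strength=r.strength)
    dropped = []
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        weakest = min(cycle, key=lambda e: (g.edges[e[0], e[1]]["strength"], e))
        g.remove_edge(*weakest[:2])
        dropped.append(tuple(weakest[:2]))
        logger.warning("dropped arc %s->%s to break a consensus cycle", *weakest[:2])
    if dropped:
        arcs = arcs[~arcs.apply(lambda r: (r["from"], r["to"]) in dropped, axis=1)]
        arcs = arcs.reset_index(drop=True)
    all_nodes = tuple(nodes) if nodes else tuple(sorted(g.nodes))
    parents: dict[str, list[str]] = {v: [] for v in all_nodes}
    for a, b in g.edges:
        parents[b].append(a)
    dag = Dag(all_nodes, {v: tuple(sorted(ps)) for v, ps in parents.items()})
    dag.validate()
    return ConsensusNetwork(dag, arcs, strength_threshold, direction_band, dropped)


def threshold_grid(confidences: ArcConfidenceTable, thresholds=(0.1, 0.2, 0.3, 0.4, 0.5)) -> pd.DataFrame:
    """Retained-arc counts across a threshold sweep (nonincreasing by design)."""
    rows = [
        {"threshold": t,
         "n_arcs": int(sum(1 for s in confidences.strength.values() if s > t))}
        for t in thresholds
    ]
    return pd.DataFrame(rows)


class BootstrapArcStrength(BaseEstimator):
    """Bagged PC-stable learner producing an arc-confidence table and consensus DAG.

    Attributes after ``fit``: ``structures_`` (list of replicate DAGs),
    ``confidence_`` (:class:`ArcConfidenceTable`), ``consensus_``
    (:class:`ConsensusNetwork`).
    """

    def __init__(self, B: int = 200, fraction: float = 0.8, alpha: float = 0.05,
                 blacklist: Blacklist | None = None, strength_threshold: float = 0.3,
                 direction_band: tuple[float, float] = (0.5, 0.6), seed: int = 0,
                 resample: bool = True, min_avg_count: float = 5.0,
                 max_cond: int | None = None):
        self.B = B
        self.fraction = fraction
        self.alpha = alpha
        self.blacklist = blacklist
        self.strength_threshold = strength_threshold
        self.direction_band = direction_band
        self.seed = seed
        self.resample = resample
        self.min_avg_count = min_avg_count
        self.max_cond = max_cond

    def fit(self, X: pd.DataFrame, y=None) -> "BootstrapArcStrength":
        self.structures_ = bootstrap_structures(
            X, self.B, self.fraction, self.alpha, self.blacklist, self.seed,
            self.resample, self.min_avg_count, self.max_cond,
        )
        self.confidence_ = arc_confidence(self.structures_, self.fraction)
        self.consensus_ = averaged_network(
            self.confidence_, self.strength_threshold, self.direction_band,
            nodes=tuple(sorted(X.columns)),
        )
        return self
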