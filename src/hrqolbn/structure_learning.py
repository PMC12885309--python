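"""Constraint-based causal structure learning under a layered blacklist.

The learner is PC-stable: a level-wise conditional-independence search whose
adjacency sets are frozen within each conditioning-set size, making the
estimated skeleton invariant to variable ordering.  Domain knowledge enters
through a *blacklist* derived from a life-course layer ordering (demographic
-> socioeconomic -> behavioral/psychological -> medical -> quality of life):
arcs from a later layer back to an earlier one are prohibited.  A pair
forbidden in both directions is excluded from the skeleton search entirely;
a pair forbidden in one direction stays a candidate edge whose orientation
is constrained.

Conditional independence is assessed with the G^2 log-likelihood-ratio test
on stratified contingency tables, the standard choice for discrete PC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "LayerMap", "Blacklist", "Cpdag", "Dag",
    "default_layer_map", "build_blacklist", "ci_test",
    "pc_stable_skeleton", "orient_cpdag", "extend_to_dag", "PCStable",
]

#: Life-course layer assignment of the 15 analysis variables.
DEFAULT_LAYERS = {
    "SEX": 1, "AGE": 1,
    "MARRY": 2, "JOB": 2, "INCOME": 2,
    "BMI": 3, "EXER": 3, "DRINK": 3, "SMOKE": 3,
    "ACT": 3, "INSOMNIA": 3, "PSS": 3,
    "nCNCD": 4,
    "PCS": 5, "MCS": 5,
}


@dataclass
class LayerMap:
    """Variable -> layer index (1 = most upstream) plus explicit extra prohibitions."""

    layers: dict[str, int]
    extra_forbidden: tuple[tuple[str, str], ...] = ()

    def validate(self) -> None:
        for a, b in self.extra_forbidden:
            if a not in self.layers or b not in self.layers:
                raise ValueError(f"extra_forbidden references unknown variable: ({a}, {b})")


def default_layer_map() -> LayerMap:
    """The five-layer assignment with the sex/age exogeneity restriction."""
    return LayerMap(dict(DEFAULT_LAYERS), (("SEX", "AGE"), ("AGE", "SEX")))


@dataclass(frozen=True)
class Blacklist:
    """Set of ordered (from, to) pairs prohibited as directed arcs."""

    pairs: frozenset[tuple[str, str]] = frozenset()

    def forbids(self, a: str, b: str) -> bool:
        return (a, b) in self.pairs

    def forbids_both(self, a: str, b: str) -> bool:
        return (a, b) in self.pairs and (b, a) in self.pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.pairs), columns=["from", "to"])


def build_blacklist(layers: LayerMap) -> Blacklist:
    """All higher-layer -> lower-layer ordered pairs plus the explicit extras."""
    layers.validate()
    pairs = set()
    for a, la in layers.layers.items():
        for b, lb in layers.layers.items():
            if a != b and la > lb:
                pairs.add((a, b))
    pairs.update(tuple(p) for p in layers.extra_forbidden)
    return Blacklist(frozenset(pairs))


@dataclass
class Cpdag:
    """Partially directed graph with separating-set bookkeeping."""

    nodes: tuple[str, ...]
    directed: set[tuple[str, str]] = field(default_factory=set)
    undirected: set[frozenset[str]] = field(default_factory=set)
    sepsets: dict[frozenset[str], tuple[str, ...]] = field(default_factory=dict)

    def adjacent(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.undirected or (a, b) in self.directed or (b, a) in self.directed

    def neighbors(self, a: str) -> list[str]:
        out = {b for b in self.nodes if b != a and self.adjacent(a, b)}
        return sorted(out)

    def validate(self) -> None:
        for e in self.undirected:
            a, b = tuple(e)
            if (a, b) in self.directed or (b, a) in self.directed:
                raise ValueError("edge present as both directed and undirected")
        g = nx.DiGraph(list(self.directed))
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("directed part of CPDAG contains a cycle")
        for pair in self.sepsets:
            a, b = tuple(pair)
            if self.adjacent(a, b):
                raise ValueError(f"sepset recorded for adjacent pair {a}-{b}")

    def copy(self) -> "Cpdag":
        return Cpdag(self.nodes, set(self.directed), set(self.undirected), dict(self.sepsets))

    def v_structures(self) -> set[tuple[str, str, str]]:
        """Unshielded colliders as (x, z, y) with x < y lexicographically."""
        out = set()
        for x, z in self.directed:
            for y, z2 in self.directed:
                if z2 == z and y != x and not self.adjacent(x, y):
                    out.add((min(x, y), z, max(x, y)))
        return out


@dataclass
class Dag:
    """Directed acyclic graph stored as per-node parent sets."""

    nodes: tuple[str, ...]
    parents: dict[str, tuple[str, ...]]

    def arcs(self) -> list[tuple[str, str]]:
        return sorted((p, c) for c, ps in self.parents.items() for p in ps)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs())
        return g

    def validate(self, blacklist: Blacklist | None = None) -> None:
        for child, ps in self.parents.items():
            if child not in self.nodes or any(p not in self.nodes for p in ps):
                raise ValueError("parent set references unknown node")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("graph contains a directed cycle")
        if blacklist is not None:
            for a, b in self.arcs():
                if blacklist.forbids(a, b):
                    raise ValueError(f"arc {a}->{b} violates the blacklist")

    def skeleton(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.arcs()}


# ---------------------------------------------------------------------------
# conditional independence testing


def _encode(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Integer-encode a categorical table once for fast repeated testing."""
    cols = list(data.columns)
    codes = np.empty((len(data), len(cols)), dtype=np.int64)
    cards = np.empty(len(cols), dtype=np.int64)
    for j, c in enumerate(cols):
        col = data[c]
        if isinstance(col.dtype, pd.CategoricalDtype):
            cd = col.cat.codes.to_numpy()
        else:
            cd = pd.Categorical(col).codes
        if (cd < 0).any():
            raise ValueError(f"missing values in column {c}")
        codes[:, j] = cd
        cards[j] = cd.max() + 1 if len(cd) else 1
    return codes, cards, cols


def _g2_from_codes(codes, cards, jx, jy, js, min_avg_count):
    kx, ky = int(cards[jx]), int(cards[jy])
    ks = 1
    strat = np.zeros(codes.shape[0], dtype=np.int64)
    for j in js:
        strat = strat * int(cards[j]) + codes[:, j]
        ks *= int(cards[j])
    n = codes.shape[0]
    if min_avg_count and n / (kx * ky * ks) < min_avg_count:
        # sparse-stratum guard: declare independence rather than trust
        # asymptotics on nearly empty cells
        return 0.0, max((kx - 1) * (ky - 1), 1), 1.0
    idx = (strat * kx + codes[:, jx]) * ky + codes[:, jy]
    counts = np.bincount(idx, minlength=ks * kx * ky).reshape(ks, kx, ky).astype(float)
    tot = counts.sum(axis=(1, 2))
    rows = counts.sum(axis=2)
    colsums = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = rows[:, :, None] * colsums[:, None, :] / tot[:, None, None]
        ratio = np.where(counts > 0, counts / expected, 1.0)
        g2 = 2.0 * float(np.sum(counts * np.log(ratio)))
    nonempty = int((tot > 0).sum())
    dof = max((kx - 1) * (ky - 1) * max(nonempty, 1), 1)
    p = float(stats.chi2.sf(g2, dof)) if g2 > 0 else 1.0
    return g2, dof, p


def ci_test(data: pd.DataFrame, x: str, y: str, s=(), min_avg_count: float = 0.0):
    """G^2 conditional-independence test of ``x`` and ``y`` given set ``s``.

    Returns ``(statistic, dof, p_value)``.  Degrees of freedom are
    ``(|x|-1)(|y|-1)`` per non-empty stratum of the conditioning set.
    """
    s = tuple(s)
    if x == y or x in s or y in s:
        raise ValueError("x, y and the conditioning set must be distinct")
    cols = [x, y, *s]
    for c in cols:
        if not isinstance(data[c].dtype, pd.CategoricalDtype) and not (
            data[c].dtype == object or str(data[c].dtype).startswith("int")
        ):
            raise ValueError(f"column {c} is not categorical")
    codes, cards, names = _encode(data[cols])
    return _g2_from_codes(codes, cards, 0, 1, list(range(2, 2 + len(s))), min_avg_count)


# ---------------------------------------------------------------------------
# PC-stable skeleton


def _skeleton_from_codes(codes, cards, nodes, blacklist, alpha, min_avg_count, max_cond):
    jidx = {v: i for i, v in enumerate(nodes)}
    order = sorted(nodes)
    adj = {
        v: {u for u in order if u != v and not (blacklist and blacklist.forbids_both(u, v))}
        for v in order
    }
    sepsets: dict[frozenset, tuple] = {}
    for v in order:  # both-direction-blacklisted pairs start non-adjacent
        for u in order:
            if u < v and blacklist and blacklist.forbids_both(u, v):
                sepsets.setdefault(frozenset((u, v)), ())
    level = 0
    while True:
        if max_cond is not None and level > max_cond:
            break
        frozen = {v: sorted(adj[v]) for v in order}
        if all(len(frozen[v]) - 1 < level for v in order):
            break
        for x in order:
            for y in frozen[x]:
                if y <= x or y not in adj[x]:
                    continue
                removed = False
                seen = set()
                for side, other in ((x, y), (y, x)):
                    cands = [c for c in frozen[side] if c != other]
                    if len(cands) < level:
                        continue
                    for S in combinations(cands, level):
                        if S in seen:
                            continue
                        seen.add(S)
                        _, _, p = _g2_from_codes(
                            codes, cards, jidx[x], jidx[y],
                            [jidx[c] for c in S], min_avg_count,
                        )
                        if p > alpha:
                            adj[x].discard(y)
                            adj[y].discard(x)
                            sepsets[frozenset((x, y))] = S
                            removed = True
                            break
                    if removed:
                        break
        level += 1
    undirected = {frozenset((x, y)) for x in order for y in adj[x] if x < y}
    return Cpdag(tuple(order), set(), undirected, sepsets)


def pc_stable_skeleton(
    data: pd.DataFrame,
    blacklist: Blacklist | None = None,
    alpha: float = 0.05,
    min_avg_count: float = 5.0,
    max_cond: int | None = None,
) -> Cpdag:
    """Estimate the PC-stable skeleton with separating sets.

    Pairs blacklisted in both directions never enter the search; pairs
    blacklisted in one direction remain candidate edges (their orientation is
    handled by :func:`orient_cpdag`).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if data.shape[1] < 2:
        raise ValueError("need at least two variables")
    codes, cards, nodes = _encode(data)
    return _skeleton_from_codes(codes, cards, nodes, blacklist, alpha, min_avg_count, max_cond)


# ---------------------------------------------------------------------------
# orientation


def _orient_allowed(cp: Cpdag, a: str, b: str, blacklist: Blacklist | None) -> bool:
    return not (blacklist and blacklist.forbids(a, b))


def _set_directed(cp: Cpdag, a: str, b: str) -> None:
    cp.undirected.discard(frozenset((a, b)))
    cp.directed.discard((b, a))
    cp.directed.add((a, b))


def orient_cpdag(
    skeleton: Cpdag,
    blacklist: Blacklist | None = None,
    data: pd.DataFrame | None = None,
    alpha: float = 0.05,
    min_avg_count: float = 5.0,
) -> Cpdag:
    """Orient v-structures, propagate the blacklist, and close under Meek's rules.

    With ``data`` supplied, each unshielded-collider candidate is confirmed
    conservatively: the triple x-z-y is oriented as a collider only if x and
    y remain dependent given sepset(x, y) plus z.  A spuriously early edge
    removal (whose recorded sepset happens to omit z) then no longer forces
    a wrong orientation.  Idempotent: orientations already present are
    preserved and re-derivable.
    """
    check = None
    if data is not None:
        codes, cards, cols = _encode(data)
        jidx = {v: i for i, v in enumerate(cols)}

        def check(x, y, s):  # True -> dependent given s, collider confirmed
            _, _, p = _g2_from_codes(
                codes, cards, jidx[x], jidx[y], [jidx[c] for c in s], min_avg_count
            )
            return p <= alpha

    return _orient_cpdag(skeleton, blacklist, check, alpha)


def _orient_cpdag(skeleton, blacklist, collider_check, alpha=0.05) -> Cpdag:
    cp = skeleton.copy()
    for pair in cp.sepsets:
        a, b = tuple(pair)
        if cp.adjacent(a, b):
            raise ValueError(f"sepset recorded for adjacent pair {a}-{b}")
    # unshielded colliders x -> z <- y with z outside sepset(x, y)
    for x, y in sorted(tuple(sorted(p)) for p in cp.sepsets):
        sep = cp.sepsets[frozenset((x, y))]
        for z in sorted(set(skeleton.neighbors(x)) & set(skeleton.neighbors(y))):
            if z in sep:
                continue
            if collider_check is not None and not collider_check(x, y, tuple(sep) + (z,)):
                continue
            if frozenset((x, z)) in cp.undirected and _orient_allowed(cp, x, z, blacklist):
                _set_directed(cp, x, z)
            if frozenset((y, z)) in cp.undirected and _orient_allowed(cp, y, z, blacklist):
                _set_directed(cp, y, z)
    changed = True
    while changed:
        changed = False
        # blacklist propagation: an edge with exactly one permitted direction
        for e in sorted(tuple(sorted(p)) for p in cp.undirected):
            a, b = e
            fa, fb = not _orient_allowed(cp, a, b, blacklist), not _orient_allowed(cp, b, a, blacklist)
            if fa and not fb:
                _set_directed(cp, b, a)
                changed = True
            elif fb and not fa:
                _set_directed(cp, a, b)
                changed = True
        dg = nx.DiGraph(list(cp.directed))
        dg.add_nodes_from(cp.nodes)
        for e in sorted(tuple(sorted(p)) for p in cp.undirected):
            for a, b in (e, e[::-1]):
                if frozenset((a, b)) not in cp.undirected:
                    continue
                if not _orient_allowed(cp, a, b, blacklist):
                    continue
                if _meek_fires(cp, dg, a, b):
                    _set_directed(cp, a, b)
                    dg.add_edge(a, b)
                    changed = True
                    break
    cp.validate()
    return cp


def _meek_fires(cp: Cpdag, dg: nx.DiGraph, a: str, b: str) -> bool:
    """Whether Meek's rules force orientation a -> b of undirected edge a-b."""
    # R1: c -> a, c and b non-adjacent  (avoid new collider c -> a <- b)
    for c in cp.nodes:
        if (c, a) in cp.directed and c != b and not cp.adjacent(c, b):
            return True
    # R2 (generalized): a directed path a ~> b exists (avoid a cycle)
    if nx.has_path(dg, a, b):
        return True
    # R3: a-c, a-d, c -> b, d -> b with c, d non-adjacent
    ns = [c for c in cp.nodes if frozenset((a, c)) in cp.undirected and c != b]
    for i, c in enumerate(ns):
        for d in ns[i + 1:]:
            if (c, b) in cp.directed and (d, b) in cp.directed and not cp.adjacent(c, d):
                return True
    # R4: a-c (adjacent), c -> d, d -> b, a adjacent to d, b and c non-adjacent
    for c in cp.nodes:
        if c in (a, b) or not cp.adjacent(a, c) or cp.adjacent(b, c):
            continue
        for d in cp.nodes:
            if d in (a, b, c):
                continue
            if (c, d) in cp.directed and (d, b) in cp.directed and cp.adjacent(a, d):
                return True
    return False


def extend_to_dag(cpdag: Cpdag, blacklist: Blacklist | None = None) -> Dag:
    """Consistent extension of a CPDAG (Dor-Tarsi) with lexicographic tie-break.

    Every directed arc is kept; undirected edges are oriented without creating
    cycles or new v-structures and without violating the blacklist.  Raises if
    no consistent extension exists.
    """
    work = cpdag.copy()
    oriented = set(cpdag.directed)
    alive = set(cpdag.nodes)
    while alive:
        progress = False
        # reverse-sorted sink candidates: an unconstrained single edge a-b
        # orients a->b (lexicographically smaller tail), the documented
        # tie-break convention
        for x in sorted(alive, reverse=True):
            if any(a == x and b in alive for a, b in work.directed):
                continue  # x has outgoing arcs; not a sink
            und = [y for y in alive if frozenset((x, y)) in work.undirected]
            adj_x = [y for y in alive if y != x and work.adjacent(x, y)]
            ok = all(
                all(work.adjacent(y, z) for z in adj_x if z != y) for y in und
            )
            if not ok:
                continue
            if any(blacklist and blacklist.forbids(y, x) for y in und):
                continue
            for y in und:
                oriented.add((y, x))
                work.undirected.discard(frozenset((x, y)))
            # remove x from the working graph
            work.directed = {(a, b) for a, b in work.directed if x not in (a, b)}
            alive.discard(x)
            progress = True
            break
        if not progress:
            raise ValueError(
                "CPDAG admits no blacklist-consistent extension; blocked on nodes "
                + ", ".join(sorted(alive))
            )
    parents: dict[str, list[str]] = {v: [] for v in cpdag.nodes}
    for a, b in oriented:
        parents[b].append(a)
    dag = Dag(cpdag.nodes, {v: tuple(sorted(ps)) for v, ps in parents.items()})
    dag.validate(blacklist)
    return dag


class PCStable(BaseEstimator):
    """scikit-learn style wrapper: fit a CPDAG and DAG extension on categorical data.

    Parameters
    ----------
    alpha:
        Significance level of the G^2 tests (edges survive only if every test
        keeps p <= alpha).
    blacklist:
        Prohibited directed arcs; see :func:`build_blacklist`.
    min_avg_count:
        Sparse-table guard: a test whose average cell count falls below this
        declares independence.  Set 0 to disable.
    max_cond:
        Optional cap on the conditioning-set size.

    Attributes
    ----------
    skeleton_ : Cpdag             undirected skeleton with sepsets
    cpdag_ : Cpdag                after collider orientation and Meek closure
    dag_ : Dag                    deterministic consistent extension
    """

    def __init__(self, alpha: float = 0.05, blacklist: Blacklist | None = None,
                 min_avg_count: float = 5.0, max_cond: int | None = None):
        self.alpha = alpha
        self.blacklist = blacklist
        self.min_avg_count = min_avg_count
        self.max_cond = max_cond

    def fit(self, X: pd.DataFrame, y=None) -> "PCStable":
        self.skeleton_ = pc_stable_skeleton(
            X, self.blacklist, self.alpha, self.min_avg_count, self.max_cond
        )
        self.cpdag_ = orient_cpdag(self.skeleton_, self.blacklist, X,
                                   self.alpha, self.min_avg_count)
        self.dag_ = extend_to_dag(self.cpdag_, self.blacklist)
        return self


# ---------------------------------------------------------------------------
# exports


def dag_to_dot(dag: Dag, layers: LayerMap | None = None,
               attrs: dict[tuple[str, str], dict] | None = None) -> str:
    """Render a DAG (or consensus graph) as Graphviz DOT text."""
    palette = {1: "khaki", 2: "lightblue", 3: "palegreen", 4: "orange", 5: "salmon"}
    lines = ["digraph G {"]
    for v in dag.nodes:
        color = palette.get(layers.layers.get(v, 0), "white") if layers else "white"
        lines.append(f'  "{v}" [style=filled, fillcolor="{color}"];')
    for a, b in dag.arcs():
        at = (attrs or {}).get((a, b), {})
        opts = ", ".join(f'{k}="{v}"' for k, v in sorted(at.items()))
        lines.append(f'  "{a}" -> "{b}"' + (f" [{opts}]" if opts else "") + ";")
    lines.append("}")
    return "\n".join(lines) + "\n"


def dag_to_graphml(dag: Dag, path, attrs: dict[tuple[str, str], dict] | None = None) -> None:
    g = dag.to_networkx()
    for (a, b), at in (attrs or {}).items():
        if g.has_edge(a, b):
            g.edges[a, b].update(at)
    nx.write_graphml(g, path)
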