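"""Exact discrete inference primitives: factors and variable elimination.

The networks handled here are small (15 nodes, domains of size 2-4), so a
plain dense-factor variable-elimination engine with a min-degree ordering is
exact and fast; no approximation is ever involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Factor", "multiply", "marginalize_out", "eliminate"]


@dataclass(frozen=True)
class Factor:
    """A nonnegative table over a tuple of named discrete variables.

    ``table.ndim == len(variables)`` and axis ``i`` ranges over the domain of
    ``variables[i]``.
    """

    variables: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        if self.table.ndim != len(self.variables):
            raise ValueError("factor table rank does not match variable list")


def multiply(a: Factor, b: Factor) -> Factor:
    """Pointwise product of two factors over the union of their scopes."""
    out_vars = list(a.variables) + [v for v in b.variables if v not in a.variables]
    ta = _broadcast(a, out_vars)
    tb = _broadcast(b, out_vars)
    return Factor(tuple(out_vars), ta * tb)


def _broadcast(f: Factor, out_vars: list[str]) -> np.ndarray:
    # permute existing axes into out_vars order, then add length-1 axes
    src = [v for v in out_vars if v in f.variables]
    perm = [f.variables.index(v) for v in src]
    t = np.transpose(f.table, perm)
    shape = []
    k = 0
    for v in out_vars:
        if v in f.variables:
            shape.append(t.shape[k])
            k += 1
        else:
            shape.append(1)
    return t.reshape(shape)


def marginalize_out(f: Factor, var: str) -> Factor:
    """Sum ``var`` out of a factor's scope."""
    i = f.variables.index(var)
    return Factor(
        tuple(v for v in f.variables if v != var), f.table.sum(axis=i)
    )


def _min_degree_order(scopes: list[set[str]], to_eliminate: set[str]) -> list[str]:
    """Min-degree elimination order on the factor interaction graph.

    Ties break lexicographically so the computation is deterministic.
    """
    adj: dict[str, set[str]] = {v: set() for s in scopes for v in s}
    for s in scopes:
        for v in s:
            adj[v] |= s - {v}
    remaining = set(to_eliminate)
    order: list[str] = []
    while remaining:
        v = min(remaining, key=lambda u: (len(adj.get(u, set()) & set(adj)), u))
        order.append(v)
        neigh = adj.pop(v, set())
        for u in neigh:
            if u in adj:
                adj[u] = (adj[u] | neigh) - {u, v}
        remaining.remove(v)
    return order


def eliminate(factors: list[Factor], keep: tuple[str, ...]) -> Factor:
    """Sum out every variable not in ``keep`` and return the joint factor.

    The result's axes follow sorted variable-name order restricted to
    ``keep``; it is NOT normalized (callers divide by the total mass when a
    probability is required).
    """
    all_vars = {v for f in factors for v in f.variables}
    order = _min_degree_order([set(f.variables) for f in factors], all_vars - set(keep))
    pool = list(factors)
    for var in order:
        related = [f for f in pool if var in f.variables]
        pool = [f for f in pool if var not in f.variables]
        if not related:
            continue
        prod = related[0]
        for f in related[1:]:
            prod = multiply(prod, f)
        pool.append(marginalize_out(prod, var))
    if not pool:
        return Factor((), np.array(1.0))
    prod = pool[0]
    for f in pool[1:]:
        prod = multiply(prod, f)
    # deterministic axis order
    want = tuple(v for v in sorted(prod.variables) if v in keep)
    perm = [prod.variables.index(v) for v in want]
    extra = [i for i in range(len(prod.variables)) if prod.variables[i] not in want]
    t = np.transpose(prod.table, perm + extra)
    for _ in extra:
        t = t.sum(axis=-1)
    return Factor(want, t)
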