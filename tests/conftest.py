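import itertools

import numpy as np
import pandas as pd
import pytest

from hrqolbn.interventional_inference import FittedBn
from hrqolbn.structure_learning import Dag
from hrqolbn.synthetic_cohort import make_default_spec, sample_cohort


def brute_force_do(bn: FittedBn, interventions: dict, event) -> float:
    """Independent oracle: exhaustive summation over all joint configurations.

    Mirrors the truncated-factorization semantics (hard do for a single
    level; restricted renormalized marginal for a set of levels) by direct
    enumeration, with no factor algebra shared with the implementation.
    """
    nodes = list(bn.dag.nodes)
    domains = [bn.domains[v] for v in nodes]
    target, levels = event
    if isinstance(levels, str):
        levels = (levels,)

    # intervention distribution per intervened node
    policies = {}
    for v, val in interventions.items():
        dom = bn.domains[v]
        if isinstance(val, str):
            policies[v] = {val: 1.0}
        elif isinstance(val, dict):
            s = sum(val.values())
            policies[v] = {k: w / s for k, w in val.items()}
        else:
            # restricted marginal, computed by brute-force enumeration too
            marg = {lvl: 0.0 for lvl in dom}
            for cfg in itertools.product(*domains):
                asn = dict(zip(nodes, cfg))
                p = 1.0
                for u in nodes:
                    ps = bn.dag.parents[u]
                    idx = tuple(bn.domains[q].index(asn[q]) for q in ps)
                    p *= bn.cpts[u][idx + (bn.domains[u].index(asn[u]),)]
                marg[asn[v]] += p
            keep = {lvl: marg[lvl] for lvl in val}
            s = sum(keep.values())
            policies[v] = {k: w / s for k, w in keep.items()}

    num = 0.0
    den = 0.0
    for cfg in itertools.product(*domains):
        asn = dict(zip(nodes, cfg))
        p = 1.0
        for u in nodes:
            if u in policies:
                p *= policies[u].get(asn[u], 0.0)
            else:
                ps = bn.dag.parents[u]
                idx = tuple(bn.domains[q].index(asn[q]) for q in ps)
                p *= bn.cpts[u][idx + (bn.domains[u].index(asn[u]),)]
        den += p
        if asn[target] in levels:
            num += p
    return num / den


def toy_bn(seed: int = 0, nodes=("A", "B", "C", "D"), arcs=(("A", "B"), ("B", "C"), ("A", "C"), ("C", "D"))) -> FittedBn:
    """Small random discrete network for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    parents = {v: tuple(sorted(a for a, b in arcs if b == v)) for v in nodes}
    domains = {v: ("x", "y") if i % 2 == 0 else ("x", "y", "z") for i, v in enumerate(nodes)}
    cpts = {}
    for v in nodes:
        shape = tuple(len(domains[p]) for p in parents[v]) + (len(domains[v]),)
        t = rng.uniform(0.1, 1.0, size=shape)
        cpts[v] = t / t.sum(axis=-1, keepdims=True)
    bn = FittedBn(Dag(tuple(nodes), parents), domains, cpts)
    bn.validate()
    return bn


def sample_discrete_frame(bn: FittedBn, n: int, seed: int) -> pd.DataFrame:
    from hrqolbn.interventional_inference import sample_from_bn

    return sample_from_bn(bn, n, np.random.default_rng(seed))


@pytest.fixture(scope="session")
def default_spec():
    return make_default_spec(0)


@pytest.fixture(scope="session")
def small_cohort(default_spec):
    return sample_cohort(default_spec, 2000, seed=1)
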