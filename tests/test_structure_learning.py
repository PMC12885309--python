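import itertools

import numpy as np
import pandas as pd
import pytest

from hrqolbn.structure_learning import (
    Blacklist, Cpdag, Dag, LayerMap, PCStable, build_blacklist, ci_test,
    default_layer_map, extend_to_dag, orient_cpdag, pc_stable_skeleton,
)


class TestBlacklist:
    def test_single_layer_empty(self):
        bl = build_blacklist(LayerMap({"A": 1, "B": 1, "C": 1}))
        assert bl.pairs == frozenset()

    def test_two_layers_six_pairs(self):
        bl = build_blacklist(LayerMap({"A": 1, "B": 1, "X": 2, "Y": 2, "Z": 2}))
        assert len(bl.pairs) == 6
        assert all(b in ("A", "B") for _, b in bl.pairs)

    def test_default_layers_give_81_pairs(self):
        # five layers of sizes 2, 3, 7, 1, 2 plus the sex/age restriction;
        # independently: sum over layer pairs i<j of |Li|*|Lj| = 79, + 2
        sizes = {1: 2, 2: 3, 3: 7, 4: 1, 5: 2}
        expected = sum(
            sizes[i] * sizes[j] for i, j in itertools.combinations(sizes, 2)
        ) + 2
        bl = build_blacklist(default_layer_map())
        assert len(bl.pairs) == expected == 81

    def test_unassigned_variable_rejected(self):
        lm = LayerMap({"A": 1}, (("A", "B"),))
        with pytest.raises(ValueError):
            build_blacklist(lm)


def _cat(values, cats=None):
    return pd.Categorical(values, categories=cats or sorted(set(values)))


class TestCiTest:
    def test_deterministic_copy_dependent(self):
        x = np.repeat(["a", "b"], 100)
        df = pd.DataFrame({"x": _cat(x), "y": _cat(x)})
        _, _, p = ci_test(df, "x", "y")
        assert p < 1e-20

    def test_balanced_table_statistic_zero(self):
        df = pd.DataFrame({
            "x": _cat(["a", "a", "b", "b"] * 25),
            "y": _cat(["u", "v", "u", "v"] * 25),
        })
        stat, dof, p = ci_test(df, "x", "y")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_fixed_2x2x2_matches_independent_implementation(self):
        counts = np.array([[[20, 5], [7, 18]], [[12, 9], [11, 13]]])  # s, x, y
        rows = []
        for s in range(2):
            for x in range(2):
                for y in range(2):
                    rows += [{"s": str(s), "x": str(x), "y": str(y)}] * counts[s, x, y]
        df = pd.DataFrame(rows).astype("category")
        stat, dof, _ = ci_test(df, "x", "y", ("s",))
        # independent log-likelihood-ratio computation
        expected = 0.0
        for s in range(2):
            tab = counts[s].astype(float)
            tot = tab.sum()
            exp = np.outer(tab.sum(1), tab.sum(0)) / tot
            expected += 2 * np.sum(tab * np.log(tab / exp))
        assert stat == pytest.approx(expected, rel=1e-12)
        assert dof == 2

    def test_rejects_overlapping_sets(self):
        df = pd.DataFrame({"x": _cat(["a", "b"]), "y": _cat(["a", "b"])})
        with pytest.raises(ValueError):
            ci_test(df, "x", "x")


def _chain_data(n=5000, seed=0):
    # A -> B -> C with strong effects
    rng = np.random.default_rng(seed)
    a = rng.random(n) < 0.5
    b = rng.random(n) < np.where(a, 0.85, 0.15)
    c = rng.random(n) < np.where(b, 0.85, 0.15)
    return pd.DataFrame({
        "A": _cat(np.where(a, "t", "f")),
        "B": _cat(np.where(b, "t", "f")),
        "C": _cat(np.where(c, "t", "f")),
    })


def _collider_data(n=5000, seed=0):
    # A -> C <- B, A and B independent
    rng = np.random.default_rng(seed)
    a = rng.random(n) < 0.5
    b = rng.random(n) < 0.5
    pc = 0.1 + 0.4 * a + 0.4 * b
    c = rng.random(n) < pc
    return pd.DataFrame({
        "A": _cat(np.where(a, "t", "f")),
        "B": _cat(np.where(b, "t", "f")),
        "C": _cat(np.where(c, "t", "f")),
    })


class TestPcStable:
    def test_chain_skeleton_and_sepset(self):
        skel = pc_stable_skeleton(_chain_data(), alpha=0.05)
        assert skel.undirected == {frozenset(("A", "B")), frozenset(("B", "C"))}
        assert skel.sepsets[frozenset(("A", "C"))] == ("B",)

    def test_independent_columns_empty_skeleton(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({
            k: _cat(rng.choice(["a", "b", "c"], 800)) for k in "WXYZ"
        })
        skel = pc_stable_skeleton(df, alpha=0.01)
        assert skel.undirected == set()

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(1)
        df = _chain_data(2000, 3)
        df["D"] = _cat(rng.choice(["a", "b"], 2000))
        base = pc_stable_skeleton(df)
        shuffled = df[["D", "C", "A", "B"]]
        perm = pc_stable_skeleton(shuffled)
        assert base.undirected == perm.undirected
        assert base.sepsets == perm.sepsets

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            pc_stable_skeleton(_chain_data(100), alpha=1.5)

    def test_both_direction_blacklist_excludes_pair(self):
        df = _chain_data()
        bl = Blacklist(frozenset({("A", "B"), ("B", "A")}))
        skel = pc_stable_skeleton(df, bl)
        assert frozenset(("A", "B")) not in skel.undirected


class TestOrientation:
    def test_collider_oriented(self):
        skel = pc_stable_skeleton(_collider_data())
        cp = orient_cpdag(skel)
        assert ("A", "C") in cp.directed
        assert ("B", "C") in cp.directed

    def test_chain_stays_undirected(self):
        cp = orient_cpdag(pc_stable_skeleton(_chain_data()))
        assert cp.directed == set()
        assert cp.undirected == {frozenset(("A", "B")), frozenset(("B", "C"))}

    def test_blacklisted_direction_forces_orientation(self):
        skel = pc_stable_skeleton(_chain_data())
        bl = Blacklist(frozenset({("B", "A")}))
        cp = orient_cpdag(skel, bl)
        assert ("A", "B") in cp.directed

    def test_idempotent(self):
        skel = pc_stable_skeleton(_collider_data())
        once = orient_cpdag(skel)
        twice = orient_cpdag(once)
        assert once.directed == twice.directed
        assert once.undirected == twice.undirected


def _random_dag(rng, n_nodes=6, p_edge=0.35) -> Dag:
    names = tuple("ABCDEF"[:n_nodes])
    parents = {v: [] for v in names}
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < p_edge:
            parents[names[j]].append(names[i])
    return Dag(names, {v: tuple(sorted(ps)) for v, ps in parents.items()})


def _pattern_of(dag: Dag) -> Cpdag:
    """CPDAG-like pattern: v-structure arcs directed, everything else undirected."""
    arcs = set(dag.arcs())
    skel = dag.skeleton()
    vs = set()
    for z in dag.nodes:
        for x, y in itertools.combinations(dag.parents[z], 2):
            if frozenset((x, y)) not in skel:
                vs.add((x, z))
                vs.add((y, z))
    und = {frozenset(e) for e in skel} - {frozenset(d) for d in vs}
    return Cpdag(dag.nodes, set(vs), und, {})


class TestExtendToDag:
    def test_directed_input_identity(self):
        cp = Cpdag(("A", "B", "C"), {("A", "B"), ("B", "C")}, set(), {})
        dag = extend_to_dag(cp)
        assert set(dag.arcs()) == {("A", "B"), ("B", "C")}

    def test_single_undirected_edge_lexicographic(self):
        cp = Cpdag(("A", "B"), set(), {frozenset(("A", "B"))}, {})
        dag = extend_to_dag(cp)
        assert dag.arcs() == [("A", "B")]

    def test_random_patterns_valid_extensions(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            true = _random_dag(rng)
            pattern = _pattern_of(true)
            dag = extend_to_dag(pattern)
            # consistent extension: acyclic, same skeleton, directed arcs
            # kept, v-structures preserved exactly
            dag.validate()
            assert dag.skeleton() == true.skeleton()
            assert pattern.directed <= set(dag.arcs())
            assert _pattern_of(dag).directed == pattern.directed

    def test_blacklist_respected(self):
        cp = Cpdag(("A", "B"), set(), {frozenset(("A", "B"))}, {})
        dag = extend_to_dag(cp, Blacklist(frozenset({("A", "B")})))
        assert dag.arcs() == [("B", "A")]


class TestPCStableEstimator:
    def test_fit_exposes_graph_attributes(self):
        est = PCStable(alpha=0.05).fit(_collider_data())
        assert hasattr(est, "skeleton_") and hasattr(est, "cpdag_")
        assert ("A", "C") in est.dag_.arcs()
        params = est.get_params()
        assert params["alpha"] == 0.05
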