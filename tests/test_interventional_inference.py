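import numpy as np
import pandas as pd
import pytest

from hrqolbn.interventional_inference import (
    FittedBn, direction_weighted_average, do_probability, effect_table,
    fit_cpts, flip_arc, sample_from_bn,
)
from hrqolbn.structure_learning import Dag

from .conftest import brute_force_do, toy_bn


class TestFitCpts:
    def test_parentless_counts(self):
        df = pd.DataFrame({"x": pd.Categorical(["a"] * 30 + ["b"] * 70)})
        bn = fit_cpts(Dag(("x",), {"x": ()}), df, pseudo_count=0)
        assert bn.cpts["x"] == pytest.approx([0.3, 0.7])

    def test_empty_stratum_uniform_fallback(self):
        df = pd.DataFrame({
            "p": pd.Categorical(["u"] * 10, categories=["u", "v"]),
            "x": pd.Categorical(["a"] * 5 + ["b"] * 5, categories=["a", "b", "c"]),
        })
        bn = fit_cpts(Dag(("p", "x"), {"p": (), "x": ("p",)}), df, pseudo_count=0)
        assert bn.cpts["x"][1] == pytest.approx([1 / 3, 1 / 3, 1 / 3])

    def test_laplace_formula(self):
        df = pd.DataFrame({
            "p": pd.Categorical(["u", "u", "v"]),
            "x": pd.Categorical(["a", "a", "b"]),
        })
        bn = fit_cpts(Dag(("p", "x"), {"p": (), "x": ("p",)}), df, pseudo_count=1)
        # stratum u: counts (2, 0) -> (3/4, 1/4)
        assert bn.cpts["x"][0] == pytest.approx([0.75, 0.25])

    def test_matches_independent_groupby_tally(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "p": pd.Categorical(rng.choice(["u", "v"], 300)),
            "q": pd.Categorical(rng.choice(["s", "t"], 300)),
            "x": pd.Categorical(rng.choice(["a", "b", "c"], 300)),
        })
        bn = fit_cpts(Dag(("p", "q", "x"), {"p": (), "q": (), "x": ("p", "q")}), df, 0)
        tally = df.groupby(["p", "q", "x"], observed=False).size().unstack("x")
        probs = tally.div(tally.sum(axis=1), axis=0)
        for i, p in enumerate(["u", "v"]):
            for j, q in enumerate(["s", "t"]):
                assert bn.cpts["x"][i, j] == pytest.approx(probs.loc[(p, q)].to_numpy())

    def test_missing_column_rejected(self):
        df = pd.DataFrame({"x": pd.Categorical(["a"])})
        with pytest.raises(ValueError):
            fit_cpts(Dag(("x", "y"), {"x": (), "y": ()}), df)


class TestDoProbability:
    def test_do_equals_see_for_root(self):
        bn = toy_bn(1)
        p_do = do_probability(bn, {"A": "x"}, ("C", "x"))
        # conditional P(C=x | A=x) by brute-force enumeration
        joint = 0.0
        cond = 0.0
        import itertools
        nodes = list(bn.dag.nodes)
        for cfg in itertools.product(*[bn.domains[v] for v in nodes]):
            asn = dict(zip(nodes, cfg))
            p = 1.0
            for u in nodes:
                idx = tuple(bn.domains[q].index(asn[q]) for q in bn.dag.parents[u])
                p *= bn.cpts[u][idx + (bn.domains[u].index(asn[u]),)]
            if asn["A"] == "x":
                joint += p
                if asn["C"] == "x":
                    cond += p
        assert p_do == pytest.approx(cond / joint, abs=1e-12)

    def test_empty_intervention_is_marginal(self):
        bn = toy_bn(2)
        assert do_probability(bn, {}, ("D", "x")) == pytest.approx(
            float(bn.marginal("D")[bn.level_index("D", "x")]), abs=1e-12
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_enumeration(self, seed):
        bn = toy_bn(seed)
        for interventions in [{"B": "x"}, {"A": "y", "C": "y"}, {"B": {"x", "y"}}]:
            for event in [("D", "x"), ("D", ("x", "y"))]:
                exact = do_probability(bn, interventions, event)
                brute = brute_force_do(bn, interventions, event)
                assert exact == pytest.approx(brute, abs=1e-10)

    def test_forward_sampling_consistency(self):
        bn = toy_bn(3)
        interventions = {"B": "y"}
        event = ("D", "x")
        exact = do_probability(bn, interventions, event)
        draws = sample_from_bn(bn, 100_000, np.random.default_rng(0), interventions)
        freq = (draws["D"] == "x").mean()
        se = np.sqrt(exact * (1 - exact) / 100_000)
        assert abs(freq - exact) < 4 * se + 1e-9

    def test_unknown_level_rejected(self):
        bn = toy_bn(0)
        with pytest.raises(ValueError):
            do_probability(bn, {"A": "nope"}, ("D", "x"))


class TestEffectTable:
    def test_rr_arithmetic_and_reference(self):
        bn = toy_bn(5)
        tab = effect_table(bn, ("D", "x"), ["A"], reference={"A": "x"})
        ref = tab[tab["is_reference"]]
        assert ref["rr"].iloc[0] == pytest.approx(1.0)
        other = tab[~tab["is_reference"]].iloc[0]
        assert other["rr"] == pytest.approx(
            other["probability"] / ref["probability"].iloc[0]
        )

    def test_negligible_flag_for_null_variable(self):
        # childless node has no effect on anything else
        bn = toy_bn(6)
        tab = effect_table(bn, ("A", "x"), ["D"])  # D is a sink
        assert tab["negligible"].all()
        assert np.allclose(tab["rr"], 1.0)


class TestDirectionSensitivity:
    def test_weighted_average_idempotent_and_arithmetic(self):
        bn = toy_bn(7)
        tab = effect_table(bn, ("D", "x"), ["A", "B"])
        same = direction_weighted_average(tab, tab, 0.56)
        assert same["probability"].to_numpy() == pytest.approx(tab.sort_values(["variable", "level"])["probability"].to_numpy())
        assert (same["prob_min"] == same["prob_max"]).all()

        ta = tab.copy()
        tb = tab.copy()
        ta["probability"] = 0.10
        tb["probability"] = 0.20
        avg = direction_weighted_average(ta, tb, 0.56)
        assert avg["probability"].to_numpy() == pytest.approx(0.144)

    def test_flip_arc_changes_only_endpoint_parents(self):
        dag = Dag(("A", "B", "C"), {"A": (), "B": ("A",), "C": ("B",)})
        flipped = flip_arc(dag, "A", "B")
        assert flipped.parents["C"] == dag.parents["C"]
        assert flipped.parents["A"] == ("B",)
        assert flipped.parents["B"] == ()

    def test_parentless_pair_flip_leaves_other_effects_identical(self):
        # X - Y parentless pair, both driving Z; reversing X->Y must not
        # change the estimated effect of any third variable
        rng = np.random.default_rng(8)
        n = 4000
        x = rng.random(n) < 0.5
        y = rng.random(n) < np.where(x, 0.8, 0.3)
        w = rng.random(n) < 0.5
        z = rng.random(n) < 0.1 + 0.3 * x + 0.2 * y + 0.3 * w
        lab = lambda v: pd.Categorical(np.where(v, "t", "f"), categories=["f", "t"])
        df = pd.DataFrame({"X": lab(x), "Y": lab(y), "W": lab(w), "Z": lab(z)})
        dag_a = Dag(("W", "X", "Y", "Z"), {"W": (), "X": (), "Y": ("X",), "Z": ("W", "X", "Y")})
        dag_b = flip_arc(dag_a, "X", "Y")
        # unsmoothed fits: reversing an arc between parentless nodes then
        # leaves the implied joint, hence every other effect, exactly equal
        bn_a = fit_cpts(dag_a, df, 0)
        bn_b = fit_cpts(dag_b, df, 0)
        assert bn_a.dag.parents["Z"] == bn_b.dag.parents["Z"]
        for lvl in ("f", "t"):
            pa = do_probability(bn_a, {"W": lvl}, ("Z", "t"))
            pb = do_probability(bn_b, {"W": lvl}, ("Z", "t"))
            assert pa == pytest.approx(pb, abs=1e-12)

    def test_mismatched_levels_rejected(self):
        bn = toy_bn(9)
        ta = effect_table(bn, ("D", "x"), ["A"])
        tb = effect_table(bn, ("D", "x"), ["B"])
        with pytest.raises(ValueError):
            direction_weighted_average(ta, tb, 0.5)


class TestSerialization:
    def test_bn_json_roundtrip(self):
        bn = toy_bn(10)
        back = FittedBn.from_json(bn.to_json())
        assert back.dag.parents == bn.dag.parents
        for v in bn.dag.nodes:
            assert back.cpts[v] == pytest.approx(bn.cpts[v])
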