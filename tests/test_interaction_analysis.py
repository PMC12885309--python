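import numpy as np
import pandas as pd
import pytest

from hrqolbn.interaction_analysis import (
    InteractionGrid, interaction_coding, interaction_measures,
    interaction_scan, joint_do_grid, relative_interaction,
)
from hrqolbn.interventional_inference import FittedBn, fit_cpts, flip_arc
from hrqolbn.structure_learning import Dag

from .conftest import brute_force_do, toy_bn


def _lmh_frame(n=300, seed=0):
    rng = np.random.default_rng(seed)
    lmh = ["Low", "Mid", "High"]
    return pd.DataFrame({
        "INSOMNIA": pd.Categorical(rng.choice(lmh, n), categories=lmh, ordered=True),
        "ACT": pd.Categorical(rng.choice(lmh, n), categories=lmh, ordered=True),
        "BMI": pd.Categorical(rng.choice(lmh, n), categories=lmh, ordered=True),
        "EXER": pd.Categorical(rng.choice(["Yes", "No"], n), categories=["Yes", "No"]),
        "CONST": pd.Categorical(["Low"] * n, categories=lmh),
    })


class TestCoding:
    def test_default_75th_percentile_high_risk(self):
        c = interaction_coding(_lmh_frame(), "INSOMNIA", "PCS")
        assert c.cut_percentile == 75 and c.level1 == ("High",)

    def test_act_low_quartile_is_risk(self):
        c = interaction_coding(_lmh_frame(), "ACT", "PCS")
        assert c.cut_percentile == 25 and c.level1 == ("Low",)

    def test_bmi_risk_side_depends_on_outcome(self):
        mcs = interaction_coding(_lmh_frame(), "BMI", "MCS")
        pcs = interaction_coding(_lmh_frame(), "BMI", "PCS")
        assert mcs.level1 == ("Low",) and mcs.cut_percentile == 25
        assert pcs.level1 == ("High",) and pcs.cut_percentile == 75

    def test_binary_adverse_side(self):
        c = interaction_coding(_lmh_frame(), "EXER", "MCS")
        assert c.level1 == ("No",)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            interaction_coding(_lmh_frame(), "CONST", "PCS")


class TestMeasures:
    def test_exact_additivity(self):
        g = InteractionGrid("v1", "v2", None, None, "o", 0.10, 0.20, 0.25, 0.35)
        m = interaction_measures(g)
        assert m.additive == pytest.approx(0.0, abs=1e-12)
        assert m.total == pytest.approx(0.25)
        assert m.relative == pytest.approx(0.0, abs=1e-10)

    def test_printed_relative_interactions(self):
        # the two self-consistent published worked rows
        assert round(relative_interaction(0.0111, 0.1719), 4) == 0.0646
        assert round(relative_interaction(0.0472, 0.3763), 4) == 0.1254

    def test_zero_total_gives_missing_relative(self):
        assert relative_interaction(0.01, 0.0) is None

    def test_reconstruction_identity(self):
        # additive = (p00 - p01) - (p10 - p11)
        g = InteractionGrid("a", "b", None, None, "o", 0.20, 0.23, 0.21, 0.20)
        m = interaction_measures(g)
        assert m.additive == pytest.approx((g.p00 - g.p01) - (g.p10 - g.p11))


def _binary_coding(var, risk, other=None):
    from hrqolbn.interaction_analysis import BinaryCoding

    if other is None:
        other = {"x": "y", "y": "x", "t": "f", "f": "t"}[risk]
    return BinaryCoding(var, 50.0, (risk,), (other,))


class TestJointDoGrid:
    def test_null_factor_gives_zero_interaction(self):
        # D is a sink: intervening on it cannot move A
        bn = toy_bn(1, nodes=("A", "B", "D"), arcs=(("A", "B"), ("B", "D")))
        c1 = _binary_coding("B", "x")
        c2 = _binary_coding("D", "x")
        g = joint_do_grid(bn, "B", "D", ("A", "x"), c1, c2)
        assert g.p00 == pytest.approx(g.p01, abs=1e-12)
        assert g.p10 == pytest.approx(g.p11, abs=1e-12)
        assert interaction_measures(g).additive == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_toy_network(self):
        bn = toy_bn(4, nodes=("A", "B", "C", "D", "E"),
                    arcs=(("A", "B"), ("A", "C"), ("B", "D"), ("C", "D"), ("D", "E")))
        c1 = _binary_coding("B", "x")
        c2 = _binary_coding("C", "x")
        g = joint_do_grid(bn, "B", "C", ("E", "x"), c1, c2)
        for (a, b), got in [((0, 0), g.p00), ((0, 1), g.p01), ((1, 0), g.p10), ((1, 1), g.p11)]:
            want = brute_force_do(
                bn, {"B": c1.levels(a), "C": c2.levels(b)}, ("E", "x")
            )
            assert got == pytest.approx(want, abs=1e-10)

    def test_swap_symmetry(self):
        bn = toy_bn(2)
        c1 = _binary_coding("A", "x")
        c2 = _binary_coding("B", "x")
        g = joint_do_grid(bn, "A", "B", ("D", "x"), c1, c2)
        h = joint_do_grid(bn, "B", "A", ("D", "x"), c2, c1)
        mg, mh = interaction_measures(g), interaction_measures(h)
        assert (h.p00, h.p01, h.p10, h.p11) == pytest.approx((g.p00, g.p10, g.p01, g.p11))
        assert mh.additive == pytest.approx(mg.additive)
        assert mh.total == pytest.approx(mg.total)

    def test_additive_risk_structure_has_zero_interaction(self, default_spec):
        # the generating model's physical outcome is additive in its parents
        from hrqolbn.interaction_analysis import interaction_coding

        oracle = default_spec.to_bn()
        frame = pd.DataFrame({
            "ACT": pd.Categorical(["Low", "High"], categories=["Low", "Mid", "High"]),
            "nCNCD": pd.Categorical(["Low", "High"], categories=["Low", "Mid", "High"]),
        })
        c1 = interaction_coding(frame, "ACT", "PCS")
        c2 = interaction_coding(frame, "nCNCD", "PCS")
        g = joint_do_grid(oracle, "ACT", "nCNCD", ("PCS", "Low"), c1, c2)
        assert interaction_measures(g).additive == pytest.approx(0.0, abs=1e-9)

    def test_planted_synergy_is_exact_in_oracle(self, default_spec):
        from hrqolbn.interaction_analysis import interaction_coding

        oracle = default_spec.to_bn()
        frame = pd.DataFrame({
            "INSOMNIA": pd.Categorical(["Low", "High"], categories=["Low", "Mid", "High"]),
            "PSS": pd.Categorical(["Low", "High"], categories=["Low", "Mid", "High"]),
        })
        c1 = interaction_coding(frame, "INSOMNIA", "MCS")
        c2 = interaction_coding(frame, "PSS", "MCS")
        g = joint_do_grid(oracle, "INSOMNIA", "PSS", ("MCS", "Low"), c1, c2)
        assert interaction_measures(g).additive == pytest.approx(0.05, abs=1e-9)


class TestDirectionInvariance:
    def _pair_networks(self):
        rng = np.random.default_rng(12)
        n = 3000
        x = rng.random(n) < 0.5
        y = rng.random(n) < np.where(x, 0.8, 0.3)
        z = rng.random(n) < 0.1 + 0.3 * x + 0.3 * y
        w = rng.random(n) < 0.2 + 0.4 * z
        lab = lambda v: pd.Categorical(np.where(v, "t", "f"), categories=["f", "t"])
        df = pd.DataFrame({"X": lab(x), "Y": lab(y), "Z": lab(z), "W": lab(w)})
        dag_a = Dag(("W", "X", "Y", "Z"), {"W": ("Z",), "X": (), "Y": ("X",), "Z": ("X", "Y")})
        dag_b = flip_arc(dag_a, "X", "Y")
        # unsmoothed fits: the two factorizations then imply the identical joint
        return fit_cpts(dag_a, df, 0), fit_cpts(dag_b, df, 0), df

    def test_doubly_intervened_pair_is_direction_invariant(self):
        bn_a, bn_b, _ = self._pair_networks()
        c1 = _binary_coding("X", "t")
        c2 = _binary_coding("Y", "t")
        ga = joint_do_grid(bn_a, "X", "Y", ("W", "t"), c1, c2)
        gb = joint_do_grid(bn_b, "X", "Y", ("W", "t"), c1, c2)
        assert (ga.p00, ga.p01, ga.p10, ga.p11) == pytest.approx(
            (gb.p00, gb.p01, gb.p10, gb.p11), abs=1e-12
        )

    def test_uninvolved_pair_is_direction_invariant(self):
        bn_a, bn_b, _ = self._pair_networks()
        c1 = _binary_coding("Z", "t")
        c2 = _binary_coding("W", "t")
        ga = joint_do_grid(bn_a, "Z", "W", ("X", "t"), c1, c2)
        gb = joint_do_grid(bn_b, "Z", "W", ("X", "t"), c1, c2)
        assert ga.p11 == pytest.approx(gb.p11, abs=1e-12)


class TestScan:
    def test_filter_excludes_interaction_with_small_total(self):
        # a pair whose joint effects cancel: additive 0.105 but total 0.005,
        # so the 1-percentage-point total-effect criterion drops it
        risk_probs = {(0, 0): 0.10, (0, 1): 0.05, (1, 0): 0.05, (1, 1): 0.105}
        exer_dom, smoke_dom = ("Yes", "No"), ("No", "Yes")  # index 1 = risk side
        cpt = np.zeros((2, 2, 2))
        for i, e in enumerate(exer_dom):
            for j, s in enumerate(smoke_dom):
                a = 1 if e == "No" else 0
                b = 1 if s == "Yes" else 0
                cpt[i, j] = [risk_probs[a, b], 1 - risk_probs[a, b]]
        bn = FittedBn(
            Dag(("EXER", "PCS", "SMOKE"),
                {"EXER": (), "SMOKE": (), "PCS": ("EXER", "SMOKE")}),
            {"EXER": exer_dom, "SMOKE": smoke_dom, "PCS": ("Low", "High")},
            {"EXER": np.array([0.5, 0.5]), "SMOKE": np.array([0.5, 0.5]), "PCS": cpt},
        )
        bn.validate()
        frame = pd.DataFrame({
            "EXER": pd.Categorical(["Yes", "No"], categories=list(exer_dom)),
            "SMOKE": pd.Categorical(["No", "Yes"], categories=list(smoke_dom)),
        })
        out = interaction_scan(bn, frame, pairs=[("EXER", "SMOKE")],
                               outcomes=("poor_PCS",), report_threshold=0.01)
        assert out.empty
        unfiltered = interaction_scan(bn, frame, pairs=[("EXER", "SMOKE")],
                                      outcomes=("poor_PCS",), report_threshold=None)
        assert unfiltered["interaction"].iloc[0] == pytest.approx(0.105)
        assert unfiltered["total"].iloc[0] == pytest.approx(0.005)

    def test_scan_reports_planted_synergy_and_filters(self, default_spec):
        oracle = default_spec.to_bn()
        lmh = ["Low", "Mid", "High"]
        frame = pd.DataFrame({
            v: pd.Categorical(["Low", "High"], categories=lmh)
            for v in ("INSOMNIA", "PSS", "BMI", "ACT", "nCNCD")
        })
        out = interaction_scan(
            oracle, frame,
            pairs=[("INSOMNIA", "PSS"), ("ACT", "nCNCD")],
            outcomes=("poor_MCS",), report_threshold=0.01,
        )
        # the additive pair is filtered out; the synergistic pair is reported
        kept = set(map(tuple, out[["var1", "var2"]].to_numpy()))
        assert ("INSOMNIA", "PSS") in kept
        assert ("ACT", "nCNCD") not in kept
        row = out[(out["var1"] == "INSOMNIA")].iloc[0]
        assert row["interaction"] == pytest.approx(0.05, abs=1e-9)
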