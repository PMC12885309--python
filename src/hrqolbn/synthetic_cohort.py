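"""Synthetic KoGES-like cohort generator with a known causal ground truth.

The generator is the study bench for the whole pipeline: it samples
person-level records from an explicit discrete causal network over the 15
analysis variables, then *emits* the raw measurements the pipeline ingests —
integer ages, income in million KRW, BMI, the five activity durations (which
sum to 24 h/day), integer insomnia and stress scale scores, a morbidity
count, and the 12 SF-12 Likert items driven by two correlated latent factors
(physical and mental health).  Because the generating network is stored
explicitly, exact interventional probabilities are available as an oracle
for parameter- and structure-recovery testing.

Design highlights
-----------------
* The discrete skeleton mirrors the expected epidemiology: demographic roots
  shape marriage, employment and income; income conditions exercise; sex
  drives smoking and (with smoking) drinking; exercise drives BMI and, with
  BMI, the morbidity count; morbidity and activity volume drive physical
  quality of life; insomnia and stress drive both quality-of-life factors;
  there is NO direct arc between the physical and mental factor — their
  observational correlation is entirely due to shared upstream causes.
* CPTs are built additively on the probability scale with mean-centered
  parent effects, so category marginals track the target frequencies and a
  planted synergy (a +0.05 boost to the probability of a poor mental outcome
  under joint high insomnia and high stress, beyond additivity) is exact.
* SF-12 item loadings are chosen so that the published factor-score weights
  recover each latent factor cleanly (the negative cross-weights cancel the
  positive cross-loadings) — the actual rationale of norm-based scoring.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .interventional_inference import FittedBn, do_probability
from .sf12_scoring import (
    ACT_DURATION_COLUMNS,
    ACT_MET_WEIGHTS,
    SF12_ITEM_RANGES,
    SF12_ITEMS,
)
from .structure_learning import DEFAULT_LAYERS, Dag

__all__ = [
    "GroundTruthSpec", "make_default_spec", "sample_cohort",
    "true_interventional_probability", "validate_cohort", "write_cohort_csv",
]

PHYSICAL_ITEMS = ("GH", "PF1", "PF2", "RP1", "RP2", "BP")
MENTAL_ITEMS = ("VT", "SF", "RE1", "RE2", "MH1", "MH2")

LMH = ("Low", "Mid", "High")
YN = ("Yes", "No")

#: latent factor location per Low/Mid/High quality-of-life level, and spread
FACTOR_LEVEL_MEANS = (-1.6, 0.0, 1.6)
FACTOR_LEVEL_SD = 0.15
ITEM_NOISE_SD = 0.10
ITEM_Z_SCALE = 1.0  # divisor applied to item scores before Likert thresholds
#: Per-item response-threshold (difficulty) offsets, staggered across the
#: item order so the coarsening error of the weighted sums varies smoothly
#: with the latent factors instead of concentrating at shared cut points.
ITEM_CUT_OFFSETS = {
    item: off for item, off in zip(SF12_ITEMS, np.linspace(-0.25, 0.25, 12))
}


@dataclass
class NodeSpec:
    name: str
    domain: tuple[str, ...]
    layer: int
    parents: tuple[str, ...]
    cpt: np.ndarray  # shape (*parent cards, |domain|), parent axes in `parents` order


@dataclass
class GroundTruthSpec:
    """Explicit generating model: discrete network + measurement emissions."""

    nodes: dict[str, NodeSpec]
    latent_loadings: dict[str, tuple[float, float, float]]
    continuous_emissions: dict[str, dict]
    seed: int = 0

    def validate(self) -> None:
        dag = self.to_dag()
        dag.validate()
        for name, node in self.nodes.items():
            if len(node.domain) == 0:
                raise ValueError(f"empty domain for {name}")
            for p in node.parents:
                if self.nodes[p].layer > node.layer:
                    raise ValueError(
                        f"layer violation: {p} (layer {self.nodes[p].layer}) -> "
                        f"{name} (layer {node.layer})"
                    )
            want = tuple(len(self.nodes[p].domain) for p in node.parents) + (len(node.domain),)
            if node.cpt.shape != want:
                raise ValueError(f"CPT shape mismatch for {name}")
            if np.any(node.cpt < 0):
                raise ValueError(f"negative CPT entry for {name}")
            if not np.allclose(node.cpt.sum(axis=-1), 1.0, atol=1e-12):
                raise ValueError(f"CPT rows of {name} do not sum to 1")
        if set(self.latent_loadings) != set(SF12_ITEMS):
            raise ValueError("latent loadings must cover the 12 SF-12 items")

    def to_dag(self) -> Dag:
        names = tuple(self.nodes)
        return Dag(names, {n: tuple(sorted(s.parents)) for n, s in self.nodes.items()})

    def to_bn(self) -> FittedBn:
        """The exact discrete network as a queryable Bayesian network."""
        dag = self.to_dag()
        cpts = {}
        for name, node in self.nodes.items():
            t = node.cpt
            # re-order parent axes to the Dag's sorted-parent convention
            order = [node.parents.index(p) for p in dag.parents[name]]
            cpts[name] = np.transpose(t, order + [len(node.parents)])
        bn = FittedBn(dag, {n: s.domain for n, s in self.nodes.items()}, cpts)
        bn.validate()
        return bn

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "nodes": {
                n: {
                    "domain": list(s.domain), "layer": s.layer,
                    "parents": list(s.parents), "cpt": s.cpt.tolist(),
                }
                for n, s in self.nodes.items()
            },
            "latent_loadings": {k: list(v) for k, v in self.latent_loadings.items()},
            "continuous_emissions": self.continuous_emissions,
        })

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthSpec":
        d = json.loads(text)
        nodes = {
            n: NodeSpec(n, tuple(s["domain"]), int(s["layer"]), tuple(s["parents"]),
                        np.asarray(s["cpt"], dtype=float))
            for n, s in d["nodes"].items()
        }
        spec = cls(nodes, {k: tuple(v) for k, v in d["latent_loadings"].items()},
                   d["continuous_emissions"], int(d["seed"]))
        spec.validate()
        return spec


def _centered(delta: np.ndarray, marginal: np.ndarray) -> np.ndarray:
    return delta - float(marginal @ delta)


def _build_cpt(
    parents: list[tuple[str, tuple[str, ...], np.ndarray]],
    base: np.ndarray,
    channel_deltas: dict[int, dict[str, np.ndarray]],
    synergies: tuple = (),
) -> np.ndarray:
    """Additive probability-scale CPT with mean-centered parent effects.

    ``channel_deltas[k][parent]`` shifts the probability of child level ``k``
    by a parent-level-specific amount (centered against the parent's marginal
    so the child's marginal stays at ``base``).  The remaining probability
    mass goes to the first unlisted child level.  Raises if any cell leaves
    (0, 1) — the default network is designed to need no clipping, keeping the
    planted effects exactly additive.
    """
    cards = [len(dom) for _, dom, _ in parents]
    k_child = len(base)
    grids = np.meshgrid(*[np.arange(c) for c in cards], indexing="ij") if cards else []
    cpt = np.zeros(tuple(cards) + (k_child,))
    listed = sorted(channel_deltas)
    free = [k for k in range(k_child) if k not in listed]
    if len(free) != 1:
        raise ValueError("exactly one child level must absorb the remainder")
    for k in listed:
        chan = np.full(tuple(cards) if cards else (), base[k])
        for j, (pname, _, marg) in enumerate(parents):
            d = channel_deltas[k].get(pname)
            if d is None:
                continue
            chan = chan + _centered(np.asarray(d, float), marg)[grids[j]]
        for (pa, la, pb, lb, chan_k, amount) in synergies:
            if chan_k != k:
                continue
            ja = [p[0] for p in parents].index(pa)
            jb = [p[0] for p in parents].index(pb)
            ia = parents[ja][1].index(la)
            ib = parents[jb][1].index(lb)
            chan = chan + amount * ((grids[ja] == ia) & (grids[jb] == ib))
        cpt[..., k] = chan
    cpt[..., free[0]] = 1.0 - cpt[..., listed].sum(axis=-1)
    if np.any(cpt <= 0) or np.any(cpt >= 1):
        raise ValueError("additive CPT left the unit interval; adjust effect sizes")
    return cpt


def make_default_spec(seed: int = 0) -> GroundTruthSpec:
    """The default KoGES-like generating model.

    Categorical marginals track the real cohort's frequencies; effect sizes
    are strong enough for desk-scale structure recovery.  Deterministic given
    ``seed`` (the seed only parameterizes later sampling).
    """
    n3 = np.array  # shorthand

    sex_m = n3([0.495, 0.505])
    age_m = n3([0.26, 0.634, 0.106])
    nodes: dict[str, NodeSpec] = {}

    def add(name, domain, parents, cpt):
        nodes[name] = NodeSpec(name, tuple(domain), DEFAULT_LAYERS[name], tuple(parents),
                               np.asarray(cpt, dtype=float))

    add("SEX", ("Male", "Female"), (), sex_m)
    add("AGE", ("50-54", "55-69", "70-81"), (), age_m)

    marry = _build_cpt(
        [("AGE", nodes["AGE"].domain, age_m)], n3([0.90, 0.10]),
        {0: {"AGE": n3([0.05, 0.007, -0.164])}},
    )
    add("MARRY", YN, ("AGE",), marry)
    marry_m = age_m @ marry[..., 0]
    marry_m = n3([marry_m, 1 - marry_m])

    job = _build_cpt(
        [("SEX", nodes["SEX"].domain, sex_m), ("AGE", nodes["AGE"].domain, age_m)],
        n3([0.603, 0.397]),
        {0: {"SEX": n3([0.17, -0.1666]), "AGE": n3([0.09, 0.015, -0.31])}},
    )
    add("JOB", YN, ("SEX", "AGE"), job)
    job_m = float(np.einsum("i,j,ijk->k", sex_m, age_m, job)[0])
    job_m = n3([job_m, 1 - job_m])

    income = _build_cpt(
        [("JOB", YN, job_m), ("MARRY", YN, marry_m), ("AGE", nodes["AGE"].domain, age_m)],
        n3([0.089, 0.538, 0.373]),
        {
            0: {"JOB": n3([-0.04, 0.0608]), "MARRY": n3([-0.015, 0.135]),
                "AGE": n3([-0.025, -0.012, 0.133])},
            2: {"JOB": n3([0.075, -0.114]), "MARRY": n3([0.013, -0.117]),
                "AGE": n3([0.028, 0.005, -0.0987])},
        },
    )
    add("INCOME", LMH, ("JOB", "MARRY", "AGE"), income)
    income_m = n3([0.089, 0.538, 0.373])  # exact: centered deltas preserve the base

    exer = _build_cpt(
        [("INCOME", LMH, income_m)], n3([0.656, 0.344]),
        {0: {"INCOME": n3([-0.18, -0.02, 0.0718])}},
    )
    add("EXER", YN, ("INCOME",), exer)
    exer_m = income_m @ exer[..., 0]
    exer_m = n3([exer_m, 1 - exer_m])

    add("SMOKE", YN, ("SEX",), n3([[0.655, 0.345], [0.115, 0.885]]))
    smoke_m = n3([0.382, 0.618])
    drink = _build_cpt(
        [("SEX", nodes["SEX"].domain, sex_m), ("SMOKE", YN, smoke_m)],
        n3([0.526, 0.474]),
        {0: {"SEX": n3([0.21, -0.2059]), "SMOKE": n3([0.12, -0.0742])}},
    )
    add("DRINK", YN, ("SEX", "SMOKE"), drink)

    bmi = _build_cpt(
        [("EXER", YN, exer_m)], n3([0.25, 0.50, 0.25]),
        {0: {"EXER": n3([0.04, -0.0763])}, 2: {"EXER": n3([-0.08, 0.1526])}},
    )
    add("BMI", LMH, ("EXER",), bmi)
    bmi_m = exer_m @ bmi.reshape(2, 3)

    add("ACT", LMH, (), n3([0.25, 0.50, 0.25]))
    # 0.26/0.50/0.24 places the empirical quartile cuts of the integer scale
    # scores strictly inside the support gaps, so re-discretization recovers
    # the generating categories exactly
    ins_m = n3([0.27, 0.50, 0.23])
    add("INSOMNIA", LMH, (), ins_m)

    pss = _build_cpt(
        [("INSOMNIA", LMH, ins_m)], n3([0.27, 0.50, 0.23]),
        {
            0: {"INSOMNIA": n3([0.16, -0.02, -0.12])},
            2: {"INSOMNIA": n3([-0.12, -0.01, 0.14])},
        },
    )
    add("PSS", LMH, ("INSOMNIA",), pss)

    ncncd = _build_cpt(
        [("BMI", LMH, bmi_m), ("EXER", YN, exer_m)], n3([0.72, 0.20, 0.08]),
        {
            1: {"BMI": n3([-0.05, -0.01, 0.07]), "EXER": n3([-0.026, 0.05])},
            2: {"BMI": n3([-0.03, -0.015, 0.06]), "EXER": n3([-0.021, 0.04])},
        },
    )
    add("nCNCD", LMH, ("BMI", "EXER"), ncncd)
    ncncd_m = n3([0.72, 0.20, 0.08])

    act_m = n3([0.25, 0.50, 0.25])
    pcs = _build_cpt(
        [("ACT", LMH, act_m), ("INSOMNIA", LMH, ins_m), ("PSS", LMH, ins_m),
         ("nCNCD", LMH, ncncd_m)],
        n3([0.25, 0.50, 0.25]),
        {
            0: {
                "ACT": n3([0.06, 0.0, -0.06]),
                "INSOMNIA": n3([-0.09, 0.0, 0.09]),
                "PSS": n3([-0.06, 0.0, 0.06]),
                "nCNCD": n3([-0.03, 0.07, 0.095]),
            },
            2: {
                "ACT": n3([-0.06, 0.0, 0.06]),
                "INSOMNIA": n3([0.075, 0.0, -0.075]),
                "PSS": n3([0.05, 0.0, -0.05]),
                "nCNCD": n3([0.0172, -0.04, -0.055]),
            },
        },
    )
    add("PCS", LMH, ("ACT", "INSOMNIA", "PSS", "nCNCD"), pcs)

    mcs = _build_cpt(
        [("BMI", LMH, bmi_m), ("EXER", YN, exer_m), ("INSOMNIA", LMH, ins_m),
         ("PSS", LMH, ins_m)],
        n3([0.25, 0.50, 0.25]),
        {
            0: {
                "BMI": n3([0.045, 0.0, -0.045]),
                "EXER": n3([-0.042, 0.08]),
                "INSOMNIA": n3([-0.07, 0.0, 0.07]),
                "PSS": n3([-0.085, 0.0, 0.085]),
            },
            2: {
                "BMI": n3([-0.04, 0.0, 0.04]),
                "EXER": n3([0.021, -0.04]),
                "INSOMNIA": n3([0.06, 0.0, -0.06]),
                "PSS": n3([0.075, 0.0, -0.075]),
            },
        },
        synergies=(("INSOMNIA", "High", "PSS", "High", 0, 0.05),),
    )
    add("MCS", LMH, ("BMI", "EXER", "INSOMNIA", "PSS"), mcs)

    # Cross-loadings are sized so the published factor-score weights cancel
    # the *other* factor in the computed summaries: the analytic ratio
    # -sum(cross-group weights)/sum(own-group weights) gives ~0.24/0.35, and
    # the values below additionally absorb the attenuation introduced by
    # Likert coarsening (3-point items coarsen more than 5-point ones), so
    # the weighted sums of the discretized, standardized items carry no
    # residual loading on the opposite latent factor.
    c_phys_on_mental = 0.3427   # mental loading of physical items
    c_ment_on_physical = 0.3691  # physical loading of mental items
    loadings = {}
    for item in PHYSICAL_ITEMS:
        loadings[item] = (1.0, c_phys_on_mental, ITEM_NOISE_SD)
    for item in MENTAL_ITEMS:
        loadings[item] = (c_ment_on_physical, 1.0, ITEM_NOISE_SD)

    z = stats.norm.ppf(0.75)  # theoretical quartile offsets
    emissions = {
        "AGE": {"bins": [[50, 55], [55, 70], [70, 82]]},
        "INCOME": {"low": [0.15, 1.0], "mid": [1.0, 4.0], "high_scale": 1.5, "high_max": 15.0},
        "BMI": {"mean": 24.52, "sd": 2.91, "range": [15.0, 40.0],
                "cuts": [24.52 - z * 2.91, 24.52 + z * 2.91]},
        "ACT": {"mean": 42.71, "sd": 6.48, "range": [24.0, 62.0],
                "cuts": [42.71 - z * 6.48, 42.71 + z * 6.48],
                "profile_low": [24.0, 0.0, 0.0, 0.0, 0.0],
                "profile_high": [6.0, 6.0, 6.0, 4.0, 2.0]},
        "INSOMNIA": {"mean": 6.74, "sd": 5.07, "supports": [[0, 3], [4, 9], [10, 28]]},
        "PSS": {"mean": 15.83, "sd": 5.08, "supports": [[0, 12], [13, 19], [20, 40]]},
        "nCNCD": {"high_probs": [0.7, 0.2, 0.1]},  # counts 2, 3, 4 within High
    }
    spec = GroundTruthSpec(nodes, loadings, emissions, seed=seed)
    spec.validate()
    return spec


#: The planted strong direct effects of the default model: (target, tail) ->
#: (variable, level) contrasts whose designed probability shift on that tail
#: is at least 0.05.  Parameter-recovery benchmarks check these contrasts;
#: weaker designed effects sit below the sampling noise of a cohort-sized
#: fit and are not individually asserted.
STRONG_PLANTED_EFFECTS = {
    ("PCS", "Low"): [("ACT", "Low"), ("ACT", "High"), ("INSOMNIA", "Low"),
                     ("INSOMNIA", "High"), ("PSS", "Low"), ("PSS", "High"),
                     ("nCNCD", "Mid"), ("nCNCD", "High")],
    ("PCS", "High"): [("ACT", "Low"), ("ACT", "High"), ("INSOMNIA", "Low"),
                      ("INSOMNIA", "High"), ("PSS", "Low"), ("PSS", "High"),
                      ("nCNCD", "High")],
    ("MCS", "Low"): [("INSOMNIA", "Low"), ("INSOMNIA", "High"), ("PSS", "Low"),
                     ("PSS", "High"), ("EXER", "No")],
    ("MCS", "High"): [("INSOMNIA", "Low"), ("INSOMNIA", "High"), ("PSS", "Low"),
                      ("PSS", "High")],
}


def _var_rng(seed: int, name: str) -> np.random.Generator:
    """Per-variable stream keyed by a stable hash of the variable name."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())]))


def _sample_discrete(spec: GroundTruthSpec, n: int, seed: int) -> dict[str, np.ndarray]:
    import networkx as nx

    order = list(nx.topological_sort(spec.to_dag().to_networkx()))
    codes: dict[str, np.ndarray] = {}
    for name in order:
        node = spec.nodes[name]
        k = len(node.domain)
        if node.parents:
            idx = np.zeros(n, dtype=np.int64)
            for p in node.parents:
                idx = idx * len(spec.nodes[p].domain) + codes[p]
            probs = node.cpt.reshape(-1, k)[idx]
        else:
            probs = np.broadcast_to(node.cpt, (n, k))
        u = _var_rng(seed, name).random(n)
        codes[name] = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1).clip(0, k - 1)
    return codes


def _trunc_norm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _banded_continuous(rng, code, cfg) -> np.ndarray:
    """Continuous emission: truncated normal within the level's quantile band."""
    lo, hi = cfg["range"]
    c1, c2 = cfg["cuts"]
    edges = [(lo, c1), (c1, c2), (c2, hi)]
    out = np.empty(len(code))
    for lvl, (a, b) in enumerate(edges):
        m = code == lvl
        if m.any():
            out[m] = _trunc_norm(rng, cfg["mean"], cfg["sd"], a, b, int(m.sum()))
    return out


def _integer_scale(rng, code, cfg) -> np.ndarray:
    """Integer scale score: discretized truncated normal on disjoint supports."""
    out = np.empty(len(code), dtype=np.int64)
    for lvl, (a, b) in enumerate(cfg["supports"]):
        m = code == lvl
        if not m.any():
            continue
        support = np.arange(a, b + 1)
        w = stats.norm.pdf(support, loc=cfg["mean"], scale=cfg["sd"])
        w = w / w.sum()
        out[m] = rng.choice(support, size=int(m.sum()), p=w)
    return out


def sample_cohort(
    spec: GroundTruthSpec, n: int, seed: int, missing_rate: float = 0.0
) -> pd.DataFrame:
    """Draw ``n`` raw person-level records by ancestral sampling + emission.

    Reproducible under a fixed seed; every variable uses its own RNG stream
    keyed by a stable hash of its name, so results do not depend on column
    order.  ``missing_rate`` plants missing-completely-at-random cells.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    spec.validate()
    codes = _sample_discrete(spec, n, seed)
    em = spec.continuous_emissions
    out = pd.DataFrame(index=range(n))

    out["SEX"] = np.asarray(spec.nodes["SEX"].domain, dtype=object)[codes["SEX"]]
    rng = _var_rng(seed, "AGE_years")
    age = np.empty(n, dtype=np.int64)
    for lvl, (a, b) in enumerate(em["AGE"]["bins"]):
        m = codes["AGE"] == lvl
        age[m] = rng.integers(a, b, size=int(m.sum()))
    out["AGE"] = age
    for v in ("MARRY", "JOB", "EXER", "DRINK", "SMOKE"):
        out[v] = np.asarray(spec.nodes[v].domain, dtype=object)[codes[v]]

    rng = _var_rng(seed, "INCOME_value")
    inc = np.empty(n)
    cfg = em["INCOME"]
    for lvl, m in enumerate([codes["INCOME"] == i for i in range(3)]):
        cnt = int(m.sum())
        if lvl == 0:
            inc[m] = rng.uniform(*cfg["low"], size=cnt)
        elif lvl == 1:
            inc[m] = rng.uniform(*cfg["mid"], size=cnt)
        else:
            inc[m] = np.minimum(4.0 + rng.exponential(cfg["high_scale"], size=cnt), cfg["high_max"])
    out["INCOME"] = inc

    out["BMI"] = _banded_continuous(_var_rng(seed, "BMI_value"), codes["BMI"], em["BMI"])

    act_val = _banded_continuous(_var_rng(seed, "ACT_value"), codes["ACT"], em["ACT"])
    p0 = np.asarray(em["ACT"]["profile_low"])
    p1 = np.asarray(em["ACT"]["profile_high"])
    a0 = float(p0 @ np.asarray(ACT_MET_WEIGHTS))
    a1 = float(p1 @ np.asarray(ACT_MET_WEIGHTS))
    t = ((act_val - a0) / (a1 - a0))[:, None]
    durations = (1 - t) * p0 + t * p1  # rows sum to 24 h and reproduce act_val exactly
    for j, c in enumerate(ACT_DURATION_COLUMNS):
        out[c] = durations[:, j]

    out["INSOMNIA"] = _integer_scale(_var_rng(seed, "INSOMNIA_score"), codes["INSOMNIA"], em["INSOMNIA"])
    out["PSS"] = _integer_scale(_var_rng(seed, "PSS_score"), codes["PSS"], em["PSS"])

    rng = _var_rng(seed, "NCNCD_count")
    ncncd = np.zeros(n, dtype=np.int64)
    ncncd[codes["nCNCD"] == 1] = 1
    m = codes["nCNCD"] == 2
    ncncd[m] = rng.choice([2, 3, 4], size=int(m.sum()), p=em["nCNCD"]["high_probs"])
    out["NCNCD"] = ncncd

    # latent quality-of-life factors and Likert items
    means = np.asarray(FACTOR_LEVEL_MEANS)
    rng_p = _var_rng(seed, "latent_physical")
    rng_m = _var_rng(seed, "latent_mental")
    phi_p = means[codes["PCS"]] + FACTOR_LEVEL_SD * rng_p.standard_normal(n)
    phi_m = means[codes["MCS"]] + FACTOR_LEVEL_SD * rng_m.standard_normal(n)
    for item in SF12_ITEMS:
        lp, lm, noise = spec.latent_loadings[item]
        z = lp * phi_p + lm * phi_m \
            + noise * _var_rng(seed, f"item_{item}").standard_normal(n)
        lo, hi = SF12_ITEM_RANGES[item]
        if hi - lo == 4:
            cuts = np.array([-1.9, -0.65, 0.65, 1.9])
        else:
            cuts = np.array([-0.9, 0.9])
        # per-item difficulty offset: staggering the response thresholds
        # across items smooths the aggregate coarsening error
        cuts = cuts + ITEM_CUT_OFFSETS[item]
        out[f"SF12_{item}"] = lo + np.searchsorted(cuts, z / ITEM_Z_SCALE).clip(0, hi - lo)

    if missing_rate > 0:
        rng = _var_rng(seed, "missingness_mask")
        mask = rng.random(out.shape) < missing_rate
        out = out.mask(mask)
    return out


def validate_cohort(table: pd.DataFrame) -> None:
    """Assert the person-level invariants of a generated cohort table."""
    d = table[list(ACT_DURATION_COLUMNS)].to_numpy(dtype=float)
    row_ok = np.isnan(d).any(axis=1) | (np.abs(d.sum(axis=1) - 24.0) < 1e-9)
    if not row_ok.all():
        raise ValueError("activity durations do not sum to 24 h/day")
    for item in SF12_ITEMS:
        lo, hi = SF12_ITEM_RANGES[item]
        col = table[f"SF12_{item}"].dropna()
        if ((col < lo) | (col > hi)).any():
            raise ValueError(f"SF-12 item {item} outside its Likert range")
    nc = table["NCNCD"].dropna()
    if ((nc < 0) | (nc > 4)).any():
        raise ValueError("NCNCD outside 0..4")


def true_interventional_probability(spec: GroundTruthSpec, interventions: dict, event) -> float:
    """Exact interventional probability in the generating discrete network.

    Uses the same truncated-factorization semantics as the analysis module
    (hard do for single levels, restricted-marginal policy for merged
    levels), evaluated on the spec's own CPTs.
    """
    return do_probability(spec.to_bn(), interventions, event)


def write_cohort_csv(table: pd.DataFrame, path, spec: GroundTruthSpec | None = None) -> None:
    """Write cohort CSV plus a sidecar ``.schema.json`` describing columns."""
    table.to_csv(path, index=False)
    schema = {}
    for col in table.columns:
        base = col
        entry: dict = {"type": "float"}
        if col in ("SEX", "MARRY", "JOB", "EXER", "DRINK", "SMOKE"):
            entry = {"type": "categorical",
                     "domain": list(spec.nodes[col].domain) if spec else sorted(table[col].dropna().unique())}
        elif col in ("AGE", "INSOMNIA", "PSS", "NCNCD") or col.startswith("SF12_"):
            entry = {"type": "int"}
        if spec:
            key = "nCNCD" if base == "NCNCD" else base
            if key in spec.nodes:
                entry["layer"] = spec.nodes[key].layer
        schema[col] = entry
    with open(str(path) + ".schema.json" if not str(path).endswith(".csv")
              else str(path)[:-4] + ".schema.json", "w") as fh:
        json.dump(schema, fh, indent=2)
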