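"""End-to-end analysis pipeline: cohort -> scores -> network -> effects.

Orchestrates the full chain on either a user-supplied cohort CSV or a
synthetic cohort: complete-case filtering, SF-12 and activity scoring,
quartile discretization, layered-blacklist bootstrap structure learning,
consensus-network construction, do-interventional effect tables for the four
tail outcomes (poor/good physical and mental quality of life, defined by the
25th/75th percentiles), a direction-sensitivity analysis for the designated
unstable arc, and the pairwise interaction scan.  Every stage's parameters,
seeds and exclusions are recorded in a run log so a run is fully auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import sf12_scoring as sf
from .bootstrap_averaging import BootstrapArcStrength, threshold_grid
from .interaction_analysis import OUTCOME_EVENTS, interaction_scan
from .interventional_inference import (
    direction_weighted_average, effect_table, fit_cpts, flip_arc,
)
from .structure_learning import build_blacklist, dag_to_dot, dag_to_graphml, default_layer_map
from .synthetic_cohort import make_default_spec, sample_cohort, write_cohort_csv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "bivariate_screen", "run_pipeline"]

ANALYSIS_VARS = ("SEX", "AGE", "MARRY", "JOB", "INCOME", "EXER", "DRINK", "SMOKE",
                 "BMI", "ACT", "INSOMNIA", "PSS", "nCNCD", "PCS", "MCS")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Declarative configuration; defaults follow the study protocol
    (B=15,000 resamples at 80%, strength threshold 0.3, direction weights
    0.56/0.44, quartile tails)."""

    input_path: str | None = None     # cohort CSV; None -> synthetic
    n: int = 2566
    spec_seed: int = 0
    seed: int = 0
    missing_rate: float = 0.0
    alpha: float = 0.05
    min_avg_count: float = 5.0
    max_cond: int | None = None
    B: int = 15000
    fraction: float = 0.8
    strength_threshold: float = 0.3
    direction_band: tuple[float, float] = (0.5, 0.6)
    sensitivity_pair: tuple[str, str] = ("INSOMNIA", "PSS")
    sensitivity_force: bool = False
    weight_a: float | None = None     # None -> use the observed direction frequency
    tail_percentiles: tuple[float, float] = (25.0, 75.0)
    interaction_threshold: float = 0.01
    pseudo_count: float = 1.0
    outdir: str = "hrqolbn_run"

    def validate(self) -> None:
        checks = [
            (self.n >= 1, "n must be >= 1"),
            (0 < self.alpha < 1, "alpha must lie in (0,1)"),
            (self.B >= 1, "B must be >= 1"),
            (0 < self.fraction <= 1, "fraction must lie in (0,1]"),
            (0 <= self.strength_threshold <= 1, "strength_threshold must lie in [0,1]"),
            (0 <= self.direction_band[0] <= self.direction_band[1] <= 1, "invalid direction band"),
            (self.weight_a is None or 0 <= self.weight_a <= 1, "weight_a must lie in [0,1]"),
            (0 < self.tail_percentiles[0] < self.tail_percentiles[1] < 100, "invalid tail percentiles"),
            (self.pseudo_count >= 0, "pseudo_count must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for key in ("direction_band", "sensitivity_pair", "tail_percentiles"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        cfg.validate()
        return cfg


def bivariate_screen(scored: pd.DataFrame, covariates=None) -> pd.DataFrame:
    """Descriptive association screen of each covariate against PCS and MCS.

    Categorical covariates use the Kruskal-Wallis test on the score across
    groups; numeric covariates use Spearman rank correlation.  Constant
    covariates are reported as not applicable.
    """
    if covariates is None:
        covariates = [v for v in ("SEX", "AGE", "MARRY", "JOB", "INCOME", "EXER",
                                  "DRINK", "SMOKE", "BMI", "ACT", "INSOMNIA", "PSS", "NCNCD")
                      if v in scored.columns]
    rows = []
    for var in covariates:
        col = scored[var]
        is_cat = col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype)
        row = {"variable": var, "test": "kruskal-wallis" if is_cat else "spearman"}
        for target in ("PCS", "MCS"):
            y = scored[target].astype(float)
            if col.nunique(dropna=True) < 2:
                row[f"p_{target}"] = np.nan
                row["test"] = "not-applicable"
                continue
            if is_cat:
                groups = [y[col == g].to_numpy() for g in col.dropna().unique()]
                stat, p = stats.kruskal(*groups)
            else:
                rho, p = stats.spearmanr(col.astype(float), y)
                row[f"rho_{target}"] = rho
            row[f"p_{target}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def _derived_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    return {"cohort": int(state[0]), "bootstrap": int(state[1]), "reserved": int(state[2])}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns in-memory artifacts and writes files.

    Artifact files: cohort/screen/blacklist/arc-confidence/threshold-grid
    CSVs, consensus DOT + GraphML, per-outcome effect CSV/JSON, interaction
    CSV/JSON, and ``run_log.json``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _derived_seeds(config.seed)
    log: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "derived_seeds": seeds,
        "assumptions": {
            "ci_test": "G2 log-likelihood ratio (asymptotic chi-square)",
            "alpha": config.alpha,
            "pseudo_count": config.pseudo_count,
            "min_avg_count_guard": config.min_avg_count,
            "direction_band": list(config.direction_band),
            "quantile_convention": "linear interpolation; ties to the lower-risk side",
        },
    }

    # --- cohort ----------------------------------------------------------
    stage = "load-cohort"
    try:
        spec = None
        if config.input_path:
            cohort = pd.read_csv(config.input_path)
        else:
            spec = make_default_spec(config.spec_seed)
            cohort = sample_cohort(spec, config.n, seeds["cohort"], config.missing_rate)
        n_raw = len(cohort)
        cohort = sf.complete_case_filter(cohort)
        log["n_raw"], log["n_complete"] = n_raw, len(cohort)
        log["n_excluded_incomplete"] = n_raw - len(cohort)
        if len(cohort) == 0:
            raise ValueError("no complete cases")
        write_cohort_csv(cohort, outdir / "cohort.csv", spec)
    except Exception as err:  # noqa: BLE001
        raise PipelineError(stage, err) from err

    # --- scoring ---------------------------------------------------------
    stage = "scoring"
    try:
        scored = cohort.copy()
        scored["ACT"] = scored[list(sf.ACT_DURATION_COLUMNS)].to_numpy(dtype=float) @ np.asarray(sf.ACT_MET_WEIGHTS)
        scorer = sf.SF12Scorer().fit(scored)
        scored = scorer.transform(scored)
        screen = bivariate_screen(scored)
        screen.to_csv(outdir / "screen.csv", index=False)
    except Exception as err:  # noqa: BLE001
        raise PipelineError(stage, err) from err

    # --- discretization --------------------------------------------------
    stage = "discretization"
    try:
        disc = sf.QuantileDiscretizer(config.tail_percentiles).fit(scored)
        analysis = disc.transform(scored)
        log["cut_points"] = {k: list(v) for k, v in disc.rules_.continuous_cuts.items()}
        (outdir / "discretization_rules.json").write_text(disc.rules_.to_json())
    except Exception as err:  # noqa: BLE001
        raise PipelineError(stage, err) from err

    # --- structure learning ----------------------------------------------
    stage = "structure-learning"
    try:
        layers = default_layer_map()
        blacklist = build_blacklist(layers)
        blacklist.to_frame().to_csv(outdir / "blacklist.csv", index=False)
        log["n_blacklist_pairs"] = len(blacklist.pairs)
        learner = BootstrapArcStrength(
            B=config.B, fraction=config.fraction, alpha=config.alpha,
            blacklist=blacklist, strength_threshold=config.strength_threshold,
            direction_band=config.direction_band, seed=seeds["bootstrap"],
            min_avg_count=config.min_avg_count, max_cond=config.max_cond,
        ).fit(analysis)
        consensus = learner.consensus_
        learner.confidence_.to_frame().to_csv(outdir / "arc_confidence.csv", index=False)
        grid = threshold_grid(learner.confidence_)
        grid.to_csv(outdir / "threshold_grid.csv", index=False)
        log["threshold_grid"] = grid.to_dict("records")
        log["n_bootstrap_structures"] = len(learner.structures_)
        log["consensus_arcs"] = consensus.arcs.to_dict("records")
        log["dropped_for_cycles"] = consensus.dropped_for_cycles
        uncertain = {frozenset(p) for p in consensus.uncertain_pairs()}
        attrs = {
            (r["from"], r["to"]): ({"style": "dashed"} if r["uncertain"] else {})
            | {"strength": f"{r['strength']:.3f}", "direction": f"{r['direction']:.3f}"}
            for r in consensus.arcs.to_dict("records")
        }
        (outdir / "consensus.dot").write_text(dag_to_dot(consensus.dag, layers, attrs))
        dag_to_graphml(consensus.dag, outdir / "consensus.graphml", attrs)
    except Exception as err:  # noqa: BLE001
        raise PipelineError(stage, err) from err

    # --- effect estimation -----------------------------------------------
    stage = "effects"
    try:
        a, b = config.sensitivity_pair
        pair_fs = frozenset((a, b))
        retained = {frozenset((r["from"], r["to"])) for r in consensus.arcs.to_dict("records")}
        sensitive = pair_fs in retained and (config.sensitivity_force or pair_fs in uncertain)
        bn_primary = fit_cpts(consensus.dag, analysis, config.pseudo_count)
        bns = bn_primary
        weight_a = config.weight_a if config.weight_a is not None else 0.56
        bn_b = None
        if sensitive:
            # network A carries sensitivity_pair[0] -> sensitivity_pair[1]
            if b in consensus.dag.parents[a]:
                dag_a, dag_b = flip_arc(consensus.dag, b, a), consensus.dag
            else:
                dag_a, dag_b = consensus.dag, flip_arc(consensus.dag, a, b)
            bn_a = fit_cpts(dag_a, analysis, config.pseudo_count)
            bn_b = fit_cpts(dag_b, analysis, config.pseudo_count)
            if config.weight_a is None:
                conf = learner.confidence_.direction.get((a, b))
                weight_a = conf if conf is not None else 0.56
            bns = (bn_a, bn_b)
        log["direction_sensitivity"] = {
            "active": sensitive, "pair": [a, b], "weight_a": weight_a,
        }
        effects = {}
        for outcome, (target, tail) in OUTCOME_EVENTS.items():
            event = (target, tail)
            variables = [v for v in ANALYSIS_VARS if v != target]
            if sensitive:
                ta = effect_table(bns[0], event, variables)
                tb = effect_table(bns[1], event, variables)
                tab = direction_weighted_average(ta, tb, weight_a)
            else:
                tab = effect_table(bn_primary, event, variables)
            effects[outcome] = tab
            tab.to_csv(outdir / f"effects_{outcome}.csv", index=False)
            (outdir / f"effects_{outcome}.json").write_text(tab.to_json(orient="records"))
    except Exception as err:  # noqa: BLE001
        raise PipelineError(stage, err) from err

    # --- interactions -----------------------------------------------------
    stage = "interactions"
    try:
        scan_input = bns if sensitive else bn_primary
        interactions = interaction_scan(
            scan_input, analysis,
            report_threshold=config.interaction_threshold,
            weight_a=weight_a, sensitive_pair=config.sensitivity_pair,
        )
        interactions.to_csv(outdir / "interactions.csv", index=False)
        (outdir / "interactions.json").write_text(interactions.to_json(orient="records"))
    except Exception as err:  # noqa: BLE001
        raise PipelineError(stage, err) from err

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return {
        "spec": spec, "cohort": cohort, "scored": scored, "analysis": analysis,
        "screen": screen, "blacklist": blacklist, "learner": learner,
        "consensus": consensus, "bn": bn_primary,
        "bn_pair": (bns if sensitive else None), "weight_a": weight_a,
        "effects": effects, "interactions": interactions, "log": log,
        "discretizer": disc,
    }
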