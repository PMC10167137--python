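"""End-to-end orchestration of the four-step analysis.

``run_pipeline`` executes, for both responses (reaction time and accuracy):

1. preprocessing (practice drop, 10-s cutoff, first-eight-correct
   retention, 50%-accuracy exclusion),
2. Step 1 — Boruta + One Rule variable screening,
3. Step 2 — the quantile / robust / distributional multiverse of the full
   model ``DV ~ G x S x T + n + a + g``,
4. Step 3 — the reduced explainable model, analysed with the ANOVA-type
   statistic when every retained covariate is categorical and with median
   quantile regression otherwise,
5. Step 4 — distributional regression trees (Ex-Gaussian for RT,
   generalized beta type 1 for squeezed accuracy), plus the
   acuity-reaction-time correlations (Kendall tau-b, percentage bend).

Every reported number is serialised from the stage that computed it; the
report carries the seed and a configuration hash so identical inputs give
an identical report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import disttree, importance, multiverse, preprocessing, stats
from .distributions import EXGAUSSIAN, GB1, squeeze_unit
from .synthetic_data import SimConfig, simulate_experiment

__all__ = ["PipelineReport", "run_pipeline"]

FULL_FACTORIAL = ("group", "set_size", "target")
FULL_MAINS = ("nystagmus", "age", "gender")
CANDIDATES = ["group", "set_size", "target", "nystagmus", "age", "gender"]
CATEGORICAL = {"group", "set_size", "target", "nystagmus", "gender"}

TREE_KINDS = {"group": "nominal", "gender": "nominal", "target": "nominal",
              "nystagmus": "nominal", "set_size": "ordinal", "age": "numeric"}


@dataclass
class PipelineReport:
    seed: int
    config_hash: str
    rt: dict = field(default_factory=dict)
    accuracy: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)
    n_participants: int = 0
    n_trials: int = 0
    partial: bool = False
    failures: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "n_participants": self.n_participants,
            "n_trials": self.n_trials,
            "rt": self.rt,
            "accuracy": self.accuracy,
            "correlations": self.correlations,
            "partial": self.partial,
            "failures": self.failures,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, default=_jsonable, **kw)

    @property
    def report_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _jsonable(o):
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _config_hash(trials: pd.DataFrame, seed: int) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(trials, index=False).values.tobytes())
    h.update(str(seed).encode())
    return h.hexdigest()


def _step3(data: pd.DataFrame, response: str, retained) -> dict:
    """The reduced explainable model: ANOVA-type statistic when every
    retained covariate is categorical and the crossed design is feasible,
    median quantile regression otherwise."""
    if not retained:
        return {"method": "none", "note": "empty retained set"}
    note = None
    if all(v in CATEGORICAL for v in retained):
        try:
            res = stats.ats(data, retained, response)
            return {"method": "ats", "table": res.to_dict()}
        except ValueError as exc:
            # structurally empty cells (e.g. nystagmus nested in group)
            # make the factorial infeasible; fall through to regression
            note = f"ats infeasible: {exc}"
    for factorial in (tuple(retained), ()):
        rformula = multiverse.ModelFormula(response, factorial,
                                           () if factorial else tuple(retained))
        try:
            Xr, _ = rformula.design(data)
        except ValueError:
            continue   # aliased interaction block; retry with main effects
        tab = multiverse.fit_quantile(Xr, data[response].to_numpy())
        out = {"method": "quantile", "formula": rformula.describe(),
               "table": tab.reset_index().rename(columns={"index": "term"})
                           .to_dict(orient="records")}
        if note:
            out["note"] = note
        return out
    return {"method": "none", "note": "no estimable reduced design"}


def _branch(table: pd.DataFrame, response: str, family, seed: int,
            squeeze: bool = False) -> dict:
    """Steps 1-4 for one response; ``table`` has one row per observation."""
    out = {"response": response}
    data = table.copy()
    if squeeze:
        data[response] = squeeze_unit(data[response].to_numpy())

    # Step 1: importance screening (participant-wise importance holdout)
    X = data[CANDIDATES]
    groups = data["participant_id"].to_numpy() if "participant_id" in data else None
    imp = importance.boruta(X, data[response].to_numpy(), seed=seed,
                            groups=groups)
    imp.one_rule_accuracy = importance.one_rule(X, data[response].to_numpy())
    out["importance"] = imp.to_dict()

    # Step 2: the multiverse of the full model
    formula = multiverse.ModelFormula(response, FULL_FACTORIAL, FULL_MAINS)
    mv = multiverse.fit_multiverse(formula, data, family=family)
    out["multiverse"] = mv.to_dict()

    # Step 3: reduced explainable model
    red = multiverse.reduce_model(mv, imp)
    retained = red["retained"]
    out["reduced"] = red
    out["step3"] = _step3(data, response, retained)

    # Step 4: distributional regression tree on the retained covariates
    tree_covs = {v: TREE_KINDS[v] for v in (retained or CANDIDATES)}
    cfg = disttree.TreeConfig(family=family, covariates=tree_covs, seed=seed)
    tree = disttree.grow(data, response, cfg)
    out["tree"] = tree.to_dict()
    out["tree_dot"] = disttree.to_dot(tree, title=response)
    return out


def run_pipeline(trials: pd.DataFrame = None, sim_config: SimConfig = None,
                 seed: int = 0, out_dir=None) -> PipelineReport:
    """Run the full pipeline on a trial table (or a fresh simulation).

    Exactly one of ``trials`` / ``sim_config`` may be given; with neither,
    the default simulated experiment is used.  When ``out_dir`` is set the
    intermediate artifacts and the report are written there.
    """
    if trials is None:
        sim_config = sim_config or SimConfig()
        trials = simulate_experiment(sim_config, seed=seed).trials
    trials = preprocessing.validate_trials(trials)

    report = PipelineReport(seed=seed, config_hash=_config_hash(trials, seed))
    report.n_participants = int(trials["participant_id"].nunique())
    report.n_trials = int(len(trials))

    rt_table, cond_table = preprocessing.preprocess(trials)
    # the RT screening/factorial stages work on the per-condition medians
    # (independent observational units); the tree sees every retained RT
    cond_rt = cond_table.rename(columns={"median_rt": "rt"}).dropna(subset=["rt"])

    try:
        rt_branch = _branch(cond_rt.assign(rt=cond_rt["rt"]), "rt",
                            EXGAUSSIAN, seed)
        # regrow the tree on the trial-level retained reaction times
        retained = rt_branch["reduced"]["retained"] or CANDIDATES
        tree_covs = {v: TREE_KINDS[v] for v in retained}
        cfg = disttree.TreeConfig(family=EXGAUSSIAN, covariates=tree_covs,
                                  seed=seed)
        rt_long = rt_table.rename(columns={"rt_s": "rt"})
        tree = disttree.grow(rt_long, "rt", cfg)
        rt_branch["tree"] = tree.to_dict()
        rt_branch["tree_dot"] = disttree.to_dot(tree, title="reaction time (s)")
        report.rt = rt_branch
    except Exception as exc:   # pragma: no cover - defensive
        report.partial = True
        report.failures["rt"] = repr(exc)

    try:
        report.accuracy = _branch(cond_table, "accuracy", GB1, seed,
                                  squeeze=True)
    except Exception as exc:   # pragma: no cover - defensive
        report.partial = True
        report.failures["accuracy"] = repr(exc)

    try:
        per_part = cond_rt.groupby("participant_id").agg(
            acuity=("acuity_logmar", "first"), rt=("rt", "median"))
        report.correlations = {
            "kendall_tau": stats.kendall_tau(per_part["acuity"], per_part["rt"]),
            "percentage_bend": stats.percentage_bend_cor(per_part["acuity"],
                                                         per_part["rt"]),
            "n": int(len(per_part)),
        }
    except Exception as exc:   # pragma: no cover - defensive
        report.partial = True
        report.failures["correlations"] = repr(exc)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rt_table.to_csv(out / "rt_table.csv", index=False)
        cond_table.to_csv(out / "condition_table.csv", index=False)
        (out / "report.json").write_text(report.to_json(indent=2))
        for branch, name in ((report.rt, "tree_rt.dot"),
                             (report.accuracy, "tree_accuracy.dot")):
            if branch and "tree_dot" in branch:
                (out / name).write_text(branch["tree_dot"])
    return report
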