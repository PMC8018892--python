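"""End-to-end analysis pipeline: simulate -> axiom tests -> IP fits ->
model fits -> comparison -> regression, driven by a single config mapping.

Config schema (YAML)::

    seed: 1
    simulate:                # or: trials: path/to/table.tsv
      agent:
        kind: value          # value | lexicographic | indifferent
        model: {kind: EU_power, params: {a: 0.8, tau: 0.05}}
        side_bias: 0.0
        within_session_decline: 0.0
      design:
        a: 0.5               # continuity test: deg(a)/deg(b)/deg(c)
        b: 0.25
        c: 0.0
        levels: 11           # count (even grid on [0,1]) or explicit list
        repeats: 30
        sessions: 2
    analyses:
      continuity: true
      models: [EV, EU_power]
      regression: true
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import axiom_tests, behavior_regression, economic_models, io
from .economic_models import ModelSpec
from .gambles import Gamble
from .preference_fitting import counts_by_level, fit_softmax_ip
from .synthetic_agent import AgentSpec, continuity_design, simulate_experiment

log = logging.getLogger("riskchoice")

__all__ = ["run_pipeline", "agent_from_config", "design_from_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def agent_from_config(cfg: dict, seed: int) -> AgentSpec:
    model_cfg = cfg.get("model", {"kind": "EV", "params": {"tau": 0.05}})
    model = ModelSpec(model_cfg["kind"],
                      {k: float(v) for k, v in model_cfg["params"].items()},
                      float(model_cfg.get("m0", 0.5)))
    return AgentSpec(model=model, kind=cfg.get("kind", "value"),
                     side_bias=float(cfg.get("side_bias", 0.0)),
                     drift_param=cfg.get("drift_param"),
                     drift_sd=float(cfg.get("drift_sd", 0.0)),
                     within_session_decline=float(
                         cfg.get("within_session_decline", 0.0)),
                     lapse=float(cfg.get("lapse", 0.02)),
                     seed=seed)


def design_from_config(cfg: dict) -> list:
    levels = cfg.get("levels", 11)
    if isinstance(levels, int):
        levels = np.round(np.linspace(0.0, 1.0, levels), 6)
    session = continuity_design(Gamble.degenerate(float(cfg.get("a", 0.5))),
                                Gamble.degenerate(float(cfg.get("b", 0.25))),
                                Gamble.degenerate(float(cfg.get("c", 0.0))),
                                levels, int(cfg.get("repeats", 30)))
    return [session for _ in range(int(cfg.get("sessions", 1)))]


def run_pipeline(config: dict, out_dir: str | Path,
                 seed: int | None = None) -> dict:
    """Execute the configured stages; write tables, summary and log.

    Deterministic given the seed (config ``seed`` unless overridden).
    Returns the in-memory results bundle that was written.
    """
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    analyses = config.get("analyses", {})
    if "models" in analyses and not analyses["models"]:
        raise PipelineError("config stage 'models': empty model list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {"meta": {"seed": seed, "version": __version__,
                              "schema": io.SCHEMA_VERSION}}

    # --- trials ---------------------------------------------------------
    stage = "simulate/load"
    try:
        if "simulate" in config:
            agent = agent_from_config(config["simulate"].get("agent", {}), seed)
            design = design_from_config(config["simulate"].get("design", {}))
            trials = simulate_experiment(agent, design)
        elif "trials" in config:
            trials = io.read_trials(config["trials"])
        else:
            raise ValueError("config needs a 'simulate' block or a 'trials' path")
        io.write_trials(trials, out_dir / "trials.tsv")
        log.info("%s: %d trials over %d sessions", stage, len(trials),
                 trials["session"].nunique())
    except Exception as err:
        raise PipelineError(f"stage {stage!r} failed: {err}") from err

    # --- continuity test + IP -------------------------------------------
    if analyses.get("continuity", True) and trials["pa"].notna().any():
        stage = "continuity"
        try:
            levels, k, n = counts_by_level(trials)
            res = axiom_tests.test_continuity(levels, k, n, n_boot=200,
                                              seed=seed)
            rows = [{"pa": lv, "k": r.k, "n": r.n, "proportion": r.proportion,
                     "ci_low": r.ci_low, "ci_high": r.ci_high,
                     "p_value": r.p_value, "p_adjusted": pa,
                     "direction": r.direction}
                    for lv, r, pa in zip(levels, res.results, res.p_adjusted)]
            results["continuity"] = pd.DataFrame(rows)
            results["continuity_summary"] = {
                "compliant": res.compliant,
                "has_preferred_level": res.has_preferred_level,
                "has_dispreferred_level": res.has_dispreferred_level,
                "rank_corr_rho": res.rank_corr_rho,
                "rank_corr_p": res.rank_corr_p,
                "alpha": res.ip.alpha, "tau": res.ip.tau,
                "alpha_ci": [res.ip.ci_low, res.ip.ci_high]}
        except Exception as err:
            raise PipelineError(f"stage {stage!r} failed: {err}") from err

    # --- model fits + comparison ----------------------------------------
    kinds = analyses.get("models", [])
    if kinds:
        stage = "models"
        try:
            fits = [economic_models.fit_model_mle(trials, kind, seed=seed)
                    for kind in kinds]
            results["model_fits"] = pd.DataFrame(
                [{"kind": f.spec.kind, **f.spec.params,
                  "log_likelihood": f.log_likelihood, "bic": f.bic,
                  "aic": f.aic, "n_trials": f.n_trials} for f in fits])
            if len(fits) >= 2:
                props = _measured_proportions(trials)
                comp = economic_models.compare_models(
                    fits, measured_proportions=props)
                results["comparison"] = comp.reset_index()
                results["model_ranking_bic"] = list(
                    comp["bic"].sort_values().index)
        except Exception as err:
            raise PipelineError(f"stage {stage!r} failed: {err}") from err

    # --- regression ------------------------------------------------------
    if analyses.get("regression", False):
        stage = "regression"
        try:
            per_session = [
                behavior_regression.fit_choice_logistic(sub, session=s)
                for s, sub in trials.groupby("session")]
            rows = []
            for r in per_session:
                row = {"session": r.session, "n_trials": r.n_trials,
                       "separation": r.separation}
                row.update({f"beta_{nm}": v for nm, v in r.params.items()})
                row.update({f"std_{nm}": v for nm, v in r.std_params.items()})
                rows.append(row)
            results["regression_sessions"] = pd.DataFrame(rows)
            if len(per_session) >= 3:
                results["regression_population"] = \
                    behavior_regression.population_beta_tests(per_session) \
                    .reset_index()
        except Exception as err:
            raise PipelineError(f"stage {stage!r} failed: {err}") from err

    io.write_report(results, out_dir)
    return results


def _measured_proportions(trials: pd.DataFrame) -> pd.DataFrame | None:
    tagged = trials.dropna(subset=["pa"])
    if not len(tagged):
        return None
    rows = []
    for (pa, cond), sub in tagged.groupby(["pa", "cond"]):
        chose_ac = (sub["chosen_side"] == sub["test_side"]).sum()
        first = sub.iloc[0]
        option_a = first.gamble_left if first.test_side == "L" else first.gamble_right
        option_b = first.gamble_right if first.test_side == "L" else first.gamble_left
        rows.append({"option_a": option_a, "option_b": option_b,
                     "k": int(chose_ac), "n": len(sub)})
    return pd.DataFrame(rows)
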