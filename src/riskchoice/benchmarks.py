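"""Replicate-level validation studies on synthetic agents.

Each function runs a complete analysis pipeline on freshly simulated data
under the study's design conditions (11-point mixture grids, 0.5/0.25/0 ml
reference triplets, ~30 choices per condition) and summarizes operating
characteristics: sensitivity and specificity of the continuity test,
parameter and model recovery of the MLE machinery, transitivity
compliance, drift recovery, and cross-IP correlation structure.  They are
used by the acceptance script and the acceptance test suite; all
randomness is controlled through the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ttest_1samp

from .axiom_tests import continuity_from_trials, test_transitivity
from .economic_models import (MODEL_KINDS, ModelSpec, compare_models,
                              fit_model_mle, ip_cross_correlation,
                              predict_indifference_point)
from .gambles import Gamble
from .preference_fitting import counts_by_level, fit_softmax_ip, \
    within_session_ip_change
from .synthetic_agent import (AgentSpec, continuity_design,
                              mixed_value_design,
                              sample_fixed_probability_counts,
                              simulate_experiment)

_MOD = 2**31 - 1


def _subseed(seed: int, stream: int, r: int = 0) -> int:
    """Derived seed for one replicate, kept below 2**31."""
    return (seed * 1_000_003 + stream * 9_973 + r) % _MOD


LEVELS11 = np.round(np.linspace(0.0, 1.0, 11), 6)
#: the basic continuity triplet: A = 0.5 ml, B = 0.25 ml, C = 0 ml
TRIPLET = (0.5, 0.25, 0.0)


def _triplet_design(repeats: int, sessions: int = 1) -> list:
    a, b, c = (Gamble.degenerate(m) for m in TRIPLET)
    sess = continuity_design(a, b, c, LEVELS11, repeats)
    return [sess for _ in range(sessions)]


def eu_power_alpha_true(a: float, m_a: float = 0.5, m_b: float = 0.25) -> float:
    """Closed-form indifference mixture for power utility with C = 0."""
    return (m_b / m_a) ** a


def continuity_sensitivity(n_reps: int = 100, repeats: int = 30,
                           a: float = 0.8, tau: float = 0.05,
                           tol: float = 0.05, seed: int = 0) -> dict:
    """Power of the continuity test on a risk-averse EU agent.

    Fraction of replicates that are both declared compliant and recover
    the closed-form indifference point within ``tol``.
    """
    model = ModelSpec("EU_power", {"a": a, "tau": tau})
    alpha_true = eu_power_alpha_true(a)
    hits = 0
    errs = []
    for r in range(n_reps):
        agent = AgentSpec(model=model, seed=_subseed(seed, 1, r))
        trials = simulate_experiment(agent, _triplet_design(repeats))
        res = continuity_from_trials(trials, n_boot=0)
        err = abs(res.ip.alpha - alpha_true)
        errs.append(err)
        hits += int(res.compliant and err <= tol)
    return {"rate": hits / n_reps, "mean_abs_err": float(np.mean(errs)),
            "alpha_true": alpha_true, "n_reps": n_reps}


def continuity_specificity(n_reps_lex: int = 100, n_reps_null: int = 1000,
                           repeats: int = 30, seed: int = 0) -> dict:
    """False-verdict rates of the continuity test.

    A magnitude-first lexicographic agent (which violates the axiom) must
    be declared non-compliant; an indifferent coin-flip agent must almost
    never be declared compliant.
    """
    model = ModelSpec("EV", {"tau": 0.05})
    noncompliant = 0
    for r in range(n_reps_lex):
        agent = AgentSpec(model=model, kind="lexicographic", lapse=0.02,
                          seed=_subseed(seed, 2, r))
        trials = simulate_experiment(agent, _triplet_design(repeats))
        res = continuity_from_trials(trials, fit_ip=False)
        noncompliant += int(not res.compliant)
    false_pos = 0
    for r in range(n_reps_null):
        agent = AgentSpec(model=model, kind="indifferent",
                          seed=_subseed(seed, 3, r))
        trials = simulate_experiment(agent, _triplet_design(repeats))
        res = continuity_from_trials(trials, fit_ip=False)
        false_pos += int(res.compliant)
    return {"lexicographic_noncompliant_rate": noncompliant / n_reps_lex,
            "indifferent_compliant_rate": false_pos / n_reps_null}


def indifference_map_closed_form_deviation(
        a_values=(0.5, 1.0, 2.0),
        b_magnitudes=np.round(np.arange(0.15, 0.501, 0.05), 3),
        probe_step: float = 0.001) -> dict:
    """Worst-case gap between the numerical IP search and the closed form.

    For power utility the indifference curve against a sure reward m_B is
    p(m) = (m_B / m)^a; the 0.001-step grid search must agree within one
    probability step at every probe magnitude.
    """
    worst = 0.0
    n_checked = 0
    for a in a_values:
        spec = ModelSpec("EU_power", {"a": a, "tau": 0.05})
        for mb in b_magnitudes:
            b = Gamble.degenerate(float(mb))
            probes = np.arange(mb + probe_step, 0.5 + probe_step / 2,
                               probe_step)
            for m in probes:
                pred = predict_indifference_point(b, float(m), spec)
                worst = max(worst, abs(pred - (mb / m) ** a))
                n_checked += 1
    return {"max_abs_deviation": worst, "n_checked": n_checked}


def mle_recovery(n_reps: int = 20, repeats: int = 114, a: float = 0.6,
                 tau: float = 0.1, seed: int = 0,
                 kinds=tuple(MODEL_KINDS)) -> dict:
    """Parameter and model recovery for the MLE machinery.

    Each replicate simulates ~5,000 trials from a power-utility agent over
    a mixed multi-test design, fits all candidate families and asks (i)
    whether the recovered exponent lands within +/-0.1 of truth and (ii)
    whether BIC ranks the generating family first.  A final run fits the
    power family to risk-neutral (EV) data and checks that the Wald 95%
    CI on the exponent covers 1.
    """
    design = [mixed_value_design(repeats=repeats)]
    gen = ModelSpec("EU_power", {"a": a, "tau": tau})
    a_ok = bic_ok = 0
    a_hats = []
    for r in range(n_reps):
        agent = AgentSpec(model=gen, seed=_subseed(seed, 4, r))
        trials = simulate_experiment(agent, design)
        fits = [fit_model_mle(trials, k, seed=seed + r) for k in kinds]
        comp = compare_models(fits)
        by = comp["bic"].idxmin()
        fit_pow = next(f for f in fits if f.spec.kind == "EU_power")
        a_hat = fit_pow.spec.params["a"]
        a_hats.append(a_hat)
        a_ok += int(abs(a_hat - a) <= 0.1)
        bic_ok += int(by == "EU_power")
    ev_agent = AgentSpec(model=ModelSpec("EV", {"tau": tau}),
                         seed=_subseed(seed, 5))
    ev_trials = simulate_experiment(ev_agent, design)
    ev_fit = fit_model_mle(ev_trials, "EU_power", seed=seed, include_ci=True)
    lo, hi = ev_fit.param_ci["a"]
    return {"a_recovery_rate": a_ok / n_reps,
            "bic_recovery_rate": bic_ok / n_reps,
            "a_hat_mean": float(np.mean(a_hats)),
            "ev_ci_contains_one": bool(lo <= 1.0 <= hi),
            "ev_a_ci": (lo, hi), "n_reps": n_reps}


def transitivity_compliance(n_reps: int = 100, n_per_pair: int = 100,
                            seed: int = 0) -> dict:
    """WST/SST operating characteristics.

    A value-ordered agent (sure rewards 0.4 > 0.3 > 0.2 ml, softmax noise)
    should satisfy both forms; a constructed stochastic cycle with
    pairwise 0.7 preferences around the cycle must violate WST.
    """
    from .synthetic_agent import transitivity_design
    model = ModelSpec("EV", {"tau": 0.1})
    design = [transitivity_design(0.4, 0.3, 0.2, n_per_pair)]
    both = 0
    for r in range(n_reps):
        agent = AgentSpec(model=model, seed=_subseed(seed, 6, r))
        trials = simulate_experiment(agent, design)
        counts = {}
        for c_idx, name in enumerate(("AB", "BC", "AC")):
            sub = trials[trials["cond"] == c_idx]
            counts[name] = (int((sub["chosen_side"] == sub["test_side"]).sum()),
                            len(sub))
        res = test_transitivity(counts)
        both += int(res.wst and res.sst)
    cycle_violations = 0
    n_cycle = 2 * n_reps
    for r in range(n_cycle):
        counts = sample_fixed_probability_counts(
            {"AB": 0.7, "BC": 0.7, "AC": 0.3}, n_per_pair,
            seed=_subseed(seed, 7, r))
        cycle_violations += int(not test_transitivity(counts).wst)
    return {"wst_sst_rate": both / n_reps,
            "cycle_wst_violation_rate": cycle_violations / n_cycle}


def within_session_drift_recovery(n_sessions: int = 50, repeats: int = 20,
                                  decline: float = -0.10,
                                  seed: int = 0) -> dict:
    """Recovery of a within-session IP decline from half-session fits.

    A drifting agent should show a significant mean IP change near the
    configured decline; the matched drift-free agent should not reach
    significance.
    """
    model = ModelSpec("EU_power", {"a": 0.8, "tau": 0.05})
    out = {}
    for label, d in (("drift", decline), ("null", 0.0)):
        agent = AgentSpec(model=model, within_session_decline=d,
                          seed=_subseed(seed, 8, 0 if label == "drift" else 1))
        trials = simulate_experiment(agent,
                                     _triplet_design(repeats, n_sessions))
        res = within_session_ip_change(trials)
        out[label] = {"mean_delta": res["mean_delta"], "p": res["p"],
                      "n_sessions": res["n_sessions"]}
    return out


def cross_ip_correlation_structure(n_sessions: int = 60, repeats: int = 15,
                                   drift_sd: float = 0.05,
                                   seed: int = 0) -> dict:
    """Correlation between session-wise IPs under shared parameter drift.

    Six continuity tests per session (B in {0.20, 0.30} ml against A in
    {0.35, 0.45, 0.50} ml, C = 0) share one randomly walking utility
    exponent, so all IPs should co-vary; with the walk switched off,
    session-level variation is independent binomial noise and the
    correlations vanish.  IPs sharing a B gamble belong to the same
    indifference curve ("within-IC" pairs).
    """
    c = Gamble.degenerate(0.0)
    tests = [(mb, ma) for mb in (0.20, 0.30) for ma in (0.35, 0.45, 0.50)]
    sess_conds = []
    for mb, ma in tests:
        sess_conds += continuity_design(Gamble.degenerate(ma),
                                        Gamble.degenerate(mb), c,
                                        LEVELS11, repeats)
    design = [sess_conds for _ in range(n_sessions)]
    ic_groups = {f"B{mb}_A{ma}": mb for mb, ma in tests}
    out = {}
    for label, sd in (("shared_drift", drift_sd), ("independent", 0.0)):
        agent = AgentSpec(model=ModelSpec("EU_power", {"a": 0.8, "tau": 0.05}),
                          drift_param="a", drift_sd=sd,
                          seed=_subseed(seed, 9, 0 if sd else 1))
        trials = simulate_experiment(agent, design)
        rows = {}
        n_levels = len(LEVELS11)
        for t_idx, (mb, ma) in enumerate(tests):
            col = f"B{mb}_A{ma}"
            vals = []
            for s, sub in trials.groupby("session"):
                block = sub[sub["cond"] // n_levels == t_idx]
                ip = fit_softmax_ip(*counts_by_level(block), n_boot=0)
                vals.append(ip.alpha)
            rows[col] = vals
        table = pd.DataFrame(rows)
        out[label] = ip_cross_correlation(table, ic_groups=ic_groups)
    return out
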