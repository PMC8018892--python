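"""Simulated choice agents and trial-table generation.

No behavioral data ship with the package; every analysis stage is instead
exercised on trial tables generated here.  An agent is a value model (or a
heuristic rule) plus choice noise: value-based agents choose through the
logistic rule of :mod:`riskchoice.economic_models`, lexicographic agents
apply a magnitude-first rule softened by a lapse rate, and "indifferent"
agents flip a fair coin.  Two slow processes emulate the nonstationarity
seen in long experiments: an across-session random walk on one named model
parameter, and a within-session linear drift of the indifference point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .economic_models import ModelSpec, gamble_value
from .gambles import Gamble, MERGE_TOL, mix

__all__ = [
    "AgentSpec",
    "Condition",
    "choice_probability_of_agent",
    "make_drift_schedule",
    "simulate_experiment",
    "continuity_design",
    "transitivity_design",
    "mixed_value_design",
    "sample_fixed_probability_counts",
]


@dataclass(frozen=True)
class Condition:
    """One repeated choice pair within a session.

    ``option_a`` is the test option (for continuity tests, the AC
    mixture), ``option_b`` the reference.  When ``option_a`` is a mixture,
    ``components = (A, C, pA)`` records its construction so that
    within-session drift can shift the *perceived* mixture probability.
    """

    option_a: Gamble
    option_b: Gamble
    repeats: int
    components: tuple[Gamble, Gamble, float] | None = None

    @property
    def pa(self) -> float | None:
        return None if self.components is None else self.components[2]


@dataclass(frozen=True)
class AgentSpec:
    """A parameterized choice agent.

    ``kind`` is one of ``"value"`` (model-based, softmax noise),
    ``"lexicographic"`` (magnitude-first rule with lapse) or
    ``"indifferent"`` (P = 0.5 everywhere).  ``side_bias`` is a logit
    offset favoring right-side choices.  ``drift_param``/``drift_sd``
    define an across-session random walk on one model parameter;
    ``within_session_decline`` is the indifference-point shift (probability
    units, typically negative) between the halves of one session.
    """

    model: ModelSpec
    kind: str = "value"
    side_bias: float = 0.0
    drift_param: str | None = None
    drift_sd: float = 0.0
    within_session_decline: float = 0.0
    lapse: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("value", "lexicographic", "indifferent"):
            raise ValueError(f"unknown agent kind {self.kind!r}")
        if self.drift_sd < 0:
            raise ValueError("drift_sd must be >= 0")
        if not 0.0 <= self.lapse < 1.0:
            raise ValueError("lapse must be in [0, 1)")


def _lexicographic_rule(gA: Gamble, gB: Gamble) -> float:
    """Magnitude-first rule: 1 if A wins, 0 if B wins, 0.5 on full tie."""
    ma, mb = gA.magnitudes.max(), gB.magnitudes.max()
    if abs(ma - mb) > MERGE_TOL:
        return 1.0 if ma > mb else 0.0
    pa = gA.probabilities[np.argmax(gA.magnitudes)]
    pb = gB.probabilities[np.argmax(gB.magnitudes)]
    if abs(pa - pb) > MERGE_TOL:
        return 1.0 if pa > pb else 0.0
    return 0.5


def choice_probability_of_agent(agent: AgentSpec, gA: Gamble, gB: Gamble,
                                state: dict | None = None) -> float:
    """P(choose A) under the agent's current state.

    ``state`` may carry ``params`` (drifted model-parameter overrides) and
    ``a_side`` ("L"/"R", for the side-bias offset; bias is a logit shift
    toward the right side).
    """
    state = state or {}
    bias = 0.0
    if agent.side_bias:
        side = state.get("a_side")
        if side == "R":
            bias = agent.side_bias
        elif side == "L":
            bias = -agent.side_bias
    if agent.kind == "indifferent":
        return float(expit(bias))
    if agent.kind == "lexicographic":
        rule = _lexicographic_rule(gA, gB)
        p = agent.lapse / 2 + (1 - agent.lapse) * rule
        # a logit side bias is ill-defined at p in {0,1}; mix on the
        # probability scale instead
        return float(np.clip(p + (expit(bias) - 0.5) * 2 * min(p, 1 - p), 0, 1))
    spec = agent.model
    if state.get("params"):
        spec = spec.replace(**state["params"])
    dv = gamble_value(gA, spec) - gamble_value(gB, spec)
    return float(expit(dv / spec.tau + bias))


def make_drift_schedule(agent: AgentSpec, n_sessions: int,
                        trials_per_session: int) -> dict:
    """Per-session parameter states and per-trial indifference-point shifts.

    The named parameter follows a Gaussian random walk across sessions
    (starting at its nominal value).  Within a session the measured
    indifference point of trial t is shifted by
    ``delta(t) = decline * (2 * frac(t) - 1)`` with ``frac`` the position
    of the trial in the session (the agent perceives the mixture
    probability as ``pA - delta``); the half-session means of delta then
    differ by exactly ``decline``, which the second-half minus first-half
    IP analysis recovers.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([agent.seed, 0xD81F]))
    params: list[dict[str, float]] = []
    if agent.drift_param is not None and agent.drift_sd > 0:
        base = agent.model.params[agent.drift_param]
        steps = rng.normal(0.0, agent.drift_sd, n_sessions)
        steps[0] = 0.0
        walk = np.clip(base + np.cumsum(steps), 1e-3, None)
        params = [{agent.drift_param: float(v)} for v in walk]
    else:
        params = [{} for _ in range(n_sessions)]
    if trials_per_session > 1:
        frac = np.arange(trials_per_session) / (trials_per_session - 1)
    else:
        frac = np.array([0.5])
    ip_shift = agent.within_session_decline * (2 * frac - 1)
    return {"params": params,
            "ip_shift": np.tile(ip_shift, (n_sessions, 1))}


def _sample_reward(g: Gamble, u: float) -> float:
    c = 0.0
    for m, p in g.outcomes:
        c += p
        if u <= c:
            return m
    return g.outcomes[-1][0]


def simulate_experiment(agent: AgentSpec,
                        design: Sequence[Sequence[Condition]]) -> pd.DataFrame:
    """Simulate a multi-session experiment into a long trial table.

    ``design`` is a list of sessions, each a list of :class:`Condition`.
    Within a session, each condition's repeats are split evenly between
    left/right placements of the test option (exact for even repeats),
    trial order is shuffled, choices are drawn independently given the
    drifted agent state, and rewards are realized by sampling the chosen
    gamble.  Reproducible via per-session substreams of ``agent.seed``.

    Returns a DataFrame with columns ``session, trial, gamble_left,
    gamble_right, chosen_side, reward_delivered, pa, test_side, cond,
    prev_choice, prev_reward``.
    """
    if not design or not any(len(s) for s in design):
        raise ValueError("empty design")
    n_sessions = len(design)
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(agent.seed).spawn(n_sessions)]
    max_trials = max(sum(c.repeats for c in sess) for sess in design)
    schedule = make_drift_schedule(agent, n_sessions, max_trials)
    rows = []
    for s_idx, sess in enumerate(design):
        rng = streams[s_idx]
        slots: list[tuple[int, str]] = []
        for c_idx, cond in enumerate(sess):
            if cond.repeats < 1:
                raise ValueError("repeats must be >= 1")
            n_left = cond.repeats // 2
            sides = ["L"] * n_left + ["R"] * (cond.repeats - n_left)
            if cond.repeats % 2:
                rng.shuffle(sides)
            slots += [(c_idx, side) for side in sides]
        rng.shuffle(slots)
        sess_params = schedule["params"][s_idx]
        shifts = schedule["ip_shift"][s_idx]
        prob_cache: dict[tuple, float] = {}
        prev_choice, prev_reward = 0, 0.0
        for t_idx, (c_idx, a_side) in enumerate(slots):
            cond = sess[c_idx]
            delta = float(shifts[t_idx]) if len(slots) > 1 else 0.0
            option_a = cond.option_a
            if cond.components is not None and delta != 0.0:
                ga, gc, pa = cond.components
                option_a = mix(ga, gc, float(np.clip(pa - delta, 0.0, 1.0)))
            key = (c_idx, a_side, round(delta, 9))
            p_a = prob_cache.get(key)
            if p_a is None:
                p_a = choice_probability_of_agent(
                    agent, option_a, cond.option_b,
                    {"params": sess_params, "a_side": a_side})
                prob_cache[key] = p_a
            chose_a = rng.random() < p_a
            chosen_side = a_side if chose_a else ("R" if a_side == "L" else "L")
            chosen = cond.option_a if chose_a else cond.option_b
            reward = _sample_reward(chosen, rng.random())
            g_left = cond.option_a if a_side == "L" else cond.option_b
            g_right = cond.option_b if a_side == "L" else cond.option_a
            rows.append((s_idx, t_idx, g_left, g_right, chosen_side, reward,
                         np.nan if cond.pa is None else cond.pa, a_side, c_idx,
                         prev_choice, prev_reward))
            prev_choice = -1 if chosen_side == "L" else 1
            prev_reward = reward
    return pd.DataFrame(rows, columns=[
        "session", "trial", "gamble_left", "gamble_right", "chosen_side",
        "reward_delivered", "pa", "test_side", "cond",
        "prev_choice", "prev_reward"])


# ---------------------------------------------------------------------------
# design builders


def continuity_design(a: Gamble, b: Gamble, c: Gamble,
                      levels: Sequence[float], repeats: int) -> list[Condition]:
    """One continuity test: B versus the AC mixture at each pA level."""
    return [Condition(option_a=mix(a, c, float(pa)), option_b=b,
                      repeats=repeats, components=(a, c, float(pa)))
            for pa in levels]


def transitivity_design(a: float, b: float, c: float,
                        repeats: int) -> list[Condition]:
    """A-vs-B, B-vs-C, A-vs-C choices between sure rewards."""
    A, B, C = (Gamble.degenerate(x) for x in (a, b, c))
    return [Condition(A, B, repeats), Condition(B, C, repeats),
            Condition(A, C, repeats)]


def mixed_value_design(repeats: int = 10,
                       b_magnitudes: Sequence[float] = (0.15, 0.25, 0.35, 0.45),
                       a_magnitude: float = 0.5,
                       levels: Sequence[float] | None = None) -> list[Condition]:
    """A session mixing several continuity tests over a B-magnitude grid.

    Every option has at most one non-zero outcome (degenerate B against a
    two-outcome A/0 mixture), so the resulting trials are scoreable under
    all six value-model families.
    """
    if levels is None:
        levels = np.round(np.arange(0.0, 1.0001, 0.1), 3)
    conds: list[Condition] = []
    c = Gamble.degenerate(0.0)
    a = Gamble.degenerate(a_magnitude)
    for mb in b_magnitudes:
        conds += continuity_design(a, Gamble.degenerate(mb), c, levels, repeats)
    return conds


def sample_fixed_probability_counts(probs: dict[str, float], n: int,
                                    seed: int = 0) -> dict[str, tuple[int, int]]:
    """Binomial choice counts for pairings with fixed choice probabilities.

    Used to construct agents defined directly by their pairwise preference
    probabilities (e.g., a stochastic cycle), which no value model can
    produce.  Returns ``{pairing: (k, n)}``.
    """
    rng = np.random.default_rng(seed)
    return {name: (int(rng.binomial(n, p)), n) for name, p in probs.items()}
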