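"""Economic value models of risky choice and their maximum-likelihood fits.

Six model families assign a scalar subjective value V to a gamble and turn
value differences into choice probabilities through a logistic (softmax)
rule P(A|{A,B}) = 1 / (1 + exp(-(V_A - V_B)/tau)):

* ``EV`` — objective expected value (linear utility).
* ``EU_power`` — expected utility with power utility U(m|a) = (m/m0)^a.
* ``EU_sshape`` — expected utility with the two-parameter Prelec form
  U(m|a,b) = exp(-b * (-log(m/m0))^a), an S-shaped utility.
* ``PW`` — prospect-theory value U(m)*w(p) with a two-parameter Prelec
  probability-weighting function; defined for gambles with at most one
  non-zero outcome.
* ``additive`` — V = w_m*U(m) + w_p*p, same one-non-zero-outcome domain.
* ``mean_variance`` — V = EV + beta*Risk, no utility concept.

Utilities are normalized to [0, 1] on [0, m0] with m0 the maximum reward
magnitude of the study design (0.5 ml by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import ttest_1samp

from .gambles import Gamble, expected_value, risk_variance

__all__ = [
    "ModelSpec",
    "FitResult",
    "MODEL_KINDS",
    "utility",
    "prelec_weight",
    "gamble_value",
    "choice_probability",
    "negative_log_likelihood",
    "fit_model_mle",
    "predict_indifference_point",
    "build_indifference_map",
    "IndifferenceMap",
    "compare_models",
    "ip_cross_correlation",
]

#: free parameters per model family, in optimizer order; "tau" always last
MODEL_KINDS: dict[str, tuple[str, ...]] = {
    "EV": ("tau",),
    "EU_power": ("a", "tau"),
    "EU_sshape": ("a", "b", "tau"),
    "PW": ("a", "a_w", "b_w", "tau"),
    "additive": ("a", "w_m", "w_p", "tau"),
    "mean_variance": ("beta", "tau"),
}

_CLIP = 1e-12  # probability clipping in likelihoods


class UnsupportedModelError(ValueError):
    """Model kind cannot score the given gamble."""


@dataclass(frozen=True)
class ModelSpec:
    """A value-model family with concrete parameter values.

    ``params`` must contain every name listed in ``MODEL_KINDS[kind]``;
    ``tau`` is the softmax temperature (> 0), ``m0`` the normalizing
    magnitude (ml).
    """

    kind: str
    params: dict[str, float] = field(default_factory=dict)
    m0: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        missing = [k for k in MODEL_KINDS[self.kind] if k not in self.params]
        if missing:
            raise ValueError(f"{self.kind} missing parameters {missing}")
        if self.params["tau"] <= 0:
            raise ValueError("temperature tau must be positive")
        if self.m0 <= 0:
            raise ValueError("m0 must be positive")
        for name in ("a", "b", "a_w", "b_w", "w_m", "w_p"):
            if name in self.params and self.params[name] <= 0:
                raise ValueError(f"parameter {name} must be positive")

    @property
    def tau(self) -> float:
        return self.params["tau"]

    @property
    def n_params(self) -> int:
        return len(MODEL_KINDS[self.kind])

    def replace(self, **updates: float) -> "ModelSpec":
        return ModelSpec(self.kind, {**self.params, **updates}, self.m0)


# ---------------------------------------------------------------------------
# primitives


def utility(m, spec: ModelSpec):
    """Utility of a sure magnitude under the spec's utility function.

    Accepts scalars or arrays.  U(0) = 0 by continuity for every form;
    the S-shaped form saturates at 1 above m0 (with a warning) since its
    log domain ends there.
    """
    m = np.asarray(m, dtype=float)
    x = m / spec.m0
    kind = spec.kind
    if kind in ("EV", "mean_variance"):
        u = x
    elif kind in ("EU_power", "PW", "additive"):
        u = np.power(x, spec.params["a"])
    elif kind == "EU_sshape":
        if np.any(x > 1 + 1e-12):
            warnings.warn("S-shaped utility evaluated above m0; saturating at 1")
        xc = np.clip(x, 0.0, 1.0)
        with np.errstate(divide="ignore", over="ignore"):
            u = np.where(xc > 0,
                         np.exp(-spec.params["b"]
                                * np.power(-np.log(np.where(xc > 0, xc, 0.5)),
                                           spec.params["a"])),
                         0.0)
    else:  # pragma: no cover
        raise ValueError(kind)
    return u if u.ndim else float(u)


def prelec_weight(p, a_w: float, b_w: float):
    """Two-parameter Prelec probability weighting w(p) = exp(-b(-ln p)^a)."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        w = np.where(p > 0,
                     np.exp(-b_w * np.power(-np.log(np.where(p > 0, p, 0.5)), a_w)),
                     0.0)
    return w if w.ndim else float(w)


def _single_nonzero(g: Gamble) -> tuple[float, float]:
    nz = g.nonzero_outcomes()
    if len(nz) > 1:
        raise UnsupportedModelError(
            f"PW/additive values are defined only for gambles with at most "
            f"one non-zero outcome; got {g!r}")
    if not nz:
        return 0.0, 0.0
    return nz[0]


def gamble_value(g: Gamble, spec: ModelSpec) -> float:
    """Subjective value of a gamble under the model.

    EV / EU kinds: V = sum_i U(m_i) p_i.  PW: V = U(m) w(p) and additive:
    V = w_m U(m) + w_p p, both applied to the single non-zero outcome.
    Mean-variance: V = EV + beta * Risk on the raw ml scale.
    """
    kind = spec.kind
    if kind in ("EV", "EU_power", "EU_sshape"):
        return float(np.dot(utility(g.magnitudes, spec), g.probabilities))
    if kind == "mean_variance":
        return expected_value(g) + spec.params["beta"] * risk_variance(g)
    m, p = _single_nonzero(g)
    if kind == "PW":
        return float(utility(m, spec) * prelec_weight(p, spec.params["a_w"],
                                                      spec.params["b_w"]))
    if kind == "additive":
        return float(spec.params["w_m"] * utility(m, spec)
                     + spec.params["w_p"] * p)
    raise ValueError(kind)  # pragma: no cover


def choice_probability(gA: Gamble, gB: Gamble, spec: ModelSpec) -> float:
    """P(choose A) = logistic of the value difference scaled by tau."""
    dv = gamble_value(gA, spec) - gamble_value(gB, spec)
    return float(expit(dv / spec.tau))


# ---------------------------------------------------------------------------
# vectorized trial scoring


class TrialMatrix:
    """Padded-array view of a trial table for fast likelihood evaluation.

    Expects a DataFrame with Gamble-valued columns ``gamble_left`` /
    ``gamble_right`` and ``chosen_side`` in {"L", "R"}.
    """

    def __init__(self, trials: pd.DataFrame):
        if len(trials) == 0:
            raise ValueError("empty trial table")
        self.n = len(trials)
        self.y_left = (trials["chosen_side"].to_numpy() == "L").astype(float)
        self._sides = {}
        for side, col in (("L", "gamble_left"), ("R", "gamble_right")):
            self._sides[side] = self._pack(trials[col].tolist())

    @staticmethod
    def _pack(gambles: Sequence[Gamble]):
        kmax = max(g.n_outcomes for g in gambles)
        n = len(gambles)
        m = np.zeros((n, kmax))
        p = np.zeros((n, kmax))
        nz_m = np.zeros(n)
        nz_p = np.zeros(n)
        nz_ok = np.ones(n, dtype=bool)
        bad_row = -1
        for i, g in enumerate(gambles):
            for j, (mj, pj) in enumerate(g.outcomes):
                m[i, j] = mj
                p[i, j] = pj
            nz = g.nonzero_outcomes()
            if len(nz) > 1:
                nz_ok[i] = False
                if bad_row < 0:
                    bad_row = i
            elif nz:
                nz_m[i], nz_p[i] = nz[0]
        return {"m": m, "p": p, "nz_m": nz_m, "nz_p": nz_p,
                "nz_ok": nz_ok, "bad_row": bad_row}

    def _values(self, side: str, spec: ModelSpec) -> np.ndarray:
        s = self._sides[side]
        kind = spec.kind
        if kind in ("EV", "EU_power", "EU_sshape"):
            return np.einsum("ij,ij->i", utility(s["m"], spec), s["p"])
        if kind == "mean_variance":
            ev = np.einsum("ij,ij->i", s["m"], s["p"])
            risk = np.einsum("ij,ij->i", (s["m"] - ev[:, None]) ** 2, s["p"])
            return ev + spec.params["beta"] * risk
        if not s["nz_ok"].all():
            raise UnsupportedModelError(
                f"trial {s['bad_row']}: {kind} model cannot score a gamble "
                f"with more than one non-zero outcome")
        u = utility(s["nz_m"], spec)
        if kind == "PW":
            return u * prelec_weight(s["nz_p"], spec.params["a_w"],
                                     spec.params["b_w"])
        return spec.params["w_m"] * u + spec.params["w_p"] * s["nz_p"]

    def nll(self, spec: ModelSpec) -> float:
        dv = self._values("L", spec) - self._values("R", spec)
        p_left = np.clip(expit(dv / spec.tau), _CLIP, 1 - _CLIP)
        ll = self.y_left * np.log(p_left) + (1 - self.y_left) * np.log1p(-p_left)
        return float(-ll.sum())


def negative_log_likelihood(trials: pd.DataFrame, spec: ModelSpec) -> float:
    """-sum of per-trial Bernoulli log-likelihoods under the choice model."""
    return TrialMatrix(trials).nll(spec)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


@dataclass
class FitResult:
    """An MLE fit: the fitted spec plus likelihood-based scores."""

    spec: ModelSpec
    log_likelihood: float
    n_trials: int
    n_params: int
    bic: float
    aic: float
    converged: bool = True
    param_ci: dict[str, tuple[float, float]] | None = None


# log-scale parameterization keeps positivity constraints implicit;
# mean_variance beta is sign-free and stays on the natural scale
_LOG_SCALE = {"a", "b", "a_w", "b_w", "w_m", "w_p", "tau"}
_INIT = {"a": 1.0, "b": 1.0, "a_w": 1.0, "b_w": 1.0,
         "w_m": 1.0, "w_p": 1.0, "beta": 0.0, "tau": 0.1}


def _to_theta(names: Iterable[str], params: dict[str, float]) -> np.ndarray:
    return np.array([np.log(params[k]) if k in _LOG_SCALE else params[k]
                     for k in names])


def _from_theta(names: Sequence[str], theta: np.ndarray) -> dict[str, float]:
    return {k: float(np.exp(t)) if k in _LOG_SCALE else float(t)
            for k, t in zip(names, theta)}


def fit_model_mle(trials: pd.DataFrame, kind: str, *, m0: float = 0.5,
                  n_starts: int = 5, seed: int = 0,
                  include_ci: bool = False) -> FitResult:
    """Fit a value model to single-trial choices by maximum likelihood.

    Derivative-free Nelder-Mead minimization of the negative log-likelihood
    from ``n_starts`` seeded starts (base initialization plus log-scale
    jitter).  Positive parameters are optimized on the log scale.

    With ``include_ci`` a 95% Wald CI per parameter is computed from the
    numerical Hessian at the optimum (delta method on the log scale).
    """
    names = MODEL_KINDS[kind]
    tm = TrialMatrix(trials)
    if tm.n < 10 * len(names):
        warnings.warn(f"only {tm.n} trials for {len(names)}-parameter "
                      f"{kind} fit; estimates may be unstable")

    def objective(theta: np.ndarray) -> float:
        p = _from_theta(names, theta)
        if not (1e-5 <= p["tau"] <= 50):
            return 1e10
        try:
            return tm.nll(ModelSpec(kind, p, m0))
        except (ValueError, FloatingPointError):
            return 1e10

    rng = np.random.default_rng(seed)
    theta0 = _to_theta(names, _INIT)
    best = None
    any_ok = False
    for s in range(max(1, n_starts)):
        start = theta0 if s == 0 else theta0 + rng.normal(0, 0.7, len(names))
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"maxiter": 500 * len(names),
                                "xatol": 1e-6, "fatol": 1e-8})
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e9:
        raise RuntimeError(f"MLE failed for {kind}: no start converged "
                           f"to a finite likelihood")
    params = _from_theta(names, best.x)
    spec = ModelSpec(kind, params, m0)
    ll = -best.fun
    k = len(names)
    fit = FitResult(spec=spec, log_likelihood=ll, n_trials=tm.n, n_params=k,
                    bic=k * np.log(tm.n) - 2 * ll, aic=2 * k - 2 * ll,
                    converged=any_ok)
    if include_ci:
        fit.param_ci = _wald_ci(objective, best.x, names)
    return fit


def _wald_ci(objective, theta: np.ndarray, names: Sequence[str],
             h: float = 1e-4) -> dict[str, tuple[float, float]]:
    k = len(theta)
    H = np.zeros((k, k))
    f0 = objective(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            if i == j:
                H[i, i] = (objective(theta + ei) - 2 * f0
                           + objective(theta - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    objective(theta + ei + ej) - objective(theta + ei - ej)
                    - objective(theta - ei + ej) + objective(theta - ei - ej)
                ) / (4 * h**2)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    out = {}
    for i, name in enumerate(names):
        lo, hi = theta[i] - 1.96 * se[i], theta[i] + 1.96 * se[i]
        if name in _LOG_SCALE:
            lo, hi = np.exp(lo), np.exp(hi)
        out[name] = (float(lo), float(hi))
    return out


# ---------------------------------------------------------------------------
# indifference-map prediction


def _two_outcome_values(m: float, p_grid: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Values of the gambles {(m, p), (0, 1-p)} over a probability grid."""
    kind = spec.kind
    if kind in ("EV", "EU_power", "EU_sshape"):
        return float(utility(m, spec)) * p_grid
    if kind == "PW":
        return float(utility(m, spec)) * prelec_weight(
            p_grid, spec.params["a_w"], spec.params["b_w"])
    if kind == "additive":
        return spec.params["w_m"] * float(utility(m, spec)) \
            + spec.params["w_p"] * p_grid
    if kind == "mean_variance":
        ev = m * p_grid
        risk = p_grid * (1 - p_grid) * m**2
        return ev + spec.params["beta"] * risk
    raise ValueError(kind)  # pragma: no cover


def predict_indifference_point(b_gamble: Gamble, probe_magnitude: float,
                               spec: ModelSpec, p_step: float = 0.001) -> float | None:
    """Model-predicted indifference probability against a reference gamble.

    Grid search over p in {p_step, 2*p_step, ..., 1} for the probability at
    which the two-outcome gamble {(probe_magnitude, p), (0, 1-p)} is
    closest in value to the reference B gamble; ties break to the smaller
    p.  Returns None when no grid probability reaches V_B (probe too
    small).
    """
    v_b = gamble_value(b_gamble, spec)
    p_grid = np.arange(1, int(round(1 / p_step)) + 1) * p_step
    v = _two_outcome_values(float(probe_magnitude), p_grid, spec)
    if v_b > v.max() + 1e-12:
        return None
    return float(p_grid[int(np.argmin(np.abs(v - v_b)))])


@dataclass
class IndifferenceMap:
    """Model-predicted indifference curves, one per reference gamble.

    ``curves`` maps each B gamble to a ``(magnitudes, probabilities)``
    array pair tracing the predicted indifference curve.
    """

    spec: ModelSpec
    curves: dict[Gamble, tuple[np.ndarray, np.ndarray]]


def build_indifference_map(spec: ModelSpec, b_gambles: Sequence[Gamble],
                           magnitude_max: float = 0.5,
                           magnitude_step: float = 0.001,
                           p_step: float = 0.001) -> IndifferenceMap:
    """Numerically trace one predicted indifference curve per B gamble.

    Probe magnitudes run from just above each B gamble's expected
    magnitude up to ``magnitude_max`` in ``magnitude_step`` increments.
    """
    curves: dict[Gamble, tuple[np.ndarray, np.ndarray]] = {}
    for b in b_gambles:
        start = max(b.magnitudes.max(), magnitude_step)
        probes = np.arange(start, magnitude_max + magnitude_step / 2,
                           magnitude_step)
        ips = np.array([
            np.nan if (ip := predict_indifference_point(b, m, spec, p_step)) is None
            else ip
            for m in probes])
        keep = ~np.isnan(ips)
        curves[b] = (probes[keep], ips[keep])
    return IndifferenceMap(spec=spec, curves=curves)


# ---------------------------------------------------------------------------
# model comparison


def compare_models(fits: Sequence[FitResult],
                   measured_ips: Sequence | None = None,
                   measured_proportions: pd.DataFrame | None = None,
                   p_step: float = 0.001) -> pd.DataFrame:
    """Four-metric comparison table; lower is better on every metric.

    Metrics: ``rmse_ip`` — root-mean-square distance between modeled and
    measured indifference points (probability units); ``bic`` and ``aic``;
    ``var_pref`` — variance across test conditions of (modeled - measured)
    choice proportions.  ``measured_ips`` is a sequence of objects with
    ``b_gamble``, ``a_magnitude`` and ``alpha`` attributes;
    ``measured_proportions`` a DataFrame with columns ``option_a``,
    ``option_b`` (Gambles), ``k``, ``n``.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    n_set = {f.n_trials for f in fits}
    if len(n_set) != 1:
        raise ValueError(f"fits cover different trial sets (n = {sorted(n_set)})")
    rows = []
    for f in fits:
        rmse = np.nan
        if measured_ips:
            errs = []
            for ip in measured_ips:
                pred = predict_indifference_point(ip.b_gamble, ip.a_magnitude,
                                                  f.spec, p_step)
                if pred is not None and ip.alpha is not None:
                    errs.append(pred - ip.alpha)
            if errs:
                rmse = float(np.sqrt(np.mean(np.square(errs))))
        var_pref = np.nan
        if measured_proportions is not None and len(measured_proportions):
            diffs = [choice_probability(r.option_a, r.option_b, f.spec) - r.k / r.n
                     for r in measured_proportions.itertuples()]
            var_pref = float(np.var(diffs, ddof=0))
        rows.append({"kind": f.spec.kind, "n_params": f.n_params,
                     "log_likelihood": f.log_likelihood, "bic": f.bic,
                     "aic": f.aic, "rmse_ip": rmse, "var_pref": var_pref})
    return pd.DataFrame(rows).set_index("kind")


def ip_cross_correlation(ip_table: pd.DataFrame,
                         ic_groups: dict[str, object] | None = None,
                         min_overlap: int = 3) -> dict:
    """Pairwise Pearson correlation between session-wise IP series.

    ``ip_table`` is sessions x IP-columns (NaN for missing cells); pairs
    with fewer than ``min_overlap`` complete sessions are skipped.  When
    ``ic_groups`` maps column -> indifference-curve label, pairs are split
    into within-IC and across-IC groups, each summarized by the mean rho
    and a one-sample t test against zero.
    """
    cols = list(ip_table.columns)
    pairs = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a, b = ip_table[cols[i]], ip_table[cols[j]]
            ok = a.notna() & b.notna()
            if ok.sum() < min_overlap:
                continue
            rho = float(np.corrcoef(a[ok], b[ok])[0, 1])
            same = (ic_groups is not None
                    and ic_groups.get(cols[i]) == ic_groups.get(cols[j]))
            pairs.append({"ip1": cols[i], "ip2": cols[j], "rho": rho,
                          "n": int(ok.sum()), "within_ic": bool(same)})
    pair_df = pd.DataFrame(pairs, columns=["ip1", "ip2", "rho", "n",
                                           "within_ic"])
    out = {"pairs": pair_df}
    groups = {"all": pair_df}
    if ic_groups is not None and len(pair_df):
        groups["within_ic"] = pair_df[pair_df["within_ic"]]
        groups["across_ic"] = pair_df[~pair_df["within_ic"]]
    for label, sub in groups.items():
        rhos = sub["rho"].dropna().to_numpy() if len(sub) else np.array([])
        if len(rhos) >= 2 and np.std(rhos) > 0:
            t = ttest_1samp(rhos, 0.0)
            out[label] = {"mean_rho": float(np.mean(rhos)), "n_pairs": len(rhos),
                          "t": float(t.statistic), "p": float(t.pvalue)}
        elif len(rhos):
            out[label] = {"mean_rho": float(np.mean(rhos)), "n_pairs": len(rhos),
                          "t": np.nan, "p": np.nan}
    return out
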