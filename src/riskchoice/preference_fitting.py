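"""Indifference-point estimation and indifference-curve fitting.

The indifference point (IP, alpha) of a continuity test is the mixture
probability at which the fitted psychometric softmax

    P(choose AC | pA) = 1 / (1 + exp(-(pA - alpha) / tau))

crosses 0.5; tau is the softmax temperature (steepness).  Sets of IPs
measured against a fixed reference gamble trace an indifference curve (IC)
in magnitude-probability space, fitted here with linear, power or
hyperbolic forms by nonlinear least squares in the probability domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit
from scipy.stats import ttest_1samp

from .gambles import Gamble

__all__ = [
    "IndifferencePoint",
    "IndifferenceCurve",
    "CurveFitError",
    "counts_by_level",
    "fit_softmax_ip",
    "fit_indifference_curve",
    "loo_coverage",
    "within_session_ip_change",
    "ip_session_series",
]


class CurveFitError(RuntimeError):
    """Indifference-curve fit is non-identifiable or failed."""


@dataclass
class IndifferencePoint:
    """A softmax-estimated indifference point.

    ``alpha`` is the 0.5-crossing of the fitted choice function (the
    fitted curve equals 0.5 at ``alpha`` exactly, by construction);
    ``extrapolated`` flags fits where the data never cross 0.5, so alpha
    lies outside the sampled range (or outside [0, 1]).
    """

    alpha: float
    tau: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_trials: int = 0
    session: object = "pooled"
    b_gamble: Gamble | None = None
    a_magnitude: float | None = None
    extrapolated: bool = False


def counts_by_level(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate mixture-tagged trials into per-pA-level choice counts.

    Uses the ``pa`` and ``test_side`` columns written by the simulator /
    trial-table reader; returns ``(levels, k, n)`` with ``k`` counting
    choices of the mixture (AC) option.
    """
    tagged = trials.dropna(subset=["pa"])
    if not len(tagged):
        raise ValueError("no mixture-tagged trials (pa column is all NaN)")
    chose_ac = tagged["chosen_side"].to_numpy() == tagged["test_side"].to_numpy()
    grp = pd.DataFrame({"pa": tagged["pa"].to_numpy(), "y": chose_ac}) \
        .groupby("pa")["y"].agg(["sum", "count"])
    return (grp.index.to_numpy(float), grp["sum"].to_numpy(int),
            grp["count"].to_numpy(int))


def _softmax_fit(levels: np.ndarray, k: np.ndarray, n: np.ndarray,
                 alpha0: float, tau0: float) -> tuple[float, float]:
    props = k / n
    w = np.sqrt(n)

    def resid(theta):
        return w * (props - expit((levels - theta[0]) / np.exp(theta[1])))

    span = levels.max() - levels.min() or 1.0
    sol = least_squares(resid, x0=[alpha0, np.log(tau0)],
                        bounds=([levels.min() - 2 * span, np.log(1e-4)],
                                [levels.max() + 2 * span, np.log(10.0)]))
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def fit_softmax_ip(levels: Sequence[float], k: Sequence[int],
                   n: Sequence[int], *, n_boot: int = 200,
                   seed: int = 0, **meta) -> IndifferencePoint:
    """Estimate an indifference point from per-level choice counts.

    Nonlinear least squares of the softmax to per-level AC-choice
    proportions, weighted by per-level trial counts.  alpha starts at the
    interpolated empirical 0.5 crossing, tau at 0.1.  The 95% CI on alpha
    comes from a seeded bootstrap that resamples trials within each level
    (``n_boot`` resamples; 0 skips the CI).  If the proportions never
    cross 0.5 the fit is still returned but flagged ``extrapolated``.
    """
    levels = np.asarray(levels, float)
    k = np.asarray(k, float)  # float-valued counts allow exact proportions
    n = np.asarray(n, int)
    if len(levels) < 3:
        raise ValueError("need at least 3 pA levels")
    if np.any(n < 1):
        raise ValueError("every level needs at least one trial")
    if np.any((k < 0) | (k > n)):
        raise ValueError("counts must satisfy 0 <= k <= n")
    order = np.argsort(levels)
    levels, k, n = levels[order], k[order], n[order]
    props = k / n

    crossing = None
    for i in range(len(levels) - 1):
        lo, hi = props[i] - 0.5, props[i + 1] - 0.5
        if lo == 0:
            crossing = levels[i]
            break
        if lo * hi < 0:
            crossing = levels[i] + (0.5 - props[i]) / (props[i + 1] - props[i]) \
                * (levels[i + 1] - levels[i])
            break
    no_crossing = crossing is None and not np.any(props == 0.5)
    alpha0 = crossing if crossing is not None \
        else float(np.average(levels, weights=n))
    alpha, tau = _softmax_fit(levels, k, n, alpha0, 0.1)

    extrapolated = bool(no_crossing or not (0.0 <= alpha <= 1.0))
    if no_crossing:
        warnings.warn("choice proportions never cross 0.5; "
                      "indifference point extrapolated")

    ci_low = ci_high = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            kb = rng.binomial(n, props)
            boots[b] = _softmax_fit(levels, kb, n, alpha, tau)[0]
        ci_low, ci_high = (float(x) for x in np.percentile(boots, [2.5, 97.5]))

    return IndifferencePoint(alpha=alpha, tau=tau, ci_low=ci_low,
                             ci_high=ci_high, n_trials=int(n.sum()),
                             extrapolated=extrapolated, **meta)


# ---------------------------------------------------------------------------
# indifference curves


@dataclass
class IndifferenceCurve:
    """A fitted IC form: probability as a function of reward magnitude."""

    form: str
    params: dict[str, float]
    mse: float
    b_gamble: Gamble | None = None

    def predict(self, x) -> np.ndarray:
        return _FORMS[self.form](np.asarray(x, float),
                                 **{k: v for k, v in self.params.items()})


def _linear(x, a, b):
    return a * x + b


def _power(x, a, b, c):
    return a * np.power(np.clip(x - c, 1e-12, None), b)


def _hyperbolic(x, a, b, c):
    return a + b / np.clip(x - c, 1e-12, None)


_FORMS = {"linear": _linear, "power": _power, "hyperbolic": _hyperbolic}
_N_PARAMS = {"linear": 2, "power": 3, "hyperbolic": 3}


def _xy(ips) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(ips[0], "alpha"):
        x = np.array([ip.a_magnitude for ip in ips], float)
        y = np.array([ip.alpha for ip in ips], float)
    else:
        arr = np.asarray(ips, float)
        x, y = arr[:, 0], arr[:, 1]
    return x, y


def fit_indifference_curve(ips, form: str) -> IndifferenceCurve:
    """Least-squares IC fit minimizing squared residuals in probability.

    ``ips`` is a sequence of :class:`IndifferencePoint` (using their
    ``a_magnitude``/``alpha``) or of ``(magnitude, probability)`` pairs.
    The power form ``a*(x-c)^b`` constrains ``0 <= c < min(x)`` to keep
    the base positive; the hyperbolic form ``a + b/(x-c)`` constrains
    ``c < min(x)``.
    """
    if form not in _FORMS:
        raise ValueError(f"unknown IC form {form!r}")
    x, y = _xy(ips)
    if len(x) < _N_PARAMS[form]:
        raise CurveFitError(f"{form} fit needs >= {_N_PARAMS[form]} points")
    if np.ptp(x) < 1e-12:
        raise CurveFitError("all magnitudes identical; IC not identifiable")

    if form == "linear":
        A = np.vstack([x, np.ones_like(x)]).T
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        return IndifferenceCurve("linear", {"a": float(coef[0]), "b": float(coef[1])},
                                 float(np.mean(resid**2)))

    cmax = float(x.min()) - 1e-6
    best = None
    if form == "power":
        pos = (x > 0) & (y > 0)
        if pos.sum() >= 2:
            b0, loga = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)
            starts = [(float(np.exp(loga)), float(b0), 0.0)]
        else:
            starts = [(1.0, -1.0, 0.0)]
        starts.append((max(y.mean(), 1e-3), -1.0, 0.0))
        lb, ub = [1e-8, -20.0, 0.0], [np.inf, 20.0, max(cmax, 1e-9)]
    else:  # hyperbolic
        A = np.vstack([np.ones_like(x), 1.0 / x]).T if np.all(x > 0) \
            else np.vstack([np.ones_like(x), 1.0 / (x - x.min() + 0.1)]).T
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        starts = [(float(coef[0]), float(coef[1]), 0.0 if x.min() > 0 else float(x.min() - 0.1)),
                  (float(y.mean()), 0.1, float(x.min() - 0.2))]
        lb, ub = [-np.inf, -np.inf, -np.inf], [np.inf, np.inf, cmax]

    fun = _FORMS[form]
    for a0, b0, c0 in starts:
        p0 = np.clip([a0, b0, c0], lb, ub)
        try:
            sol = least_squares(lambda th: fun(x, *th) - y, p0,
                                bounds=(lb, ub))
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise CurveFitError(f"{form} fit failed from all starts")
    a, b, c = best.x
    mse = float(np.mean((fun(x, a, b, c) - y) ** 2))
    return IndifferenceCurve(form, {"a": float(a), "b": float(b), "c": float(c)}, mse)


def loo_coverage(ips, form: str, *, n_boot: int = 200, seed: int = 0) -> float:
    """Leave-one-out calibration of the IC fit.

    For each point: refit on the remaining points, build a bootstrap 95%
    prediction band at the left-out magnitude (resampling the remaining
    points), and record whether the left-out probability falls inside.
    Returns the covered fraction.
    """
    x, y = _xy(ips)
    if len(x) < 4:
        raise ValueError("leave-one-out coverage needs at least 4 points")
    rng = np.random.default_rng(seed)
    covered = 0
    for i in range(len(x)):
        keep = np.ones(len(x), bool)
        keep[i] = False
        xs, ys = x[keep], y[keep]
        preds = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(xs), len(xs))
            if np.ptp(xs[idx]) < 1e-12:
                continue
            try:
                fit = fit_indifference_curve(np.column_stack([xs[idx], ys[idx]]),
                                             form)
            except CurveFitError:
                continue
            preds.append(float(fit.predict([x[i]])[0]))
        if not preds:
            continue
        lo, hi = np.percentile(preds, [2.5, 97.5])
        # exact zero-noise fits collapse the band; allow numerical slack
        if lo - 1e-6 <= y[i] <= hi + 1e-6:
            covered += 1
    return covered / len(x)


# ---------------------------------------------------------------------------
# IP variability


def within_session_ip_change(trials: pd.DataFrame, *, min_per_level: int = 1,
                             **fit_kw) -> dict:
    """Second-half minus first-half indifference point, per session.

    Sessions are split at the trial-index midpoint (odd counts: middle
    trial to the first half); each half gets its own softmax IP fit and
    the per-session differences are tested against zero with a one-sample
    t test.  Sessions where either half cannot be fit are excluded with a
    warning.
    """
    fit_kw.setdefault("n_boot", 0)
    deltas, sessions = [], []
    for sess, sub in trials.groupby("session"):
        sub = sub.sort_values("trial")
        half = (len(sub) + 1) // 2
        try:
            ips = [fit_softmax_ip(*counts_by_level(part), **fit_kw)
                   for part in (sub.iloc[:half], sub.iloc[half:])]
        except (ValueError, RuntimeError) as err:
            warnings.warn(f"session {sess} excluded from IP-change analysis: {err}")
            continue
        deltas.append(ips[1].alpha - ips[0].alpha)
        sessions.append(sess)
    if not deltas:
        raise ValueError("no session produced a pair of half-session IPs")
    deltas = np.asarray(deltas)
    if len(deltas) >= 2:
        t = ttest_1samp(deltas, 0.0)
        tstat, pval = float(t.statistic), float(t.pvalue)
        if len(deltas) == 2:
            warnings.warn("IP-change test has df=1; interpret with caution")
    else:
        tstat = pval = np.nan
    return {"per_session": pd.DataFrame({"session": sessions, "delta_ip": deltas}),
            "mean_delta": float(np.mean(deltas)), "t": tstat, "p": pval,
            "n_sessions": len(deltas)}


def ip_session_series(ips: Sequence[float], window: int = 5) -> np.ndarray:
    """Centered moving average of a session-wise IP series.

    Windows shrink symmetrically at the edges (min one observation), so a
    constant series is returned unchanged and a single session passes
    through.
    """
    s = pd.Series(np.asarray(ips, float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()
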