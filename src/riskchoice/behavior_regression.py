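"""Single-trial logistic regression of choice behavior.

The right-choice indicator is regressed on the magnitudes and
probabilities of the two options plus a history regressor:

    Logit(P_R) = b0 + b1*m_L + b2*p_L + b3*m_R + b4*p_R + b5*preCh*preRew

where preCh is the previous trial's chosen side (-1 left, +1 right) and
preRew the reward it delivered (ml); the first trial of a session gets 0.
Coefficients are standardized by SD(x)/SD(y) and tested across sessions
with one-sample t tests under FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import ttest_1samp

from .axiom_tests import bh_fdr
from .gambles import Gamble, expected_value

__all__ = [
    "RegressionResult",
    "COEF_NAMES",
    "encode_regressors",
    "fit_choice_logistic",
    "standardize_coefficients",
    "population_beta_tests",
]

COEF_NAMES = ("intercept", "m_L", "p_L", "m_R", "p_R", "preChxpreRew")


def _mp(g: Gamble) -> tuple[float, float]:
    """Scalar (magnitude, probability) encoding of one option.

    m is the largest outcome magnitude and p its probability (degenerate
    gambles: p = 1; the all-zero gamble encodes as (0, 1)).  The model is
    written for scalar per-side attributes; multi-outcome gambles have no
    canonical encoding, so this one is applied uniformly.
    """
    m = float(g.magnitudes.max())
    p = float(g.probabilities[int(np.argmax(g.magnitudes))])
    if m <= 0:
        return 0.0, 1.0
    return m, p


def encode_regressors(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix (with intercept) and right-choice indicator."""
    rows = []
    for row in trials.itertuples():
        m_l, p_l = _mp(row.gamble_left)
        m_r, p_r = _mp(row.gamble_right)
        rows.append((1.0, m_l, p_l, m_r, p_r,
                     row.prev_choice * row.prev_reward))
    X = np.asarray(rows)
    y = (trials["chosen_side"].to_numpy() == "R").astype(float)
    return X, y


@dataclass
class RegressionResult:
    """A fitted choice regression for one session (or pooled)."""

    params: pd.Series            # raw coefficients, indexed by COEF_NAMES
    std_params: pd.Series        # standardized (intercept NaN)
    n_trials: int
    converged: bool
    separation: bool = False
    session: object = "pooled"


def fit_choice_logistic(trials: pd.DataFrame, session: object = "pooled") -> RegressionResult:
    """MLE logistic fit of the right-choice indicator on the five regressors.

    Perfect separation (or non-convergence) triggers a flagged ridge-
    penalized refit.  Warns below 50 trials and on rank-deficient designs.
    """
    X, y = encode_regressors(trials)
    if len(y) < 50:
        warnings.warn(f"only {len(y)} trials; regression may be unstable")
    # zero-variance regressors are not identified next to the intercept;
    # drop them from the fit and report NaN
    keep = np.ones(X.shape[1], bool)
    for i in range(1, X.shape[1]):
        if np.std(X[:, i]) < 1e-12:
            keep[i] = False
    if not keep.all():
        warnings.warn("zero-variance regressor(s) excluded: "
                      + ", ".join(np.array(COEF_NAMES)[~keep]))
    Xk = X[:, keep]
    rank = np.linalg.matrix_rank(Xk)
    if rank < Xk.shape[1]:
        warnings.warn(f"design matrix rank {rank} < {Xk.shape[1]}; "
                      "some coefficients are not identified")
    separation = False
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="statsmodels")
        try:
            fit = sm.Logit(y, Xk).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
            if not converged or np.any(~np.isfinite(fit.bse)):
                raise sm.tools.sm_exceptions.PerfectSeparationError
            params_k = np.asarray(fit.params)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                np.linalg.LinAlgError):
            separation = True
            fit = sm.Logit(y, Xk).fit_regularized(disp=0, alpha=1e-3, L1_wt=0.0)
            params_k = np.asarray(fit.params)
            converged = True
    full = np.full(X.shape[1], np.nan)
    full[keep] = params_k
    params = pd.Series(full, index=COEF_NAMES)
    result = RegressionResult(params=params, std_params=pd.Series(dtype=float),
                              n_trials=len(y), converged=converged,
                              separation=separation, session=session)
    result.std_params = standardize_coefficients(result, trials)
    return result


def standardize_coefficients(result: RegressionResult,
                             trials: pd.DataFrame) -> pd.Series:
    """beta_std = beta * SD(x) / SD(y); undefined for the intercept.

    Zero-variance regressors get NaN with a warning (their effect is not
    identified on this table).
    """
    X, y = encode_regressors(trials)
    sd_y = float(np.std(y, ddof=0))
    out = {}
    for i, name in enumerate(COEF_NAMES):
        if name == "intercept":
            out[name] = np.nan
            continue
        sd_x = float(np.std(X[:, i], ddof=0))
        if sd_x < 1e-12 or sd_y < 1e-12:
            warnings.warn(f"regressor {name} (or the response) has zero "
                          "variance; standardized beta undefined")
            out[name] = np.nan
        else:
            out[name] = float(result.params[name]) * sd_x / sd_y
    return pd.Series(out)


def population_beta_tests(results: list[RegressionResult],
                          q: float = 0.05) -> pd.DataFrame:
    """Across-session one-sample t tests per coefficient, FDR-corrected.

    Standardized betas are tested for the slope coefficients; the raw
    intercept (the side bias, which has no standardized form) is tested on
    its natural scale.  FDR is applied across the six coefficients.
    """
    if len(results) < 3:
        raise ValueError("population tests need at least 3 sessions")
    table = []
    for name in COEF_NAMES:
        if name == "intercept":
            vals = np.array([r.params[name] for r in results], float)
        else:
            vals = np.array([r.std_params[name] for r in results], float)
        vals = vals[np.isfinite(vals)]
        if len(vals) >= 2 and np.std(vals) > 0:
            t = ttest_1samp(vals, 0.0)
            tstat, p = float(t.statistic), float(t.pvalue)
            se = np.std(vals, ddof=1) / np.sqrt(len(vals))
            ci = (float(np.mean(vals) - 1.96 * se),
                  float(np.mean(vals) + 1.96 * se))
        else:
            tstat, p, ci = np.nan, 1.0, (np.nan, np.nan)
        table.append({"coefficient": name, "mean": float(np.mean(vals)) if len(vals) else np.nan,
                      "n_sessions": len(vals), "t": tstat, "p": p,
                      "ci_low": ci[0], "ci_high": ci[1]})
    df = pd.DataFrame(table).set_index("coefficient")
    reject, p_adj = bh_fdr(df["p"].to_numpy(), q)
    df["p_adjusted"] = p_adj
    df["significant"] = reject
    return df
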