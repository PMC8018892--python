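"""Stochastic tests of the expected-utility axioms.

Deterministic axioms (dominance, transitivity, continuity) are interpreted
stochastically: option A counts as preferred to option B when the
proportion of A choices exceeds 0.5 and an exact two-sided binomial test
rejects indifference at the 5% level.  The continuity test additionally
applies a Benjamini-Hochberg FDR correction across its pA levels and a
trial-level Spearman rank correlation for monotonicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest, spearmanr
from statsmodels.stats.multitest import multipletests

from .gambles import Gamble, fsd_dominates
from . import preference_fitting as pf

__all__ = [
    "PreferenceResult",
    "FSDResult",
    "TransitivityResult",
    "ContinuityResult",
    "RankedGamblesError",
    "binomial_preference",
    "bh_fdr",
    "test_fsd",
    "fsd_counts_from_trials",
    "test_transitivity",
    "test_continuity",
    "continuity_from_trials",
]

ALPHA = 0.05


class RankedGamblesError(ValueError):
    """The A > B > C precheck failed; the continuity test is undefined."""


@dataclass
class PreferenceResult:
    """Outcome of one stochastic preference comparison."""

    k: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float
    p_value: float
    direction: str  # preferred | dispreferred | indifferent


def binomial_preference(k: int, n: int, alpha: float = ALPHA) -> PreferenceResult:
    """Exact two-sided binomial test of a choice proportion against 0.5.

    Direction is assigned from the point estimate only when the test is
    significant; the 95% CI is Clopper-Pearson.
    """
    if n < 1:
        raise ValueError("need at least one trial")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    res = binomtest(k, n, 0.5)
    ci = res.proportion_ci(confidence_level=0.95, method="exact")
    prop = k / n
    if res.pvalue < alpha and prop != 0.5:
        direction = "preferred" if prop > 0.5 else "dispreferred"
    else:
        direction = "indifferent"
    return PreferenceResult(k=k, n=n, proportion=prop, ci_low=float(ci.low),
                            ci_high=float(ci.high), p_value=float(res.pvalue),
                            direction=direction)


def bh_fdr(p_values: Sequence[float], q: float = ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns ``(reject, p_adjusted)``; adjusted p-values are monotone.
    """
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# first-order stochastic dominance


@dataclass
class FSDResult:
    """Per-pair dominance preferences plus a pooled compliance verdict."""

    per_pair: list[PreferenceResult]
    pooled: PreferenceResult
    compliant: bool


def test_fsd(pair_counts: Sequence[tuple[Gamble, Gamble, int, int]],
             alpha: float = ALPHA) -> FSDResult:
    """Test preference for the dominant option across FSD pairs.

    Each entry is ``(g1, g2, k1, n)`` with ``k1`` choices of ``g1``; one
    of the two gambles must first-order stochastically dominate the other.
    Compliance is pooled: the binomial 95% CI of the overall
    dominant-choice proportion must lie above 0.5.
    """
    per_pair = []
    k_tot = n_tot = 0
    for g1, g2, k1, n in pair_counts:
        if fsd_dominates(g1, g2):
            k_dom = k1
        elif fsd_dominates(g2, g1):
            k_dom = n - k1
        else:
            raise ValueError(f"no dominance relation between {g1!r} and {g2!r}")
        per_pair.append(binomial_preference(k_dom, n, alpha))
        k_tot += k_dom
        n_tot += n
    if not per_pair:
        raise ValueError("no dominance pairs supplied")
    pooled = binomial_preference(k_tot, n_tot, alpha)
    return FSDResult(per_pair=per_pair, pooled=pooled,
                     compliant=bool(pooled.ci_low > 0.5))


def fsd_counts_from_trials(trials: pd.DataFrame) -> list[tuple[Gamble, Gamble, int, int]]:
    """Aggregate a trial table into per-gamble-pair choice counts."""
    counts: dict[tuple[Gamble, Gamble], list[int]] = {}
    for row in trials.itertuples():
        g1, g2 = row.gamble_left, row.gamble_right
        chose_first = row.chosen_side == "L"
        if (g2, g1) in counts:
            g1, g2 = g2, g1
            chose_first = not chose_first
        entry = counts.setdefault((g1, g2), [0, 0])
        entry[0] += int(chose_first)
        entry[1] += 1
    return [(g1, g2, k, n) for (g1, g2), (k, n) in counts.items()]


# ---------------------------------------------------------------------------
# stochastic transitivity


@dataclass
class TransitivityResult:
    """Weak/strong stochastic transitivity over one A, B, C triplet."""

    p_ab: float
    p_bc: float
    p_ac: float
    results: dict[str, PreferenceResult]
    wst: bool
    sst: bool


def test_transitivity(counts: dict[str, tuple[int, int]],
                      alpha: float = ALPHA) -> TransitivityResult:
    """WST/SST verdicts from triplet choice counts.

    ``counts`` maps ``"AB"``, ``"BC"``, ``"AC"`` to ``(k, n)`` where k
    counts choices of the first-named (putatively better) option.  WST
    requires all three proportions significantly above 0.5; SST
    additionally requires P(A over C) to be at least the maximum of the
    other two point estimates.
    """
    missing = {"AB", "BC", "AC"} - set(counts)
    if missing:
        raise ValueError(f"missing pairings: {sorted(missing)}")
    results = {pair: binomial_preference(*counts[pair], alpha=alpha)
               for pair in ("AB", "BC", "AC")}
    p_ab, p_bc, p_ac = (results[p].proportion for p in ("AB", "BC", "AC"))
    wst = all(r.direction == "preferred" for r in results.values())
    sst = bool(wst and p_ac >= max(p_ab, p_bc))
    return TransitivityResult(p_ab=p_ab, p_bc=p_bc, p_ac=p_ac,
                              results=results, wst=wst, sst=sst)


# ---------------------------------------------------------------------------
# continuity


@dataclass
class ContinuityResult:
    """Verdict of one continuity-axiom test.

    Compliance requires (i) at least one interior pA level (0 < pA < 1)
    where the mixture is significantly dispreferred and one where it is
    significantly preferred after FDR correction across levels (the
    Archimedean criterion), and (ii) a significant positive trial-level
    rank correlation between pA and choice (monotonicity).  The endpoint
    levels pA = 0 and pA = 1 are pure C-vs-B and A-vs-B choices — they
    restate the A > B > C premise rather than probe the axiom, so they do
    not count toward the Archimedean criterion.
    """

    levels: np.ndarray
    proportions: np.ndarray
    results: list[PreferenceResult]
    p_adjusted: np.ndarray
    rank_corr_rho: float
    rank_corr_p: float
    has_dispreferred_level: bool
    has_preferred_level: bool
    compliant: bool
    ip: pf.IndifferencePoint | None = None
    extra: dict = field(default_factory=dict)


def test_continuity(levels: Sequence[float], k: Sequence[int],
                    n: Sequence[int], *, alpha: float = ALPHA,
                    q: float = ALPHA,
                    precheck: dict[str, tuple[int, int]] | None = None,
                    fit_ip: bool = True, n_boot: int = 0, seed: int = 0,
                    **ip_meta) -> ContinuityResult:
    """Stochastic continuity-axiom test on per-level AC-choice counts.

    ``k[i]`` counts choices of the AC mixture out of ``n[i]`` trials at
    mixture probability ``levels[i]``.  Per-level binomial tests against
    0.5 are BH-FDR corrected within this test; significance (and hence
    preference direction) is taken from the FDR rejection.  ``precheck``
    optionally supplies ``{"AB": (k, n), "BC": (k, n)}`` counts that must
    establish A > B and B > C, else :class:`RankedGamblesError` is raised.
    The indifference point is delegated to
    :func:`riskchoice.preference_fitting.fit_softmax_ip`.
    """
    levels = np.asarray(levels, float)
    k = np.asarray(k, int)
    n = np.asarray(n, int)
    if len(levels) < 3:
        raise ValueError("need at least 3 pA levels")
    if precheck is not None:
        for pair in ("AB", "BC"):
            if pair not in precheck:
                raise ValueError(f"precheck missing {pair} counts")
            res = binomial_preference(*precheck[pair], alpha=alpha)
            if res.direction != "preferred":
                raise RankedGamblesError(
                    f"precheck {pair}: proportion {res.proportion:.3f} "
                    f"(p={res.p_value:.3g}) does not establish the required "
                    f"ranking; continuity test undefined")
    order = np.argsort(levels)
    levels, k, n = levels[order], k[order], n[order]
    raw = [binomial_preference(int(ki), int(ni), alpha) for ki, ni in zip(k, n)]
    reject, p_adj = bh_fdr([r.p_value for r in raw], q)
    results = []
    for r, rej in zip(raw, reject):
        direction = "indifferent"
        if rej and r.proportion != 0.5:
            direction = "preferred" if r.proportion > 0.5 else "dispreferred"
        results.append(PreferenceResult(r.k, r.n, r.proportion, r.ci_low,
                                        r.ci_high, r.p_value, direction))
    props = k / n
    interior = (levels > 0.0) & (levels < 1.0)
    has_lo = any(r.direction == "dispreferred"
                 for r, inside in zip(results, interior) if inside)
    has_hi = any(r.direction == "preferred"
                 for r, inside in zip(results, interior) if inside)

    # trial-level rank correlation between pA and the binary choice
    x = np.repeat(levels, n)
    y = np.concatenate([np.concatenate([np.ones(ki), np.zeros(ni - ki)])
                        for ki, ni in zip(k, n)])
    if np.ptp(y) > 0:
        rho, rho_p = spearmanr(x, y)
    else:
        rho, rho_p = 0.0, 1.0
    monotone = bool(rho > 0 and rho_p < alpha)
    compliant = bool(has_lo and has_hi and monotone)

    ip = None
    if fit_ip:
        ip = pf.fit_softmax_ip(levels, k, n, n_boot=n_boot, seed=seed, **ip_meta)
    return ContinuityResult(levels=levels, proportions=props, results=results,
                            p_adjusted=p_adj, rank_corr_rho=float(rho),
                            rank_corr_p=float(rho_p),
                            has_dispreferred_level=has_lo,
                            has_preferred_level=has_hi,
                            compliant=compliant, ip=ip)


def continuity_from_trials(trials: pd.DataFrame, **kwargs) -> ContinuityResult:
    """Run :func:`test_continuity` on a mixture-tagged trial table."""
    levels, k, n = pf.counts_by_level(trials)
    return test_continuity(levels, k, n, **kwargs)
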