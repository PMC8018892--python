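"""Gamble algebra for risky binary choice.

A gamble is a finite, known probability distribution over liquid-reward
magnitudes (ml).  Everything downstream — axiom tests, indifference-point
estimation, value models — operates on these objects.  Gambles are kept in
a canonical form: outcomes sorted by ascending magnitude, equal magnitudes
merged, zero-probability outcomes dropped, probabilities renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: magnitudes closer than this (ml) are merged into one outcome
MERGE_TOL = 1e-9
#: probabilities must sum to 1 within this tolerance before renormalization
PROB_TOL = 1e-9


class GambleError(ValueError):
    """Invalid gamble construction or operation."""


@dataclass(frozen=True)
class Gamble:
    """A finite lottery over reward magnitudes.

    Parameters
    ----------
    outcomes
        Iterable of ``(magnitude_ml, probability)`` pairs.  Probabilities
        must sum to 1 within ``PROB_TOL``; magnitudes must be >= 0.
    """

    outcomes: tuple[tuple[float, float], ...]

    def __init__(self, outcomes: Iterable[tuple[float, float]]):
        pairs = [(float(m), float(p)) for m, p in outcomes]
        if not pairs:
            raise GambleError("a gamble needs at least one outcome")
        for m, p in pairs:
            if m < 0:
                raise GambleError(f"negative magnitude {m}")
            if p < -PROB_TOL:
                raise GambleError(f"negative probability {p}")
        total = sum(p for _, p in pairs)
        if abs(total - 1.0) > PROB_TOL:
            raise GambleError(f"probabilities sum to {total}, not 1")
        # canonicalize: renormalize, merge near-equal magnitudes, sort, drop p=0
        pairs = [(m, p / total) for m, p in pairs]
        pairs.sort(key=lambda mp: mp[0])
        merged: list[list[float]] = []
        for m, p in pairs:
            if merged and m - merged[-1][0] <= MERGE_TOL:
                merged[-1][1] += p
            else:
                merged.append([m, p])
        kept = [(m, p) for m, p in merged if p > 1e-12]
        if not kept:  # all mass on (near-)zero-probability outcomes
            kept = [max(merged, key=lambda mp: mp[1])]
        total = sum(p for _, p in kept)
        canon = tuple((m, p / total) for m, p in kept)
        object.__setattr__(self, "outcomes", canon)

    # -- constructors ------------------------------------------------------

    @classmethod
    def degenerate(cls, magnitude: float) -> "Gamble":
        """Sure reward: a single outcome with probability 1."""
        return cls([(magnitude, 1.0)])

    @classmethod
    def two_outcome(cls, magnitude: float, p: float, low: float = 0.0) -> "Gamble":
        """Gamble paying `magnitude` with probability ``p``, else `low`."""
        if not 0.0 <= p <= 1.0:
            raise GambleError(f"probability {p} outside [0, 1]")
        return cls([(magnitude, p), (low, 1.0 - p)])

    # -- accessors ---------------------------------------------------------

    @property
    def magnitudes(self) -> np.ndarray:
        return np.array([m for m, _ in self.outcomes])

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([p for _, p in self.outcomes])

    @property
    def n_outcomes(self) -> int:
        return len(self.outcomes)

    @property
    def is_degenerate(self) -> bool:
        return len(self.outcomes) == 1

    def nonzero_outcomes(self) -> list[tuple[float, float]]:
        """Outcomes with strictly positive magnitude."""
        return [(m, p) for m, p in self.outcomes if m > MERGE_TOL]

    def __repr__(self) -> str:  # compact, round-trips via io.parse_gamble
        body = ";".join(f"{m:g}:{p:g}" for m, p in self.outcomes)
        return f"Gamble({body})"


def expected_value(g: Gamble) -> float:
    """Objective expected value, EV = sum_i m_i * p_i (ml)."""
    return float(np.dot(g.magnitudes, g.probabilities))


def risk_variance(g: Gamble) -> float:
    """Outcome variance, Risk = sum_i p_i * (m_i - EV)^2 (ml^2)."""
    ev = expected_value(g)
    return float(np.dot(g.probabilities, (g.magnitudes - ev) ** 2))


def mix(gA: Gamble, gC: Gamble, pA: float) -> Gamble:
    """Probabilistic combination pA*A + (1-pA)*C.

    The result's outcome set is the union of the two components' outcomes,
    canonicalized (shared magnitudes merge), so a mixture of two-outcome
    gambles with one common magnitude is a three-outcome gamble.
    """
    if not 0.0 <= pA <= 1.0:
        raise GambleError(f"mixture probability {pA} outside [0, 1]")
    pairs = [(m, pA * p) for m, p in gA.outcomes]
    pairs += [(m, (1.0 - pA) * p) for m, p in gC.outcomes]
    return Gamble(pairs)


def _cdf_on(g: Gamble, grid: np.ndarray) -> np.ndarray:
    m = g.magnitudes
    p = g.probabilities
    return np.array([p[m <= x + MERGE_TOL].sum() for x in grid])


def fsd_dominates(g1: Gamble, g2: Gamble) -> bool:
    """First-order stochastic dominance of ``g1`` over ``g2``.

    True iff the CDF of g1 lies at or below that of g2 at every magnitude,
    strictly below somewhere — the probabilistic analog of "more is
    better".
    """
    grid = np.unique(np.concatenate([g1.magnitudes, g2.magnitudes]))
    c1 = _cdf_on(g1, grid)
    c2 = _cdf_on(g2, grid)
    return bool(np.all(c1 <= c2 + PROB_TOL) and np.any(c1 < c2 - PROB_TOL))


@dataclass(frozen=True)
class MMPoint:
    """A gamble's coordinates in the Marschak–Machina triangle.

    ``p1`` and ``p3`` are the probabilities of the lowest and highest of
    the three fixed magnitudes; the middle-outcome probability is
    ``p2 = 1 - p1 - p3``.
    """

    p1: float
    p3: float
    levels: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.p1 < -PROB_TOL or self.p3 < -PROB_TOL or self.p1 + self.p3 > 1 + PROB_TOL:
            raise GambleError(f"invalid triangle point ({self.p1}, {self.p3})")

    @property
    def p2(self) -> float:
        return 1.0 - self.p1 - self.p3


def mm_coordinates(g: Gamble, levels: Sequence[float]) -> MMPoint:
    """Map a gamble onto the Marschak–Machina triangle.

    Every outcome magnitude of ``g`` must equal one of the three fixed
    ``levels`` (ascending); levels missing from the gamble get probability
    zero.
    """
    lv = tuple(sorted(float(x) for x in levels))
    if len(lv) != 3:
        raise GambleError("exactly three magnitude levels required")
    probs = [0.0, 0.0, 0.0]
    for m, p in g.outcomes:
        hits = [i for i, x in enumerate(lv) if abs(m - x) <= MERGE_TOL]
        if not hits:
            raise GambleError(f"outcome magnitude {m} is not one of the levels {lv}")
        probs[hits[0]] += p
    return MMPoint(p1=probs[0], p3=probs[2], levels=lv)


def from_mm_coordinates(point: MMPoint) -> Gamble:
    """Inverse of :func:`mm_coordinates` on the point's fixed levels."""
    lo, mid, hi = point.levels
    return Gamble([(lo, point.p1), (mid, point.p2), (hi, point.p3)])
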