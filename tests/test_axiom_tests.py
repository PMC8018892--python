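"""Stochastic axiom tests: binomial inference, FDR, FSD, WST/SST, continuity."""

from math import comb

import numpy as np
import pytest

from riskchoice import Gamble, ModelSpec
from riskchoice.axiom_tests import (RankedGamblesError, bh_fdr,
                                    binomial_preference, continuity_from_trials,
                                    fsd_counts_from_trials)
from riskchoice.axiom_tests import test_continuity as run_continuity
from riskchoice.axiom_tests import test_fsd as run_fsd
from riskchoice.axiom_tests import test_transitivity as run_transitivity
from riskchoice.synthetic_agent import (AgentSpec, Condition,
                                        continuity_design, simulate_experiment)


def exact_two_sided_p(k, n):
    """Brute-force two-sided binomial p-value: sum of pmf <= pmf(k)."""
    pmf = [comb(n, j) / 2**n for j in range(n + 1)]
    return min(1.0, sum(p for p in pmf if p <= pmf[k] * (1 + 1e-12)))


def bh_oracle(p, q):
    """Brute-force step-up rule: reject 1..i* with i* = max{i: p(i) <= iq/m}."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p, kind="stable")
    istar = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            istar = rank
    reject = np.zeros(m, bool)
    reject[order[:istar]] = True
    return reject


class TestBinomialPreference:
    @pytest.mark.parametrize("k,n,p_expect,direction", [
        (9, 10, 0.021484375, "preferred"),
        (5, 10, 1.0, "indifferent"),
        (0, 20, 2 * 2.0**-20, "dispreferred"),
    ])
    def test_exact_examples(self, k, n, p_expect, direction):
        res = binomial_preference(k, n)
        assert res.p_value == pytest.approx(p_expect, rel=1e-9)
        assert res.direction == direction

    def test_matches_brute_force_enumeration_small_n(self):
        for n in range(1, 13):
            for k in range(n + 1):
                res = binomial_preference(k, n)
                assert res.p_value == pytest.approx(exact_two_sided_p(k, n),
                                                    rel=1e-9)

    def test_ci_is_exact_clopper_pearson(self):
        res = binomial_preference(9, 10)
        assert 0 <= res.ci_low < res.proportion < res.ci_high <= 1

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            binomial_preference(0, 0)


class TestBHFDR:
    def test_all_small_p_rejected(self):
        reject, _ = bh_fdr([0.01, 0.02, 0.04], q=0.05)
        assert reject.all()

    def test_null_p_never_rejected(self):
        reject, p_adj = bh_fdr([1.0, 1.0, 1.0])
        assert not reject.any()
        assert np.all(p_adj == 1.0)

    def test_single_p_reduces_to_plain_test(self):
        reject, p_adj = bh_fdr([0.04], q=0.05)
        assert reject[0] and p_adj[0] == pytest.approx(0.04)

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m = rng.integers(1, 25)
            p = np.round(rng.uniform(size=m) ** rng.uniform(0.5, 3), 4)
            reject, _ = bh_fdr(p, q=0.05)
            assert np.array_equal(reject, bh_oracle(p, 0.05))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestFSD:
    def test_single_perfect_pair_compliant(self, deg):
        hi = Gamble([(0.3, 0.75), (0.0, 0.25)])
        lo = Gamble([(0.3, 0.25), (0.0, 0.75)])
        res = run_fsd([(hi, lo, 30, 30)])
        assert res.compliant and res.pooled.direction == "preferred"

    def test_orientation_is_inferred(self):
        hi = Gamble([(0.3, 0.75), (0.0, 0.25)])
        lo = Gamble([(0.3, 0.25), (0.0, 0.75)])
        # counts given for the dominated option; 2/30 dominated choices
        res = run_fsd([(lo, hi, 2, 30)])
        assert res.pooled.proportion == pytest.approx(28 / 30)

    def test_coin_flip_counts_not_compliant(self):
        hi = Gamble([(0.3, 0.75), (0.0, 0.25)])
        lo = Gamble([(0.3, 0.25), (0.0, 0.75)])
        res = run_fsd([(hi, lo, 15, 30), (hi, lo, 14, 30)])
        assert not res.compliant

    def test_no_dominance_pair_rejected(self, deg):
        risky = Gamble([(0.5, 0.5), (0.0, 0.5)])
        with pytest.raises(ValueError):
            run_fsd([(risky, deg(0.25), 10, 20)])

    def test_simulated_ev_agent_prefers_dominant_options(self, deg):
        agent = AgentSpec(model=ModelSpec("EV", {"tau": 0.05}), seed=4)
        rng = np.random.default_rng(1)
        conds = []
        for _ in range(20):
            m = rng.choice([0.2, 0.3, 0.4, 0.5])
            p_hi = rng.uniform(0.6, 0.95)
            conds.append(Condition(Gamble.two_outcome(m, p_hi),
                                   Gamble.two_outcome(m, p_hi - 0.4), 30))
        trials = simulate_experiment(agent, [conds])
        res = run_fsd(fsd_counts_from_trials(trials))
        assert res.compliant


class TestTransitivity:
    def test_consistent_proportions_satisfy_both_forms(self):
        res = run_transitivity({"AB": (80, 100), "BC": (70, 100),
                                 "AC": (90, 100)})
        assert res.wst and res.sst

    def test_weak_but_not_strong(self):
        res = run_transitivity({"AB": (80, 100), "BC": (70, 100),
                                 "AC": (75, 100)})
        assert res.wst and not res.sst

    def test_missing_pairing_rejected(self):
        with pytest.raises(ValueError):
            run_transitivity({"AB": (80, 100), "BC": (70, 100)})

    def test_nonsignificant_proportion_breaks_wst(self):
        res = run_transitivity({"AB": (55, 100), "BC": (70, 100),
                                 "AC": (90, 100)})
        assert not res.wst


class TestContinuity:
    def _simulate_counts(self, agent, levels, repeats, deg):
        design = [continuity_design(deg(0.5), deg(0.25), deg(0.0),
                                    levels, repeats)]
        return simulate_experiment(agent, design)

    def test_eu_agent_compliant_with_interior_ip(self, eu_power_agent, deg,
                                                 levels11):
        trials = self._simulate_counts(eu_power_agent, levels11, 30, deg)
        res = continuity_from_trials(trials)
        assert res.compliant
        assert 0 < res.ip.alpha < 1
        assert res.rank_corr_rho > 0

    def test_lexicographic_agent_violates(self, deg, levels11):
        agent = AgentSpec(model=ModelSpec("EV", {"tau": 0.05}),
                          kind="lexicographic", lapse=0.02, seed=13)
        trials = self._simulate_counts(agent, levels11, 30, deg)
        res = continuity_from_trials(trials)
        # AC preferred at every interior level: no dispreferred level
        assert not res.has_dispreferred_level
        assert not res.compliant

    def test_constant_half_proportions_not_compliant(self, levels11):
        n = np.full(11, 30)
        k = np.full(11, 15)
        res = run_continuity(levels11, k, n)
        assert not res.compliant
        assert all(r.direction == "indifferent" for r in res.results)

    def test_precheck_failure_raises(self, levels11):
        k = np.linspace(2, 28, 11).round().astype(int)
        with pytest.raises(RankedGamblesError):
            run_continuity(levels11, k, np.full(11, 30),
                            precheck={"AB": (15, 30), "BC": (28, 30)})

    def test_endpoints_alone_cannot_satisfy_archimedean(self, levels11):
        # all-or-nothing only at the endpoint levels: premise, not evidence
        k = np.full(11, 15)
        k[0], k[-1] = 0, 30
        res = run_continuity(levels11, k, np.full(11, 30))
        assert not res.has_dispreferred_level
        assert not res.has_preferred_level

    def test_type_i_rate_of_compliance_verdict(self, levels11):
        # an indifferent agent must rarely be called compliant (needs two
        # opposite significant levels); 300 binomial replicates
        rng = np.random.default_rng(99)
        false_pos = sum(
            run_continuity(levels11, rng.binomial(30, 0.5, 11),
                            np.full(11, 30), fit_ip=False).compliant
            for _ in range(300))
        assert false_pos / 300 <= 0.05
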