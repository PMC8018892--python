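"""Value models, likelihoods, MLE, indifference-map prediction, comparison."""

import numpy as np
import pandas as pd
import pytest

from riskchoice import Gamble, ModelSpec
from riskchoice.economic_models import (UnsupportedModelError,
                                        build_indifference_map,
                                        choice_probability, compare_models,
                                        fit_model_mle, gamble_value,
                                        ip_cross_correlation,
                                        negative_log_likelihood,
                                        predict_indifference_point,
                                        prelec_weight, utility)
from riskchoice.gambles import expected_value
from riskchoice.synthetic_agent import (AgentSpec, mixed_value_design,
                                        simulate_experiment)


def spec_of(kind, **params):
    return ModelSpec(kind, params)


class TestUtility:
    def test_linear_normalization_endpoint(self):
        assert utility(0.5, spec_of("EV", tau=0.1)) == pytest.approx(1.0)

    def test_power_form(self):
        s = spec_of("EU_power", a=2.0, tau=0.1)
        assert utility(0.25, s) == pytest.approx(0.25)

    def test_sshape_endpoint_forced_to_one(self):
        s = spec_of("EU_sshape", a=1.4, b=0.8, tau=0.1)
        assert utility(0.5, s) == pytest.approx(1.0)
        assert utility(0.0, s) == 0.0

    def test_sshape_above_m0_warns_and_saturates(self):
        s = spec_of("EU_sshape", a=1.4, b=0.8, tau=0.1)
        with pytest.warns(UserWarning, match="above m0"):
            assert utility(0.6, s) == pytest.approx(1.0)


class TestPrelec:
    def test_endpoint(self):
        assert prelec_weight(1.0, 0.7, 1.2) == pytest.approx(1.0)

    def test_identity_reduction(self):
        p = np.linspace(0.05, 1.0, 20)
        assert np.allclose(prelec_weight(p, 1.0, 1.0), p)

    def test_fixed_point_evaluation(self):
        assert prelec_weight(np.exp(-1), 0.5, 1.0) == pytest.approx(np.exp(-1))


class TestGambleValue:
    def test_eu_linear_two_outcome(self):
        g = Gamble([(0.5, 0.5), (0.0, 0.5)])
        assert gamble_value(g, spec_of("EV", tau=0.1)) == pytest.approx(0.5)

    def test_mean_variance_reduces_to_ev_at_beta_zero(self):
        g = Gamble([(0.5, 0.3), (0.1, 0.7)])
        v = gamble_value(g, spec_of("mean_variance", beta=0.0, tau=0.1))
        assert v == pytest.approx(expected_value(g))

    def test_pw_identity_weighting_equals_eu(self):
        g = Gamble([(0.4, 0.35), (0.0, 0.65)])
        pw = spec_of("PW", a=0.8, a_w=1.0, b_w=1.0, tau=0.1)
        eu = spec_of("EU_power", a=0.8, tau=0.1)
        assert gamble_value(g, pw) == pytest.approx(gamble_value(g, eu))

    def test_ev_reduction_invariant_random_gambles(self):
        rng = np.random.default_rng(0)
        s = spec_of("EV", tau=0.1)
        for _ in range(50):
            k = rng.integers(1, 4)
            mags = rng.uniform(0, 0.5, k)
            probs = rng.dirichlet(np.ones(k))
            g = Gamble(list(zip(mags, probs)))
            assert gamble_value(g, s) == pytest.approx(expected_value(g) / 0.5)

    def test_pw_rejects_two_nonzero_outcomes(self):
        g = Gamble([(0.5, 0.5), (0.05, 0.5)])
        with pytest.raises(UnsupportedModelError):
            gamble_value(g, spec_of("PW", a=1.0, a_w=1.0, b_w=1.0, tau=0.1))


class TestChoiceProbability:
    def test_symmetry(self, deg):
        g = Gamble([(0.5, 0.5), (0.0, 0.5)])
        assert choice_probability(g, g, spec_of("EV", tau=0.1)) == 0.5

    def test_unit_logit_point(self, deg):
        s = spec_of("EV", tau=0.2)
        p = choice_probability(deg(0.4), deg(0.3), s)
        assert p == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-9)
        assert p == pytest.approx(0.7311, abs=5e-5)

    def test_complementarity(self, deg):
        s = spec_of("EU_power", a=0.7, tau=0.05)
        a, b = deg(0.4), Gamble([(0.5, 0.6), (0.0, 0.4)])
        assert choice_probability(a, b, s) + choice_probability(b, a, s) \
            == pytest.approx(1.0)


class TestLikelihood:
    def _table(self, pairs_choices):
        rows = [{"gamble_left": l, "gamble_right": r, "chosen_side": ch}
                for l, r, ch in pairs_choices]
        return pd.DataFrame(rows)

    def test_indifferent_trials_give_n_log2(self, deg):
        g = deg(0.25)
        trials = self._table([(g, g, "L")] * 7 + [(g, g, "R")] * 3)
        nll = negative_log_likelihood(trials, spec_of("EV", tau=0.1))
        assert nll == pytest.approx(10 * np.log(2))

    def test_single_trial_closed_form(self, deg):
        s = spec_of("EV", tau=0.2)
        trials = self._table([(deg(0.4), deg(0.3), "L")])
        nll = negative_log_likelihood(trials, s)
        assert nll == pytest.approx(-np.log(1 / (1 + np.exp(-1))), abs=1e-9)
        assert nll == pytest.approx(0.3133, abs=5e-5)

    def test_duplication_doubles_nll(self, deg):
        s = spec_of("EU_power", a=0.8, tau=0.1)
        rows = [(deg(0.4), deg(0.3), "L"), (deg(0.2), deg(0.3), "R")]
        once = negative_log_likelihood(self._table(rows), s)
        twice = negative_log_likelihood(self._table(rows * 2), s)
        assert twice == pytest.approx(2 * once)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            negative_log_likelihood(pd.DataFrame(
                columns=["gamble_left", "gamble_right", "chosen_side"]),
                spec_of("EV", tau=0.1))


class TestIndifferencePrediction:
    @pytest.mark.parametrize("a", [0.5, 1.0, 2.0])
    def test_matches_power_closed_form_within_grid_step(self, deg, a):
        s = spec_of("EU_power", a=a, tau=0.05)
        for mb in (0.15, 0.25, 0.40):
            for probe in (mb + 0.05, 0.45, 0.5):
                pred = predict_indifference_point(deg(mb), probe, s)
                assert abs(pred - (mb / probe) ** a) <= 0.001 + 1e-12

    def test_probe_at_b_magnitude_gives_certainty(self, deg):
        s = spec_of("EU_power", a=1.0, tau=0.05)
        assert predict_indifference_point(deg(0.25), 0.25, s) == pytest.approx(1.0)

    def test_undefined_ip_for_too_small_probe(self, deg):
        s = spec_of("EU_power", a=1.0, tau=0.05)
        assert predict_indifference_point(deg(0.25), 0.2, s) is None

    def test_predicted_ip_decreases_with_probe_magnitude(self, deg):
        s = spec_of("EU_sshape", a=1.3, b=0.9, tau=0.05)
        probes = np.arange(0.26, 0.51, 0.02)
        ips = [predict_indifference_point(deg(0.25), m, s) for m in probes]
        assert np.all(np.diff(ips) < 0)

    def test_map_follows_ev_closed_form(self, deg):
        s = spec_of("EV", tau=0.05)
        bs = [deg(m) for m in (0.15, 0.25)]
        imap = build_indifference_map(s, bs, magnitude_step=0.01)
        for b, (mags, probs) in imap.curves.items():
            mb = b.magnitudes.max()
            assert np.all(np.abs(probs - mb / mags) <= 0.0011)

    def test_equal_value_b_gambles_share_curves(self, deg):
        s = spec_of("EV", tau=0.05)
        b1 = deg(0.25)
        b2 = Gamble([(0.5, 0.5), (0.0, 0.5)])  # same EV
        imap = build_indifference_map(s, [b1, b2], magnitude_step=0.01)
        m1, p1 = imap.curves[b1]
        m2, p2 = imap.curves[b2]
        common = np.isin(m2.round(6), m1.round(6))
        assert np.allclose(p2[common], p1[np.isin(m1.round(6), m2.round(6))])


class TestMLE:
    def test_parameter_recovery_eu_power(self):
        gen = ModelSpec("EU_power", {"a": 0.6, "tau": 0.1})
        trials = simulate_experiment(AgentSpec(model=gen, seed=2),
                                     [mixed_value_design(repeats=45)])
        fit = fit_model_mle(trials, "EU_power", seed=1)
        assert fit.spec.params["a"] == pytest.approx(0.6, abs=0.1)
        assert fit.spec.params["tau"] == pytest.approx(0.1, abs=0.03)
        assert fit.bic == pytest.approx(
            2 * np.log(fit.n_trials) - 2 * fit.log_likelihood)
        assert fit.aic == pytest.approx(4 - 2 * fit.log_likelihood)

    def test_profile_nll_minimized_near_truth(self):
        gen = ModelSpec("EU_power", {"a": 0.6, "tau": 0.1})
        trials = simulate_experiment(AgentSpec(model=gen, seed=8),
                                     [mixed_value_design(repeats=45)])
        nll_true = negative_log_likelihood(trials, gen)
        for factor in (0.8, 1.2):
            pert = gen.replace(a=0.6 * factor)
            assert nll_true <= negative_log_likelihood(trials, pert)

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            fit_model_mle(pd.DataFrame(
                columns=["gamble_left", "gamble_right", "chosen_side"]), "EV")


class TestComparison:
    def test_identical_specs_identical_metrics(self, deg):
        gen = ModelSpec("EU_power", {"a": 0.8, "tau": 0.08})
        trials = simulate_experiment(AgentSpec(model=gen, seed=5),
                                     [mixed_value_design(repeats=10)])
        f1 = fit_model_mle(trials, "EU_power", seed=1)
        f2 = fit_model_mle(trials, "EU_power", seed=2)
        comp = compare_models([f1, f2])
        assert comp.iloc[0]["bic"] == pytest.approx(comp.iloc[1]["bic"], rel=1e-6)

    def test_different_trial_sets_rejected(self, deg):
        gen = ModelSpec("EV", {"tau": 0.08})
        t1 = simulate_experiment(AgentSpec(model=gen, seed=5),
                                 [mixed_value_design(repeats=5)])
        t2 = t1.iloc[:-10]
        f1 = fit_model_mle(t1, "EV", seed=1)
        f2 = fit_model_mle(t2, "EV", seed=1)
        with pytest.raises(ValueError):
            compare_models([f1, f2])

    def test_misspecification_gap_in_rmse(self, deg):
        # measured IPs on the a=0.5 power closed form: the matching EU fit
        # must beat the risk-neutral model in IP distance
        from riskchoice.preference_fitting import IndifferencePoint
        ips = [IndifferencePoint(alpha=(0.25 / m) ** 0.5, tau=0.05,
                                 b_gamble=deg(0.25), a_magnitude=m)
               for m in (0.3, 0.35, 0.4, 0.45, 0.5)]
        gen = ModelSpec("EU_power", {"a": 0.5, "tau": 0.08})
        trials = simulate_experiment(AgentSpec(model=gen, seed=6),
                                     [mixed_value_design(repeats=25)])
        fits = [fit_model_mle(trials, k, seed=1) for k in ("EU_power", "EV")]
        comp = compare_models(fits, measured_ips=ips)
        assert comp.loc["EU_power", "rmse_ip"] < comp.loc["EV", "rmse_ip"]


class TestIPCrossCorrelation:
    def test_common_drift_without_noise_gives_unit_correlation(self):
        a_walk = 0.8 + np.cumsum(np.random.default_rng(1).normal(0, 0.05, 30))
        table = pd.DataFrame({f"ip{j}": (0.25 / (0.3 + 0.05 * j)) ** a_walk
                              for j in range(4)})
        out = ip_cross_correlation(table)
        assert np.all(out["pairs"]["rho"] > 0.999)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.uniform(0.3, 0.7, (60, 4)),
                             columns=[f"ip{j}" for j in range(4)])
        out = ip_cross_correlation(table)
        assert out["all"]["p"] > 0.05

    def test_short_overlap_pairs_skipped(self):
        table = pd.DataFrame({"a": [0.1, 0.2, np.nan, np.nan],
                              "b": [np.nan, np.nan, 0.3, 0.4],
                              "c": [0.1, 0.2, 0.3, 0.4]})
        out = ip_cross_correlation(table)
        assert not ((out["pairs"]["ip1"] == "a")
                    & (out["pairs"]["ip2"] == "b")).any()
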