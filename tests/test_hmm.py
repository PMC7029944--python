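import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import approx_fprime

from helpers import brute_hmm_trial
from spikeattn import (ConditionScheme, FitConfig, HMMParams, fit_hmm,
                       hmm_moments, session_loglik, state_distribution,
                       trial_state_loglik)
from spikeattn.fitbase import prepare_session
from spikeattn.hmm import _HMMPack, _hmm_objective
from spikeattn.simulate import TABLE3_ALPHA, TABLE3_HMM, hmm_preset, simulate_session

ALPHA = np.array(TABLE3_ALPHA)


class TestStateDistribution:
    def test_first_interval_is_lam(self):
        lam = np.array([0.2, 0.5, 0.3])
        assert np.allclose(state_distribution(lam, np.eye(3), 1), lam)

    def test_identity_transitions_freeze_lam(self):
        lam = np.array([0.7, 0.2, 0.1])
        for t in (2, 5, 9):
            assert np.allclose(state_distribution(lam, np.eye(3), t), lam)

    def test_matches_stepwise_propagation(self):
        rng = np.random.default_rng(4)
        lam = rng.dirichlet(np.ones(3))
        Gamma = rng.dirichlet(np.ones(3), size=3)
        stepped = lam.copy()
        for _ in range(3):
            stepped = stepped @ Gamma
        assert np.allclose(state_distribution(lam, Gamma, 4), stepped)


class TestMoments:
    @pytest.mark.parametrize("pi, expected_p, expected_rho", [
        (TABLE3_HMM[2], 0.54, 0.69),
        (TABLE3_HMM[3], 0.51, 0.41),
    ])
    def test_tabulated_moments(self, pi, expected_p, expected_rho):
        mom = hmm_moments(np.array(pi), np.eye(3), ALPHA, 1)
        assert mom.p_t == pytest.approx(expected_p, abs=0.005)
        assert mom.rho_t == pytest.approx(expected_rho, abs=0.005)

    def test_equal_alphas_uncorrelated(self):
        mom = hmm_moments(np.array([0.3, 0.3, 0.4]), np.eye(3),
                          np.array([0.6, 0.6, 0.6]), 1)
        assert mom.rho_t == pytest.approx(0.0, abs=1e-12)

    def test_correlation_nonnegative(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            mom = hmm_moments(rng.dirichlet(np.ones(3)),
                              rng.dirichlet(np.ones(3), size=3),
                              rng.random(3), int(rng.integers(1, 6)))
            if mom.rho_defined:
                assert mom.rho_t >= -1e-12

    def test_degenerate_p_flagged(self):
        mom = hmm_moments(np.array([1.0, 0.0, 0.0]), np.eye(3),
                          np.array([1.0, 0.5, 0.5]), 1)
        assert not mom.rho_defined and mom.rho_t is None


class TestLikelihoodOracles:
    def test_trial_state_loglik_enumeration(self, tiny_hmm):
        # two neurons: the per-state emission equals the sum over the four
        # attention assignments weighted by alpha_c
        design, session, _ = tiny_hmm
        from helpers import trial_ll_table
        trial = session.trials[0]
        ll = trial_ll_table(trial, session, design.params.cif)
        for t in (1, 2):
            for c in (1, 2, 3):
                a = design.params.alpha[c - 1]
                expect = np.log(
                    np.prod([a * np.exp(ll[i, t - 1, 1])
                             + (1 - a) * np.exp(ll[i, t - 1, 0])
                             for i in range(2)]))
                got = trial_state_loglik(trial, session, t, c,
                                         design.params, design.scheme)
                assert got == pytest.approx(expect)

    def test_session_loglik_exhaustive_paths(self, small_hmm):
        design, session, _ = small_hmm
        total = 0.0
        for trial in session.trials:
            ll, _, _, _ = brute_hmm_trial(trial, session, design.params,
                                          design.scheme)
            total += ll
        assert session_loglik(session, design.params, design.scheme) == \
            pytest.approx(total, rel=1e-9)

    def test_additive_over_trials(self, tiny_hmm):
        design, session, _ = tiny_hmm
        parts = [
            session_loglik(replace(session, trials=(tr,)), design.params,
                           design.scheme)
            for tr in session.trials
        ]
        assert session_loglik(session, design.params, design.scheme) == \
            pytest.approx(sum(parts))

    def test_degenerate_chain_collapses(self, tiny_hmm):
        # lam=(1,0,0), absorbing state 1, alpha_1=1: only x=1 contributes
        design, session, _ = tiny_hmm
        from helpers import trial_ll_table
        params = HMMParams(
            lam=np.array([1.0, 0.0, 0.0]),
            Gamma={1: np.array([[1.0, 0, 0], [0, 1, 0], [0, 0, 1.0]])},
            alpha=np.array([1.0, 0.5, 0.5]),
            cif=design.params.cif,
        )
        expect = 0.0
        for trial in session.trials:
            ll = trial_ll_table(trial, session, params.cif)
            expect += ll[:, :, 1].sum()
        assert session_loglik(session, params, design.scheme) == \
            pytest.approx(expect)

    def test_empty_session_rejected(self, tiny_hmm):
        design, session, _ = tiny_hmm
        with pytest.raises(ValueError, match="empty"):
            session_loglik(replace(session, trials=()), design.params,
                           design.scheme)


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, small_hmm):
        design, session, _ = small_hmm
        rindex, classes, _, tds = prepare_session(session, design.scheme)
        pack = _HMMPack(rindex.size, len(classes))
        rng = np.random.default_rng(3)
        x0 = rng.normal(0, 0.5, pack.size)
        x0[:rindex.size] = np.log(0.03) + rng.normal(0, 0.3, rindex.size)
        num = approx_fprime(x0, lambda x: _hmm_objective(x, pack, tds)[0], 1e-6)
        ana = _hmm_objective(x0, pack, tds)[1]
        assert np.allclose(num, ana, rtol=1e-4, atol=1e-4)


class TestFit:
    def test_parameter_count_formula(self, study_hmm):
        design, _, _ = study_hmm
        # 15 + 6|M| + 7|N| with |M|=1 class present and |N|=10 neurons
        assert design.params.n_free_parameters == 15 + 6 * 1 + 7 * 10

    def test_all_attend_same_stimulus_recovered_as_serial(self):
        # alpha=(1,1,1): every neuron always attends the same stimulus.  The
        # side label is not identifiable from a single condition (swapping
        # x and the two rates leaves the likelihood unchanged), but the
        # fitted attention must be extreme at every interval.
        base = hmm_preset(1, n_neurons=5, n_trials=10, n_intervals=4)
        params = HMMParams(lam=base.params.lam, Gamma=base.params.Gamma,
                           alpha=np.array([1.0, 1.0, 1.0]),
                           cif=base.params.cif)
        design = replace(base, params=params, seed=21)
        session, _ = simulate_session(design)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted, report = fit_hmm(session, design.scheme,
                                     FitConfig(n_starts=2, seed=5))
        for t in range(1, 5):
            mom = hmm_moments(fitted.lam, fitted.Gamma[1], fitted.alpha, t)
            assert min(mom.p_t, 1.0 - mom.p_t) < 0.05

    def test_mle_dominates_truth(self):
        design = hmm_preset(2, n_neurons=5, n_trials=10, n_intervals=5,
                            seed=33)
        session, _ = simulate_session(design)
        ll_true = session_loglik(session, design.params, design.scheme)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted, report = fit_hmm(session, design.scheme,
                                     FitConfig(n_starts=2, seed=1))
        assert report.loglik >= ll_true
        assert report.loglik == pytest.approx(
            session_loglik(session, fitted, design.scheme), rel=1e-8)

    def test_alpha_ordering_constraint(self):
        design = hmm_preset(3, n_neurons=4, n_trials=6, n_intervals=3,
                            seed=55)
        session, _ = simulate_session(design)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted, _ = fit_hmm(session, design.scheme,
                                FitConfig(n_starts=2, seed=2))
        assert fitted.alpha[0] >= fitted.alpha[1] >= fitted.alpha[2]

    def test_label_permutation_invariance(self, tiny_hmm):
        design, session, _ = tiny_hmm
        perm = np.array([2, 0, 1])
        params = design.params
        permuted = HMMParams(
            lam=params.lam[perm],
            Gamma={m: g[np.ix_(perm, perm)] for m, g in params.Gamma.items()},
            alpha=params.alpha[perm],
            cif=params.cif,
        )
        assert session_loglik(session, permuted, design.scheme) == \
            pytest.approx(session_loglik(session, params, design.scheme))
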