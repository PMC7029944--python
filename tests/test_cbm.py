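import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import approx_fprime

from helpers import brute_cbm_interval, trial_ll_table
from spikeattn import (CBMParams, FitConfig, HMMParams, cbm_interval_loglik,
                       cbm_session_loglik, fit_cbm, session_loglik)
from spikeattn.cbm import _CBMPack, _cbm_objective
from spikeattn.fitbase import prepare_session
from spikeattn.simulate import cbm_preset, simulate_session


def _with_attention(design, p, rho):
    I = design.n_intervals
    params = CBMParams(
        p1=p, rho1=rho,
        p={1: {t: p for t in range(2, I + 1)}},
        rho={1: {t: rho for t in range(2, I + 1)}},
        cif=design.params.cif, n_intervals=I,
    )
    return replace(design, params=params)


class TestIntervalLikelihood:
    def test_rho_zero_reduces_to_independent_mixture(self, small_cbm):
        design, session, _ = small_cbm
        d0 = _with_attention(design, 0.45, 0.0)
        trial = session.trials[0]
        ll = trial_ll_table(trial, session, design.params.cif)
        for t in (1, 2, 3):
            expect = np.sum(np.log(
                0.45 * np.exp(ll[:, t - 1, 1]) + 0.55 * np.exp(ll[:, t - 1, 0])))
            assert cbm_interval_loglik(trial, session, t, d0.params,
                                       design.scheme) == pytest.approx(expect)

    def test_single_neuron_rho_irrelevant(self, small_cbm):
        # with one neuron the binomial and fully-correlated components agree
        design, session, _ = small_cbm
        trial = session.trials[0]
        one = replace(trial, trains={"n00": trial.trains["n00"]})
        v0 = cbm_interval_loglik(one, session, 2,
                                 _with_attention(design, 0.3, 0.0).params,
                                 design.scheme)
        v1 = cbm_interval_loglik(one, session, 2,
                                 _with_attention(design, 0.3, 1.0).params,
                                 design.scheme)
        assert v0 == pytest.approx(v1)

    def test_matches_component_assignment_enumeration(self, small_cbm):
        design, session, _ = small_cbm
        for trial in session.trials:
            for t in (1, 2, 3):
                expect, _, _, _ = brute_cbm_interval(trial, session, t,
                                                     design.params,
                                                     design.scheme)
                assert cbm_interval_loglik(
                    trial, session, t, design.params, design.scheme
                ) == pytest.approx(expect, rel=1e-9)

    def test_flat_when_rates_equal(self, small_cbm):
        # identical rates for both stimuli: likelihood independent of (p, rho)
        design, session, _ = small_cbm
        from spikeattn.point_process import CIFParams
        flat_cif = CIFParams(
            rates={n: {k: 0.03 for k in tbl}
                   for n, tbl in design.params.cif.rates.items()},
            beta=design.params.cif.beta)
        trial = session.trials[0]
        vals = set()
        for p, rho in [(0.1, 0.0), (0.7, 0.5), (0.45, 1.0)]:
            d = _with_attention(design, p, rho)
            params = CBMParams(p1=d.params.p1, rho1=d.params.rho1,
                               p=d.params.p, rho=d.params.rho,
                               cif=flat_cif, n_intervals=3)
            vals.add(round(cbm_interval_loglik(trial, session, 2, params,
                                               design.scheme), 9))
        assert len(vals) == 1


class TestSessionLikelihood:
    def test_sums_over_trials_and_intervals(self, small_cbm):
        design, session, _ = small_cbm
        expect = sum(
            cbm_interval_loglik(tr, session, t, design.params, design.scheme)
            for tr in session.trials for t in (1, 2, 3))
        assert cbm_session_loglik(session, design.params, design.scheme) == \
            pytest.approx(expect)

    def test_independent_subcase_matches_hmm(self, small_cbm):
        # rho=0 equals an HMM with equal alphas: neurons iid Bernoulli(p)
        design, session, _ = small_cbm
        p = 0.45
        cbm = _with_attention(design, p, 0.0)
        pi = np.array([0.2, 0.3, 0.5])
        hmm = HMMParams(lam=pi, Gamma={1: np.tile(pi, (3, 1))},
                        alpha=np.array([p, p, p]), cif=design.params.cif)
        assert cbm_session_loglik(session, cbm.params, design.scheme) == \
            pytest.approx(session_loglik(session, hmm, design.scheme))

    def test_fully_correlated_subcase_matches_hmm(self, small_cbm):
        # rho=1 equals an iid-state HMM whose states are the shared draw:
        # pi=(p, 1-p, 0) with alpha=(1, 0, .)
        design, session, _ = small_cbm
        p = 0.3
        cbm = _with_attention(design, p, 1.0)
        pi = np.array([p, 1.0 - p, 0.0])
        hmm = HMMParams(lam=pi, Gamma={1: np.tile(pi, (3, 1))},
                        alpha=np.array([1.0, 0.0, 0.5]),
                        cif=design.params.cif)
        assert cbm_session_loglik(session, cbm.params, design.scheme) == \
            pytest.approx(session_loglik(session, hmm, design.scheme))


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, small_cbm):
        design, session, _ = small_cbm
        rindex, classes, _, tds = prepare_session(session, design.scheme)
        pack = _CBMPack(rindex.size, len(classes), session.n_intervals)
        rng = np.random.default_rng(8)
        x0 = rng.normal(0, 0.5, pack.size)
        x0[:rindex.size] = np.log(0.03) + rng.normal(0, 0.3, rindex.size)
        num = approx_fprime(x0, lambda x: _cbm_objective(x, pack, tds)[0], 1e-6)
        ana = _cbm_objective(x0, pack, tds)[1]
        assert np.allclose(num, ana, rtol=1e-4, atol=1e-4)


class TestFit:
    def test_parameter_count_formula(self, study_cbm):
        design, _, _ = study_cbm
        # 12 + 2|M|(I-1) + 7|N| with |M|=1, I=5, |N|=10
        assert design.params.n_free_parameters == 12 + 2 * 1 * 4 + 7 * 10

    def test_parameter_budget_enforced(self, study_cbm):
        design, session, _ = study_cbm
        with pytest.raises(ValueError, match="budget"):
            fit_cbm(session, design.scheme, FitConfig(n_starts=1),
                    attention_param_budget=4)

    def test_mle_dominates_truth(self):
        design = cbm_preset(1, n_neurons=5, n_trials=10, n_intervals=4,
                            seed=77)
        session, _ = simulate_session(design)
        ll_true = cbm_session_loglik(session, design.params, design.scheme)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted, report = fit_cbm(session, design.scheme,
                                     FitConfig(n_starts=2, seed=3))
        assert report.loglik >= ll_true
        assert report.loglik == pytest.approx(
            cbm_session_loglik(session, fitted, design.scheme), rel=1e-8)

    def test_full_correlation_recovered(self):
        # rho=1: every interval has all neurons in agreement, fitted rho -> 1
        design = cbm_preset(2, n_neurons=8, n_trials=15, n_intervals=3,
                            seed=91)
        design = _with_attention(design, 0.3, 1.0)
        session, _ = simulate_session(design)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted, report = fit_cbm(session, design.scheme,
                                     FitConfig(n_starts=2, seed=4))
        rhos = [fitted.rho_at(t, 1) for t in range(1, 4)]
        assert np.median(rhos) > 0.8
        assert report.boundary_flags  # near-boundary estimates are reported
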