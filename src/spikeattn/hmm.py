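"""Three-state hidden Markov model of population attention.

A latent attentional regime ``C_t`` (three states, e.g. mostly-contra,
mixed, mostly-ipsi) evolves over the ``I`` analysis intervals of each trial
with initial distribution ``lambda`` (shared across conditions) and a
per-condition-class transition matrix ``Gamma_m``.  Conditional on the
state, each recorded neuron independently attends the contralateral
stimulus with probability ``alpha_{C_t}``, and its spikes follow the
point-process model of :mod:`spikeattn.point_process` with the base rate
selected by the attended stimulus.

Marginally the attention count at interval ``t`` is a mixture of three
binomials with weights ``pi_t = lambda Gamma^{t-1}``; the induced attention
probability ``p_t = pi_t . alpha`` and pairwise correlation ``rho_t`` are
the model's prior serial-vs-parallel summaries.

Fitting is direct maximum likelihood over all parameters (rates, history
weights, lambda, Gamma_m, alpha) with the attention indicators and hidden
states marginalized out by the forward recursion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize

from ._fitcore import (TrialData, cif_backward, cif_tables,
                       forward_backward_core, mixture_emissions)
from .fitbase import (FitConfig, FitReport, contra_split, empirical_log_rates,
                      logit, prepare_session, sigmoid, softmax)
from .point_process import CIFParams, N_LAGS
from .session import ConditionScheme, Session, Trial

__all__ = ["HMMParams", "Moments", "state_distribution", "hmm_moments",
           "trial_state_loglik", "session_loglik", "fit_hmm"]

N_STATES = 3


@dataclass(frozen=True)
class HMMParams:
    """Parameters of the attention HMM.

    ``Gamma`` maps a condition class id to its 3x3 row-stochastic transition
    matrix; ``lam`` and ``alpha`` are shared across classes.
    """

    lam: np.ndarray
    Gamma: Mapping[int, np.ndarray]
    alpha: np.ndarray
    cif: CIFParams

    def __post_init__(self) -> None:
        lam = np.asarray(self.lam, dtype=float)
        alpha = np.asarray(self.alpha, dtype=float)
        if lam.shape != (N_STATES,) or abs(lam.sum() - 1) > 1e-8 or np.any(lam < 0):
            raise ValueError("lam must be a distribution over 3 states")
        if alpha.shape != (N_STATES,) or np.any((alpha < 0) | (alpha > 1)):
            raise ValueError("alpha must be 3 probabilities")
        G = {int(m): np.asarray(g, dtype=float) for m, g in self.Gamma.items()}
        for m, g in G.items():
            if g.shape != (N_STATES, N_STATES) or np.any(g < 0) or \
                    np.max(np.abs(g.sum(axis=1) - 1)) > 1e-8:
                raise ValueError(f"Gamma[{m}] must be 3x3 row-stochastic")
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "Gamma", G)

    @property
    def n_free_parameters(self) -> int:
        """Statistical dimension: 15 + 6|M| + 7|N| (2 for lambda, 6 per
        transition matrix, 3 attention probabilities, 7 rates per neuron,
        10 shared history weights)."""
        return 15 + 6 * len(self.Gamma) + 7 * len(self.cif.rates)


@dataclass(frozen=True)
class Moments:
    """Per-interval attention probability and pairwise correlation."""

    p_t: float
    rho_t: float | None
    rho_defined: bool = True


def state_distribution(lam, Gamma, t: int) -> np.ndarray:
    """Distribution ``pi_t = lam Gamma^{t-1}`` of the hidden state at t >= 1."""
    if t < 1:
        raise ValueError("intervals are numbered from 1")
    lam = np.asarray(lam, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    return lam @ np.linalg.matrix_power(Gamma, t - 1)


def hmm_moments(lam, Gamma, alpha, t: int) -> Moments:
    """Attention probability p_t and correlation rho_t at interval t.

    p_t = pi_t . alpha;  rho_t = (pi_t . alpha^2 - p_t^2) / (p_t (1 - p_t)).
    The correlation is non-negative (it is driven purely by the shared
    hidden state) and undefined when p_t is 0 or 1.
    """
    alpha = np.asarray(alpha, dtype=float)
    pi_t = state_distribution(lam, Gamma, t)
    p = float(pi_t @ alpha)
    var = p * (1.0 - p)
    if var <= 0.0:
        return Moments(p_t=p, rho_t=None, rho_defined=False)
    cov = float(pi_t @ alpha**2) - p * p
    return Moments(p_t=p, rho_t=cov / var, rho_defined=True)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _emission_table(trial: Trial, session: Session, params: HMMParams,
                    scheme: ConditionScheme):
    """(I, 3) table of log P(y_t^{N_k} | C_t = c) for one trial."""
    from ._fitcore import build_rate_index, build_trial_data
    from .session import condition_class

    rindex = build_rate_index(session)
    logr = np.array([np.log(params.cif.rates[nid][key])
                     for nid, key in rindex.entries])
    cls = condition_class(trial.condition, scheme)
    td = build_trial_data(trial, session, rindex, scheme, (cls,))
    ll, _, _, _ = cif_tables(td, logr, params.cif.beta)
    logB, w1 = mixture_emissions(ll, params.alpha)
    return logB, ll, w1, td


def trial_state_loglik(trial: Trial, session: Session, t: int, c: int,
                       params: HMMParams, scheme: ConditionScheme) -> float:
    """log P(y_t^{N_k} | C_t = c): the per-state mixture emission."""
    if not (1 <= t <= session.n_intervals):
        raise ValueError(f"interval {t} out of range 1..{session.n_intervals}")
    if not (1 <= c <= N_STATES):
        raise ValueError(f"hidden state {c} out of range 1..{N_STATES}")
    logB, _, _, _ = _emission_table(trial, session, params, scheme)
    return float(logB[t - 1, c - 1])


def session_loglik(session: Session, params: HMMParams,
                   scheme: ConditionScheme | None = None) -> float:
    """Marginal log likelihood of all trials, hidden structure summed out."""
    scheme = scheme or ConditionScheme()
    from .session import condition_class

    if not session.trials:
        raise ValueError(f"session {session.session_id} is empty")
    total = 0.0
    for tr in session.trials:
        cls = condition_class(tr.condition, scheme)
        if cls not in params.Gamma:
            raise ValueError(
                f"trial {tr.trial_id}: no transition matrix for class {cls}"
            )
        logB, _, _, _ = _emission_table(tr, session, params, scheme)
        ll, _, _ = forward_backward_core(logB, params.lam, params.Gamma[cls])
        if not np.isfinite(ll):
            raise FloatingPointError(
                f"non-finite log likelihood in trial {tr.trial_id}"
            )
        total += ll
    return total


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

class _HMMPack:
    """Flat packing [log r | beta | u_lam | u_Gamma (9 per class) | t_alpha]."""

    def __init__(self, n_rates: int, n_classes: int):
        self.n_rates = n_rates
        self.n_classes = n_classes
        self.size = n_rates + N_LAGS + N_STATES + 9 * n_classes + N_STATES

    def unpack(self, x: np.ndarray):
        R, M = self.n_rates, self.n_classes
        o = 0
        logr = x[o:o + R]; o += R
        beta = x[o:o + N_LAGS]; o += N_LAGS
        u_lam = x[o:o + N_STATES]; o += N_STATES
        u_G = x[o:o + 9 * M].reshape(M, N_STATES, N_STATES); o += 9 * M
        t_alpha = x[o:o + N_STATES]
        return logr, beta, u_lam, u_G, t_alpha


def _hmm_objective(x: np.ndarray, pack: _HMMPack, tds: list[TrialData]):
    """Negative log likelihood and exact gradient over all trials."""
    logr, beta, u_lam, u_G, t_alpha = pack.unpack(x)
    lam = softmax(u_lam)
    Gammas = softmax(u_G, axis=2)
    alpha = sigmoid(t_alpha)
    dlogr = np.zeros_like(logr)
    dbeta = np.zeros(N_LAGS)
    dlam = np.zeros(N_STATES)
    dG = np.zeros_like(u_G)
    dalpha_t = np.zeros(N_STATES)
    total = 0.0
    for td in tds:
        ll, g, G, r = cif_tables(td, logr, beta)
        logB, w1 = mixture_emissions(ll, alpha)
        llk, gamma, xi = forward_backward_core(logB, lam, Gammas[td.class_pos])
        total += llk
        # emission gradients via smoothing posteriors
        dll = np.empty_like(ll)
        dll[:, :, 1] = np.einsum("tc,cit->it", gamma, w1)
        dll[:, :, 0] = np.einsum("tc,cit->it", gamma, 1.0 - w1)
        dalpha_t += np.einsum("tc,cit->c", gamma, w1 - alpha[:, None, None])
        dlam += gamma[0] - lam
        dG[td.class_pos] += xi - Gammas[td.class_pos] * xi.sum(axis=1)[:, None]
        dr, db = cif_backward(td, dll, g, G, r, pack.n_rates)
        dlogr += dr
        dbeta += db
    grad = np.concatenate([dlogr, dbeta, dlam, dG.ravel(), dalpha_t])
    return -total, -grad


def _order_states(lam, Gamma, alpha):
    """Resolve label switching: sort states by alpha, descending."""
    perm = np.argsort(-np.asarray(alpha))
    already = bool(np.all(perm == np.arange(N_STATES)))
    lam = np.asarray(lam)[perm]
    alpha = np.asarray(alpha)[perm]
    Gamma = {m: g[np.ix_(perm, perm)] for m, g in Gamma.items()}
    return lam, Gamma, alpha, not already


def _start_vector(pack: _HMMPack, logr0: np.ndarray, split: np.ndarray,
                  rng: np.random.Generator, first: bool) -> np.ndarray:
    x = np.zeros(pack.size)
    R = pack.n_rates
    x[:R] = logr0 + (split if first else rng.normal(0.0, 0.4, R))
    # beta starts at 0 (no history effect)
    o = R + N_LAGS
    x[o:o + N_STATES] = 0.0 if first else rng.normal(0.0, 0.5, N_STATES)
    o += N_STATES
    g0 = np.eye(N_STATES) * 1.5  # mild diagonal boost: sticky states
    for m in range(pack.n_classes):
        x[o:o + 9] = (g0 + (0.0 if first else rng.normal(0.0, 0.5, (3, 3)))).ravel()
        o += 9
    a0 = np.array([0.9, 0.5, 0.1]) if first else \
        np.sort(rng.uniform(0.05, 0.95, N_STATES))[::-1]
    x[o:o + N_STATES] = logit(a0)
    return x


def fit_hmm(session: Session, scheme: ConditionScheme | None = None,
            config: FitConfig | None = None) -> tuple[HMMParams, FitReport]:
    """Maximum-likelihood fit of the attention HMM to one session."""
    scheme = scheme or ConditionScheme()
    config = config or FitConfig()
    rindex, class_order, dropped, tds = prepare_session(session, scheme)
    if dropped:
        warnings.warn(
            f"session {session.session_id}: no trials for condition "
            f"classes {dropped}; they are not modelled", stacklevel=2
        )
    pack = _HMMPack(rindex.size, len(class_order))
    logr0 = empirical_log_rates(session, rindex)
    split = contra_split(rindex)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.log_rate_bounds
    bounds = ([(lo, hi)] * rindex.size
              + [(-config.beta_bound, config.beta_bound)] * N_LAGS
              + [(-config.logit_bound, config.logit_bound)]
              * (pack.size - rindex.size - N_LAGS))
    best = None
    start_logliks = []
    for s in range(config.n_starts):
        x0 = _start_vector(pack, logr0, split, rng, first=(s == 0))
        res = optimize.minimize(
            _hmm_objective, x0, args=(pack, tds), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": config.max_iter, "gtol": config.gtol,
                     "ftol": config.ftol},
        )
        start_logliks.append(-float(res.fun))
        if best is None or -res.fun > -best.fun:
            best = res
    logr, beta, u_lam, u_G, t_alpha = pack.unpack(best.x)
    lam = softmax(u_lam)
    Gamma = {cls: softmax(u_G[i], axis=1)
             for i, cls in enumerate(class_order)}
    alpha = sigmoid(t_alpha)
    lam, Gamma, alpha, reordered = _order_states(lam, Gamma, alpha)
    rates: dict[str, dict[str, float]] = {}
    for (nid, key), lr in zip(rindex.entries, logr):
        rates.setdefault(nid, {})[key] = float(np.exp(lr))
    params = HMMParams(lam=lam, Gamma=Gamma, alpha=alpha,
                       cif=CIFParams(rates=rates, beta=beta))
    report = FitReport(
        loglik=-float(best.fun),
        n_iter=int(best.nit),
        converged=bool(best.success),
        message=str(best.message),
        start_logliks=start_logliks,
        n_starts=config.n_starts,
        alpha_ordering_applied=reordered,
        n_free_parameters=params.n_free_parameters,
        dropped_classes=dropped,
    )
    if not best.success:
        warnings.warn(
            f"HMM fit did not formally converge: {best.message}; "
            "returning best parameters found", stacklevel=2
        )
    return params, report
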