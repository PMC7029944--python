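"""Posterior decoding of hidden states and per-neuron attended stimuli.

Given fitted parameters and the spike trains of one trial, decoding
computes, per analysis interval:

* the smoothing posterior over the latent structure — the three attentional
  regimes of the HMM (via forward-backward over the whole trial), or the
  binomial-vs-fully-correlated component of the CBM (intervals independent);
* the marginal posterior probability that each neuron attended the
  contralateral stimulus;
* the posterior PMF of the number of neurons attending the contralateral
  stimulus — a mixture of Poisson binomials across HMM states, or of a
  Poisson binomial and a modified Bernoulli on {0, n} for the CBM — and its
  deviation statistic D_n.

All outputs are probabilities; no hard state or attention labels are
assigned, so ties never need arbitrary breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fitcore import forward_backward_core
from .cbm import CBMParams, _interval_logliks, _trial_tables
from .distributions import AttentionPMF, dn, poisson_binomial_pmf
from .hmm import HMMParams, _emission_table
from .session import ConditionScheme, Session, Trial, condition_class

__all__ = ["DecodeResult", "forward_backward", "attention_posterior_hmm",
           "decoded_count_pmf_hmm", "decode_trial_hmm", "decode_cbm",
           "decode_session"]

DEFAULT_MIN_NEURONS = 10


@dataclass(frozen=True)
class DecodeResult:
    """Posterior decoding of one trial."""

    trial_id: str
    neurons: tuple[str, ...]
    state_post: np.ndarray          # (I, n_components)
    attn_post: np.ndarray           # (n, I): P(X_t^i = 1 | data)
    count_pmfs: tuple[AttentionPMF, ...]  # one per interval
    d_n: np.ndarray                 # (I,)
    loglik: float

    def to_dict(self) -> dict:
        return {
            "trial_id": self.trial_id,
            "neurons": list(self.neurons),
            "state_post": self.state_post.tolist(),
            "attn_post": {nid: self.attn_post[i].tolist()
                          for i, nid in enumerate(self.neurons)},
            "count_pmf": [pmf.mass.tolist() for pmf in self.count_pmfs],
            "dn": self.d_n.tolist(),
            "loglik": self.loglik,
        }


def forward_backward(trial: Trial, session: Session, params: HMMParams,
                     scheme: ConditionScheme | None = None
                     ) -> tuple[np.ndarray, float]:
    """Smoothing posterior P(C_t | y_{1:I}) over the 3 states, plus the
    trial's marginal log likelihood (the forward normalizer)."""
    scheme = scheme or ConditionScheme()
    cls = condition_class(trial.condition, scheme)
    logB, _, _, _ = _emission_table(trial, session, params, scheme)
    loglik, gamma, _ = forward_backward_core(logB, params.lam, params.Gamma[cls])
    return gamma, loglik


def attention_posterior_hmm(trial: Trial, session: Session,
                            state_post: np.ndarray, params: HMMParams,
                            scheme: ConditionScheme | None = None
                            ) -> np.ndarray:
    """Marginal per-neuron attention posterior P(X_t^i = 1 | y_{1:I}).

    Mixes the state-conditional posteriors (which depend on the neuron's own
    interval data and alpha_c) over the smoothing state posterior.
    """
    scheme = scheme or ConditionScheme()
    _, _, w1, _ = _emission_table(trial, session, params, scheme)
    # w1: (C, n, I); state_post: (I, C)
    return np.einsum("tc,cit->it", state_post, w1)


def decoded_count_pmf_hmm(trial: Trial, session: Session,
                          state_post: np.ndarray, params: HMMParams,
                          scheme: ConditionScheme | None = None
                          ) -> tuple[tuple[AttentionPMF, ...], np.ndarray]:
    """Posterior attention-count PMF per interval: a mixture of three
    Poisson binomials (one per hidden state), and its D_n values."""
    scheme = scheme or ConditionScheme()
    _, _, w1, _ = _emission_table(trial, session, params, scheme)
    C, n, I = w1.shape
    pmfs = []
    for t in range(I):
        mass = np.zeros(n + 1)
        for c in range(C):
            mass += state_post[t, c] * poisson_binomial_pmf(w1[c, :, t]).mass
        pmfs.append(AttentionPMF(mass / mass.sum()))
    d = np.array([dn(p) for p in pmfs])
    return tuple(pmfs), d


def decode_trial_hmm(trial: Trial, session: Session, params: HMMParams,
                     scheme: ConditionScheme | None = None) -> DecodeResult:
    """Full HMM decoding of one trial."""
    scheme = scheme or ConditionScheme()
    state_post, loglik = forward_backward(trial, session, params, scheme)
    attn = attention_posterior_hmm(trial, session, state_post, params, scheme)
    pmfs, d = decoded_count_pmf_hmm(trial, session, state_post, params, scheme)
    return DecodeResult(
        trial_id=trial.trial_id, neurons=tuple(sorted(trial.neuron_ids)),
        state_post=state_post, attn_post=attn, count_pmfs=pmfs, d_n=d,
        loglik=loglik,
    )


def decode_cbm(trial: Trial, session: Session, params: CBMParams,
               scheme: ConditionScheme | None = None) -> DecodeResult:
    """CBM decoding of one trial; intervals are decoded independently.

    ``state_post[t]`` holds the posterior over (binomial, fully-correlated)
    components.  The count PMF mixes a Poisson binomial (independent
    per-neuron posteriors) with a modified Bernoulli on {0, n} whose success
    probability is the posterior of the shared attention bit.
    """
    scheme = scheme or ConditionScheme()
    ll, cls = _trial_tables(trial, session, params, scheme)
    n = ll.shape[0]
    I = session.n_intervals
    state_post = np.empty((I, 2))
    attn = np.empty((n, I))
    pmfs = []
    total = 0.0
    for t in range(1, I + 1):
        p, rho = params.p_at(t, cls), params.rho_at(t, cls)
        logP, w1, v1, u_bin = _interval_logliks(ll[:, t - 1, :], p, rho)
        total += logP
        u_ber = 1.0 - u_bin
        state_post[t - 1] = (u_bin, u_ber)
        attn[:, t - 1] = u_bin * w1 + u_ber * v1
        mass = u_bin * poisson_binomial_pmf(w1).mass
        mass[0] += u_ber * (1.0 - v1)
        mass[n] += u_ber * v1
        pmfs.append(AttentionPMF(mass / mass.sum()))
    d = np.array([dn(pmf) for pmf in pmfs])
    return DecodeResult(
        trial_id=trial.trial_id, neurons=tuple(sorted(trial.neuron_ids)),
        state_post=state_post, attn_post=attn, count_pmfs=tuple(pmfs), d_n=d,
        loglik=total,
    )


def decode_session(session: Session, params: HMMParams | CBMParams,
                   scheme: ConditionScheme | None = None,
                   min_neurons: int = DEFAULT_MIN_NEURONS
                   ) -> list[DecodeResult]:
    """Decode every trial with at least ``min_neurons`` simultaneously
    recorded neurons (posterior D_n is too noisy below that; the threshold
    applies to decoding reports only, never to fitting)."""
    scheme = scheme or ConditionScheme()
    out = []
    for tr in session.trials:
        if len(tr.neuron_ids) < min_neurons:
            continue
        if isinstance(params, HMMParams):
            out.append(decode_trial_hmm(tr, session, params, scheme))
        else:
            out.append(decode_cbm(tr, session, params, scheme))
    return out
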