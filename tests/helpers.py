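"""Brute-force oracles used by the tests.

Everything here is written as plain loops / exhaustive enumeration,
independent of the package's vectorized likelihood code, so it can serve as
ground truth on tiny problems.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

from spikeattn.session import condition_class, discretize

N_LAGS = 10


def brute_interval_loglik(counts, start, stop, r, beta):
    """Per-bin Bernoulli/Poisson product: log h at spike bins minus sum h."""
    ll = 0.0
    for b in range(start, stop):
        expo = sum(beta[j - 1] * counts[b - j] for j in range(1, N_LAGS + 1))
        h = r * math.exp(expo)
        if counts[b]:
            ll += math.log(h)
        ll -= h
    return ll


def trial_ll_table(trial, session, cif):
    """ll[i][t][x] per neuron (sorted), interval (0-based), attended x."""
    neurons = sorted(trial.neuron_ids)
    I = session.n_intervals
    L = session.interval_length_ms
    start, _ = session.analysis_window
    table = np.empty((len(neurons), I, 2))
    for i, nid in enumerate(neurons):
        disc = discretize(trial.trains[nid], session)
        off = start - disc.t0_ms
        for t in range(I):
            for x in (0, 1):
                r = cif.rate(nid, trial.condition, x)
                table[i, t, x] = brute_interval_loglik(
                    disc.counts, off + t * L, off + (t + 1) * L, r, cif.beta)
    return table


def brute_hmm_trial(trial, session, params, scheme):
    """Exhaustive sum over hidden-state paths and attention assignments.

    Returns (loglik, state_post (I, 3), attn_post (n, I), count_pmf list).
    """
    ll = trial_ll_table(trial, session, params.cif)
    n, I, _ = ll.shape
    lik = np.exp(ll - ll.max())  # common scaling; restored at the end
    scale = float(ll.max())
    cls = condition_class(trial.condition, scheme)
    Gamma = params.Gamma[cls]
    alpha = params.alpha
    total = 0.0
    state_post = np.zeros((I, 3))
    attn_post = np.zeros((n, I))
    count_joint = [np.zeros(n + 1) for _ in range(I)]
    for path in product(range(3), repeat=I):
        prior = params.lam[path[0]]
        for t in range(1, I):
            prior *= Gamma[path[t - 1], path[t]]
        if prior == 0.0:
            continue
        for flat in product((0, 1), repeat=n * I):
            x = np.array(flat).reshape(n, I)
            w = prior
            for t in range(I):
                c = path[t]
                for i in range(n):
                    pa = alpha[c] if x[i, t] == 1 else 1.0 - alpha[c]
                    w *= pa * lik[i, t, x[i, t]]
            total += w
            for t in range(I):
                state_post[t, path[t]] += w
                count_joint[t][int(x[:, t].sum())] += w
            attn_post += w * x
    loglik = math.log(total) + scale * n * I
    state_post /= total
    attn_post /= total
    count_pmfs = [cj / total for cj in count_joint]
    return loglik, state_post, attn_post, count_pmfs


def brute_cbm_interval(trial, session, t, params, scheme):
    """Enumeration over components x attention assignments for interval t.

    Returns (loglik, comp_post (2,), attn_post (n,), count_pmf).
    """
    ll = trial_ll_table(trial, session, params.cif)
    n = ll.shape[0]
    lik = np.exp(ll)
    cls = condition_class(trial.condition, scheme)
    p = params.p_at(t, cls)
    rho = params.rho_at(t, cls)
    total = 0.0
    comp_post = np.zeros(2)
    attn_post = np.zeros(n)
    count = np.zeros(n + 1)
    for comp in (0, 1):
        wc = (1.0 - rho) if comp == 0 else rho
        for flat in product((0, 1), repeat=n):
            x = np.array(flat)
            if comp == 0:
                px = np.prod(np.where(x == 1, p, 1.0 - p))
            else:  # fully correlated: all share one draw
                if len(set(flat)) > 1:
                    continue
                px = p if flat[0] == 1 else 1.0 - p
            w = wc * px
            for i in range(n):
                w *= lik[i, t - 1, x[i]]
            total += w
            comp_post[comp] += w
            attn_post += w * x
            count[int(x.sum())] += w
    return math.log(total), comp_post / total, attn_post / total, count / total


def brute_poisson_binomial(probs):
    """2^n enumeration of a sum of independent Bernoullis."""
    n = len(probs)
    mass = np.zeros(n + 1)
    for flat in product((0, 1), repeat=n):
        w = 1.0
        for x, p in zip(flat, probs):
            w *= p if x else 1.0 - p
        mass[sum(flat)] += w
    return mass
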