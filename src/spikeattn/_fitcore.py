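"""Internal vectorized likelihood machinery shared by the HMM and CBM fitters.

Everything here works on precomputed per-trial arrays so that one likelihood
(+ gradient) evaluation is a handful of numpy operations:

* ``TrialData`` caches, per trial, the binary spike matrix over the analysis
  window, the lagged spike tensor feeding the history kernel, per-interval
  spike counts, and the indices into the flat base-rate vector for the two
  attention alternatives.
* ``cif_tables`` turns (log-rates, beta) into the table
  ``ll[i, t, x] = log P(y_t^i | X_t^i = x)`` using the sufficient-statistic
  decomposition ``ll = K log r + S - r G`` (K spike count, S history log-sum
  over spike bins, G integrated history factor), and ``cif_backward``
  back-propagates a gradient w.r.t. that table onto log-rates and beta.
* ``forward_backward_core`` is a scaled forward-backward pass over the three
  hidden states returning the log likelihood, smoothing posteriors and
  summed two-slice posteriors (the quantities whose standard identities give
  exact likelihood gradients).

Gradients returned here are exact; the unit tests check them against finite
differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .point_process import N_LAGS, rate_key
from .session import Session, Trial, ConditionScheme, condition_class, discretize

__all__ = [
    "RateIndex",
    "TrialData",
    "build_rate_index",
    "build_trial_data",
    "cif_tables",
    "cif_backward",
    "mixture_emissions",
    "forward_backward_core",
]


@dataclass(frozen=True)
class RateIndex:
    """Flat indexing of the distinct (neuron, rate-key) base-rate parameters."""

    entries: tuple[tuple[str, str], ...]  # (neuron_id, rate_key)

    @property
    def size(self) -> int:
        return len(self.entries)

    def position(self, neuron: str, key: str) -> int:
        return self.entries.index((neuron, key))


def build_rate_index(session: Session) -> RateIndex:
    """Collect the rate parameters actually identified by the session.

    A (neuron, key) slot is included iff some trial exposes that neuron to
    that stimulus/side; a full 12-condition session yields 7 slots/neuron.
    """
    seen: list[tuple[str, str]] = []
    for tr in session.trials:
        keys = (
            rate_key(tr.condition.contra, "contra"),
            rate_key(tr.condition.ipsi, "ipsi"),
        )
        for nid in sorted(tr.neuron_ids):
            for k in keys:
                if (nid, k) not in seen:
                    seen.append((nid, k))
    return RateIndex(tuple(sorted(seen)))


@dataclass
class TrialData:
    """Precomputed arrays for one trial (neurons x bins over the window)."""

    trial_id: str
    neurons: tuple[str, ...]
    spikes: np.ndarray        # (n, B) float, analysis-window bins only
    lags: np.ndarray          # (n, B, N_LAGS) spike history at lags 1..10
    K: np.ndarray             # (n, I) spike count per interval
    S_lag: np.ndarray         # (n, I, N_LAGS) sum of lag indicators at spike bins
    rate_idx: np.ndarray      # (n, 2) flat rate index for x=0, x=1
    class_pos: int            # 0-based position of the trial's condition class
    n_intervals: int
    interval_len: int


def build_trial_data(trial: Trial, session: Session, rindex: RateIndex,
                     scheme: ConditionScheme,
                     class_order: tuple[int, ...]) -> TrialData:
    start, end = session.analysis_window
    B = end - start
    I = session.n_intervals
    L = session.interval_length_ms
    neurons = tuple(sorted(trial.neuron_ids))
    n = len(neurons)
    spikes = np.zeros((n, B))
    lags = np.zeros((n, B, N_LAGS))
    for i, nid in enumerate(neurons):
        disc = discretize(trial.trains[nid], session)
        full = disc.counts.astype(float)       # covers [start - lead, end)
        off = start - disc.t0_ms               # bins of history lead
        if off < N_LAGS:
            raise ValueError(
                f"trial {trial.trial_id}: only {off} ms of pre-window history; "
                f"{N_LAGS} required"
            )
        spikes[i] = full[off:]
        for j in range(1, N_LAGS + 1):
            lags[i, :, j - 1] = full[off - j:off - j + B]
    K = spikes.reshape(n, I, L).sum(axis=2)
    S_lag = (lags * spikes[:, :, None]).reshape(n, I, L, N_LAGS).sum(axis=2)
    key1 = rate_key(trial.condition.contra, "contra")
    key0 = rate_key(trial.condition.ipsi, "ipsi")
    rate_idx = np.array(
        [[rindex.position(nid, key0), rindex.position(nid, key1)]
         for nid in neurons],
        dtype=np.int64,
    )
    cls = condition_class(trial.condition, scheme)
    return TrialData(
        trial_id=trial.trial_id, neurons=neurons, spikes=spikes, lags=lags,
        K=K, S_lag=S_lag, rate_idx=rate_idx,
        class_pos=class_order.index(cls), n_intervals=I, interval_len=L,
    )


def cif_tables(td: TrialData, log_rates: np.ndarray, beta: np.ndarray):
    """Interval log likelihood table ll[i, t, x] plus gradient intermediates."""
    n, B = td.spikes.shape
    I, L = td.n_intervals, td.interval_len
    logg = td.lags @ beta                       # (n, B)
    g = np.exp(logg)
    G = g.reshape(n, I, L).sum(axis=2)          # integrated history factor
    S = (logg * td.spikes).reshape(n, I, L).sum(axis=2)
    logr = log_rates[td.rate_idx]               # (n, 2)
    r = np.exp(logr)
    ll = (td.K[:, :, None] * logr[:, None, :]
          + S[:, :, None]
          - G[:, :, None] * r[:, None, :])      # (n, I, 2)
    return ll, g, G, r


def cif_backward(td: TrialData, dll: np.ndarray, g: np.ndarray, G: np.ndarray,
                 r: np.ndarray, n_rates: int):
    """Chain a gradient w.r.t. ll[i, t, x] back to (log-rates, beta)."""
    n, B = td.spikes.shape
    I, L = td.n_intervals, td.interval_len
    # d ll / d log r_{i,x} = K - r G
    coef = dll * (td.K[:, :, None] - G[:, :, None] * r[:, None, :])  # (n,I,2)
    dlogr = np.zeros(n_rates)
    np.add.at(dlogr, td.rate_idx[:, 0], coef[:, :, 0].sum(axis=1))
    np.add.at(dlogr, td.rate_idx[:, 1], coef[:, :, 1].sum(axis=1))
    # beta enters through S (coefficient a) and G (coefficient c)
    a = dll.sum(axis=2)                                     # (n, I)
    c = -(dll[:, :, 0] * r[:, None, 0] + dll[:, :, 1] * r[:, None, 1])
    a_b = np.repeat(a, L, axis=1)                           # (n, B)
    c_b = np.repeat(c, L, axis=1)
    w = a_b * td.spikes + c_b * g
    dbeta = np.einsum("nb,nbj->j", w, td.lags)
    return dlogr, dbeta


def mixture_emissions(ll: np.ndarray, alpha: np.ndarray):
    """Per-state emission log probabilities of a trial's spike trains.

    ``ll`` is the (n, I, 2) interval table; ``alpha`` the per-state attention
    probabilities.  Returns ``logB`` of shape (I, n_states) with
    logB[t, c] = sum_i log(alpha_c P(y|x=1) + (1-alpha_c) P(y|x=0)),
    and the per-neuron responsibilities w1[c, i, t] = P(x=1 | y, C=c).
    """
    with np.errstate(divide="ignore"):
        la = np.log(alpha)[:, None, None]       # (C,1,1)
        l1a = np.log1p(-alpha)[:, None, None]
    t1 = la + ll[None, :, :, 1]                 # (C, n, I)
    t0 = l1a + ll[None, :, :, 0]
    lme = np.logaddexp(t1, t0)
    w1 = np.exp(t1 - lme)
    logB = lme.sum(axis=1).T                    # (I, C)
    return logB, w1


def forward_backward_core(logB: np.ndarray, lam: np.ndarray,
                          Gamma: np.ndarray):
    """Scaled forward-backward over hidden states.

    Returns (loglik, gamma, xi_sum) where gamma[t, c] = P(C_t=c | y_{1:I})
    and xi_sum[k, l] = sum_t P(C_t=k, C_{t+1}=l | y_{1:I}).
    """
    I, C = logB.shape
    m = logB.max(axis=1)
    Bm = np.exp(logB - m[:, None])              # scaled emissions, max 1
    ahat = np.empty((I, C))
    cs = np.empty(I)
    a = lam * Bm[0]
    cs[0] = a.sum()
    if cs[0] <= 0:
        raise FloatingPointError("all-zero emission row at interval 1")
    ahat[0] = a / cs[0]
    for t in range(1, I):
        a = (ahat[t - 1] @ Gamma) * Bm[t]
        cs[t] = a.sum()
        if cs[t] <= 0:
            raise FloatingPointError(f"all-zero emission row at interval {t + 1}")
        ahat[t] = a / cs[t]
    loglik = float(np.sum(np.log(cs)) + np.sum(m))
    bhat = np.empty((I, C))
    bhat[-1] = 1.0
    xi_sum = np.zeros((C, C))
    for t in range(I - 2, -1, -1):
        nxt = Bm[t + 1] * bhat[t + 1]
        bhat[t] = (Gamma @ nxt) / cs[t + 1]
        xi_sum += (ahat[t][:, None] * Gamma * nxt[None, :]) / cs[t + 1]
    gamma = ahat * bhat
    gamma /= gamma.sum(axis=1, keepdims=True)
    return loglik, gamma, xi_sum
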