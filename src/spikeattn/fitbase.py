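"""Shared fitting infrastructure: configs, reports, transforms, warm starts.

Both latent-attention models are fitted by direct maximum likelihood on an
unconstrained parameter space: log base rates, raw history weights, softmax
logits for probability vectors (initial distribution, transition rows) and
log-odds for probabilities (per-state attention probabilities, CBM p and
rho).  Optimization uses L-BFGS-B with exact analytic gradients and a
seeded multi-start scheme; the best start by final log likelihood wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fitcore import RateIndex, build_rate_index, build_trial_data
from .session import ConditionScheme, Session, condition_class

__all__ = ["FitConfig", "FitReport", "softmax", "sigmoid", "logit"]


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for maximum-likelihood fitting."""

    n_starts: int = 5
    max_iter: int = 400
    gtol: float = 1e-5
    ftol: float = 1e-9
    seed: int = 0
    #: unconstrained-parameter box keeping probabilities off the exact
    #: boundary (log-odds ~ +-8 means p within ~3e-4 of 0/1)
    logit_bound: float = 8.0
    log_rate_bounds: tuple[float, float] = (-10.0, 2.0)
    beta_bound: float = 4.0


@dataclass
class FitReport:
    """Outcome of one multi-start maximum-likelihood fit."""

    loglik: float
    n_iter: int
    converged: bool
    message: str
    start_logliks: list[float] = field(default_factory=list)
    n_starts: int = 0
    alpha_ordering_applied: bool = False
    boundary_flags: list[str] = field(default_factory=list)
    n_free_parameters: int = 0
    dropped_classes: list[int] = field(default_factory=list)


def softmax(u: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(u - np.max(u, axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(t: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(t, dtype=float)))


def logit(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def prepare_session(session: Session, scheme: ConditionScheme):
    """Precompute trial arrays and the class/rate bookkeeping for fitting."""
    if not session.trials:
        raise ValueError(f"session {session.session_id} has no trials")
    present = sorted({condition_class(tr.condition, scheme)
                      for tr in session.trials})
    all_classes = sorted(set(scheme.classes.values()))
    dropped = [c for c in all_classes if c not in present]
    rindex = build_rate_index(session)
    class_order = tuple(present)
    tds = [build_trial_data(tr, session, rindex, scheme, class_order)
           for tr in session.trials]
    return rindex, class_order, dropped, tds


def empirical_log_rates(session: Session, rindex: RateIndex) -> np.ndarray:
    """Warm-start log rates from pooled empirical firing within the window.

    Attention is unobserved, so the pooled rate (which mixes both attended
    stimuli) only sets the scale; multi-start jitter explores around it.
    """
    start, end = session.analysis_window
    span = end - start
    counts = {e: 0.0 for e in rindex.entries}
    times = {e: 0.0 for e in rindex.entries}
    from .point_process import rate_key

    for tr in session.trials:
        keys = (rate_key(tr.condition.ipsi, "ipsi"),
                rate_key(tr.condition.contra, "contra"))
        for nid, train in tr.trains.items():
            ts = np.asarray(train.spike_times)
            k = float(np.sum((ts >= start) & (ts < end)))
            for key in keys:
                if (nid, key) in counts:
                    counts[(nid, key)] += k
                    times[(nid, key)] += span
    out = np.empty(rindex.size)
    for i, e in enumerate(rindex.entries):
        rate = counts[e] / times[e] if times[e] > 0 else 0.01
        out[i] = np.log(max(rate, 1e-4))
    return out


def contra_split(rindex: RateIndex, spread: float = 0.3) -> np.ndarray:
    """Deterministic symmetry breaker for the first optimizer start.

    The pooled empirical rates are identical for both attended stimuli, a
    saddle of the likelihood where attention parameters have zero gradient;
    nudging contralateral rates up and ipsilateral ones down (the typical
    laterality of the recordings) moves the start off it.
    """
    out = np.zeros(rindex.size)
    for i, (_, key) in enumerate(rindex.entries):
        if key.endswith(":contra"):
            out[i] = spread
        elif key.endswith(":ipsi"):
            out[i] = -spread
    return out
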