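"""Correlated binomial model (CBM) of population attention.

At each analysis interval ``t`` of a trial in condition class ``m``, the
attention indicators of the simultaneously recorded neurons follow
CBin(n, p_{t,m}, rho_{t,m}): with probability ``1 - rho`` the neurons choose
independently (Bernoulli(p) each, the binomial component), and with
probability ``rho`` they all share one Bernoulli(p) draw (the fully
correlated, modified-Bernoulli component on {0, n}).  Intervals are
independent apart from the spike-history carry-over in the intensity model,
and at ``t = 1`` the parameters are tied across conditions (attention is
initially driven by stimulus position only, before identity is perceived).

The trial likelihood of an interval mixes the two components at the level
of the spike-train probabilities; attention indicators are marginalized
analytically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize

from ._fitcore import TrialData, cif_backward, cif_tables
from .fitbase import (FitConfig, FitReport, contra_split, empirical_log_rates,
                      logit, prepare_session, sigmoid)
from .point_process import CIFParams, N_LAGS
from .session import ConditionScheme, Session, Trial, condition_class

__all__ = ["CBMParams", "cbm_interval_loglik", "cbm_session_loglik", "fit_cbm"]

#: cap on the number of attention parameters 2(|M|(I-1)+1); beyond this the
#: per-interval mixtures are hopelessly under-determined at session scale
DEFAULT_ATTENTION_PARAM_BUDGET = 128


@dataclass(frozen=True)
class CBMParams:
    """CBM parameters: per-(interval, class) attention probability and
    correlation, with the first interval tied across classes."""

    p1: float
    rho1: float
    p: Mapping[int, Mapping[int, float]]    # class -> {t >= 2: p_{t,m}}
    rho: Mapping[int, Mapping[int, float]]  # class -> {t >= 2: rho_{t,m}}
    cif: CIFParams
    n_intervals: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p1 < 1.0):
            raise ValueError("p1 must be in (0, 1)")
        if not (0.0 <= self.rho1 <= 1.0):
            raise ValueError("rho1 must be in [0, 1]")
        for m, tbl in self.p.items():
            for t, v in tbl.items():
                if not (2 <= t <= self.n_intervals):
                    raise ValueError(f"p[{m}][{t}]: t out of range")
                if not (0.0 < v < 1.0):
                    raise ValueError(f"p[{m}][{t}] must be in (0, 1)")
        for m, tbl in self.rho.items():
            for t, v in tbl.items():
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"rho[{m}][{t}] must be in [0, 1]")

    def p_at(self, t: int, cls: int) -> float:
        return self.p1 if t == 1 else float(self.p[cls][t])

    def rho_at(self, t: int, cls: int) -> float:
        return self.rho1 if t == 1 else float(self.rho[cls][t])

    @property
    def n_free_parameters(self) -> int:
        """Statistical dimension: 12 + 2|M|(I-1) + 7|N| (two attention
        parameters per class and interval beyond the shared first interval,
        7 rates per neuron, 10 history weights)."""
        M = len(self.p)
        return 12 + 2 * M * (self.n_intervals - 1) + 7 * len(self.cif.rates)


def _interval_logliks(ll_t: np.ndarray, p: float, rho: float):
    """Mixture log likelihood of one interval given the (n, 2) table ll_t.

    Returns (logP, w1, v1, u_bin): per-neuron binomial-component posteriors
    w1, shared Bernoulli-component posterior v1, and the binomial component
    weight u_bin — the responsibilities reused by gradients and decoding.
    """
    with np.errstate(divide="ignore"):
        lp, l1p = np.log(p), np.log1p(-p)
        lrho = np.log(rho) if rho > 0 else -np.inf
        l1rho = np.log1p(-rho) if rho < 1 else -np.inf
    t1 = lp + ll_t[:, 1]
    t0 = l1p + ll_t[:, 0]
    lme = np.logaddexp(t1, t0)                  # per-neuron mixture
    w1 = np.exp(t1 - lme)
    log_bin = float(lme.sum())
    s1, s0 = float(ll_t[:, 1].sum()), float(ll_t[:, 0].sum())
    log_ber = np.logaddexp(lp + s1, l1p + s0)
    v1 = float(np.exp(lp + s1 - log_ber))
    logP = np.logaddexp(l1rho + log_bin, lrho + log_ber)
    u_bin = float(np.exp(l1rho + log_bin - logP))
    return float(logP), w1, v1, u_bin


def _trial_tables(trial: Trial, session: Session, params: CBMParams,
                  scheme: ConditionScheme):
    from ._fitcore import build_rate_index, build_trial_data

    rindex = build_rate_index(session)
    logr = np.array([np.log(params.cif.rates[nid][key])
                     for nid, key in rindex.entries])
    cls = condition_class(trial.condition, scheme)
    td = build_trial_data(trial, session, rindex, scheme, (cls,))
    ll, _, _, _ = cif_tables(td, logr, params.cif.beta)
    return ll, cls


def cbm_interval_loglik(trial: Trial, session: Session, t: int,
                        params: CBMParams,
                        scheme: ConditionScheme | None = None) -> float:
    """log P(y_t^{N_k}) under the CBM mixture for interval t (1-based)."""
    scheme = scheme or ConditionScheme()
    if not (1 <= t <= session.n_intervals):
        raise ValueError(f"interval {t} out of range 1..{session.n_intervals}")
    ll, cls = _trial_tables(trial, session, params, scheme)
    logP, _, _, _ = _interval_logliks(
        ll[:, t - 1, :], params.p_at(t, cls), params.rho_at(t, cls)
    )
    if not np.isfinite(logP):
        raise FloatingPointError(
            f"non-finite CBM likelihood in trial {trial.trial_id}, interval {t}"
        )
    return logP


def cbm_session_loglik(session: Session, params: CBMParams,
                       scheme: ConditionScheme | None = None) -> float:
    """Total CBM log likelihood: sum over trials and intervals."""
    scheme = scheme or ConditionScheme()
    if not session.trials:
        raise ValueError(f"session {session.session_id} is empty")
    total = 0.0
    for tr in session.trials:
        ll, cls = _trial_tables(tr, session, params, scheme)
        for t in range(1, session.n_intervals + 1):
            logP, _, _, _ = _interval_logliks(
                ll[:, t - 1, :], params.p_at(t, cls), params.rho_at(t, cls)
            )
            if not np.isfinite(logP):
                raise FloatingPointError(
                    f"non-finite CBM likelihood in trial {tr.trial_id}, "
                    f"interval {t}"
                )
            total += logP
    return total


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

class _CBMPack:
    """Flat packing [log r | beta | t_p (1 + M(I-1)) | t_rho (same)]."""

    def __init__(self, n_rates: int, n_classes: int, I: int):
        self.n_rates = n_rates
        self.n_classes = n_classes
        self.I = I
        self.n_attn = 1 + n_classes * (I - 1)
        self.size = n_rates + N_LAGS + 2 * self.n_attn

    def attn_index(self, class_pos: int, t: int) -> int:
        """Flat index of the attention parameter for (class, interval t)."""
        return 0 if t == 1 else 1 + class_pos * (self.I - 1) + (t - 2)

    def unpack(self, x: np.ndarray):
        R, A = self.n_rates, self.n_attn
        o = 0
        logr = x[o:o + R]; o += R
        beta = x[o:o + N_LAGS]; o += N_LAGS
        t_p = x[o:o + A]; o += A
        t_rho = x[o:o + A]
        return logr, beta, t_p, t_rho


def _cbm_objective(x: np.ndarray, pack: _CBMPack, tds: list[TrialData]):
    logr, beta, t_p, t_rho = pack.unpack(x)
    p_all = sigmoid(t_p)
    rho_all = sigmoid(t_rho)
    dlogr = np.zeros_like(logr)
    dbeta = np.zeros(N_LAGS)
    dt_p = np.zeros_like(t_p)
    dt_rho = np.zeros_like(t_rho)
    total = 0.0
    for td in tds:
        ll, g, G, r = cif_tables(td, logr, beta)
        dll = np.empty_like(ll)
        for t in range(1, td.n_intervals + 1):
            ai = pack.attn_index(td.class_pos, t)
            p, rho = float(p_all[ai]), float(rho_all[ai])
            logP, w1, v1, u_bin = _interval_logliks(ll[:, t - 1, :], p, rho)
            total += logP
            u_ber = 1.0 - u_bin
            dll[:, t - 1, 1] = u_bin * w1 + u_ber * v1
            dll[:, t - 1, 0] = u_bin * (1.0 - w1) + u_ber * (1.0 - v1)
            dt_p[ai] += u_bin * float(np.sum(w1 - p)) + u_ber * (v1 - p)
            dt_rho[ai] += u_ber * (1.0 - rho) - u_bin * rho
        dr, db = cif_backward(td, dll, g, G, r, pack.n_rates)
        dlogr += dr
        dbeta += db
    grad = np.concatenate([dlogr, dbeta, dt_p, dt_rho])
    return -total, -grad


def fit_cbm(session: Session, scheme: ConditionScheme | None = None,
            config: FitConfig | None = None,
            attention_param_budget: int = DEFAULT_ATTENTION_PARAM_BUDGET
            ) -> tuple[CBMParams, FitReport]:
    """Maximum-likelihood fit of the CBM to one session."""
    scheme = scheme or ConditionScheme()
    config = config or FitConfig()
    rindex, class_order, dropped, tds = prepare_session(session, scheme)
    if dropped:
        warnings.warn(
            f"session {session.session_id}: no trials for condition "
            f"classes {dropped}; they are not modelled", stacklevel=2
        )
    I = session.n_intervals
    n_attn = 2 * (1 + len(class_order) * (I - 1))
    if n_attn > attention_param_budget:
        raise ValueError(
            f"CBM would need {n_attn} attention parameters "
            f"(|M|={len(class_order)}, I={I}), exceeding the budget of "
            f"{attention_param_budget}; use a coarser discretization or "
            "merged condition classes"
        )
    pack = _CBMPack(rindex.size, len(class_order), I)
    logr0 = empirical_log_rates(session, rindex)
    split = contra_split(rindex)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.log_rate_bounds
    bounds = ([(lo, hi)] * rindex.size
              + [(-config.beta_bound, config.beta_bound)] * N_LAGS
              + [(-config.logit_bound, config.logit_bound)] * (2 * pack.n_attn))
    best = None
    start_logliks = []
    for s in range(config.n_starts):
        x0 = np.zeros(pack.size)
        x0[:rindex.size] = logr0 + (split if s == 0 else
                                    rng.normal(0.0, 0.4, rindex.size))
        o = rindex.size + N_LAGS
        p0 = np.full(pack.n_attn, 0.5) if s == 0 else \
            rng.uniform(0.2, 0.8, pack.n_attn)
        rho0 = np.full(pack.n_attn, 0.3) if s == 0 else \
            rng.uniform(0.1, 0.9, pack.n_attn)
        x0[o:o + pack.n_attn] = logit(p0)
        x0[o + pack.n_attn:] = logit(rho0)
        res = optimize.minimize(
            _cbm_objective, x0, args=(pack, tds), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": config.max_iter, "gtol": config.gtol,
                     "ftol": config.ftol},
        )
        start_logliks.append(-float(res.fun))
        if best is None or -res.fun > -best.fun:
            best = res
    logr, beta, t_p, t_rho = pack.unpack(best.x)
    p_all = sigmoid(t_p)
    rho_all = sigmoid(t_rho)
    p_map: dict[int, dict[int, float]] = {}
    rho_map: dict[int, dict[int, float]] = {}
    flags = []
    for i, cls in enumerate(class_order):
        p_map[cls] = {}
        rho_map[cls] = {}
        for t in range(2, I + 1):
            ai = pack.attn_index(i, t)
            p_map[cls][t] = float(p_all[ai])
            rho_map[cls][t] = float(rho_all[ai])
            if min(rho_all[ai], 1.0 - rho_all[ai]) < 1e-3:
                flags.append(f"rho[class {cls}, t={t}] at boundary "
                             f"{round(float(rho_all[ai]))}")
    if min(rho_all[0], 1.0 - rho_all[0]) < 1e-3:
        flags.append(f"rho1 at boundary {round(float(rho_all[0]))}")
    rates: dict[str, dict[str, float]] = {}
    for (nid, key), lr in zip(rindex.entries, logr):
        rates.setdefault(nid, {})[key] = float(np.exp(lr))
    params = CBMParams(
        p1=float(p_all[0]), rho1=float(rho_all[0]), p=p_map, rho=rho_map,
        cif=CIFParams(rates=rates, beta=beta), n_intervals=I,
    )
    report = FitReport(
        loglik=-float(best.fun),
        n_iter=int(best.nit),
        converged=bool(best.success),
        message=str(best.message),
        start_logliks=start_logliks,
        n_starts=config.n_starts,
        boundary_flags=flags,
        n_free_parameters=params.n_free_parameters,
        dropped_classes=dropped,
    )
    if not best.success:
        warnings.warn(
            f"CBM fit did not formally converge: {best.message}; "
            "returning best parameters found", stacklevel=2
        )
    return params, report
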