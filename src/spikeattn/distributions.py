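"""Distributions of the number of neurons attending one of two stimuli.

With ``n`` exchangeable neurons each attending exactly one of two stimuli,
the count ``Z`` of neurons attending stimulus 1 has a PMF ``f(z)`` on
``{0, ..., n}`` whose shape distinguishes parallel processing (mass near
``n/2``) from serial processing (mass near 0 and/or ``n``).  This module
provides the PMFs used by the two latent-attention models — a mixture of
three binomials (HMM marginal), the correlated binomial, and the Poisson
binomial arising in decoding — together with the normalized deviation
statistic

    D_n = sum_z |z - n/2| f(z) / (n/2)

and its large-n limits D* for the parametric families.  D_n is 0 for a point
mass at n/2 (maximally parallel) and 1 for mass confined to {0, n}
(fully serial).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AttentionPMF",
    "dn",
    "bin3_pmf",
    "cbin_pmf",
    "poisson_binomial_pmf",
    "dstar_hmm",
    "dstar_cbm",
]

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class AttentionPMF:
    """PMF of the number of neurons (out of ``n``) attending stimulus 1."""

    mass: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "mass", m)
        if m.ndim != 1 or m.size < 1:
            raise ValueError("mass must be a 1-d vector over z = 0..n")
        if np.any(m < -_NORM_TOL):
            raise ValueError("PMF has negative mass")
        if abs(m.sum() - 1.0) > 1e-9:
            raise ValueError(f"PMF mass sums to {m.sum()}, not 1")

    @property
    def n(self) -> int:
        return self.mass.size - 1

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.mass.size)


def dn(pmf: AttentionPMF) -> float:
    """Normalized expected deviation of the attention count from n/2.

    Returns ``E|Z - n/2| / (n/2)``, in [0, 1].
    """
    n = pmf.n
    if n == 0:
        raise ValueError("D_n undefined for n = 0")
    z = pmf.support
    return float(np.sum(np.abs(z - n / 2.0) * pmf.mass) / (n / 2.0))


def _check_simplex(w: np.ndarray, name: str, tol: float = 1e-8) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if np.any(w < -tol) or abs(w.sum() - 1.0) > tol:
        raise ValueError(f"{name} must lie on the probability simplex, got {w}")
    return np.clip(w, 0.0, 1.0)


def bin3_pmf(pi_t, alpha, n: int) -> AttentionPMF:
    """Mixture of three binomials: the HMM's marginal attention-count law.

    Conditional on hidden state k the count is Binomial(n, alpha_k); the
    state distribution ``pi_t`` supplies the mixture weights.
    """
    pi_t = _check_simplex(np.asarray(pi_t, dtype=float), "pi_t")
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (3,) or np.any((alpha < 0) | (alpha > 1)):
        raise ValueError("alpha must be three probabilities in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    z = np.arange(n + 1)
    mass = sum(
        w * stats.binom.pmf(z, n, a) for w, a in zip(pi_t, alpha)
    )
    return AttentionPMF(mass / mass.sum())


def cbin_pmf(n: int, p: float, rho: float) -> AttentionPMF:
    """Correlated binomial CBin(n, p, rho).

    A mixture of an ordinary Binomial(n, p) (weight 1 - rho) and a fully
    correlated component on {0, n} putting mass p at n and 1 - p at 0
    (weight rho).  rho is both the mixture weight and the pairwise
    correlation of the individual attention indicators.
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must be in [0, 1]; the mixture cannot represent "
                         "negative correlation")
    z = np.arange(n + 1)
    mass = (1.0 - rho) * stats.binom.pmf(z, n, p)
    mass[0] += rho * (1.0 - p)
    mass[n] += rho * p
    return AttentionPMF(mass / mass.sum())


def poisson_binomial_pmf(probs) -> AttentionPMF:
    """Exact PMF of a sum of independent Bernoullis with unequal probabilities.

    Computed by iterative convolution, O(n^2); exact for the population sizes
    that occur here (n of order tens).
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or probs.size < 1:
        raise ValueError("probs must be a non-empty vector")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    mass = np.array([1.0])
    for p in probs:
        mass = np.convolve(mass, [1.0 - p, p])
    mass = np.clip(mass, 0.0, None)
    return AttentionPMF(mass / mass.sum())


def dstar_hmm(pi_t, alpha) -> float:
    """Large-n limit of D_n under the mixture of three binomials.

    Equals ``2 * sum_k pi_k |alpha_k - 1/2|``: as n grows each binomial
    concentrates at n*alpha_k, so only the state-wise offsets from 1/2 remain.
    """
    pi_t = _check_simplex(np.asarray(pi_t, dtype=float), "pi_t")
    alpha = np.asarray(alpha, dtype=float)
    return float(2.0 * np.sum(pi_t * np.abs(alpha - 0.5)))


def dstar_cbm(p: float, rho: float) -> float:
    """Large-n limit of D_n under CBin: ``2(1 - rho)|p - 1/2| + rho``."""
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must be in [0, 1]")
    return float(2.0 * (1.0 - rho) * abs(p - 0.5) + rho)
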