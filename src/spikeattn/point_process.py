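"""Point-process spike model: conditional intensity with spike-history kernel.

Each neuron fires as a discrete-time point process on the 1 ms grid.  Given
the stimulus the neuron currently attends, the conditional intensity at bin
``s`` is

    h(s | H_s; x) = r * exp( sum_{j=1..10} beta_j * dN_{s-j} )

where ``r = r^i(x)`` is a neuron-specific base rate (spikes/ms) that depends
only on the attended stimulus identity and its side (contra/ipsi), and the
shared weights ``beta_1..beta_10`` let the previous 10 ms of the neuron's own
spiking modulate the rate (e.g. refractoriness for negative weights).  Seven
rates per neuron cover T, NI, NC at either side plus a single rate for the
no-stimulus display.

The probability of a spike pattern in an interval, given constant attention
``x`` over the interval, is the product of ``h*u`` over spike bins times
``exp(-sum h*u)`` over all bins (u = 1 ms) — the discrete-time evaluation of
the point-process likelihood, exact for piecewise-constant intensity at the
recording resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .session import Condition, StimulusLabel

__all__ = ["CIFParams", "rate_key", "RATE_KEYS", "cif_path", "interval_loglik"]

N_LAGS = 10

# The 7 distinct base-rate slots per neuron: side matters for real stimuli,
# the blank display has a single side-independent rate.
RATE_KEYS: tuple[str, ...] = (
    "T:contra", "T:ipsi", "NI:contra", "NI:ipsi", "NC:contra", "NC:ipsi", "NO",
)


def rate_key(label: StimulusLabel, side: str) -> str:
    """Rate-table key for a stimulus label at a given side."""
    if side not in ("contra", "ipsi"):
        raise ValueError(f"side must be 'contra' or 'ipsi', got {side!r}")
    if label == StimulusLabel.NO:
        return "NO"
    return f"{label.value}:{side}"


@dataclass(frozen=True)
class CIFParams:
    """Base rates (spikes/ms) per neuron and shared history weights."""

    rates: Mapping[str, Mapping[str, float]]
    beta: np.ndarray = field(default_factory=lambda: np.zeros(N_LAGS))

    def __post_init__(self) -> None:
        b = np.asarray(self.beta, dtype=float)
        if b.shape != (N_LAGS,):
            raise ValueError(f"beta must have length {N_LAGS}, got shape {b.shape}")
        object.__setattr__(self, "beta", b)
        for nid, table in self.rates.items():
            for key, r in table.items():
                if key not in RATE_KEYS:
                    raise ValueError(f"neuron {nid}: unknown rate key {key!r}")
                if not r > 0:
                    raise ValueError(f"neuron {nid}: rate {key} must be > 0")

    def rate(self, neuron: str, condition: Condition, x: int) -> float:
        """Base rate of ``neuron`` when attending stimulus ``x`` (1=contra)."""
        if x == 1:
            key = rate_key(condition.contra, "contra")
        elif x == 0:
            key = rate_key(condition.ipsi, "ipsi")
        else:
            raise ValueError(f"attended stimulus must be 0 or 1, got {x}")
        return float(self.rates[neuron][key])


def _history_factor(counts: np.ndarray, beta: np.ndarray,
                    start: int, stop: int) -> np.ndarray:
    """exp(sum_j beta_j dN_{b-j}) for bins start..stop-1 of ``counts``."""
    if start < N_LAGS:
        raise ValueError(
            f"history missing: need {N_LAGS} bins before bin {start}; "
            "analysed data is never zero-padded"
        )
    counts = np.asarray(counts, dtype=float)
    expo = np.zeros(stop - start)
    for j in range(1, N_LAGS + 1):
        expo += beta[j - 1] * counts[start - j:stop - j]
    return np.exp(expo)


def cif_path(counts: np.ndarray, neuron: str, x: int, condition: Condition,
             params: CIFParams, start: int = N_LAGS,
             stop: int | None = None) -> np.ndarray:
    """Conditional intensity per 1 ms bin over ``counts[start:stop]``.

    ``counts`` is the binary spike indicator at 1 ms resolution; bins before
    ``start`` provide the observed history (at least 10 required).
    """
    counts = np.asarray(counts)
    if stop is None:
        stop = counts.size
    r = params.rate(neuron, condition, x)
    h = r * _history_factor(counts, params.beta, start, stop)
    if not np.all(np.isfinite(h)):
        bad = start + int(np.argmax(~np.isfinite(h)))
        raise FloatingPointError(f"non-finite intensity at bin {bad}")
    return h


def interval_loglik(counts: np.ndarray, start: int, stop: int, neuron: str,
                    x: int, condition: Condition, params: CIFParams) -> float:
    """log P(spike pattern in bins [start, stop) | attended stimulus x).

    Discrete-time point-process log likelihood with u = 1 ms:
    ``sum_{spike bins} log(h u) - sum_{all bins} h u``.  The spike history
    entering h may extend before ``start`` (it is observed data).
    """
    counts = np.asarray(counts)
    h = cif_path(counts, neuron, x, condition, params, start, stop)
    spikes = counts[start:stop].astype(bool)
    ll = float(np.sum(np.log(h[spikes])) - np.sum(h))
    if not np.isfinite(ll):
        raise FloatingPointError(
            f"non-finite interval log likelihood on bins [{start}, {stop})"
        )
    return ll
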