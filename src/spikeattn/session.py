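"""Domain model for recording sessions of simultaneously recorded spike trains.

A *session* is one recording day: a roster of neurons ``N`` and a list of
trials.  Each trial presents a pair of visual stimuli (one contralateral, one
ipsilateral to the recording site) drawn from the 12-condition scheme, and
carries the spike trains of the neurons that were still isolated at that
point in the session (the per-trial subset ``N_k``).

Spike times are integer milliseconds since stimulus onset on a 1 ms grid,
with half-open bins ``[b, b+1)``.  The analysis window (default
``[100, 500)`` ms) is divided into ``I`` equal intervals; the 10 ms of spike
history preceding the window is kept so the conditional-intensity model has
observed history at the first analysed bin.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "StimulusLabel",
    "Condition",
    "ConditionScheme",
    "SpikeTrain",
    "Trial",
    "Session",
    "DiscretizedTrain",
    "CONDITIONS",
    "condition_class",
    "discretize",
    "read_session",
    "write_session",
    "SessionValidationError",
]


class SessionValidationError(ValueError):
    """Raised when a session, trial or spike train violates the data contract."""


class StimulusLabel(str, Enum):
    """The four stimulus identities a display location can carry."""

    T = "T"    # cued target
    NI = "NI"  # inconsistent non-target (a target on other trials)
    NC = "NC"  # consistent non-target (never a target)
    NO = "NO"  # no stimulus, grey dot only


@dataclass(frozen=True)
class Condition:
    """A stimulus pair: what is shown contralateral and ipsilateral."""

    id: int
    contra: StimulusLabel
    ipsi: StimulusLabel


# The 12 stimulus-pair conditions.  Conditions 1-3 have the target on the
# contralateral side, 4-6 on the ipsilateral side, 7-12 contain no target.
_CONDITION_PAIRS = [
    ("T", "NI"), ("T", "NC"), ("T", "NO"),
    ("NI", "T"), ("NC", "T"), ("NO", "T"),
    ("NI", "NC"), ("NI", "NO"), ("NC", "NO"),
    ("NC", "NI"), ("NO", "NI"), ("NO", "NC"),
]

CONDITIONS: dict[int, Condition] = {
    i + 1: Condition(i + 1, StimulusLabel(c), StimulusLabel(p))
    for i, (c, p) in enumerate(_CONDITION_PAIRS)
}


@dataclass(frozen=True)
class ConditionScheme:
    """How the 12 conditions are grouped into classes for model fitting.

    ``all12`` keeps every condition separate; ``merged3`` merges into
    target-contra (ids 1-3), target-ipsi (4-6) and no-target (7-12).
    """

    mode: str = "merged3"

    def __post_init__(self) -> None:
        if self.mode not in ("all12", "merged3"):
            raise SessionValidationError(f"unknown condition scheme {self.mode!r}")

    @property
    def classes(self) -> dict[int, int]:
        if self.mode == "all12":
            return {i: i for i in range(1, 13)}
        return {i: (1 if i <= 3 else 2 if i <= 6 else 3) for i in range(1, 13)}

    @property
    def n_classes(self) -> int:
        return 12 if self.mode == "all12" else 3


def condition_class(condition: Condition | int, scheme: ConditionScheme) -> int:
    """Map a condition to its class id under the given scheme."""
    cid = condition.id if isinstance(condition, Condition) else int(condition)
    try:
        return scheme.classes[cid]
    except KeyError:
        raise SessionValidationError(f"invalid condition id {cid}") from None


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one neuron in one trial, ms since stimulus onset.

    ``window`` is the half-open recording interval ``[T_s, T_e)`` the times
    must fall in; at most one spike per 1 ms bin.
    """

    spike_times: tuple[int, ...]
    window: tuple[int, int] = (0, 500)

    def __post_init__(self) -> None:
        ts = np.asarray(self.spike_times, dtype=np.int64)
        if ts.size and (np.any(np.diff(ts) <= 0)):
            raise SessionValidationError(
                "spike times must be strictly increasing on the 1 ms grid"
            )
        lo, hi = self.window
        if ts.size and (ts[0] < lo or ts[-1] >= hi):
            raise SessionValidationError(
                f"spike times outside window [{lo}, {hi})"
            )

    def __len__(self) -> int:
        return len(self.spike_times)


@dataclass(frozen=True)
class Trial:
    """One stimulus presentation with the spike trains of the active neurons."""

    trial_id: str
    condition: Condition
    trains: Mapping[str, SpikeTrain]

    @property
    def neuron_ids(self) -> frozenset[str]:
        return frozenset(self.trains)

    def __post_init__(self) -> None:
        windows = {tr.window for tr in self.trains.values()}
        if len(windows) > 1:
            raise SessionValidationError(
                f"trial {self.trial_id}: spike trains disagree on the window"
            )


@dataclass(frozen=True)
class Session:
    """A full recording session."""

    session_id: str
    neuron_ids: tuple[str, ...]
    trials: tuple[Trial, ...]
    analysis_window: tuple[int, int] = (100, 500)
    n_intervals: int = 5
    history_lead_ms: int = 10

    def __post_init__(self) -> None:
        start, end = self.analysis_window
        if self.n_intervals < 2:
            raise SessionValidationError("n_intervals must be at least 2")
        if (end - start) % self.n_intervals != 0:
            raise SessionValidationError(
                f"window length {end - start} ms not divisible by I={self.n_intervals}"
            )
        roster = set(self.neuron_ids)
        for tr in self.trials:
            extra = tr.neuron_ids - roster
            if extra:
                raise SessionValidationError(
                    f"trial {tr.trial_id} references neurons outside the "
                    f"session roster: {sorted(extra)}"
                )

    @property
    def interval_length_ms(self) -> int:
        start, end = self.analysis_window
        return (end - start) // self.n_intervals


@dataclass(frozen=True)
class DiscretizedTrain:
    """Binary spike indicator at 1 ms resolution plus interval labels.

    ``counts[b]`` is 1 iff a spike fell in ``[t0_ms + b, t0_ms + b + 1)``.
    ``interval_of_bin[b]`` is the 1-based analysis interval of bin ``b``, or
    -1 for history-lead bins preceding the analysis window.
    """

    counts: np.ndarray
    t0_ms: int
    interval_of_bin: np.ndarray


def discretize(train: SpikeTrain, session: Session) -> DiscretizedTrain:
    """Bin a spike train over ``[start - history_lead, end)`` at 1 ms.

    Raises if the train's window does not cover the required span.
    """
    start, end = session.analysis_window
    t0 = start - session.history_lead_ms
    if train.window[0] > t0 or train.window[1] < end:
        raise SessionValidationError(
            f"train window {train.window} does not cover [{t0}, {end})"
        )
    n_bins = end - t0
    counts = np.zeros(n_bins, dtype=np.int8)
    ts = np.asarray(train.spike_times, dtype=np.int64)
    ts = ts[(ts >= t0) & (ts < end)]
    counts[ts - t0] = 1
    interval = np.full(n_bins, -1, dtype=np.int64)
    L = session.interval_length_ms
    analysed = np.arange(start, end) - t0
    interval[analysed] = 1 + (np.arange(end - start) // L)
    return DiscretizedTrain(counts=counts, t0_ms=t0, interval_of_bin=interval)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _session_to_dict(session: Session) -> dict:
    return {
        "session_id": session.session_id,
        "neuron_ids": list(session.neuron_ids),
        "analysis_window": list(session.analysis_window),
        "n_intervals": session.n_intervals,
        "history_lead_ms": session.history_lead_ms,
        "trials": [
            {
                "trial_id": tr.trial_id,
                "condition_id": tr.condition.id,
                "window": list(next(iter(tr.trains.values())).window)
                if tr.trains else [0, 500],
                "neurons": {
                    nid: list(map(int, st.spike_times))
                    for nid, st in tr.trains.items()
                },
            }
            for tr in session.trials
        ],
    }


def _session_from_dict(doc: dict) -> Session:
    try:
        trials = []
        for td in doc["trials"]:
            window = tuple(td.get("window", [0, 500]))
            cond = CONDITIONS.get(int(td["condition_id"]))
            if cond is None:
                raise SessionValidationError(
                    f"trial {td.get('trial_id')}: invalid condition id "
                    f"{td['condition_id']}"
                )
            trains = {
                str(nid): SpikeTrain(tuple(int(t) for t in ts), window)
                for nid, ts in td["neurons"].items()
            }
            trials.append(Trial(str(td["trial_id"]), cond, trains))
        return Session(
            session_id=str(doc["session_id"]),
            neuron_ids=tuple(str(n) for n in doc["neuron_ids"]),
            trials=tuple(trials),
            analysis_window=tuple(doc.get("analysis_window", [100, 500])),
            n_intervals=int(doc.get("n_intervals", 5)),
            history_lead_ms=int(doc.get("history_lead_ms", 10)),
        )
    except (KeyError, TypeError) as exc:
        raise SessionValidationError(f"malformed session document: {exc}") from exc


def write_session(session: Session, path: str | Path, format: str = "json") -> None:
    """Write a session to disk as JSON or as a flat CSV + JSON sidecar header."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_session_to_dict(session), indent=1))
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["trial_id", "condition_id", "neuron_id", "spike_ms"])
            for tr in session.trials:
                for nid, st in tr.trains.items():
                    for t in st.spike_times:
                        writer.writerow([tr.trial_id, tr.condition.id, nid, t])
                    if not st.spike_times:  # keep silent neurons visible
                        writer.writerow([tr.trial_id, tr.condition.id, nid, ""])
        header = _session_to_dict(session)
        for td in header["trials"]:
            td.pop("neurons")
        Path(str(path) + ".meta.json").write_text(json.dumps(header, indent=1))
    else:
        raise ValueError(f"unknown session format {format!r}")


def read_session(path: str | Path, format: str = "json") -> Session:
    """Read a session written by :func:`write_session`."""
    path = Path(path)
    if format == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise SessionValidationError(f"not valid JSON: {exc}") from exc
        return _session_from_dict(doc)
    if format == "csv":
        header = json.loads(Path(str(path) + ".meta.json").read_text())
        spikes: dict[tuple[str, str], list[int]] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                key = (str(row["trial_id"]), str(row["neuron_id"]))
                spikes.setdefault(key, [])
                if row["spike_ms"] not in ("", None):
                    spikes[key].append(int(row["spike_ms"]))
        for td in header["trials"]:
            tid = str(td["trial_id"])
            td["neurons"] = {
                nid: sorted(ts)
                for (t, nid), ts in spikes.items()
                if t == tid
            }
        return _session_from_dict(header)
    raise ValueError(f"unknown session format {format!r}")
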