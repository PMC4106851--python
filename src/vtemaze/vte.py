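"""Vicarious trial-and-error (VTE) detection, suppression and summaries.

The robot has no head independent of its body, so VTE is read off the
signed motor output m = 2u - 1: one VTE event is a sign change of m larger
than a threshold band +-theta. The default detector uses Schmitt-trigger
(hysteresis) semantics - an event requires crossing from beyond +theta to
beyond -theta (or vice versa) since the last event - which filters noisy
fluctuation around a turning degree of zero. A per-step rule (sign change
with |dm| > 2 theta) is available behind ``rule="delta"``.

Suppression replays a session with an online detector that overrides the
motor output to u = 0.5 (zero angular velocity) on every would-be event;
theta = 1 blocks nothing (m never exceeds 1), theta = 0 blocks every sign
change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trial import TrialRecord, run_session, success_rate

__all__ = [
    "DEFAULT_THETA",
    "VTEEvent",
    "VTETrialSummary",
    "count_vtes",
    "counts_per_trial",
    "VTESuppressor",
    "SuppressionResult",
    "suppress_vte_session",
    "classify_pattern",
]

DEFAULT_THETA = 0.1


@dataclass(frozen=True)
class VTEEvent:
    """One detected sign crossing of the signed motor output."""

    neural_step: int
    from_value: float  # m beyond the opposite band before the crossing
    to_value: float    # m at the crossing step

    def __post_init__(self):
        if self.from_value * self.to_value > 0:
            raise ValueError("VTE event endpoints must have opposite signs")


def count_vtes(u_series: Sequence[float], theta: float = DEFAULT_THETA,
               rule: str = "hysteresis") -> tuple[int, list[VTEEvent]]:
    """Count VTE events in a motor-output series (u per neural step).

    Returns the count and the event list. Empty series yield 0 events.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must be in [0, 1]")
    u = np.asarray(u_series, dtype=float)
    if u.size and (u.min() < 0.0 or u.max() > 1.0):
        raise ValueError("motor outputs must lie in [0, 1]")
    m = 2.0 * u - 1.0
    events: list[VTEEvent] = []
    if rule == "hysteresis":
        side = 0
        last_m = 0.0
        for t, mt in enumerate(m):
            if mt > theta:
                if side == -1:
                    events.append(VTEEvent(t, last_m, float(mt)))
                side = 1
                last_m = float(mt)
            elif mt < -theta:
                if side == 1:
                    events.append(VTEEvent(t, last_m, float(mt)))
                side = -1
                last_m = float(mt)
    elif rule == "delta":
        for t in range(1, len(m)):
            if m[t - 1] * m[t] < 0 and abs(m[t] - m[t - 1]) > 2.0 * theta:
                events.append(VTEEvent(t, float(m[t - 1]), float(m[t])))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return len(events), events


def counts_per_trial(records: Sequence[TrialRecord],
                     theta: float = DEFAULT_THETA,
                     rule: str = "hysteresis") -> np.ndarray:
    """VTE count of each trial's motor-output log."""
    out = np.zeros(len(records), dtype=int)
    for k, rec in enumerate(records):
        if rec.neural_log is not None:
            out[k] = count_vtes(rec.neural_log.u, theta, rule)[0]
    return out


class VTESuppressor:
    """Online motor filter: zero the angular velocity on each would-be VTE.

    The detector state advances on the *effective* (possibly overridden)
    outputs, so a blocked event leaves the hysteresis side unchanged
    (m = 0 crosses nothing) and each subsequent attempted crossing is
    blocked again.
    """

    def __init__(self, theta: float):
        if not 0.0 <= theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        self.theta = theta
        self.blocked = 0
        self.reset()

    def reset(self) -> None:
        """Forget the hysteresis state (called at each trial start)."""
        self._side = 0

    def __call__(self, u: float) -> float:
        m = 2.0 * u - 1.0
        th = self.theta
        if m > th:
            if self._side == -1:
                self.blocked += 1
                return 0.5
            self._side = 1
        elif m < -th:
            if self._side == 1:
                self.blocked += 1
                return 0.5
            self._side = -1
        return u


@dataclass
class SuppressionResult:
    theta: float
    records: list[TrialRecord]
    blocked: int
    success_rate: float  # percent, over the session

    def summary(self) -> dict:
        return {"theta": self.theta, "blocked": self.blocked,
                "success_rate_percent": self.success_rate,
                "n_trials": len(self.records)}


def suppress_vte_session(controller, maze, theta: float,
                         n_trials: int = 100, *, seed: int = 0,
                         start_pose=None) -> SuppressionResult:
    """Run a maze-solving session with online VTE suppression at ``theta``.

    Learning still sees the overridden motor state. With theta = 1.0 the
    filter never fires and the session is bit-identical to an unsuppressed
    run of the same controller.
    """
    suppressor = VTESuppressor(theta)
    records = run_session(
        controller, maze, n_trials=n_trials, seed=seed, start_pose=start_pose,
        motor_filter=suppressor, on_trial_start=lambda k: suppressor.reset(),
    )
    return SuppressionResult(
        theta=theta, records=records, blocked=suppressor.blocked,
        success_rate=100.0 * success_rate(records),
    )


@dataclass(frozen=True)
class VTETrialSummary:
    """Per-trial VTE counts and the heuristic pattern label.

    The label heuristic is analysis plumbing, not part of the model: HL
    (high early, low late), L (low throughout), H (high throughout) or
    unclassified. The three summary means always accompany the label.
    """

    counts: np.ndarray
    label: str
    early_mean: float
    late_mean: float
    overall_mean: float
    theta: float = DEFAULT_THETA


def classify_pattern(counts: Sequence[float], *,
                     early_trials: int = 20, late_start: int = 50,
                     floor: float = 2.0, decline_ratio: float = 2.0,
                     theta: float = DEFAULT_THETA) -> VTETrialSummary:
    """Heuristic HL / L / H labeling of a per-trial VTE count profile.

    HL: early mean at least ``decline_ratio`` times the late mean and an
    early peak of at least ``floor``. L: overall mean below ``floor``.
    H: overall mean at or above ``floor`` with no such decline. Anything
    else is unclassified.
    """
    c = np.asarray(counts, dtype=float)
    if c.size < early_trials:
        raise ValueError(f"need at least {early_trials} trials, got {c.size}")
    early = c[:early_trials]
    late = c[late_start:] if c.size > late_start else c[c.size // 2:]
    early_mean = float(early.mean())
    late_mean = float(late.mean())
    overall = float(c.mean())
    if early_mean >= decline_ratio * late_mean and early.max() >= floor:
        label = "HL"
    elif overall < floor:
        label = "L"
    elif overall >= floor:
        label = "H"
    else:  # pragma: no cover - exhaustive above
        label = "unclassified"
    return VTETrialSummary(counts=c, label=label, early_mean=early_mean,
                           late_mean=late_mean, overall_mean=overall,
                           theta=theta)
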