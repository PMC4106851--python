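"""Deterministic fixtures: scripted policies, canned genomes, test series."""

from __future__ import annotations

import numpy as np

from .ga import GENOME_LENGTH
from .policies import CirclingPolicy, OraclePolicy, ZigzagPolicy, policy_params

__all__ = ["make_fixture", "logistic_series", "sine_series"]


def logistic_series(n: int = 5000, x0: float = 0.1234, r: float = 4.0) -> np.ndarray:
    """Logistic-map iterates x <- r x (1 - x); at r = 4 the Lyapunov
    exponent is exactly ln 2."""
    x = np.empty(n)
    x[0] = x0
    for i in range(1, n):
        x[i] = r * x[i - 1] * (1.0 - x[i - 1])
    return x


def sine_series(n: int = 2000, period: float = 50.0,
                amplitude: float = 1.0) -> np.ndarray:
    t = np.arange(n, dtype=float)
    return amplitude * np.sin(2.0 * np.pi * t / period)


def canned_genome(seed: int = 7) -> np.ndarray:
    """A fixed, arbitrary but reproducible genome in [0, 1]^49."""
    return np.random.default_rng(seed).random(GENOME_LENGTH)


_KINDS = ("oracle_policy", "timeout_policy", "zigzag_policy",
          "canned_genome", "logistic_series", "sine_series")


def make_fixture(kind: str, **kwargs):
    """Build a named deterministic fixture.

    Kinds: ``oracle_policy`` (steers to the rewarded arm from ground
    truth), ``timeout_policy`` (circles in place until the step budget),
    ``zigzag_policy`` (known VTE count), ``canned_genome``,
    ``logistic_series`` and ``sine_series``.
    """
    if kind == "oracle_policy":
        return OraclePolicy(policy_params(**kwargs))
    if kind == "timeout_policy":
        return CirclingPolicy(policy_params(**kwargs))
    if kind == "zigzag_policy":
        params = policy_params(**{k: v for k, v in kwargs.items()
                                  if k in ("v_forward", "c_turn", "delta")})
        rest = {k: v for k, v in kwargs.items() if k in ("u_high", "u_low", "period")}
        return ZigzagPolicy(params, **rest)
    if kind == "canned_genome":
        return canned_genome(**kwargs)
    if kind == "logistic_series":
        return logistic_series(**kwargs)
    if kind == "sine_series":
        return sine_series(**kwargs)
    raise ValueError(f"unknown fixture kind {kind!r}; known: {_KINDS}")
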