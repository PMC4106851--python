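"""Maximum Lyapunov exponent (MLE) estimation via the Rosenstein method.

The Rosenstein small-data algorithm estimates the largest Lyapunov
exponent of a scalar series x(t): delay-embed into m-dimensional vectors
X_i = (x_i, x_{i+J}, ..., x_{i+(m-1)J}); pair each X_i with its Euclidean
nearest neighbor separated in time by more than the mean period of the
series (from the FFT power spectrum), so the pair is not trivially
correlated; track the log distance of each pair k steps forward and
average over pairs; the MLE is the least-squares slope of the first
``fit_len`` points of that average divergence curve.

Two acceptance gates follow the analysis protocol used here: a fit is
adopted only when its R-squared exceeds 0.8 (otherwise the MLE is reported
as 0.0), and negative estimates - which only measure the convergence speed
of an already-settled orbit - are also reported as 0.0.

Neural time series come from the controller logs: the motor module
contributes its virtual unit v (which *is* the motor command), every
sensory module the within-module mean of v - s, the mismatch signal that
actually propagates to the motor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .controller import MODULES
from .trial import TrialRecord

__all__ = [
    "MLEEstimate",
    "mean_period",
    "mle_rosenstein",
    "extract_module_series",
    "session_mle",
    "DEFAULT_EMBED_DIM",
    "DEFAULT_DELAY",
    "DEFAULT_FIT_LEN",
    "R_SQUARED_GATE",
]

DEFAULT_EMBED_DIM = 5
DEFAULT_DELAY = 1
DEFAULT_FIT_LEN = 10
R_SQUARED_GATE = 0.8


@dataclass(frozen=True)
class MLEEstimate:
    """One MLE fit with its quality gates.

    ``lambda1`` is per neural step and is always >= 0 in reported form:
    rejected fits (R-squared <= 0.8) and negative slopes are set to 0.0.
    ``raw_slope`` keeps the ungated value for inspection.
    """

    lambda1: float
    r_squared: float
    accepted: bool
    n_points: int
    m: int
    J: int
    fit_len: int
    raw_slope: float = 0.0
    divergence_curve: np.ndarray | None = None

    def __post_init__(self):
        assert self.lambda1 >= 0.0
        assert self.accepted == (self.r_squared > R_SQUARED_GATE)


def mean_period(x: np.ndarray, method: str = "power_weighted") -> float:
    """Mean period of a series from its FFT power spectrum.

    ``power_weighted`` (the convention used here): reciprocal of the
    power-weighted mean frequency. ``dominant``: period of the spectral
    peak. Spectrally empty (constant) series fall back to a period of 1.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0)
    power, freqs = power[1:], freqs[1:]
    total = power.sum()
    if total <= 0 or freqs.size == 0:
        return 1.0
    if method == "power_weighted":
        fbar = float((power * freqs).sum() / total)
    elif method == "dominant":
        fbar = float(freqs[int(np.argmax(power))])
    else:
        raise ValueError(f"unknown mean-period method {method!r}")
    return 1.0 / fbar if fbar > 0 else 1.0


def _nearest_neighbors(Y: np.ndarray, exclude: int) -> np.ndarray:
    """Index of each point's nearest neighbor with |i - j| > exclude.

    Brute force in row chunks; series here are short (tens to a few
    thousand embedded points).
    """
    M = Y.shape[0]
    nn = np.full(M, -1, dtype=int)
    chunk = 512
    idx = np.arange(M)
    sq = np.einsum("ij,ij->i", Y, Y)
    for lo in range(0, M, chunk):
        hi = min(lo + chunk, M)
        d2 = sq[lo:hi, None] + sq[None, :] - 2.0 * (Y[lo:hi] @ Y.T)
        mask = np.abs(idx[None, :] - idx[lo:hi, None]) <= exclude
        d2[mask] = np.inf
        nn[lo:hi] = np.argmin(d2, axis=1)
        nn[lo:hi][~np.isfinite(d2[np.arange(hi - lo), nn[lo:hi]])] = -1
    return nn


def mle_rosenstein(
    x: Sequence[float],
    m: int = DEFAULT_EMBED_DIM,
    J: int = DEFAULT_DELAY,
    fit_len: int = DEFAULT_FIT_LEN,
    *,
    max_steps: int | None = None,
    period_method: str = "power_weighted",
    keep_curve: bool = True,
) -> MLEEstimate:
    """Estimate the largest Lyapunov exponent of a scalar series.

    Raises ``ValueError`` when the series is too short for the embedding
    plus the fit window. All-degenerate pairings (every distance zero)
    yield a rejected estimate rather than an error.
    """
    x = np.asarray(x, dtype=float)
    N = x.size
    min_len = (m - 1) * J + fit_len + 2
    if N < min_len:
        raise ValueError(f"series of length {N} too short for m={m}, J={J}, "
                         f"fit_len={fit_len} (need >= {min_len})")
    M = N - (m - 1) * J
    Y = np.lib.stride_tricks.sliding_window_view(x, (m - 1) * J + 1)[:, ::J]
    assert Y.shape == (M, m)

    exclude = max(1, int(math.ceil(mean_period(x, period_method))))
    if exclude >= M - 1:
        exclude = max(1, M // 4)
    nn = _nearest_neighbors(Y, exclude)

    n_steps = fit_len if max_steps is None else max(fit_len, max_steps)
    n_steps = min(n_steps, M - 1)
    scale = float(np.ptp(x)) or 1.0
    floor = np.finfo(float).eps * scale

    valid = nn >= 0
    i_idx = np.nonzero(valid)[0]
    j_idx = nn[i_idx]
    d0 = np.linalg.norm(Y[i_idx] - Y[j_idx], axis=1)
    live = d0 > 0  # pairs starting at exactly zero distance are excluded
    i_idx, j_idx = i_idx[live], j_idx[live]
    if i_idx.size == 0:
        return MLEEstimate(0.0, 0.0, False, N, m, J, fit_len,
                           raw_slope=0.0, divergence_curve=None)

    curve = np.full(n_steps, np.nan)
    for k in range(n_steps):
        ok = (i_idx + k < M) & (j_idx + k < M)
        if not ok.any():
            break
        d = np.linalg.norm(Y[i_idx[ok] + k] - Y[j_idx[ok] + k], axis=1)
        curve[k] = float(np.mean(np.log(np.maximum(d, floor))))

    fit_pts = curve[:fit_len]
    good = np.isfinite(fit_pts)
    ks = np.arange(fit_len, dtype=float)[good]
    ys = fit_pts[good]
    if ks.size < 3 or np.allclose(ys, ys[0]):
        return MLEEstimate(0.0, 0.0, False, N, m, J, fit_len, raw_slope=0.0,
                           divergence_curve=curve if keep_curve else None)
    fit = stats.linregress(ks, ys)
    r2 = float(fit.rvalue ** 2)
    accepted = r2 > R_SQUARED_GATE
    slope = float(fit.slope)
    lam = slope if (accepted and slope > 0) else 0.0
    return MLEEstimate(lam, r2, accepted, N, m, J, fit_len, raw_slope=slope,
                       divergence_curve=curve if keep_curve else None)


def extract_module_series(records: Sequence[TrialRecord]) -> list[dict[str, np.ndarray]]:
    """Per-trial, per-module scalar series for MLE estimation.

    Motor: the virtual unit (the motor command) per neural step. Sensory
    modules: mean over the module's neurons of v - s.
    """
    out = []
    for rec in records:
        log = rec.neural_log
        if log is None or not log.s:
            raise ValueError(f"trial {rec.trial_index} has no neural log")
        series = {}
        for mod in MODULES:
            if mod == "motor":
                series[mod] = log.v[mod][:, 0].copy()
            else:
                series[mod] = (log.v[mod] - log.s[mod]).mean(axis=1)
        out.append(series)
    return out


def session_mle(
    records: Sequence[TrialRecord],
    m: int = DEFAULT_EMBED_DIM,
    J: int = DEFAULT_DELAY,
    fit_len: int = DEFAULT_FIT_LEN,
) -> dict[str, dict]:
    """Per-module mean and SD of the MLE across a session's trials.

    Trials too short for the embedding contribute a rejected (0.0)
    estimate, mirroring the R-squared gate's treatment.
    """
    per_trial = extract_module_series(records)
    out: dict[str, dict] = {}
    for mod in MODULES:
        lams, n_accepted = [], 0
        for series in per_trial:
            try:
                est = mle_rosenstein(series[mod], m, J, fit_len, keep_curve=False)
            except ValueError:
                est = MLEEstimate(0.0, 0.0, False, len(series[mod]), m, J, fit_len)
            lams.append(est.lambda1)
            n_accepted += est.accepted
        lams = np.array(lams)
        out[mod] = {
            "mean": float(lams.mean()),
            "sd": float(lams.std(ddof=0)),
            "n_trials": len(lams),
            "n_accepted": int(n_accepted),
        }
    return out
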