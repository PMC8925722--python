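"""Behavioral statistics: three-choice entropy, running-entropy session
truncation, reward rate, preference switches, and the psychometric curve."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

from .agents import LatentTrajectory, ModelParams
from .envs import L, MISS, R, Session

#: all 2^3 = 8 three-choice patterns, in a fixed enumeration order
PATTERNS: tuple[str, ...] = tuple("".join(p) for p in product((L, R), repeat=3))


def _clean_choices(choices: Sequence[str]) -> np.ndarray:
    arr = np.asarray(list(choices), dtype=object)
    return arr[arr != MISS]


def pattern_frequencies(choices: Sequence[str]) -> np.ndarray:
    """Frequencies of the 8 three-choice patterns over overlapping windows."""
    c = _clean_choices(choices)
    if len(c) < 3:
        raise ValueError("need at least 3 non-MISS choices")
    counts = dict.fromkeys(PATTERNS, 0)
    for i in range(len(c) - 2):
        counts["".join(c[i : i + 3])] += 1
    freqs = np.array([counts[p] for p in PATTERNS], dtype=float)
    return freqs / freqs.sum()


def three_choice_entropy(choices: Sequence[str]) -> float:
    """Shannon entropy (bits) of the overlapping three-choice pattern
    distribution; maximum 3 bits, with 0 * log 0 := 0."""
    p = pattern_frequencies(choices)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def running_entropy(choices: Sequence[str], window: int = 30) -> np.ndarray:
    """Three-choice entropy of each sliding ``window``-trial block."""
    c = _clean_choices(choices)
    if len(c) < window:
        raise ValueError("session shorter than window")
    return np.array(
        [three_choice_entropy(c[i : i + window]) for i in range(len(c) - window + 1)]
    )


def _piecewise_linear_fit(y: np.ndarray) -> np.ndarray:
    """Least-squares fit with at most one slope/intercept change.

    Evaluates every breakpoint splitting the series into two independently
    fitted lines and returns the fitted values of the best (lowest SSE)
    configuration, including the no-breakpoint single line.
    """
    n = len(y)
    x = np.arange(n, dtype=float)

    def line_fit(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        if len(ys) == 1:
            return ys.copy()
        coef = np.polyfit(xs, ys, 1)
        return np.polyval(coef, xs)

    best_fit = line_fit(x, y)
    best_sse = float(((y - best_fit) ** 2).sum())
    for b in range(2, n - 1):
        f1 = line_fit(x[:b], y[:b])
        f2 = line_fit(x[b:], y[b:])
        sse = float(((y[:b] - f1) ** 2).sum() + ((y[b:] - f2) ** 2).sum())
        if sse < best_sse - 1e-12:
            best_sse = sse
            best_fit = np.concatenate([f1, f2])
    return best_fit


def detect_last_trial(
    choices: Sequence[str], window: int = 30, threshold: float = 1.0
) -> int:
    """Truncation index from the running-entropy changepoint fit.

    The running three-choice entropy is fitted with a piecewise-linear
    function (at most one slope change); the trial at which the fitted
    function first crosses below ``threshold`` is the last trial. If the fit
    recovers above the threshold afterward, or never crosses, the whole
    session is kept.
    """
    c = _clean_choices(choices)
    n = len(c)
    if n <= window:
        return n
    fitted = _piecewise_linear_fit(running_entropy(c, window))
    below = fitted < threshold
    if not below.any():
        return n
    first = int(np.argmax(below))
    if not below[first:].all():  # recovers above threshold later
        return n
    # window i covers trials i+1 .. i+window (1-based); report the window end
    return first + window


@dataclass
class SessionSummary:
    """Headline statistics of one session."""

    n_trials: int
    reward_rate: float
    entropy: float
    pattern_freqs: np.ndarray
    last_trial: int
    n_preference_switches: int


def preference_switches(choices: Sequence[str], sigma: float = 5.0) -> int:
    """Number of times the Gaussian-smoothed running P(choose L) crosses 0.5."""
    c = _clean_choices(choices)
    if len(c) < 2:
        return 0
    left = (c == L).astype(float)
    smoothed = gaussian_filter1d(left, sigma=sigma, mode="nearest")
    above = smoothed > 0.5
    return int(np.count_nonzero(np.diff(above)))


def summarize_session(
    session: Session,
    trajectory: Optional[LatentTrajectory] = None,
    sigma: float = 5.0,
    window: int = 30,
) -> SessionSummary:
    choices = session.choices
    valid = choices != MISS
    outcomes = session.outcomes[valid]
    reward_rate = float(outcomes.mean()) if len(outcomes) else 0.0
    return SessionSummary(
        n_trials=session.n_trials,
        reward_rate=reward_rate,
        entropy=three_choice_entropy(choices),
        pattern_freqs=pattern_frequencies(choices),
        last_trial=detect_last_trial(choices, window=window),
        n_preference_switches=preference_switches(choices, sigma=sigma),
    )


def psychometric_curve(
    sessions: Sequence[Session],
    trajectories: Sequence[LatentTrajectory],
    params: ModelParams,
    n_bins: int = 11,
) -> pd.DataFrame:
    """Observed vs predicted P(choose L) binned by the weighted sum of the
    action-value and choice-kernel differences, pooled over sessions.

    Returns a frame with columns ``bin_center``, ``n``, ``observed``,
    ``predicted``; empty bins are dropped.
    """
    xs, ys = [], []
    for session, traj in zip(sessions, trajectories):
        choices = session.choices
        keep = choices != MISS
        w = params.beta * traj.dq + params.beta_k * traj.dk
        xs.append(w[keep])
        ys.append((choices[keep] == L).astype(float))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    edges = np.linspace(x.min(), x.max() + 1e-12, n_bins + 1)
    idx = np.digitize(x, edges) - 1
    rows = []
    for b in range(n_bins):
        m = idx == b
        if not m.any():
            continue
        center = 0.5 * (edges[b] + edges[b + 1])
        rows.append(
            {
                "bin_center": center,
                "n": int(m.sum()),
                "observed": float(y[m].mean()),
                "predicted": float(expit(center)),
            }
        )
    return pd.DataFrame(rows)
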