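"""Synthetic datasets with known ground truth for every pipeline stage.

Behavioral sessions come from closed-loop simulation of a known agent;
pupil traces are built by planting a linear combination of trial regressors
(smooth temporal kernels per predictor) on top of slow drift, band-limited
noise, and sparse outlier artifacts — the inverse of the preprocessing
conventions, so that preprocessing + regression recovers the planted
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml
from scipy.signal import butter, sosfiltfilt

from .agents import LatentTrajectory, ModelParams
from .envs import Session
from .pupil import build_design
from .simulation import simulate_session


def default_hybrid_params() -> ModelParams:
    """Hybrid-model parameters consistent with the fitted ratios
    (alpha_k/alpha = 0.22, beta_k/(beta+beta_k) = 0.76, beta+beta_k = 2.15)."""
    return ModelParams(
        model="FQ_RPE_CK", alpha=0.60, alpha_k=0.13, beta=0.52, beta_k=1.63
    )


@dataclass
class BehaviorSpec:
    """Generative recipe for a set of behavioral sessions."""

    params: ModelParams
    env: str = "mp"
    n_sessions: int = 10
    n_trials: int = 500

    def to_yaml(self, path) -> None:
        from .agents import FREE_PARAMS

        d = {
            "model": self.params.model,
            "params": {
                n: float(getattr(self.params, n)) for n in FREE_PARAMS[self.params.model]
            },
            "env": self.env,
            "n_sessions": self.n_sessions,
            "n_trials": self.n_trials,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "BehaviorSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        params = ModelParams(model=d["model"], **d.get("params", {}))
        return cls(
            params=params,
            env=d.get("env", "mp"),
            n_sessions=int(d.get("n_sessions", 10)),
            n_trials=int(d.get("n_trials", 500)),
        )


def generate_behavior(
    spec: BehaviorSpec, rng: np.random.Generator
) -> tuple[list[Session], list[LatentTrajectory], ModelParams]:
    """Simulate sessions from a known agent; returns the ground truth too."""
    sessions, trajectories = [], []
    for _ in range(spec.n_sessions):
        s, t = simulate_session(spec.params, spec.env, spec.n_trials, rng)
        sessions.append(s)
        trajectories.append(t)
    return sessions, trajectories, spec.params


# ---------------------------------------------------------------------------
# pupil traces


@dataclass
class PupilSpec:
    """Planted-regression recipe for a synthetic pupil trace.

    ``planted`` maps predictor names (columns of the chosen design) to
    ``(coefficient, t_start, t_end)`` — the coefficient is active on the
    given peri-cue window with a flat top and raised-cosine ramps of
    ``edge_s`` seconds at each end.
    """

    design: str = "observable"
    planted: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    noise_sd: float = 0.3
    drift_amplitude: float = 0.5
    drift_period_s: float = 1500.0
    outlier_rate: float = 0.001
    outlier_scale: float = 10.0
    fs: float = 20.0
    edge_s: float = 0.25
    #: top up the trace variance to ~1 with extra background noise so the
    #: moving z-score leaves planted coefficients on their original scale
    calibrate: bool = True
    #: band-limit all injected noise below the 4-Hz preprocessing cutoff so
    #: the preprocessing filter does not change the noise variance
    band_limit: bool = True
    pad_s: float = 6.0

    def to_yaml(self, path) -> None:
        d = {
            "design": self.design,
            "planted": {k: list(map(float, v)) for k, v in self.planted.items()},
            "noise_sd": self.noise_sd,
            "drift_amplitude": self.drift_amplitude,
            "drift_period_s": self.drift_period_s,
            "outlier_rate": self.outlier_rate,
            "outlier_scale": self.outlier_scale,
            "fs": self.fs,
            "edge_s": self.edge_s,
            "calibrate": self.calibrate,
            "band_limit": self.band_limit,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PupilSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "planted" in d:
            d["planted"] = {k: tuple(v) for k, v in d["planted"].items()}
        return cls(**d)


def _kernel(t0: float, t1: float, edge: float, fs: float) -> tuple[int, np.ndarray]:
    """Flat-top kernel with raised-cosine ramps; returns (sample offset, values)."""
    if t1 <= t0:
        raise ValueError("kernel window must have positive length")
    n = int(round((t1 - t0) * fs)) + 1
    t = t0 + np.arange(n) / fs
    k = np.ones(n)
    e = min(edge, (t1 - t0) / 2)
    if e > 0:
        up = t < t0 + e
        k[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - t0) / e))
        dn = t > t1 - e
        k[dn] = 0.5 * (1 - np.cos(np.pi * (t1 - t[dn]) / e))
    return int(round(t0 * fs)), k


def _band_limited_noise(
    n: int, sd: float, fs: float, rng: np.random.Generator, band_limit: bool
) -> np.ndarray:
    if sd <= 0 or n == 0:
        return np.zeros(n)
    x = rng.standard_normal(n)
    if band_limit and n > 30:
        sos = butter(4, 4.0, btype="low", fs=fs, output="sos")
        x = sosfiltfilt(sos, x)
        s = x.std()
        if s > 0:
            x = x / s
    return sd * x


def generate_pupil(
    session: Session,
    trajectory: Optional[LatentTrajectory],
    spec: PupilSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize a raw pupil trace with planted regression structure.

    Returns ``(raw_trace, cue_times)`` at ``spec.fs`` Hz. Per trial the trace
    gains ``sum_j coef_j * x_j * kernel_j(t)`` for the planted predictors,
    superposed on a slow sinusoidal drift, noise, and sparse outlier spikes.
    """
    fs = spec.fs
    cue_times = session.cue_times
    n = int(round((cue_times[-1] + spec.pad_s) * fs)) + 1
    sig = np.zeros(n)

    design = build_design(session, trajectory, spec=spec.design)
    if spec.planted:
        missing = set(spec.planted) - set(design.predictors)
        if missing:
            raise ValueError(f"planted predictors not in design: {sorted(missing)}")
        kernels = {
            name: _kernel(t0, t1, spec.edge_s, fs)
            for name, (_, t0, t1) in spec.planted.items()
        }
        X = design.X
        for row, trial_idx in enumerate(design.trial_indices):
            cue_sample = int(round(cue_times[trial_idx - 1] * fs))
            for name, (coef, _, _) in spec.planted.items():
                off, k = kernels[name]
                i0 = cue_sample + off
                i1 = i0 + len(k)
                if i0 < 0 or i1 > n:
                    continue
                sig[i0:i1] += coef * float(X[name].iloc[row]) * k

    core = sig + _band_limited_noise(n, spec.noise_sd, fs, rng, spec.band_limit)
    if spec.calibrate:
        # top the variance up to 1 as seen AFTER the preprocessing lowpass, so
        # the moving z-score leaves planted coefficients on their own scale
        if spec.band_limit and n > 30:
            sos = butter(4, 4.0, btype="low", fs=fs, output="sos")
            var = sosfiltfilt(sos, core).var()
            if var < 1.0:
                b1 = sosfiltfilt(sos, rng.standard_normal(n))
                b2_var = sosfiltfilt(sos, b1).var()
                core = core + b1 * np.sqrt((1.0 - var) / b2_var)
        else:
            var = core.var()
            if var < 1.0:
                core = core + float(np.sqrt(1.0 - var)) * rng.standard_normal(n)

    t = np.arange(n) / fs
    drift = np.zeros(n)
    if spec.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        drift = spec.drift_amplitude * np.sin(2 * np.pi * t / spec.drift_period_s + phase)

    raw = core + drift
    if spec.outlier_rate > 0:
        n_out = rng.binomial(n, spec.outlier_rate)
        if n_out:
            idx = rng.choice(n, size=n_out, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_out)
            raw[idx] += signs * spec.outlier_scale * max(raw.std(), 1e-12)
    return raw, cue_times
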