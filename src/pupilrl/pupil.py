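"""Pupillometry pipeline: preprocessing of the diameter trace, trial-aligned
baseline-subtracted responses, per-bin multiple linear regression against
behavioral and latent-variable designs, and across-session summaries.

Preprocessing order is fixed: 4-Hz lowpass, 3-scaled-MAD outlier masking,
10-min moving-window z-scoring. Regressions run per 100-ms bin on the
[-3, 5] s peri-cue grid; summaries report the fraction of sessions with
p < 0.01 per predictor per bin, a chi-square test of that fraction against a
1% chance level, and bootstrap confidence intervals on mean coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import butter, sosfiltfilt

from .agents import LatentTrajectory
from .envs import L, MISS, Session

logger = logging.getLogger(__name__)

#: consistency factor making the MAD an estimator of the Gaussian SD
MAD_SCALE = 1.4826

DESIGN_SPECS = ("observable", "selection", "updating")


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class PupilTrace:
    """A preprocessed pupil-diameter trace.

    ``z`` carries NaN at masked (outlier) frames; ``z_filled`` interpolates
    them linearly for downstream binning only.
    """

    fs: float
    raw: np.ndarray
    z: np.ndarray
    valid: np.ndarray
    cue_times: np.ndarray
    z_filled: np.ndarray

    @classmethod
    def from_z(cls, z: np.ndarray, cue_times, fs: float = 20.0) -> "PupilTrace":
        """Wrap an already-normalized signal (identity preprocessing)."""
        z = np.asarray(z, dtype=float)
        return cls(
            fs=fs,
            raw=z.copy(),
            z=z.copy(),
            valid=np.ones(len(z), dtype=bool),
            cue_times=np.asarray(cue_times, dtype=float),
            z_filled=z.copy(),
        )


def _moving_zscore(x: np.ndarray, window: int) -> np.ndarray:
    s = pd.Series(x)
    roll = s.rolling(window=window, center=True, min_periods=2)
    mean = roll.mean().to_numpy()
    sd = roll.std().to_numpy()
    z = np.full(len(x), np.nan)
    finite = np.isfinite(x)
    good = finite & np.isfinite(sd) & (sd > 0)
    z[good] = (x[good] - mean[good]) / sd[good]
    degenerate = finite & ~good
    z[degenerate] = 0.0
    return z


def preprocess_trace(
    raw: np.ndarray,
    fs: float = 20.0,
    cue_times: Sequence[float] = (),
    window_s: float = 600.0,
    lowpass_hz: Optional[float] = 4.0,
    mad_thresh: Optional[float] = 3.0,
    zscore: str = "moving",
) -> PupilTrace:
    """Lowpass-filter, mask outlier frames, and z-score a raw diameter trace.

    Parameters
    ----------
    zscore:
        ``"moving"`` (default) uses a centered moving-window mean and SD of
        length ``window_s``; ``"moving_mean"`` subtracts the moving mean but
        divides by the global SD; ``"global"`` uses whole-trace mean and SD;
        ``"none"`` skips normalization.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw trace must be finite")
    x = raw
    if lowpass_hz is not None:
        if not 0 < lowpass_hz < fs / 2:
            raise ValueError("lowpass_hz must be in (0, fs/2)")
        sos = butter(4, lowpass_hz, btype="low", fs=fs, output="sos")
        x = sosfiltfilt(sos, x)

    valid = np.ones(len(x), dtype=bool)
    if mad_thresh is not None:
        med = np.median(x)
        smad = MAD_SCALE * np.median(np.abs(x - med))
        if smad > 0:
            valid = np.abs(x - med) <= mad_thresh * smad
    masked = np.where(valid, x, np.nan)

    window = int(round(window_s * fs))
    if zscore == "moving":
        if len(x) < window:
            warnings.warn(
                "trace shorter than the z-scoring window; falling back to a "
                "single-window z-score",
                stacklevel=2,
            )
            zscore = "global"
    if zscore == "moving":
        z = _moving_zscore(masked, window)
    elif zscore == "moving_mean":
        if len(x) < window:
            warnings.warn("trace shorter than window; using global mean", stacklevel=2)
            mean = np.full(len(x), np.nanmean(masked))
        else:
            mean = (
                pd.Series(masked)
                .rolling(window=window, center=True, min_periods=2)
                .mean()
                .to_numpy()
            )
        sd = np.nanstd(masked - mean)
        z = (masked - mean) / sd if sd > 0 else np.where(np.isfinite(masked), 0.0, np.nan)
    elif zscore == "global":
        mu, sd = np.nanmean(masked), np.nanstd(masked)
        z = (masked - mu) / sd if sd > 0 else np.where(np.isfinite(masked), 0.0, np.nan)
    elif zscore == "none":
        z = masked
    else:
        raise ValueError(f"unknown zscore mode {zscore!r}")

    z_filled = (
        pd.Series(z).interpolate(limit_direction="both").fillna(0.0).to_numpy()
    )
    return PupilTrace(
        fs=fs,
        raw=raw,
        z=z,
        valid=valid,
        cue_times=np.asarray(cue_times, dtype=float),
        z_filled=z_filled,
    )


# ---------------------------------------------------------------------------
# trial-aligned responses


@dataclass
class TrialResponseMatrix:
    """Baseline-subtracted per-trial pupil responses on a fixed bin grid."""

    responses: np.ndarray  # (n_trials_kept, n_bins)
    bin_edges: np.ndarray  # length n_bins + 1, seconds from cue
    trial_indices: np.ndarray  # 1-based indices of the kept session trials
    baselines: np.ndarray

    @property
    def bin_starts(self) -> np.ndarray:
        return self.bin_edges[:-1]

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1


def trial_responses(
    trace: PupilTrace,
    t_pre: float = 3.0,
    t_post: float = 5.0,
    bin_s: float = 0.1,
    baseline_window: tuple[float, float] = (-2.0, -1.0),
) -> TrialResponseMatrix:
    """Per-trial baseline-subtracted responses in ``bin_s`` bins on
    [-t_pre, t_post] s around each cue; out-of-range trials are dropped."""
    fs = trace.fs
    spb = bin_s * fs
    if abs(spb - round(spb)) > 1e-9:
        raise ValueError("bin_s must be an integer number of samples")
    spb = int(round(spb))
    n_bins = int(round((t_pre + t_post) / bin_s))
    edges = -t_pre + bin_s * np.arange(n_bins + 1)

    rows, kept, bases = [], [], []
    z = trace.z_filled
    for i, cue in enumerate(trace.cue_times, start=1):
        i0 = int(round((cue - t_pre) * fs))
        i1 = i0 + n_bins * spb
        b0 = int(round((cue + baseline_window[0]) * fs))
        b1 = int(round((cue + baseline_window[1]) * fs))
        if i0 < 0 or b0 < 0 or i1 > len(z) or b1 > len(z):
            logger.info("dropping trial %d: window exceeds trace", i)
            continue
        base = float(z[b0:b1].mean())
        rows.append(z[i0:i1].reshape(n_bins, spb).mean(axis=1) - base)
        kept.append(i)
        bases.append(base)
    return TrialResponseMatrix(
        responses=np.array(rows) if rows else np.empty((0, n_bins)),
        bin_edges=edges,
        trial_indices=np.array(kept, dtype=int),
        baselines=np.array(bases),
    )


# ---------------------------------------------------------------------------
# design matrices


@dataclass
class DesignMatrix:
    """Per-trial regressors for one of the three regression models."""

    X: pd.DataFrame  # includes the intercept column
    trial_indices: np.ndarray  # 1-based session trial index per row
    spec: str

    @property
    def predictors(self) -> list[str]:
        return list(self.X.columns)


def moving_average_reward(outcomes: np.ndarray, window: int = 20) -> np.ndarray:
    """Mean outcome over the ``window`` most recent trials including the
    current one; early trials average over the available history."""
    r = np.asarray(outcomes, dtype=float)
    csum = np.concatenate(([0.0], np.cumsum(r)))
    n = len(r)
    idx = np.arange(1, n + 1)
    lo = np.maximum(idx - window, 0)
    return (csum[idx] - csum[lo]) / (idx - lo)


def cumulative_reward_fraction(outcomes: np.ndarray) -> np.ndarray:
    """Cumulative reward normalized by the session total (zeros if no reward)."""
    r = np.asarray(outcomes, dtype=float)
    total = r.sum()
    if total == 0:
        return np.zeros(len(r))
    return np.cumsum(r) / total


def build_design(
    session: Session,
    trajectory: Optional[LatentTrajectory],
    spec: str = "observable",
    ma_window: int = 20,
) -> DesignMatrix:
    """Build the per-trial regressor table for one regression model.

    ``spec``:

    * ``"observable"`` — choices, outcomes and their interactions for trials
      n+1, n, n-1, n-2, plus moving-average and normalized cumulative reward.
    * ``"selection"`` — current/previous choice, outcome, interaction, plus
      value difference, chosen value, kernel difference, chosen kernel.
    * ``"updating"`` — current/previous choice, previous outcome, value and
      kernel differences, reward prediction error, choice-kernel error.

    Choices are dummy-coded 0 = left, 1 = right; rows missing any required
    lag or lead (or involving a MISS trial) are dropped.
    """
    if spec not in DESIGN_SPECS:
        raise ValueError(f"unknown design spec {spec!r}")
    if spec in ("selection", "updating") and trajectory is None:
        raise ValueError(f"design {spec!r} requires a latent trajectory")
    if trajectory is not None and len(trajectory) != session.n_trials:
        raise ValueError("trajectory length does not match session")

    choices = session.choices
    n = session.n_trials
    c = np.where(choices == L, 0.0, np.where(choices == MISS, np.nan, 1.0)).astype(float)
    r = session.outcomes.astype(float)
    r_obs = np.where(np.isnan(c), np.nan, r)  # outcome undefined on MISS

    def lag(x: np.ndarray, k: int) -> np.ndarray:
        out = np.full(n, np.nan)
        if k > 0:
            out[k:] = x[:-k]
        elif k < 0:
            out[:k] = x[-k:]
        else:
            out = x.copy()
        return out

    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    r_ma = moving_average_reward(r, window=ma_window)
    r_cum = cumulative_reward_fraction(r)

    if spec == "observable":
        for name, k in (("next", -1), ("", 0), ("prev1", 1), ("prev2", 2)):
            suffix = f"_{name}" if name else ""
            cc, rr = lag(c, k), lag(r_obs, k)
            cols[f"c{suffix}"] = cc
            cols[f"r{suffix}"] = rr
            cols[f"cxr{suffix}"] = cc * rr
    elif spec == "selection":
        for name, k in (("", 0), ("prev1", 1)):
            suffix = f"_{name}" if name else ""
            cc, rr = lag(c, k), lag(r_obs, k)
            cols[f"c{suffix}"] = cc
            cols[f"r{suffix}"] = rr
            cols[f"cxr{suffix}"] = cc * rr
        cols["dq"] = trajectory.dq
        cols["q_chosen"] = trajectory.q_chosen(choices)
        cols["dk"] = trajectory.dk
        cols["k_chosen"] = trajectory.k_chosen(choices)
    else:  # updating
        cols["c"] = c
        cols["c_prev1"] = lag(c, 1)
        cols["r_prev1"] = lag(r_obs, 1)
        cols["dq"] = trajectory.dq
        cols["rpe"] = trajectory.rpe
        cols["dk"] = trajectory.dk
        cols["cke"] = trajectory.cke
    cols["r_ma"] = r_ma
    cols["r_cum"] = r_cum

    X = pd.DataFrame(cols)
    keep = ~X.isna().any(axis=1)
    X = X.loc[keep].reset_index(drop=True)
    trial_idx = np.flatnonzero(keep.to_numpy()) + 1
    return DesignMatrix(X=X, trial_indices=trial_idx, spec=spec)


# ---------------------------------------------------------------------------
# regression


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Greedy in-order selection of a maximal linearly independent column set."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    return np.array(keep, dtype=int)


def _ols_bins(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of every column of Y on X; returns (coef, pval, kept_column_mask).

    Aliased design columns are dropped (coefficients NaN) with a warning.
    """
    n, p = X.shape
    keep = _independent_columns(X)
    if len(keep) < p:
        warnings.warn(
            f"design is rank deficient; dropping {p - len(keep)} aliased column(s)",
            stacklevel=2,
        )
    Xk = X[:, keep]
    rank = Xk.shape[1]
    dof = n - rank
    if dof <= 0:
        raise ValueError("not enough rows for the design")
    beta, *_ = np.linalg.lstsq(Xk, Y, rcond=None)
    resid = Y - Xk @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(Xk.T @ Xk)
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, 0.0)
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)

    coef_full = np.full((p, Y.shape[1]), np.nan)
    pval_full = np.full((p, Y.shape[1]), np.nan)
    coef_full[keep] = beta
    pval_full[keep] = pval
    mask = np.zeros(p, dtype=bool)
    mask[keep] = True
    return coef_full, pval_full, mask


def regress_session(
    responses: TrialResponseMatrix, design: DesignMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin OLS for one session; rows are matched on the trial index.

    Returns (coefs, pvals), each (n_predictors, n_bins).
    """
    common, ri, di = np.intersect1d(
        responses.trial_indices, design.trial_indices, return_indices=True
    )
    if len(common) == 0:
        raise ValueError("no overlapping trials between responses and design")
    Y = responses.responses[ri]
    X = design.X.to_numpy(dtype=float)[di]
    coef, pval, _ = _ols_bins(X, Y)
    return coef, pval


@dataclass
class RegressionSummary:
    """Across-session summary of the per-bin regressions."""

    predictors: list[str]
    bin_starts: np.ndarray
    coefs: np.ndarray  # (n_sessions, n_predictors, n_bins)
    pvals: np.ndarray
    frac_significant: np.ndarray  # (n_predictors, n_bins)
    chi2_pvalues: np.ndarray
    mean_coef: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    alpha: float

    @property
    def n_sessions(self) -> int:
        return self.coefs.shape[0]

    def predictor_index(self, name: str) -> int:
        return self.predictors.index(name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, pred in enumerate(self.predictors):
            for b, t0 in enumerate(self.bin_starts):
                rows.append(
                    {
                        "predictor": pred,
                        "bin_start_s": float(t0),
                        "frac_significant": self.frac_significant[i, b],
                        "chi2_p": self.chi2_pvalues[i, b],
                        "mean_coef": self.mean_coef[i, b],
                        "ci_low": self.ci_low[i, b],
                        "ci_high": self.ci_high[i, b],
                    }
                )
        return pd.DataFrame(rows)


def _proportion_chi2(x: int, s: int, p0: float) -> float:
    """One-sample proportion chi-square test (no continuity correction)."""
    if s == 0:
        return np.nan
    expected = np.array([p0 * s, (1 - p0) * s])
    observed = np.array([x, s - x], dtype=float)
    stat = ((observed - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(stat, df=1))


def regress_and_summarize(
    sessions: Sequence[tuple[TrialResponseMatrix, DesignMatrix]],
    alpha: float = 0.01,
    n_boot: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> RegressionSummary:
    """Fit every session per bin and summarize across sessions.

    For each predictor and bin: the fraction of sessions significant at
    ``alpha``, a chi-square test of that fraction against ``alpha`` chance,
    and a bootstrap (resampling sessions) percentile CI on the mean
    coefficient.
    """
    if len(sessions) == 0:
        raise ValueError("need at least one session")
    predictors = sessions[0][1].predictors
    bin_starts = sessions[0][0].bin_starts
    n_bins = sessions[0][0].n_bins
    for resp, des in sessions:
        if des.predictors != predictors:
            raise ValueError("sessions have mismatched designs")
        if resp.n_bins != n_bins or not np.allclose(resp.bin_starts, bin_starts):
            raise ValueError("sessions have mismatched bin grids")

    S, P = len(sessions), len(predictors)
    coefs = np.full((S, P, n_bins), np.nan)
    pvals = np.full((S, P, n_bins), np.nan)
    for si, (resp, des) in enumerate(sessions):
        coefs[si], pvals[si] = regress_session(resp, des)

    with np.errstate(invalid="ignore"):
        sig = pvals < alpha
    n_tested = np.isfinite(pvals).sum(axis=0)
    n_sig = np.where(np.isfinite(pvals), sig, False).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_tested > 0, n_sig / np.maximum(n_tested, 1), np.nan)

    chi2_p = np.full((P, n_bins), np.nan)
    for i in range(P):
        for b in range(n_bins):
            chi2_p[i, b] = _proportion_chi2(int(n_sig[i, b]), int(n_tested[i, b]), alpha)

    mean_coef = np.nanmean(coefs, axis=0)
    rng = np.random.default_rng() if rng is None else rng
    draws = rng.integers(0, S, size=(n_boot, S))
    boot = np.nanmean(coefs[draws], axis=1)  # (n_boot, P, n_bins)
    ci_low = np.nanpercentile(boot, 2.5, axis=0)
    ci_high = np.nanpercentile(boot, 97.5, axis=0)

    return RegressionSummary(
        predictors=predictors,
        bin_starts=bin_starts,
        coefs=coefs,
        pvals=pvals,
        frac_significant=frac,
        chi2_pvalues=chi2_p,
        mean_coef=mean_coef,
        ci_low=ci_low,
        ci_high=ci_high,
        alpha=alpha,
    )


def _subset_design(design: DesignMatrix, row_mask: np.ndarray) -> DesignMatrix:
    return DesignMatrix(
        X=design.X.loc[row_mask].reset_index(drop=True),
        trial_indices=design.trial_indices[row_mask],
        spec=design.spec,
    )


def rpe_sign_split(
    sessions: Sequence[tuple[TrialResponseMatrix, DesignMatrix]],
    min_rows: Optional[int] = None,
    alpha: float = 0.01,
    n_boot: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Optional[RegressionSummary], Optional[RegressionSummary]]:
    """Refit the value-updating regression separately on trials with positive
    and negative reward prediction error.

    Within a group the outcome is constant so any aliased column is dropped
    by the rank check. Returns (positive, negative); a group with no usable
    sessions is returned as ``None``.
    """
    for _, des in sessions:
        if des.spec != "updating":
            raise ValueError("rpe_sign_split requires the 'updating' design")
    out = []
    for sign in (1, -1):
        group = []
        for resp, des in sessions:
            rpe = des.X["rpe"].to_numpy()
            mask = rpe > 0 if sign > 0 else rpe < 0
            need = min_rows if min_rows is not None else des.X.shape[1] + 3
            if mask.sum() < need:
                continue
            group.append((resp, _subset_design(des, mask)))
        if group:
            out.append(
                regress_and_summarize(group, alpha=alpha, n_boot=n_boot, rng=rng)
            )
        else:
            out.append(None)
    return out[0], out[1]


def eye_coefficient_correlation(
    left: RegressionSummary,
    right: RegressionSummary,
    predictor: str = "c",
    window: tuple[float, float] = (3.0, 5.0),
) -> tuple[float, float]:
    """Pearson correlation between per-session per-bin coefficients of the two
    eyes for one predictor, restricted to bins inside ``window`` seconds."""
    if left.coefs.shape[0] != right.coefs.shape[0]:
        raise ValueError("summaries cover different numbers of sessions")
    if len(left.bin_starts) != len(right.bin_starts) or not np.allclose(
        left.bin_starts, right.bin_starts
    ):
        raise ValueError("summaries have mismatched bin grids")
    i = left.predictor_index(predictor)
    j = right.predictor_index(predictor)
    in_win = (left.bin_starts >= window[0] - 1e-9) & (left.bin_starts < window[1] - 1e-9)
    a = left.coefs[:, i, in_win].ravel()
    b = right.coefs[:, j, in_win].ravel()
    good = np.isfinite(a) & np.isfinite(b)
    res = stats.pearsonr(a[good], b[good])
    return float(res.statistic), float(res.pvalue)
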