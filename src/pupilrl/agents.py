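"""Trial-by-trial decision models for two-choice tasks.

Five models are implemented:

* ``WSLS`` — win-stay / lose-switch with adherence probability ``p``.
* ``Q_RPE`` — Q-learning: the chosen value moves toward the outcome at rate
  ``alpha``; the unchosen value is unchanged.
* ``FQ_RPE`` — forgetting Q-learning: like ``Q_RPE`` but the unchosen value
  decays by ``(1 - alpha)``.
* ``DQ_RPE`` — differential Q-learning: the chosen value moves toward 1 at
  rate ``alpha_r`` (rewarded) or ``alpha_u`` (unrewarded).
* ``FQ_RPE_CK`` — forgetting Q-learning plus choice kernels that track recent
  choices at rate ``alpha_k``; action selection weighs values by ``beta`` and
  kernels by ``beta_k`` in a softmax.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import yaml

from .envs import L, MISS, R, Session

MODELS = ("WSLS", "Q_RPE", "FQ_RPE", "DQ_RPE", "FQ_RPE_CK")

#: free parameters per model (defines k for BIC)
FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "WSLS": ("p_wsls",),
    "Q_RPE": ("alpha", "beta"),
    "FQ_RPE": ("alpha", "beta"),
    "DQ_RPE": ("alpha_r", "alpha_u", "beta"),
    "FQ_RPE_CK": ("alpha", "alpha_k", "beta", "beta_k"),
}

_PROB_FLOOR = 1e-12


@dataclass
class ModelParams:
    """Parameter set for one of the five models; only the fields named in
    ``FREE_PARAMS[model]`` are read."""

    model: str
    alpha: float = 0.0
    alpha_k: float = 0.0
    alpha_r: float = 0.0
    alpha_u: float = 0.0
    beta: float = 1.0
    beta_k: float = 1.0
    p_wsls: float = 0.5
    # non-default variant of DQ_RPE that pulls unrewarded values toward 0
    dq_toward_zero: bool = False

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        for name in ("alpha", "alpha_k", "alpha_r", "alpha_u", "p_wsls"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("beta", "beta_k"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FREE_PARAMS[self.model]])

    @classmethod
    def from_free_values(cls, model: str, x, **kwargs) -> "ModelParams":
        return cls(model=model, **dict(zip(FREE_PARAMS[model], map(float, x))), **kwargs)

    def to_yaml(self, path) -> None:
        d = {"model": self.model}
        d.update({n: float(getattr(self, n)) for n in FREE_PARAMS[self.model]})
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


@dataclass(frozen=True)
class AgentState:
    """Current action values and choice kernels."""

    q_left: float = 0.0
    q_right: float = 0.0
    k_left: float = 0.0
    k_right: float = 0.0


def update_state(
    params: ModelParams, state: AgentState, choice: str, outcome: int
) -> AgentState:
    """Apply one trial's learning update. MISS trials leave the state unchanged."""
    if choice == MISS:
        return state
    if choice not in (L, R):
        raise ValueError(f"invalid choice {choice!r}")
    r = float(outcome)
    m = params.model
    qc = state.q_left if choice == L else state.q_right
    qu = state.q_right if choice == L else state.q_left

    if m == "WSLS":
        return state
    if m == "Q_RPE":
        qc = qc + params.alpha * (r - qc)
    elif m in ("FQ_RPE", "FQ_RPE_CK"):
        a = params.alpha
        qc = qc + a * (r - qc)
        qu = (1.0 - a) * qu
    elif m == "DQ_RPE":
        rate = params.alpha_r if r == 1.0 else params.alpha_u
        if params.dq_toward_zero and r == 0.0:
            qc = (1.0 - rate) * qc
        else:
            qc = qc + rate * (1.0 - qc)

    kc = state.k_left if choice == L else state.k_right
    ku = state.k_right if choice == L else state.k_left
    if m == "FQ_RPE_CK":
        ak = params.alpha_k
        kc = kc + ak * (1.0 - kc)
        ku = (1.0 - ak) * ku

    if choice == L:
        return AgentState(q_left=qc, q_right=qu, k_left=kc, k_right=ku)
    return AgentState(q_left=qu, q_right=qc, k_left=ku, k_right=kc)


def _sigmoid(x: float) -> float:
    # stable logistic
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


def action_probability(
    params: ModelParams,
    state: AgentState,
    prev_choice: Optional[str] = None,
    prev_outcome: Optional[int] = None,
) -> float:
    """Probability of choosing left on the upcoming trial."""
    m = params.model
    if m == "WSLS":
        if prev_choice not in (L, R):
            return 0.5
        p = params.p_wsls
        stay_left = prev_choice == L
        if prev_outcome == 1:
            return p if stay_left else 1.0 - p
        return 1.0 - p if stay_left else p
    if m == "FQ_RPE_CK":
        x = params.beta * (state.q_left - state.q_right) + params.beta_k * (
            state.k_left - state.k_right
        )
    else:
        x = params.beta * (state.q_left - state.q_right)
    return _sigmoid(x)


@dataclass
class LatentTrajectory:
    """Per-trial latent variables implied by a model on an observed session.

    All arrays are session-length; ``q_*``/``k_*`` hold the pre-choice state.
    MISS trials carry NaN for choice-dependent quantities.
    """

    q_left: np.ndarray
    q_right: np.ndarray
    k_left: np.ndarray
    k_right: np.ndarray
    p_left: np.ndarray
    rpe: np.ndarray
    cke: np.ndarray

    @property
    def dq(self) -> np.ndarray:
        return self.q_left - self.q_right

    @property
    def dk(self) -> np.ndarray:
        return self.k_left - self.k_right

    def q_chosen(self, choices: np.ndarray) -> np.ndarray:
        out = np.where(choices == L, self.q_left, self.q_right)
        return np.where(choices == MISS, np.nan, out.astype(float))

    def k_chosen(self, choices: np.ndarray) -> np.ndarray:
        out = np.where(choices == L, self.k_left, self.k_right)
        return np.where(choices == MISS, np.nan, out.astype(float))

    def __len__(self) -> int:
        return len(self.p_left)

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self) + 1),
                "qL": self.q_left,
                "qR": self.q_right,
                "kL": self.k_left,
                "kR": self.k_right,
                "pL": self.p_left,
                "rpe": self.rpe,
                "cke": self.cke,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def latent_trajectory(
    params: ModelParams,
    session: Session,
    init_state: Optional[AgentState] = None,
) -> LatentTrajectory:
    """Deterministic forward pass over an observed session.

    Stores the pre-choice state, the model's left-choice probability, and the
    two teaching signals (reward prediction error and choice-kernel error)
    for every trial. MISS trials trigger no update.
    """
    state = init_state if init_state is not None else AgentState()
    n = session.n_trials
    qL = np.empty(n)
    qR = np.empty(n)
    kL = np.empty(n)
    kR = np.empty(n)
    pL = np.empty(n)
    rpe = np.full(n, np.nan)
    cke = np.full(n, np.nan)
    prev_choice: Optional[str] = None
    prev_outcome: Optional[int] = None
    for i, trial in enumerate(session.trials):
        qL[i], qR[i] = state.q_left, state.q_right
        kL[i], kR[i] = state.k_left, state.k_right
        pL[i] = action_probability(params, state, prev_choice, prev_outcome)
        c, r = trial.choice, trial.outcome
        if c != MISS:
            q_c = state.q_left if c == L else state.q_right
            k_c = state.k_left if c == L else state.k_right
            rpe[i] = r - q_c
            cke[i] = 1.0 - k_c
            state = update_state(params, state, c, r)
            prev_choice, prev_outcome = c, r
    return LatentTrajectory(qL, qR, kL, kR, pL, rpe, cke)
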