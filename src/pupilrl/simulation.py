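"""Closed-loop agent-vs-environment simulation and kernel-weight sweeps."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .agents import (
    AgentState,
    LatentTrajectory,
    ModelParams,
    action_probability,
    latent_trajectory,
)
from .envs import (
    L,
    R,
    BanditState,
    MatchingPenniesOpponent,
    Session,
    TimingConfig,
    Trial,
    bandit_step,
    sample_trial_timing,
)


class ModelAgent:
    """Stateful wrapper turning a :class:`ModelParams` into a playing agent."""

    def __init__(self, params: ModelParams, init_state: Optional[AgentState] = None):
        self.params = params
        self.state = init_state if init_state is not None else AgentState()
        self.prev_choice: Optional[str] = None
        self.prev_outcome: Optional[int] = None

    def act(self, rng: np.random.Generator) -> str:
        p_left = action_probability(
            self.params, self.state, self.prev_choice, self.prev_outcome
        )
        return L if rng.random() < p_left else R

    def update(self, choice: str, outcome: int) -> None:
        from .agents import update_state

        self.state = update_state(self.params, self.state, choice, outcome)
        self.prev_choice, self.prev_outcome = choice, outcome


class FixedPolicyAgent:
    """Memoryless agent choosing left with a fixed probability (1.0 = always L)."""

    def __init__(self, p_left: float = 0.5):
        self.p_left = float(p_left)
        self.params = None

    def act(self, rng: np.random.Generator) -> str:
        if self.p_left >= 1.0:
            return L
        if self.p_left <= 0.0:
            return R
        return L if rng.random() < self.p_left else R

    def update(self, choice: str, outcome: int) -> None:
        pass


class GreedyBanditAgent:
    """Picks the arm with the higher running reward average (oracle-free)."""

    def __init__(self, alpha: float = 0.3):
        self.alpha = alpha
        self.q = {L: 0.0, R: 0.0}
        self.params = None

    def act(self, rng: np.random.Generator) -> str:
        if self.q[L] == self.q[R]:
            return L if rng.random() < 0.5 else R
        return L if self.q[L] > self.q[R] else R

    def update(self, choice: str, outcome: int) -> None:
        self.q[choice] += self.alpha * (outcome - self.q[choice])


def _as_agent(agent: Union[ModelParams, object]) -> object:
    if isinstance(agent, ModelParams):
        return ModelAgent(agent)
    return agent


def make_env(env, **kwargs):
    """Build an environment from a name ('mp'/'matching_pennies' or 'bandit')."""
    if isinstance(env, (MatchingPenniesOpponent, BanditState)):
        return env
    if env in ("mp", "matching_pennies", "opponent"):
        return MatchingPenniesOpponent(**kwargs)
    if env == "bandit":
        return BanditState(**kwargs)
    raise ValueError(f"unknown environment {env!r}")


def simulate_session(
    agent_params: Union[ModelParams, object],
    env: Union[str, MatchingPenniesOpponent, BanditState],
    n_trials: int,
    rng: np.random.Generator,
    timing: Optional[TimingConfig] = None,
    first_cue: float = 10.0,
) -> tuple[Session, Optional[LatentTrajectory]]:
    """Simulate one session of a two-choice task.

    Each trial the environment acts first where applicable (the opponent
    draws its own choice before seeing the agent's), the agent samples its
    choice from its policy, the outcome is determined, and both sides update.
    Fully reproducible from ``rng``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    env = make_env(env)
    if isinstance(env, MatchingPenniesOpponent):
        env.reset()
    agent = _as_agent(agent_params)
    timing = timing if timing is not None else TimingConfig()

    trials = []
    bandit_state = env if isinstance(env, BanditState) else None
    blocks: list[tuple[int, float, float]] = []
    cue = first_cue
    for n in range(1, n_trials + 1):
        response_time = float(rng.uniform(0.3, 0.7))
        computer = None
        if bandit_state is not None:
            if not blocks or (blocks[-1][1], blocks[-1][2]) != (
                bandit_state.p_left,
                bandit_state.p_right,
            ):
                blocks.append((n, bandit_state.p_left, bandit_state.p_right))
            choice = agent.act(rng)
            outcome, bandit_state = bandit_step(bandit_state, choice, rng)
        else:
            computer = env.choose(rng)
            choice = agent.act(rng)
            outcome = int(choice == computer)
            env.observe(choice, outcome)
        agent.update(choice, outcome)
        trials.append(
            Trial(
                index=n,
                choice=choice,
                outcome=outcome,
                computer_choice=computer,
                cue_time=cue,
                response_time=response_time,
            )
        )
        iti, delay = sample_trial_timing(timing, penalty_licks=0, rng=rng)
        cue += response_time + delay

    session = Session(
        trials,
        task="bandit" if bandit_state is not None else "matching_pennies",
        block_schedule=blocks or None,
    )
    traj = None
    if isinstance(agent, ModelAgent):
        traj = latent_trajectory(agent.params, session)
    return session, traj


def reward_rate(session: Session) -> float:
    return float(session.outcomes.mean())


@dataclass
class SweepResult:
    """Reward rate as a function of the relative choice-kernel weight."""

    grid: np.ndarray  # beta_k / (beta + beta_k)
    mean_reward: np.ndarray
    sd_reward: np.ndarray
    rates: np.ndarray  # (len(grid), n_reps)
    alpha: float
    alpha_k: float
    beta_sum: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"w": self.grid, "mean_reward": self.mean_reward, "sd_reward": self.sd_reward}
        )


def sweep_kernel_weight(
    grid,
    alpha: float,
    alpha_k: float,
    beta_sum: float,
    n_reps: int,
    n_trials: int,
    env: str,
    rng: np.random.Generator,
) -> SweepResult:
    """Vary ``beta_k / (beta + beta_k)`` at fixed learning rates and fixed
    total inverse temperature; simulate ``n_reps`` sessions per grid point."""
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.min() < 0 or grid.max() > 1:
        raise ValueError("grid must lie in [0, 1]")
    rates = np.empty((len(grid), n_reps))
    for i, w in enumerate(grid):
        params = ModelParams(
            model="FQ_RPE_CK",
            alpha=alpha,
            alpha_k=alpha_k,
            beta=max((1.0 - w) * beta_sum, 1e-9),
            beta_k=max(w * beta_sum, 1e-9),
        )
        for j in range(n_reps):
            session, _ = simulate_session(params, env, n_trials, rng)
            rates[i, j] = reward_rate(session)
    return SweepResult(
        grid=grid,
        mean_reward=rates.mean(axis=1),
        sd_reward=rates.std(axis=1),
        rates=rates,
        alpha=alpha,
        alpha_k=alpha_k,
        beta_sum=beta_sum,
    )
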