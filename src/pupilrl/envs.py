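"""Task environments: exploitative matching-pennies opponent, block-structured
two-armed bandit, and the trial-timing (ITI) generator.

The opponent mines the animal's within-session history for exploitable
regularities: it estimates the probability of a left choice conditional on the
preceding N choices (N = 0..4) and the preceding N choice-outcome pairs
(N = 1..4), tests each of the nine estimates against 0.5 with an exact binomial
test, and counters the most deviant significant prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

L = "L"
R = "R"
MISS = "MISS"

#: the nine history conditions, in fixed precedence order (ties in the
#: farthest-from-0.5 rule are broken by this order)
CONDITIONS: tuple[tuple[str, int], ...] = tuple(
    [("choice", n) for n in range(5)] + [("choice_outcome", n) for n in range(1, 5)]
)


# ---------------------------------------------------------------------------
# session containers


@dataclass
class Trial:
    """One trial of a two-choice task."""

    index: int  # 1-based
    choice: str  # "L", "R" or "MISS"
    outcome: int  # 0 or 1
    computer_choice: Optional[str] = None  # matching pennies only
    cue_time: float = float("nan")  # s from session start
    response_time: Optional[float] = None  # s from cue onset

    def __post_init__(self) -> None:
        if self.choice not in (L, R, MISS):
            raise ValueError(f"invalid choice {self.choice!r}")
        if self.outcome not in (0, 1):
            raise ValueError(f"invalid outcome {self.outcome!r}")
        if self.choice == MISS and self.outcome != 0:
            raise ValueError("MISS trials carry outcome 0")


@dataclass
class Session:
    """An ordered list of trials from one behavioral session."""

    trials: list[Trial]
    task: str = "matching_pennies"
    block_schedule: Optional[list[tuple[int, float, float]]] = None

    def __post_init__(self) -> None:
        for i, t in enumerate(self.trials, start=1):
            if t.index != i:
                raise ValueError("trial indices must be consecutive from 1")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def choices(self) -> np.ndarray:
        return np.array([t.choice for t in self.trials], dtype=object)

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([t.outcome for t in self.trials], dtype=int)

    @property
    def cue_times(self) -> np.ndarray:
        return np.array([t.cue_time for t in self.trials], dtype=float)

    def drop_miss(self) -> "Session":
        """Return a copy with MISS trials removed and indices renumbered."""
        kept = [t for t in self.trials if t.choice != MISS]
        trials = [replace(t, index=i) for i, t in enumerate(kept, start=1)]
        return Session(trials, task=self.task, block_schedule=self.block_schedule)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": [t.index for t in self.trials],
                "choice": [t.choice for t in self.trials],
                "outcome": [t.outcome for t in self.trials],
                "computer_choice": [t.computer_choice for t in self.trials],
                "cue_time": [t.cue_time for t in self.trials],
                "response_time": [t.response_time for t in self.trials],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, task: str = "matching_pennies") -> "Session":
        trials = []
        for _, row in df.iterrows():
            cc = row.get("computer_choice")
            if cc is not None and (not isinstance(cc, str) or cc == ""):
                cc = None
            rt = row.get("response_time")
            if rt is not None and (isinstance(rt, float) and math.isnan(rt)):
                rt = None
            trials.append(
                Trial(
                    index=int(row["trial"]),
                    choice=str(row["choice"]),
                    outcome=int(row["outcome"]),
                    computer_choice=cc,
                    cue_time=float(row.get("cue_time", float("nan"))),
                    response_time=None if rt is None else float(rt),
                )
            )
        return cls(trials, task=task)

    @classmethod
    def from_csv(cls, path, task: str = "matching_pennies") -> "Session":
        return cls.from_frame(pd.read_csv(path), task=task)


# ---------------------------------------------------------------------------
# matching-pennies opponent


@dataclass
class ConditionalEstimate:
    """One of the opponent's nine conditional left-probability estimates."""

    condition: tuple[str, int]
    estimate: float
    n: int
    pvalue: float


_PVAL_CACHE: dict[tuple[int, int], float] = {}


def binomial_pvalue(k: int, n: int) -> float:
    """Two-sided exact binomial p-value of k successes in n trials vs p=0.5.

    For the symmetric null this equals ``scipy.stats.binomtest`` but is cheap
    enough to call once per trial per condition.
    """
    if n == 0:
        return 1.0
    key = (min(k, n - k), n)
    p = _PVAL_CACHE.get(key)
    if p is None:
        p = min(1.0, 2.0 * stats.binom.cdf(key[0], n, 0.5))
        _PVAL_CACHE[key] = p
    return p


class MatchingPenniesOpponent:
    """The exploitative computer player.

    Keeps the full within-session record of the animal's choices and outcomes
    and incrementally maintains suffix-occurrence counts for the nine history
    conditions, so prediction is O(1) per trial.

    Parameters
    ----------
    alpha_test:
        Significance level of the per-condition binomial tests. ``0`` makes
        the opponent a fair coin.
    counter_mode:
        ``"stochastic"`` plays left with probability ``1 - q*`` where ``q*``
        is the selected left-probability estimate; ``"deterministic"`` plays
        the counter side outright.
    include_miss:
        Whether MISS trials enter the history record (default: excluded).
    """

    def __init__(
        self,
        alpha_test: float = 0.05,
        counter_mode: str = "stochastic",
        include_miss: bool = False,
    ) -> None:
        if counter_mode not in ("stochastic", "deterministic"):
            raise ValueError(f"invalid counter_mode {counter_mode!r}")
        self.alpha_test = float(alpha_test)
        self.counter_mode = counter_mode
        self.include_miss = include_miss
        self.reset()

    def reset(self) -> None:
        self.choice_history: list[str] = []
        self.outcome_history: list[int] = []
        # per condition: suffix -> [n_left_next, n_total]
        self._counts: list[dict[tuple, list[int]]] = [dict() for _ in CONDITIONS]

    # -- state bookkeeping --------------------------------------------------

    def _suffix(self, kind: str, n: int) -> Optional[tuple]:
        ch, oh = self.choice_history, self.outcome_history
        if len(ch) < n:
            return None
        if kind == "choice":
            return tuple(ch[len(ch) - n :])
        return tuple(zip(ch[len(ch) - n :], oh[len(oh) - n :]))

    def observe(self, choice: str, outcome: int) -> None:
        """Record the animal's completed trial."""
        if choice == MISS:
            if not self.include_miss:
                return
        for ci, (kind, n) in enumerate(CONDITIONS):
            key = self._suffix(kind, n)
            if key is None:
                continue
            cnt = self._counts[ci].setdefault(key, [0, 0])
            cnt[0] += choice == L
            cnt[1] += 1
        self.choice_history.append(choice)
        self.outcome_history.append(int(outcome))

    # -- prediction and action ----------------------------------------------

    def predict(self) -> list[ConditionalEstimate]:
        """The nine (estimate, sample size, p-value) triples for the next trial."""
        if len(self.choice_history) != len(self.outcome_history):
            raise ValueError("choice and outcome histories have different lengths")
        out = []
        for ci, (kind, n) in enumerate(CONDITIONS):
            key = self._suffix(kind, n)
            k_left, total = (0, 0)
            if key is not None:
                k_left, total = self._counts[ci].get(key, (0, 0))
            if total == 0:
                est, p = 0.5, 1.0
            else:
                est = k_left / total
                p = binomial_pvalue(k_left, total)
            out.append(ConditionalEstimate((kind, n), est, total, p))
        return out

    def choose(self, rng: np.random.Generator) -> str:
        """Draw the computer's choice for the upcoming trial."""
        q_star = None
        if self.alpha_test > 0:
            best_dev = -1.0
            for e in self.predict():
                if e.n > 0 and e.pvalue < self.alpha_test:
                    dev = abs(e.estimate - 0.5)
                    if dev > best_dev + 1e-15:
                        best_dev = dev
                        q_star = e.estimate
        if q_star is None:
            return L if rng.random() < 0.5 else R
        if self.counter_mode == "deterministic":
            return R if q_star > 0.5 else L
        return L if rng.random() < 1.0 - q_star else R

    def play_trial(self, mouse_choice: str, rng: np.random.Generator) -> tuple[str, int]:
        """One full opponent turn: computer choice, then outcome + bookkeeping."""
        computer = self.choose(rng)
        outcome = int(mouse_choice == computer) if mouse_choice != MISS else 0
        self.observe(mouse_choice, outcome)
        return computer, outcome


def opponent_predict(state: MatchingPenniesOpponent) -> list[ConditionalEstimate]:
    return state.predict()


def opponent_choose(state: MatchingPenniesOpponent, rng: np.random.Generator) -> str:
    return state.choose(rng)


# ---------------------------------------------------------------------------
# two-armed bandit


@dataclass(frozen=True)
class BanditState:
    """Reward-block state of the two-armed bandit."""

    p_left: float = 0.7
    p_right: float = 0.1
    hits_in_block: int = 0
    switch_armed: bool = False
    p_switch: float = 1.0 / 11.0

    def __post_init__(self) -> None:
        if {round(self.p_left, 6), round(self.p_right, 6)} != {0.7, 0.1}:
            raise ValueError("reward probabilities must be the set {0.7, 0.1}")

    @property
    def high_side(self) -> str:
        return L if self.p_left > self.p_right else R


def bandit_step(
    state: BanditState, choice: str, rng: np.random.Generator
) -> tuple[int, BanditState]:
    """Advance the bandit one trial: draw the outcome, count hits, maybe switch.

    The hit counter counts choices of the high-probability side; once it
    reaches 10 the block is armed and every trial (including the 10th-hit
    trial itself) switches the probabilities with probability ``p_switch``,
    which swaps the sides and resets the counter.
    """
    if choice == MISS:
        return 0, state
    if choice not in (L, R):
        raise ValueError(f"invalid choice {choice!r}")
    p = state.p_left if choice == L else state.p_right
    outcome = int(rng.random() < p)
    hits = state.hits_in_block + int(choice == state.high_side)
    armed = hits >= 10
    if armed and rng.random() < state.p_switch:
        new = BanditState(
            p_left=state.p_right,
            p_right=state.p_left,
            hits_in_block=0,
            switch_armed=False,
            p_switch=state.p_switch,
        )
    else:
        new = replace(state, hits_in_block=hits, switch_armed=armed)
    return outcome, new


# ---------------------------------------------------------------------------
# trial timing


@dataclass(frozen=True)
class TimingConfig:
    """Trial-timing constants: response window, consumption, and ITI draw."""

    response_window: float = 2.0
    consumption: float = 3.0
    iti_lambda: float = 1.0 / 3.0
    iti_lo: float = 1.0
    iti_hi: float = 5.0
    max_draws: int = 5

    def __post_init__(self) -> None:
        if not self.iti_lo < self.iti_hi:
            raise ValueError("iti_lo must be < iti_hi")
        if self.max_draws < 1:
            raise ValueError("max_draws must be >= 1")


def truncated_exp_draw(cfg: TimingConfig, rng: np.random.Generator) -> float:
    """Inverse-CDF draw from Exp(iti_lambda) truncated to [iti_lo, iti_hi]."""
    lam = cfg.iti_lambda
    a = math.exp(-lam * cfg.iti_lo)
    b = math.exp(-lam * cfg.iti_hi)
    u = rng.random()
    return -math.log(a - u * (a - b)) / lam


def truncated_exp_mean(cfg: TimingConfig) -> float:
    """Closed-form mean of the truncated exponential ITI draw."""
    lam = cfg.iti_lambda
    lo, hi = cfg.iti_lo, cfg.iti_hi
    a, b = math.exp(-lam * lo), math.exp(-lam * hi)
    num = (lo + 1 / lam) * a - (hi + 1 / lam) * b
    return num / (a - b)


def sample_trial_timing(
    cfg: TimingConfig, penalty_licks: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Return (iti_seconds, total_post_outcome_delay).

    One base draw plus one extra draw per penalty lick, capped at
    ``max_draws`` total; the post-outcome delay adds the consumption window.
    """
    if penalty_licks < 0:
        raise ValueError("penalty_licks must be >= 0")
    n_draws = min(1 + penalty_licks, cfg.max_draws)
    iti = sum(truncated_exp_draw(cfg, rng) for _ in range(n_draws))
    return iti, cfg.consumption + iti
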