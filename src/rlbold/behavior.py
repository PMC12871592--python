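"""Go/no-go odor discrimination task: schedules, simulated agents, events files.

The task is organised in 50-trial blocks (25 presentations of each of two
neutral odorants, in pseudo-random order).  On each 2.5-s trial an odor is
presented for 1 s and the animal has a 2-s response window from odor onset;
licking the go odor delivers a water reward, licking the no-go odor is
unrewarded but never punished.  Inter-trial intervals are drawn uniformly
from 5-12.5 s.  In the reversal phase the go/no-go roles of the two
odorants are swapped.

Schedules, choices and outcomes round-trip through BIDS-style tab-separated
events files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .rl import (
    ACTIONS,
    QState,
    SubjectParams,
    TrialLikelihoodInput,
    decision_variable,
    lick_probability,
    q_update,
)

OUTCOMES = ("Hit", "FA", "CR", "Miss")

#: columns every events table must carry, in on-disk order
EVENTS_COLUMNS = (
    "onset",
    "duration",
    "trial_type",
    "choice",
    "reward",
    "phase",
    "session",
    "block",
    "odor_id",
)


class ConfigurationError(ValueError):
    """A task configuration violates one of its stated constraints."""


@dataclass
class TaskConfig:
    trials_per_block: int = 50
    per_odor_count: int = 25
    block_duration: float = 360.0  # nominal six-minute block label
    odor_duration: float = 1.0
    response_window: float = 2.0
    iti_range: Tuple[float, float] = (5.0, 12.5)
    trial_duration: float = 2.5
    control_odor_fraction: float = 0.0
    reward_volume: float = 2.5  # microliters, metadata only
    seed: int = 0
    max_run_length: Optional[int] = None  # cap on consecutive same-odor trials

    def __post_init__(self) -> None:
        if 2 * self.per_odor_count > self.trials_per_block:
            raise ConfigurationError(
                "per_odor_count x 2 exceeds trials_per_block "
                f"({self.per_odor_count} x 2 > {self.trials_per_block})"
            )
        if self.iti_range[0] > self.iti_range[1]:
            raise ConfigurationError(
                f"iti_range min > max: {self.iti_range}"
            )
        for name in ("block_duration", "odor_duration", "response_window", "trial_duration"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.iti_range[0] <= 0:
            raise ConfigurationError("iti_range values must be positive")
        if not 0.0 <= self.control_odor_fraction < 1.0:
            raise ConfigurationError("control_odor_fraction must lie in [0, 1)")
        if self.n_control + 2 * self.per_odor_count != self.trials_per_block:
            raise ConfigurationError(
                "control_odor_fraction inconsistent with block composition: "
                f"{self.n_control} control + 2 x {self.per_odor_count} != "
                f"{self.trials_per_block} trials"
            )

    @property
    def n_control(self) -> int:
        return int(round(self.control_odor_fraction * self.trials_per_block))


@dataclass
class Trial:
    trial_index: int
    session_index: int
    block_index: int
    phase: str  # acquisition | reversal
    odor_id: str  # A | B | control
    odor_role: str  # go | nogo | control
    onset: float  # seconds within the run (block)


@dataclass
class TaskSchedule:
    trials: List[Trial]
    config: TaskConfig

    def __len__(self) -> int:
        return len(self.trials)

    def odor_codes(self) -> np.ndarray:
        """Integer codes into QState.odors, by each trial's *role in acquisition*.

        The Q-learning state is keyed by odor identity, not by current role;
        code 0 is the odor that is `go` during acquisition (odor A), code 1
        its partner (odor B), code 2 the control stream.
        """
        mapping = {"A": 0, "B": 1, "control": 2}
        return np.array([mapping[t.odor_id] for t in self.trials], dtype=np.int64)


@dataclass
class BehaviorRecord:
    choice: np.ndarray  # 1 lick, 0 no-lick
    reward: np.ndarray
    outcome: List[str]  # Hit | FA | CR | Miss | control
    dv: Optional[np.ndarray] = None
    theta: Optional[np.ndarray] = None
    q_trajectory: Optional[np.ndarray] = None  # (T, 3, 2), values after each update
    params: Optional[SubjectParams] = None
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.choice)

    def likelihood_input(self, schedule: TaskSchedule) -> TrialLikelihoodInput:
        return TrialLikelihoodInput(schedule.odor_codes(), self.choice, self.reward)


def classify_outcome(odor_role: str, choice: str) -> str:
    """Hit / FA / CR / Miss from role x choice; control trials form their own class."""
    if odor_role == "control":
        return "control"
    if odor_role not in ("go", "nogo"):
        raise ValueError(f"odor_role must be go/nogo/control, got {odor_role!r}")
    if choice not in ("lick", "nolick"):
        raise ValueError(f"choice must be lick or nolick, got {choice!r}")
    table = {
        ("go", "lick"): "Hit",
        ("nogo", "lick"): "FA",
        ("nogo", "nolick"): "CR",
        ("go", "nolick"): "Miss",
    }
    return table[(odor_role, choice)]


def _role_for(odor_id: str, phase: str) -> str:
    if odor_id == "control":
        return "control"
    if phase == "acquisition":
        return "go" if odor_id == "A" else "nogo"
    return "nogo" if odor_id == "A" else "go"


def _block_odor_order(config: TaskConfig, rng: np.random.Generator) -> List[str]:
    odors = (
        ["A"] * config.per_odor_count
        + ["B"] * config.per_odor_count
        + ["control"] * config.n_control
    )
    for _ in range(10_000):
        order = list(rng.permutation(odors))
        if config.max_run_length is None:
            return order
        run, ok = 1, True
        for prev, cur in zip(order, order[1:]):
            run = run + 1 if cur == prev else 1
            if run > config.max_run_length:
                ok = False
                break
        if ok:
            return order
    raise ConfigurationError(
        f"could not satisfy max_run_length={config.max_run_length} "
        "for the block odor composition"
    )


def generate_schedule(
    config: TaskConfig,
    n_blocks: int,
    reversal_at_block: Optional[int] = None,
    *,
    blocks_per_session: int = 1,
    enforce_block_duration: bool = False,
) -> TaskSchedule:
    """Pseudo-random task schedule of ``n_blocks`` blocks.

    ``reversal_at_block`` (1-based) marks the first block of the reversal
    phase; from there the go/no-go roles of odors A and B are swapped.
    Onsets restart at zero in each block (each block is one fMRI run) with
    successive onsets separated by ``trial_duration`` plus a uniform ITI.

    The nominal ``block_duration`` is metadata: 50 trials with these ITIs
    necessarily span slightly more than six minutes.  With
    ``enforce_block_duration=True`` the worst-case block length is checked
    and a :class:`ConfigurationError` names the violated constraint.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if reversal_at_block is not None and not 1 <= reversal_at_block <= n_blocks:
        raise ValueError(
            f"reversal_at_block must lie in [1, {n_blocks}], got {reversal_at_block}"
        )
    if enforce_block_duration:
        min_span = (config.trials_per_block - 1) * (
            config.trial_duration + config.iti_range[0]
        ) + config.trial_duration
        if min_span > config.block_duration:
            raise ConfigurationError(
                f"{config.trials_per_block} trials need at least {min_span:.1f} s "
                f"(trial_duration + minimum ITI) but block_duration is "
                f"{config.block_duration:.1f} s"
            )
    rng = np.random.default_rng(config.seed)
    trials: List[Trial] = []
    t_index = 0
    for b in range(n_blocks):
        phase = (
            "reversal"
            if reversal_at_block is not None and (b + 1) >= reversal_at_block
            else "acquisition"
        )
        order = _block_odor_order(config, rng)
        onset = float(rng.uniform(*config.iti_range))
        for odor_id in order:
            trials.append(
                Trial(
                    trial_index=t_index,
                    session_index=b // blocks_per_session,
                    block_index=b,
                    phase=phase,
                    odor_id=odor_id,
                    odor_role=_role_for(odor_id, phase),
                    onset=onset,
                )
            )
            onset += config.trial_duration + float(rng.uniform(*config.iti_range))
            t_index += 1
    return TaskSchedule(trials=trials, config=config)


def simulate_agent(
    schedule: TaskSchedule, params: SubjectParams, seed: int
) -> BehaviorRecord:
    """Simulate choices of a Q-learning agent on a schedule.

    Values start at zero and carry over across blocks, sessions and the
    reversal boundary (no reset).  On each trial the lick probability is
    computed from the current values of the presented odor, the choice is
    drawn, reward assigned by the current contingency, and only the
    realized (odor, action) value is updated.
    """
    rng = np.random.default_rng(seed)
    state = QState()
    codes = schedule.odor_codes()
    n = len(schedule)
    choice = np.zeros(n, dtype=np.int64)
    reward = np.zeros(n, dtype=np.int64)
    dv = np.zeros(n)
    theta = np.zeros(n)
    q_traj = np.zeros((n, 3, 2))
    outcomes: List[str] = []
    for t, trial in enumerate(schedule.trials):
        o = int(codes[t])
        dv[t] = decision_variable(state, o)
        theta[t] = lick_probability(dv[t], params.beta0, params.beta1)
        c = int(rng.random() < theta[t])
        choice[t] = c
        r = int(trial.odor_role == "go" and c == 1)
        reward[t] = r
        action = ACTIONS[c]
        state.set(o, action, q_update(state.get(o, action), r, params.alpha))
        q_traj[t] = state.values
        outcomes.append(
            classify_outcome(trial.odor_role, "lick" if c else "nolick")
        )
    return BehaviorRecord(
        choice=choice,
        reward=reward,
        outcome=outcomes,
        dv=dv,
        theta=theta,
        q_trajectory=q_traj,
        params=params,
        seed=seed,
    )


def write_events_table(
    record: BehaviorRecord, schedule: TaskSchedule, path
) -> pd.DataFrame:
    """Write a BIDS-style events.tsv; the odor event duration is the 1-s pulse."""
    rows = []
    for t, trial in enumerate(schedule.trials):
        rows.append(
            {
                "onset": trial.onset,
                "duration": schedule.config.odor_duration,
                "trial_type": f"{trial.odor_role}_{record.outcome[t]}",
                "choice": int(record.choice[t]),
                "reward": int(record.reward[t]),
                "phase": trial.phase,
                "session": trial.session_index,
                "block": trial.block_index,
                "odor_id": trial.odor_id,
            }
        )
        if record.dv is not None:
            rows[-1]["dv"] = float(record.dv[t])
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_events_table(path, config: Optional[TaskConfig] = None):
    """Read an events.tsv back into (TaskSchedule, BehaviorRecord)."""
    df = pd.read_csv(path, sep="\t")
    for col in EVENTS_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"events table is missing required column {col!r}")
    trials = []
    outcomes = []
    for i, row in df.iterrows():
        role, outcome = str(row["trial_type"]).split("_", 1)
        outcomes.append(outcome)
        trials.append(
            Trial(
                trial_index=i,
                session_index=int(row["session"]),
                block_index=int(row["block"]),
                phase=str(row["phase"]),
                odor_id=str(row["odor_id"]),
                odor_role=role,
                onset=float(row["onset"]),
            )
        )
    schedule = TaskSchedule(trials=trials, config=config or TaskConfig())
    record = BehaviorRecord(
        choice=df["choice"].to_numpy(dtype=np.int64),
        reward=df["reward"].to_numpy(dtype=np.int64),
        outcome=outcomes,
        dv=df["dv"].to_numpy(dtype=float) if "dv" in df.columns else None,
    )
    return schedule, record
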