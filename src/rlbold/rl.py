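"""Q-learning model of go/no-go odor discrimination.

The agent maintains one value per (odor, action) pair — three odors
(go-odor, no-go-odor, control) times two actions (lick, no-lick), six
values in total.  After each trial the value of the realized pair is
nudged toward the obtained reward by the learning rate ``alpha``::

    Q <- Q + alpha * (r - Q)

The decision variable for the presented odor ``o`` is

    dV = Q(o, lick) - Q(o, nolick)

and the lick probability follows a logistic policy

    P(lick) = 1 / (1 + exp(-(beta0 + beta1 * dV)))

where ``beta0`` is a lick-bias intercept and ``beta1`` an inverse
temperature.  All functions here are pure; no file I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit

ODORS = ("go", "nogo", "control")
ACTIONS = ("nolick", "lick")

# lick probabilities are clipped to this band inside the likelihood so a
# single extreme parameter draw cannot produce -inf during sampling
THETA_CLIP = 1e-12


@dataclass
class SubjectParams:
    """Per-subject model parameters."""

    alpha: float
    beta0: float
    beta1: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")


@dataclass
class QState:
    """The six Q(odor, action) values, indexed by odor id and action name."""

    values: np.ndarray = field(default_factory=lambda: np.zeros((3, 2)))
    odors: tuple = ODORS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.odors), 2):
            raise ValueError(
                f"QState needs {len(self.odors)}x2 values, got {self.values.shape}"
            )

    @property
    def n_values(self) -> int:
        return self.values.size

    def _odor_index(self, odor_id) -> int:
        if isinstance(odor_id, (int, np.integer)):
            if not 0 <= odor_id < len(self.odors):
                raise KeyError(f"unknown odor index {odor_id}")
            return int(odor_id)
        try:
            return self.odors.index(odor_id)
        except ValueError:
            raise KeyError(f"unknown odor {odor_id!r}") from None

    def get(self, odor_id, action: str) -> float:
        return float(self.values[self._odor_index(odor_id), ACTIONS.index(action)])

    def set(self, odor_id, action: str, value: float) -> None:
        self.values[self._odor_index(odor_id), ACTIONS.index(action)] = value


@dataclass
class TrialLikelihoodInput:
    """Realized trial sequence for one subject: odor codes, choices, rewards.

    ``odor`` holds integer codes into ``QState.odors``; ``choice`` is 1 for
    lick, 0 for no-lick; ``reward`` is 1 for a rewarded lick else 0.
    """

    odor: np.ndarray
    choice: np.ndarray
    reward: np.ndarray

    def __post_init__(self) -> None:
        self.odor = np.asarray(self.odor, dtype=np.int64)
        self.choice = np.asarray(self.choice, dtype=np.int64)
        self.reward = np.asarray(self.reward, dtype=np.int64)
        n = len(self.odor)
        if len(self.choice) != n or len(self.reward) != n:
            raise ValueError("odor, choice and reward must have equal length")
        if n and (self.choice.min() < 0 or self.choice.max() > 1):
            raise ValueError("choices must be 0/1")
        if n and (self.reward.min() < 0 or self.reward.max() > 1):
            raise ValueError("rewards must be 0/1")

    def __len__(self) -> int:
        return len(self.odor)


def q_update(q: float, r: float, alpha: float) -> float:
    """Delta-rule update of a single value toward the obtained reward."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return q + alpha * (r - q)


def decision_variable(state: QState, odor_id) -> float:
    """Q(o, lick) - Q(o, nolick) for the presented odor."""
    return state.get(odor_id, "lick") - state.get(odor_id, "nolick")


def lick_probability(dv: float, beta0: float, beta1: float):
    """Logistic lick policy; numerically stable for arbitrarily large inputs."""
    return expit(beta0 + beta1 * np.asarray(dv, dtype=float))


def forward_pass(inp: TrialLikelihoodInput, alpha: float):
    """Run the value recursion over a realized choice/reward sequence.

    Returns ``(dv, q_before)`` where ``dv[t]`` is the decision variable of
    the presented odor at trial ``t`` (computed from the values *before*
    the trial-t update) and ``q_before`` is the full (T, 3, 2) trajectory
    of values entering each trial.

    Within the sub-sequence of trials on which a given (odor, action) pair
    is realized, the update is a first-order exponential filter
    ``q' = (1 - alpha) q + alpha r``, so each of the six streams is
    evaluated with a linear filter and scattered back onto the trial axis.
    """
    n = len(inp)
    q_before = np.zeros((n, 3, 2))
    dv = np.zeros(n)
    if n == 0:
        return dv, q_before
    trial_idx = np.arange(n)
    for o in range(3):
        on_o = inp.odor == o
        for a in (0, 1):
            idx = trial_idx[on_o & (inp.choice == a)]
            if not idx.size:
                continue  # value never updated; stays at its zero initialization
            r_sub = inp.reward[idx].astype(float)
            # y[k] = (1-alpha) y[k-1] + alpha r[k], y[-1] = 0
            q_after = lfilter([alpha], [1.0, -(1.0 - alpha)], r_sub)
            # value entering trial t = value after the last stream event < t
            pos = np.searchsorted(idx, trial_idx, side="left")
            q_before[:, o, a] = np.where(pos == 0, 0.0, q_after[np.maximum(pos - 1, 0)])
    dv = q_before[trial_idx, inp.odor, 1] - q_before[trial_idx, inp.odor, 0]
    return dv, q_before


def sequence_loglik(inp: TrialLikelihoodInput, params: SubjectParams):
    """Bernoulli log-likelihood of a choice sequence under the model.

    Returns ``(loglik, theta, dv)``; the per-trial lick probabilities and
    decision variables are reused downstream as fMRI regressors.
    """
    dv, _ = forward_pass(inp, params.alpha)
    theta = lick_probability(dv, params.beta0, params.beta1)
    theta = np.clip(theta, THETA_CLIP, 1.0 - THETA_CLIP)
    c = inp.choice
    ll = float(np.sum(c * np.log(theta) + (1 - c) * np.log1p(-theta)))
    return ll, theta, dv


def _loglik_only(odor, choice, reward, alpha, beta0, beta1) -> float:
    """Hot path used by the sampler: same math as sequence_loglik, no wrapping."""
    inp = TrialLikelihoodInput.__new__(TrialLikelihoodInput)
    inp.odor, inp.choice, inp.reward = odor, choice, reward
    dv, _ = forward_pass(inp, alpha)
    theta = np.clip(expit(beta0 + beta1 * dv), THETA_CLIP, 1.0 - THETA_CLIP)
    return float(np.sum(choice * np.log(theta) + (1 - choice) * np.log1p(-theta)))
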