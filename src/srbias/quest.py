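"""Bayesian adaptive staircase (QUEST) for titrating letter luminance.

Maintains a discretized posterior over the log10 threshold of a Weibull
psychometric function and places each trial at the current posterior-mean
threshold.  The staircase targets 70% correct in the 6-alternative
forced-choice letter task (guess rate 1/6), and the titrated letter
increment from its final estimate is used for all subsequent blocks.

Intensity is log10 of the letter increment above the fixed grey background,
not absolute luminance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "QuestParams", "QuestState", "quest_init", "quest_likelihood",
    "quest_update", "quest_next_intensity", "quest_estimate", "run_titration",
]


@dataclass(frozen=True)
class QuestParams:
    """Psychometric model and prior for the staircase.

    beta : Weibull slope.
    delta : lapse probability.
    gamma : guess rate (1/6 for the 6AFC letter task).
    target_p : proportion correct the staircase aims for.
    grid : ordered candidate log10-threshold values.
    prior_mean, prior_sd : Gaussian prior over the log10 threshold.
    """

    beta: float = 3.5
    delta: float = 0.01
    gamma: float = 1.0 / 6.0
    target_p: float = 0.70
    prior_mean: float = 0.0
    prior_sd: float = 1.0
    grid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma < self.target_p < 1.0 - self.delta):
            raise ValueError("need 0 < gamma < target_p < 1 - delta")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")
        if self.grid is None:
            g = np.linspace(self.prior_mean - 2.5, self.prior_mean + 2.5, 201)
            object.__setattr__(self, "grid", g)
        else:
            g = np.asarray(self.grid, dtype=float)
            if g.size == 0:
                raise ValueError("grid must be nonempty")
            if g.size > 1 and np.any(np.diff(g) <= 0):
                raise ValueError("grid must be strictly increasing")
            object.__setattr__(self, "grid", g)


@dataclass(frozen=True)
class QuestState:
    params: QuestParams
    log_posterior: np.ndarray
    history: tuple[tuple[float, bool], ...] = ()

    @property
    def posterior(self) -> np.ndarray:
        """Normalized posterior probabilities over the grid."""
        w = np.exp(self.log_posterior - self.log_posterior.max())
        return w / w.sum()


def quest_init(params: QuestParams) -> QuestState:
    """Posterior initialized to the discretized Gaussian prior."""
    z = (params.grid - params.prior_mean) / params.prior_sd
    logp = -0.5 * z ** 2
    logp -= np.log(np.sum(np.exp(logp - logp.max()))) + logp.max()
    return QuestState(params=params, log_posterior=logp)


def quest_likelihood(log_intensity, log_threshold, params: QuestParams):
    """Weibull probability correct at a given log10 intensity and threshold.

    p = delta*gamma + (1-delta) * [1 - (1-gamma) * exp(-10**(beta*(x - T)))]

    Bounded in [gamma, 1 - delta*(1-gamma)] and monotone nondecreasing in
    the intensity.
    """
    x = np.asarray(log_intensity, dtype=float)
    t = np.asarray(log_threshold, dtype=float)
    expo = np.clip(params.beta * (x - t), -20.0, 20.0)
    p_detect = 1.0 - (1.0 - params.gamma) * np.exp(-np.power(10.0, expo))
    return params.delta * params.gamma + (1.0 - params.delta) * p_detect


def quest_update(state: QuestState, tested_log_intensity: float,
                 correct: bool) -> QuestState:
    """Bayes update of the threshold posterior with one trial outcome."""
    p = quest_likelihood(tested_log_intensity, state.params.grid, state.params)
    like = p if correct else 1.0 - p
    logp = state.log_posterior + np.log(np.clip(like, 1e-300, None))
    logp = logp - (np.log(np.sum(np.exp(logp - logp.max()))) + logp.max())
    return QuestState(params=state.params, log_posterior=logp,
                      history=state.history + ((float(tested_log_intensity), bool(correct)),))


def quest_next_intensity(state: QuestState) -> float:
    """Posterior-mean placement rule, clamped to the grid range."""
    mean = float(np.dot(state.posterior, state.params.grid))
    return float(np.clip(mean, state.params.grid[0], state.params.grid[-1]))


def quest_estimate(state: QuestState) -> tuple[float, float]:
    """Posterior-mean log10 threshold and the implied increment (grey units)."""
    est = float(np.dot(state.posterior, state.params.grid))
    return est, float(10.0 ** est)


def run_titration(params: QuestParams, respond, n_trials: int = 50,
                  rng=None) -> QuestState:
    """Drive a full staircase against a responder.

    ``respond(log_intensity, rng) -> bool`` supplies each trial's outcome
    (a simulated observer or a bridge to recorded data).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(rng)
    state = quest_init(params)
    for _ in range(n_trials):
        x = quest_next_intensity(state)
        state = quest_update(state, x, bool(respond(x, rng)))
    return state


def weibull_responder(true_log_threshold: float, params: QuestParams):
    """Simulated observer whose true psychometric function is the QUEST model."""
    def respond(log_intensity: float, rng: np.random.Generator) -> bool:
        p = float(quest_likelihood(log_intensity, true_log_threshold, params))
        return bool(rng.random() < p)
    return respond
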