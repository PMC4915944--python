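"""QUEST adaptive staircase driving a simulated 2-AFC speed comparison.

Each staircase compares a fixed reference grating (speed ``v_ref``, contrast
``c_ref``) with a test grating of higher contrast whose speed is adjusted from
trial to trial.  QUEST maintains a posterior over the point of subjective
equality (PSE) on a log-spaced speed grid; every trial is placed at the current
posterior mode, the simulated observer answers by sampling its two Gaussian
posteriors, and the final posterior mode after a fixed number of trials is
recorded as the PSE.

The psychometric kernel used for the Bayesian update is a Weibull (Gumbel) in
log10 speed whose *median* sits at the candidate PSE, so that the response
probability is exactly 0.5 when the shown test speed equals the candidate:
this is the appropriate centring for a matching task, where the quantity of
interest is the 50% point rather than a detection threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Union

import numpy as np

from .models import ObserverSpec, posterior_mean, posterior_var

__all__ = [
    "QuestConfig",
    "QuestState",
    "TrialRecord",
    "StaircaseResult",
    "init_state",
    "quest_recommend",
    "quest_update",
    "simulate_choice",
    "run_staircase",
]

RngLike = Union[int, np.random.Generator]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class QuestConfig:
    """QUEST staircase settings.

    The grid, psychometric slope and lapse rate are procedure internals (not
    dictated by the task design); defaults follow common QUEST practice.
    ``prior_mean_guess=None`` centres the initial PSE prior on the reference
    speed of the condition being run.
    """

    grid_lo: float = 0.05  # deg/s
    grid_hi: float = 40.0  # deg/s
    grid_n: int = 201
    prior_mean_guess: Optional[float] = None  # deg/s
    prior_sd: float = 0.5  # log10 units
    slope_beta: float = 3.5
    lapse_delta: float = 0.01
    guess_gamma: float = 0.5  # 2-AFC chance level
    n_trials: int = 35

    def __post_init__(self):
        if self.grid_lo <= 0 or self.grid_lo >= self.grid_hi:
            raise ValueError("require 0 < grid_lo < grid_hi")
        if self.grid_n < 2:
            raise ValueError("grid_n must be at least 2")
        if not 0 <= self.lapse_delta < 0.1:
            raise ValueError("lapse_delta must lie in [0, 0.1)")
        if self.guess_gamma != 0.5:
            raise ValueError("guess_gamma must be 0.5 for a 2-AFC task")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")


@dataclass(frozen=True)
class QuestState:
    """Posterior over candidate PSEs on a fixed log10-speed grid (unnormalized)."""

    log_speed_grid: np.ndarray  # log10 deg/s
    log_posterior: np.ndarray

    def __post_init__(self):
        if not np.any(np.isfinite(self.log_posterior)):
            raise ValueError("posterior must be finite at one or more grid points")
        object.__setattr__(self, "log_speed_grid", np.asarray(self.log_speed_grid, float))
        object.__setattr__(self, "log_posterior", np.asarray(self.log_posterior, float))


@dataclass(frozen=True)
class TrialRecord:
    session: int
    condition_id: str
    staircase_id: int
    trial_index: int
    v_ref: float
    c_ref: float
    v_test: float
    c_test: float
    reference_side: str  # "left" | "right"
    response_test_faster: bool

    def __post_init__(self):
        if not self.c_ref < self.c_test:
            raise ValueError("reference must be the lower-contrast grating")
        if self.reference_side not in ("left", "right"):
            raise ValueError("reference_side must be 'left' or 'right'")


@dataclass(frozen=True)
class StaircaseResult:
    condition_id: str
    session: int
    pse: float  # deg/s
    n_trials: int
    trials: List[TrialRecord]
    staircase_id: int = 0


def init_state(config: QuestConfig, prior_mean_guess: Optional[float] = None) -> QuestState:
    """Fresh QUEST state: log-spaced grid with a Gaussian prior in log10 speed."""
    guess = prior_mean_guess if prior_mean_guess is not None else config.prior_mean_guess
    if guess is None:
        raise ValueError("an initial PSE guess is required")
    if guess <= 0:
        raise ValueError("prior_mean_guess must be positive")
    grid = np.linspace(np.log10(config.grid_lo), np.log10(config.grid_hi), config.grid_n)
    log_prior = -0.5 * ((grid - np.log10(guess)) / config.prior_sd) ** 2
    return QuestState(log_speed_grid=grid, log_posterior=log_prior)


def quest_recommend(state: QuestState) -> float:
    """Test speed at the posterior mode (ties broken toward the lower speed)."""
    idx = int(np.argmax(state.log_posterior))  # argmax takes the first maximum
    return float(10.0 ** state.log_speed_grid[idx])


def _kernel_p_faster(config: QuestConfig, z: np.ndarray) -> np.ndarray:
    """P(respond 'test faster') at log10 speed offset z from the candidate PSE.

    Median-centred Weibull in log10 speed: exactly 0.5 at z = 0, approaching
    the lapse-limited asymptotes ``delta`` and ``1 - delta``.
    """
    core = 1.0 - np.exp2(-np.power(10.0, config.slope_beta * z))
    d = config.lapse_delta
    return d + (1.0 - 2.0 * d) * core


def quest_update(
    state: QuestState,
    shown_speed: float,
    response_test_faster: bool,
    config: QuestConfig,
) -> QuestState:
    """Bayesian update of the PSE posterior after one trial.

    Adds the log psychometric kernel evaluated at the shown speed relative to
    every candidate PSE; updates commute across trial order.
    """
    if shown_speed <= 0:
        raise ValueError("shown_speed must be positive")
    z = np.log10(shown_speed) - state.log_speed_grid
    p = _kernel_p_faster(config, z)
    lik = p if response_test_faster else 1.0 - p
    with np.errstate(divide="ignore"):
        log_lik = np.log(lik)
    return replace(state, log_posterior=state.log_posterior + log_lik)


def simulate_choice(
    observer: ObserverSpec,
    v_ref: float,
    c_ref: float,
    v_test: float,
    c_test: float,
    rng_seed: RngLike,
) -> bool:
    """One simulated 2-AFC response: is the test grating judged faster?

    The observer draws one sample from each grating's Gaussian posterior and
    chooses the grating with the larger sampled speed.
    """
    rng = _rng(rng_seed)
    e_ref = posterior_mean(observer, v_ref, c_ref)
    e_test = posterior_mean(observer, v_test, c_test)
    sd_ref = np.sqrt(posterior_var(observer, v_ref, c_ref))
    sd_test = np.sqrt(posterior_var(observer, v_test, c_test))
    sample_ref = rng.normal(e_ref, sd_ref)
    sample_test = rng.normal(e_test, sd_test)
    return bool(sample_test > sample_ref)


def run_staircase(
    observer: ObserverSpec,
    condition,
    config: QuestConfig,
    rng_seed: RngLike,
    session: int = 1,
    staircase_id: int = 0,
) -> StaircaseResult:
    """Run one full QUEST staircase for a condition and record its PSE.

    ``condition`` needs attributes ``condition_id``, ``v_ref``, ``c_ref`` and
    ``c_test``.  The reference side is randomized once per staircase (fixed
    within it, as in the task design) and logged; it does not influence the
    simulated observer.
    """
    rng = _rng(rng_seed)
    reference_side = "left" if rng.random() < 0.5 else "right"
    state = init_state(config, prior_mean_guess=condition.v_ref)
    trials: List[TrialRecord] = []
    for t in range(config.n_trials):
        v_test = quest_recommend(state)
        response = simulate_choice(
            observer, condition.v_ref, condition.c_ref, v_test, condition.c_test, rng
        )
        state = quest_update(state, v_test, response, config)
        trials.append(
            TrialRecord(
                session=session,
                condition_id=condition.condition_id,
                staircase_id=staircase_id,
                trial_index=t,
                v_ref=condition.v_ref,
                c_ref=condition.c_ref,
                v_test=v_test,
                c_test=condition.c_test,
                reference_side=reference_side,
                response_test_faster=response,
            )
        )
    return StaircaseResult(
        condition_id=condition.condition_id,
        session=session,
        pse=quest_recommend(state),
        n_trials=config.n_trials,
        trials=trials,
        staircase_id=staircase_id,
    )
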