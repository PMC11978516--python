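"""Generative agents: logistic choice policies and a mood model.

Agents "play" the task through :func:`predforage.engine.run_session`.
Choices follow the same logistic regressions later used to analyze them:

* pre-discovery — P(check vs forage) is a logistic function of reward,
  time pressure, whether a check sequence is underway, predator speed,
  number of cones, block index and a first-epoch flag;
* post-discovery — first P(hide), then P(forage vs check | not hiding),
  both logistic in reward, position uncertainty, proximity and the same
  block-level controls.

Regressors are standardized with the fixed reference scaling in
:mod:`predforage.features` so generative weights and refit weights share
a scale.

Mood (stress, excitement on 0-100) is generated per block as a linear
function of block features, with an AR(1)-style carryover and an optional
homeostatic loop: the stress residual raises the next block's foraging
and hiding propensity, while the block's foraging rate lowers the next
stress rating.  The generative mood direction is this package's own
construction; only the descriptive (fitting) direction is constrained by
the analysis models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .features import standardize

__all__ = [
    "PolicyParams",
    "MoodGenParams",
    "policy_choice",
    "generate_moods",
    "LogisticPolicyAgent",
    "ScriptedAgent",
    "PRE_REGRESSORS",
    "POST_REGRESSORS",
]

PRE_REGRESSORS = (
    "reward",
    "time_pressure",
    "check_seq_started",
    "speed_rank",
    "n_cones",
    "env_index",
    "first_epoch",
)
POST_REGRESSORS = (
    "reward",
    "position_uncertainty",
    "proximity",
    "speed_rank",
    "n_cones",
    "env_index",
    "first_epoch",
)

#: scaling used to standardize block-level mood regressors
MOOD_SCALING = {
    "reward_max": (65.0, 17.0),
    "reward_min": (25.0, 17.0),
    "speed_rank": (1.0, 0.8165),
    "n_cones": (2.5, 1.118),
    "lives_gained": (1.0, 1.0),
    "block_index": (9.5, 5.766),
    "caught": (0.25, 0.5),
}


@dataclass
class PolicyParams:
    """Weights of the three logistic choice models plus timing parameters.

    ``pre`` orders as (intercept,) + PRE_REGRESSORS with the positive class
    being *check*; ``post_hide`` and ``post_fc`` order as (intercept,) +
    POST_REGRESSORS with positive classes *hide* and *forage*.
    """

    pre: np.ndarray
    post_hide: np.ndarray
    post_fc: np.ndarray
    decision_rate: float = 2.5  # polls per second
    inactive_press_rate: float = 0.15  # vigor: presses per locked second

    def __post_init__(self):
        self.pre = np.asarray(self.pre, dtype=float)
        self.post_hide = np.asarray(self.post_hide, dtype=float)
        self.post_fc = np.asarray(self.post_fc, dtype=float)
        if self.pre.shape != (8,) or self.post_hide.shape != (8,) or self.post_fc.shape != (8,):
            raise ValueError("each weight vector must have 8 entries (intercept + 7)")
        if not (
            np.all(np.isfinite(self.pre))
            and np.all(np.isfinite(self.post_hide))
            and np.all(np.isfinite(self.post_fc))
        ):
            raise ValueError("policy weights must be finite")
        if self.decision_rate <= 0 or self.inactive_press_rate < 0:
            raise ValueError("rates must be positive")

    @staticmethod
    def default() -> "PolicyParams":
        """A competent mid-range player: forages when safe, checks under
        time pressure, hides as the discovered predator closes in."""
        return PolicyParams(
            pre=[-0.9, -0.4, 3.2, 0.6, 0.3, 0.2, 0.0, 0.0],
            post_hide=[0.5, -0.3, 0.6, 3.5, 0.6, 0.0, 0.0, 0.0],
            post_fc=[0.8, 0.5, 0.0, -0.4, -0.2, 0.0, 0.0, 0.0],
            decision_rate=2.5,
        )

    def as_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.pre, self.post_hide, self.post_fc, [self.decision_rate, self.inactive_press_rate]]
        )

    @staticmethod
    def names() -> list:
        out = [f"pre_{n}" for n in ("intercept",) + PRE_REGRESSORS]
        out += [f"hide_{n}" for n in ("intercept",) + POST_REGRESSORS]
        out += [f"fc_{n}" for n in ("intercept",) + POST_REGRESSORS]
        return out + ["decision_rate", "inactive_press_rate"]


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def _eta(weights, names, view) -> float:
    eta = weights[0]
    for w, name in zip(weights[1:], names):
        eta += w * standardize(name, view[name])
    if not math.isfinite(eta):
        raise ValueError("non-finite linear predictor")
    return eta


def _fold(weights, names):
    """Fold (mean, sd) standardization into raw-scale coefficients."""
    from .features import FEATURE_SCALING

    c = [float(weights[0])]
    for w, name in zip(weights[1:], names):
        m, s = FEATURE_SCALING[name]
        c[0] -= w * m / s
        c.append(w / s)
    return c


def policy_choice(phase: str, features: dict, params: PolicyParams, rng) -> str:
    """Sample one action from the logistic policy for the given phase."""
    if phase == "pre":
        p_check = _logistic(_eta(params.pre, PRE_REGRESSORS, features))
        return "check" if rng.random() < p_check else "forage"
    if phase == "post":
        if rng.random() < _logistic(_eta(params.post_hide, POST_REGRESSORS, features)):
            return "hide"
        p_forage = _logistic(_eta(params.post_fc, POST_REGRESSORS, features))
        return "forage" if rng.random() < p_forage else "check"
    raise ValueError(f"unknown phase {phase!r}")


@dataclass
class MoodGenParams:
    """Generative mood parameters (stress and excitement, 0-100 scales).

    ``stress_w`` / ``excite_w`` weight the standardized block features
    (reward_max, reward_min, speed_rank, n_cones, lives_gained,
    block_index, caught).  ``gain_stress_to_forage`` shifts the next
    block's pre-discovery forage propensity (logit units per 10 points of
    stress residual), ``gain_stress_to_hide`` does the same for hiding,
    and ``gain_forage_to_stress`` lowers the next stress rating per
    standardized unit of foraging rate (negative = homeostatic relief).
    """

    stress_base: float = 45.0
    excite_base: float = 50.0
    stress_w: dict = field(
        default_factory=lambda: {
            "reward_max": 2.0,
            "reward_min": 1.0,
            "speed_rank": 6.0,
            "n_cones": 3.0,
            "lives_gained": 0.0,
            "block_index": -2.0,
            "caught": 8.0,
        }
    )
    excite_w: dict = field(
        default_factory=lambda: {
            "reward_max": 4.0,
            "reward_min": 2.0,
            "speed_rank": 5.0,
            "n_cones": 2.0,
            "lives_gained": 3.0,
            "block_index": -2.0,
            "caught": -5.0,
        }
    )
    carryover: float = 0.2
    gain_stress_to_forage: float = 0.0
    gain_stress_to_hide: float = 0.0
    gain_forage_to_stress: float = 0.0
    noise_sd: float = 8.0


def generate_moods(block_summary: dict, params: MoodGenParams, prev_state: dict, rng):
    """One (stress, excitement) pair for a finished block.

    ``prev_state`` carries ``stress_resid`` / ``excite_resid`` from the
    previous block (0.0 at the start of a session) and is updated in
    place with the new residuals.
    """
    z = {k: standardize_mood(k, block_summary[k]) for k in MOOD_SCALING}
    stress_pred = params.stress_base + sum(params.stress_w[k] * z[k] for k in z)
    excite_pred = params.excite_base + sum(params.excite_w[k] * z[k] for k in z)
    stress_pred += params.carryover * prev_state.get("stress_resid", 0.0)
    excite_pred += params.carryover * prev_state.get("excite_resid", 0.0)
    forage_z = (block_summary.get("forage_rate", 0.0) - 0.35) / 0.15
    homeo = params.gain_forage_to_stress * forage_z
    stress = stress_pred + homeo + rng.normal(0.0, params.noise_sd)
    excite = excite_pred + rng.normal(0.0, params.noise_sd)
    stress = min(100.0, max(0.0, stress))
    excite = min(100.0, max(0.0, excite))
    # residual relative to the task-predicted component (what the
    # homeostatic loop responds to)
    prev_state["stress_resid"] = stress - stress_pred
    prev_state["excite_resid"] = excite - excite_pred
    return stress, excite


def standardize_mood(name: str, value: float) -> float:
    m, s = MOOD_SCALING[name]
    return (value - m) / s


class LogisticPolicyAgent:
    """Plays the task with :func:`policy_choice`; rates mood after blocks."""

    def __init__(self, params: PolicyParams, mood: MoodGenParams = None):
        self.params = params
        self.mood = mood or MoodGenParams()
        self.decision_rate = params.decision_rate
        self.inactive_press_rate = params.inactive_press_rate
        self._mood_state = {}
        self._pre_shift = 0.0
        self._hide_shift = 0.0
        # fold the fixed reference scaling into the weights once:
        # eta = w0 + sum w_i (x_i - m_i)/s_i  ==  c0 + sum (w_i/s_i) x_i
        self._pre_c = _fold(params.pre, PRE_REGRESSORS)
        self._hide_c = _fold(params.post_hide, POST_REGRESSORS)
        self._fc_c = _fold(params.post_fc, POST_REGRESSORS)
        self._pre_base = self._hide_base = self._fc_base = 0.0

    def begin_block(self, block_index, block, config):
        # block-constant regressors (speed, cones, block index) fold into
        # a per-block baseline logit
        sr, nc, bi = float(block.speed_rank), float(block.n_segments), float(block_index)
        for name, c in (("_pre", self._pre_c), ("_hide", self._hide_c), ("_fc", self._fc_c)):
            base = c[0] + c[4] * sr + c[5] * nc + c[6] * bi
            setattr(self, name + "_base", base)

    def decide(self, view, rng):
        if view["phase"] == "pre":
            c = self._pre_c
            # homeostatic shift: stress pushes toward foraging (away from
            # checking), so it enters the check-logit with a negative sign
            eta = (
                self._pre_base
                + c[1] * view["reward"]
                + c[2] * view["time_pressure"]
                + c[3] * view["check_seq_started"]
                + c[7] * view["first_epoch"]
                - self._pre_shift
            )
            return "check" if rng.random() < _logistic(eta) else "forage"
        c = self._hide_c
        eta_h = (
            self._hide_base
            + c[1] * view["reward"]
            + c[2] * view["position_uncertainty"]
            + c[3] * view["proximity"]
            + c[7] * view["first_epoch"]
            + self._hide_shift
        )
        if rng.random() < _logistic(eta_h):
            return "hide"
        c = self._fc_c
        eta_f = (
            self._fc_base
            + c[1] * view["reward"]
            + c[2] * view["position_uncertainty"]
            + c[3] * view["proximity"]
            + c[7] * view["first_epoch"]
        )
        return "forage" if rng.random() < _logistic(eta_f) else "check"

    def end_block(self, summary, rng):
        block_summary = {
            "reward_max": summary["reward_max"],
            "reward_min": summary["reward_min"],
            "speed_rank": summary["speed_rank"],
            "n_cones": summary["n_cones"],
            "lives_gained": summary["lives_gained"],
            "block_index": summary["block_index"],
            "caught": summary["caught"],
            "forage_rate": summary["forage_rate"],
        }
        stress, excite = generate_moods(block_summary, self.mood, self._mood_state, rng)
        resid = self._mood_state["stress_resid"]
        self._pre_shift = self.mood.gain_stress_to_forage * resid / 10.0
        self._hide_shift = self.mood.gain_stress_to_hide * resid / 10.0
        return stress, excite


class ScriptedAgent:
    """Deterministic agents for oracle tests.

    ``policy`` options:

    * ``"always_forage"`` — never checks or hides; every predator catches it.
    * ``"check_then_hide"`` — checks until discovery, hides immediately,
      returns as soon as the predator leaves; never caught.
    * ``"always_check"`` — checks at every unlock.
    """

    def __init__(self, policy: str, decision_rate: float = 4.0, inactive_press_rate: float = 0.0):
        if policy not in ("always_forage", "check_then_hide", "always_check"):
            raise ValueError(policy)
        self.policy = policy
        self.decision_rate = decision_rate
        self.inactive_press_rate = inactive_press_rate

    def decide(self, view, rng):
        if self.policy == "always_forage":
            return "forage"
        if self.policy == "always_check":
            return "check"
        return "check" if view["phase"] == "pre" else "hide"

    def end_block(self, summary, rng):
        return 50.0, 50.0
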