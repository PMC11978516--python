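"""Bespoke decision features of the single-choice policy models.

Three quantities summarize threat at the moment of a choice:

* ``time_pressure`` — how close an *unseen* predator could possibly be:
  the time since the participant last completed a full check of every
  segment (the last moment predator absence was certain), scaled by the
  shortest possible onset delay plus the predator's approach time.  1.0
  means an undetected predator could be arriving right now.
* ``position_uncertainty`` — for a *discovered* predator, the time since
  it was last seen relative to its approach time.
* ``proximity`` — signed seconds until the predator's scheduled arrival
  at the center (negative before arrival).

``FEATURE_SCALING`` holds the fixed reference means/sds used to
standardize regressors both when generative agents compute choice
probabilities and when the choice models are refit, so that simulated and
estimated weights live on the same scale.
"""

from __future__ import annotations

import math

__all__ = [
    "time_pressure",
    "position_uncertainty",
    "proximity",
    "FEATURE_SCALING",
    "standardize",
]


def time_pressure(t: float, last_full_check_t: float, speed_b: float, min_delay: float) -> float:
    """Scaled time since the last completed full sweep of all segments."""
    gap = t - last_full_check_t
    if gap < 0:
        raise ValueError("t must not precede last_full_check_t")
    return gap / (min_delay + speed_b)


def position_uncertainty(t: float, last_seen_t: float, speed_b: float) -> float:
    """Time since the discovered predator was last seen, scaled by its speed."""
    if last_seen_t is None or (isinstance(last_seen_t, float) and math.isnan(last_seen_t)):
        raise ValueError("position uncertainty requires a discovered predator")
    gap = t - last_seen_t
    if gap < 0:
        raise ValueError("t must not precede last_seen_t")
    return gap / speed_b


def proximity(t: float, delay_e: float, speed_b: float) -> float:
    """Signed seconds relative to the predator's scheduled arrival time.

    ``t`` is time since epoch start; arrival is at ``delay_e + speed_b``.
    """
    return t - (delay_e + speed_b)


# Fixed reference scaling (mean, sd) per regressor.  Values are nominal
# moments under the task design (e.g. reward mean ~ U(0, 90); speed rank
# and cone count uniform over their levels; block index uniform over 20),
# with the threat features' moments taken from pilot simulated play.
FEATURE_SCALING = {
    "reward": (45.0, 26.0),
    "time_pressure": (0.45, 0.35),
    "check_seq_started": (0.25, 0.43),
    "position_uncertainty": (0.15, 0.15),
    "proximity": (-8.0, 5.5),
    "speed_rank": (1.0, 0.8165),
    "n_cones": (2.5, 1.118),
    "env_index": (9.5, 5.766),
    "first_epoch": (0.22, 0.41),
}


def standardize(name: str, value: float) -> float:
    m, s = FEATURE_SCALING[name]
    return (value - m) / s
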