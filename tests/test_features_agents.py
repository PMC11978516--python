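"""Decision-feature formulas and the generative choice/mood policies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from predforage import (
    MoodGenParams,
    PolicyParams,
    generate_moods,
    policy_choice,
    position_uncertainty,
    proximity,
    time_pressure,
)


@pytest.mark.parametrize(
    "gap,speed,expected",
    [(12.5, 10.0, 1.0), (0.0, 10.0, 0.0), (4.5, 20.0, 0.2)],
)
def test_time_pressure_examples(gap, speed, expected):
    assert time_pressure(100.0 + gap, 100.0, speed, 2.5) == pytest.approx(expected)


@pytest.mark.parametrize("gap,speed,expected", [(5.0, 10.0, 0.5), (0.0, 10.0, 0.0), (15.0, 20.0, 0.75)])
def test_position_uncertainty_examples(gap, speed, expected):
    assert position_uncertainty(50.0 + gap, 50.0, speed) == pytest.approx(expected)


def test_proximity_examples():
    assert proximity(14.0, 4.0, 10.0) == 0.0
    assert proximity(9.0, 4.0, 10.0) == -5.0
    assert proximity(27.5 - 3.0, 7.5, 20.0) == -3.0


def test_feature_preconditions():
    with pytest.raises(ValueError):
        time_pressure(1.0, 2.0, 10.0, 2.5)
    with pytest.raises(ValueError):
        position_uncertainty(5.0, math.nan, 10.0)
    with pytest.raises(ValueError):
        position_uncertainty(5.0, None, 10.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    t=st.floats(0, 90),
    gap=st.floats(0, 90),
    speed=st.sampled_from([10.0, 15.0, 20.0]),
    delay=st.floats(2.0, 10.5),
)
def test_feature_formulas_match_direct_arithmetic(t, gap, speed, delay):
    """Each feature equals its arithmetic definition to 1e-12."""
    assert abs(time_pressure(t + gap, t, speed, 2.5) - gap / (2.5 + speed)) < 1e-12
    assert abs(position_uncertainty(t + gap, t, speed) - gap / speed) < 1e-12
    assert abs(proximity(t, delay, speed) - (t - delay - speed)) < 1e-12


class _FixedRng:
    """Deterministic uniform stream for probing choice thresholds."""

    def __init__(self, vals):
        self.vals = list(vals)

    def random(self):
        return self.vals.pop(0)


def _neutral_features():
    from predforage.features import FEATURE_SCALING

    return {k: m for k, (m, s) in FEATURE_SCALING.items()}


def test_policy_choice_even_odds_with_zero_weights():
    params = PolicyParams(pre=np.zeros(8), post_hide=np.zeros(8), post_fc=np.zeros(8))
    feats = _neutral_features()
    assert policy_choice("pre", feats, params, _FixedRng([0.499])) == "check"
    assert policy_choice("pre", feats, params, _FixedRng([0.501])) == "forage"


def test_policy_choice_saturates_with_huge_intercept():
    params = PolicyParams(
        pre=[30.0] + [0] * 7, post_hide=np.zeros(8), post_fc=np.zeros(8)
    )
    assert policy_choice("pre", _neutral_features(), params, _FixedRng([0.999999])) == "check"


def test_policy_choice_logistic_one_threshold():
    """With intercept 0 and a unit weight on standardized reward = 1, the
    check probability equals logistic(1) = 0.7311."""
    from predforage.features import FEATURE_SCALING

    params = PolicyParams(
        pre=[0.0, 1.0, 0, 0, 0, 0, 0, 0], post_hide=np.zeros(8), post_fc=np.zeros(8)
    )
    feats = _neutral_features()
    m, s = FEATURE_SCALING["reward"]
    feats["reward"] = m + s  # standardized value exactly 1
    p = 1.0 / (1.0 + math.exp(-1.0))
    assert policy_choice("pre", feats, params, _FixedRng([p - 1e-4])) == "check"
    assert policy_choice("pre", feats, params, _FixedRng([p + 1e-4])) == "forage"
    with pytest.raises(ValueError):
        bad = dict(feats, reward=math.inf)
        policy_choice("pre", bad, params, _FixedRng([0.5]))


class _ZeroRng:
    def normal(self, loc, scale, size=None):
        return 0.0 if size is None else np.zeros(size)


def _block_summary(**kw):
    base = dict(
        reward_max=65.0, reward_min=25.0, speed_rank=1.0, n_cones=2.5,
        lives_gained=1.0, block_index=9.5, caught=0.25, forage_rate=0.35,
    )
    base.update(kw)
    return base


def test_generate_moods_baseline_with_zero_weights():
    params = MoodGenParams(
        stress_w={k: 0.0 for k in MoodGenParams().stress_w},
        excite_w={k: 0.0 for k in MoodGenParams().excite_w},
        noise_sd=0.0, carryover=0.0,
    )
    state = {}
    for _ in range(3):
        s, e = generate_moods(_block_summary(), params, state, _ZeroRng())
        assert s == params.stress_base and e == params.excite_base


def test_generate_moods_planted_caught_weight_is_exact():
    w = {k: 0.0 for k in MoodGenParams().stress_w}
    w["caught"] = 10.0 * 0.5  # +10 stress per caught block (scaling sd 0.5)
    params = MoodGenParams(
        stress_w=w, excite_w={k: 0.0 for k in MoodGenParams().excite_w},
        noise_sd=0.0, carryover=0.0,
    )
    s0, _ = generate_moods(_block_summary(caught=0.0), params, {}, _ZeroRng())
    s1, _ = generate_moods(_block_summary(caught=1.0), params, {}, _ZeroRng())
    assert s1 - s0 == pytest.approx(10.0)


def test_generate_moods_truncated_to_scale():
    params = MoodGenParams(stress_base=150.0, excite_base=-20.0, noise_sd=0.0)
    s, e = generate_moods(_block_summary(), params, {}, _ZeroRng())
    assert 0.0 <= s <= 100.0 and 0.0 <= e <= 100.0
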