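"""Quality screening: participant filters, epoch classes, technical errors."""

import math

import numpy as np
import pytest

from predforage import (
    QCThresholds,
    classify_epochs,
    detect_technical_errors,
    epochize,
    screen_participant,
)
from predforage.events import Event, EventLog
from predforage.measures import EpochRecord
from predforage.screening import _classify_one, removed_epoch_cutoff


def test_competent_player_passes_all_screens(default_log, records):
    include, reasons = screen_participant(
        default_log, {"repeat_diffs": [0, 1, 1]}, records=records
    )
    assert include and reasons == []


def test_never_checking_player_excluded(forager_log, config):
    include, reasons = screen_participant(forager_log, {"repeat_diffs": [0, 0, 0]}, config=config)
    assert not include
    assert "too few checks" in reasons
    assert "caught too often" in reasons  # caught every epoch


def test_consistency_rule_boundary(default_log, records):
    ok, reasons = screen_participant(default_log, {"repeat_diffs": [0, 1, 1]}, records=records)
    assert ok  # mean 0.667 <= 1
    bad, reasons = screen_participant(default_log, {"repeat_diffs": [2, 1, 1]}, records=records)
    assert "inconsistent questionnaire answers" in reasons
    with pytest.warns(UserWarning, match="consistency"):
        screen_participant(default_log, {}, records=records)


def test_participant_checks_are_order_free(default_log, records):
    """The include flag is a pure conjunction: rerunning yields the same
    answer (idempotent) regardless of which criterion fires first."""
    a = screen_participant(default_log, {"repeat_diffs": [0, 0, 0]}, records=records)
    b = screen_participant(default_log, {"repeat_diffs": [0, 0, 0]}, records=records)
    assert a == b


def _rec(**kw):
    base = dict(
        participant_id="p", block=0, epoch=0, start=0.0, end=20.0, speed=10.0,
        speed_rank=2, n_segments=2, reward_mean=50.0, onset_delay=5.0,
        first_epoch=True, enter_t=5.0, discovery_t=math.nan, outcome="hid_safe",
        started_hiding=False, initial_hide_duration=math.nan, n_hides=0,
        hide_t=math.nan, progress_at_hide=math.nan, last_action_before_hide="",
        time_seen_to_hide=math.nan, time_to_first_action=1.0,
    )
    base.update(kw)
    return EpochRecord(**base)


@pytest.mark.parametrize(
    "kw,expected",
    [
        (dict(started_hiding=True, initial_hide_duration=2.3), "excluded"),
        (dict(started_hiding=True, initial_hide_duration=2.1, discovery_t=8.0,
              n_hides=1, outcome="hid_safe"), "full"),
        (dict(n_hides=2, discovery_t=8.0), "excluded"),
        (dict(outcome="caught"), "within_epoch_only"),
        (dict(discovery_t=8.0, outcome="hid_safe", n_hides=1), "full"),
        (dict(discovery_t=8.0, outcome="discovered_end"), "pre_only"),
        (dict(outcome="undiscovered_end", end=12.0), "rate_and_first_action"),
        (dict(outcome="undiscovered_end", end=9.0), "first_action_only"),
    ],
)
def test_epoch_availability_classes(kw, expected):
    assert _classify_one(_rec(**kw), QCThresholds()) == expected


def test_simulator_clean_logs_pass_technical_screen(default_log, hider_log, config):
    for log in (default_log, hider_log):
        _, removed = detect_technical_errors(log, config=config)
        assert removed == set()


def _hand_log(schedule, events):
    return EventLog("hand", schedule, events)


def test_lockout_undershoot_removes_epoch_and_rest_of_block(schedule, config):
    ev = [
        Event(1.0, 0, 0, "forage", 50.0, 50.0),
        Event(2.35, 0, 0, "forage", 50.0, 50.0),  # 1.35 s gap: 150 ms undershoot
        Event(4.0, 0, 0, "epoch_end", 2.0),
        Event(5.0, 0, 1, "forage", 50.0, 50.0),
        Event(90.0, 0, 1, "epoch_end", 2.0),
        Event(90.0, 0, 1, "block_end"),
        Event(1.0, 1, 0, "forage", 50.0, 50.0),
        Event(2.45, 1, 0, "forage", 50.0, 50.0),  # 50 ms undershoot: tolerated
        Event(90.0, 1, 0, "epoch_end", 2.0),
        Event(90.0, 1, 0, "block_end"),
    ]
    _, removed = detect_technical_errors(_hand_log(schedule, ev), config=config)
    assert (0, 0) in removed and (0, 1) in removed
    assert not any(b == 1 for b, _ in removed)


def test_actions_after_capture_are_stripped(schedule, config):
    ev = [
        Event(1.0, 0, 0, "forage", 50.0, 50.0),
        Event(14.0, 0, 0, "caught", 0.0),
        Event(14.5, 0, 0, "forage", 50.0, 50.0),  # pressed on the caught screen
        Event(14.6, 0, 0, "epoch_end", 1.0),
        Event(90.0, 0, 0, "block_end"),
    ]
    clean, removed = detect_technical_errors(_hand_log(schedule, ev), config=config)
    kinds = [e.kind for e in clean.events]
    assert kinds.count("forage") == 1
    assert removed == set()  # the epoch itself is retained


def test_removed_epoch_cutoff_targets_cohort_fraction():
    counts = list(range(100))  # 0..99 removed epochs across a cohort
    cut = removed_epoch_cutoff(counts, target=0.025)
    assert (np.asarray(counts) > cut).mean() <= 0.025
    assert removed_epoch_cutoff([], 0.025) == math.inf
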