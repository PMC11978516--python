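"""Participant- and epoch-level data-quality screening.

Participants are excluded for inattentive or degenerate play: more than 6
epochs without any action, fewer than 40 checks in the whole session,
caught more than 9 times, fewer than 5 lives earned, or a mean absolute
difference above 1 on the repeated questionnaire items.  Epochs are
excluded when the avatar lingered in hiding at the epoch start for more
than 2.2 s or hid more than once; otherwise each epoch is assigned an
availability class that determines which behavioral measures it may feed
(see :data:`predforage.measures.GRANTS`).

Technical-error screening strips actions recorded after a capture and
removes any epoch (plus the remainder of its block) where an action
lockout was undershot by more than 100 ms; participants losing too many
epochs are dropped, with the cutoff calibrated on the cohort so that
this criterion alone removes at most a target fraction (2.5%) of
participants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .events import ACTION_KINDS, EventLog
from .measures import EpochRecord, epochize
from .task import TaskConfig

__all__ = [
    "QCThresholds",
    "ScreenReport",
    "screen_participant",
    "classify_epochs",
    "detect_technical_errors",
    "removed_epoch_cutoff",
]


@dataclass(frozen=True)
class QCThresholds:
    max_inactive_epochs: int = 6
    min_checks: int = 40
    max_caught: int = 9
    min_lives: int = 5
    max_consistency_diff: float = 1.0
    max_initial_hide: float = 2.2
    lockout_violation: float = 0.100
    min_partial_epoch: float = 10.0
    max_removed_epoch_fraction: float = 0.025

    def __post_init__(self):
        for f_ in (
            self.max_inactive_epochs,
            self.min_checks,
            self.max_caught,
            self.min_lives,
            self.max_consistency_diff,
            self.max_initial_hide,
            self.lockout_violation,
            self.min_partial_epoch,
            self.max_removed_epoch_fraction,
        ):
            if f_ < 0:
                raise ValueError("thresholds must be non-negative")


@dataclass
class ScreenReport:
    include: bool
    reasons: list = field(default_factory=list)
    epoch_availability: dict = field(default_factory=dict)  # (block, epoch) -> class


def screen_participant(log: EventLog, questionnaire: dict = None, thr: QCThresholds = None,
                       config: TaskConfig = None, records=None):
    """Participant-level inclusion decision. Returns (include, reasons)."""
    thr = thr or QCThresholds()
    config = config or TaskConfig()
    records = records if records is not None else epochize(log, config)
    reasons = []
    inactive = sum(
        1 for r in records if sum(r.n_forage) + sum(r.n_check) + r.n_hides == 0
    )
    if inactive > thr.max_inactive_epochs:
        reasons.append("too many inactive epochs")
    n_checks = sum(1 for e in log.events if e.kind == "check")
    if n_checks < thr.min_checks:
        reasons.append("too few checks")
    caught = sum(1 for r in records if r.outcome == "caught")
    if caught > thr.max_caught:
        reasons.append("caught too often")
    total_reward = sum(r.reward_collected[0] + r.reward_collected[1] for r in records)
    if total_reward // config.energy_per_life < thr.min_lives:
        reasons.append("too few lives earned")
    diffs = (questionnaire or {}).get("repeat_diffs")
    if diffs is None:
        warnings.warn("repeat questions missing; consistency check skipped")
    elif float(np.mean(np.abs(diffs))) > thr.max_consistency_diff:
        reasons.append("inconsistent questionnaire answers")
    return (not reasons), reasons


def classify_epochs(log_or_records, thr: QCThresholds = None, config: TaskConfig = None) -> dict:
    """Availability class per epoch, keyed by (block, epoch)."""
    thr = thr or QCThresholds()
    if isinstance(log_or_records, EventLog):
        records = epochize(log_or_records, config or TaskConfig())
    else:
        records = log_or_records
    out = {}
    for r in records:
        out[(r.block, r.epoch)] = _classify_one(r, thr)
    return out


def _classify_one(r: EpochRecord, thr: QCThresholds) -> str:
    if not math.isnan(r.initial_hide_duration) and r.initial_hide_duration > thr.max_initial_hide:
        return "excluded"
    if r.n_hides > 1:
        return "excluded"
    if r.outcome == "caught":
        return "within_epoch_only"
    if r.discovered:
        return "full" if r.outcome == "hid_safe" else "pre_only"
    if r.outcome == "hid_safe":
        # hid without ever seeing the predator: complete epoch, no post phase
        return "full"
    # undiscovered, incomplete (block ended mid-epoch)
    if r.duration >= thr.min_partial_epoch:
        return "rate_and_first_action"
    return "first_action_only"


def detect_technical_errors(log: EventLog, thr: QCThresholds = None, config: TaskConfig = None):
    """Strip post-capture actions and flag lockout-undershoot epochs.

    Returns ``(clean_log, removed)`` where ``removed`` is the set of
    (block, epoch) keys invalidated by a lockout violation (including all
    later epochs of the affected block).
    """
    thr = thr or QCThresholds()
    config = config or TaskConfig()
    costs = config.action_costs
    removed = set()
    kept = []
    caught_at = {}  # block -> capture time of current epoch
    last_action = {}  # block -> (kind, t)
    violation_from = {}  # block -> first bad epoch index
    max_epoch = {}
    for e in log.events:
        max_epoch[e.block] = max(max_epoch.get(e.block, 0), e.epoch)
        if e.kind == "caught":
            caught_at[(e.block, e.epoch)] = e.t
        if e.kind in ACTION_KINDS:
            cap = caught_at.get((e.block, e.epoch))
            if cap is not None and e.t > cap:
                continue  # action recorded after capture: stripped
            prev = last_action.get(e.block)
            if prev is not None:
                kind, t0 = prev
                undershoot = costs[kind] - (e.t - t0)
                if undershoot > thr.lockout_violation and e.block not in violation_from:
                    violation_from[e.block] = e.epoch
            last_action[e.block] = (e.kind, e.t)
        kept.append(e)
    for b, e0 in violation_from.items():
        for ep in range(e0, max_epoch.get(b, e0) + 1):
            removed.add((b, ep))
    clean = EventLog(log.participant_id, log.schedule, kept, valid=log.valid)
    return clean, removed


def removed_epoch_cutoff(removed_counts, target: float = 0.025) -> float:
    """Cohort-calibrated cutoff for "too many removed epochs".

    The cutoff is the empirical (1 - target) quantile of the per-
    participant removed-epoch counts, so that this single criterion
    excludes at most ``target`` of the cohort.
    """
    counts = np.asarray(list(removed_counts), dtype=float)
    if counts.size == 0:
        return float("inf")
    return float(np.quantile(counts, 1.0 - target, method="higher"))
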