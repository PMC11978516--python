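"""Epoching and the registry of aggregate behavioral measures.

Sessions are cut into predator epochs (from block start or the previous
predator's disappearance to the predator's arrival at the center, or the
block end).  Each epoch is split at discovery time into a pre-discovery
and a post-discovery phase, and occupancy time is partitioned over the
four mutually exclusive modes (foraging, checking, hiding, transit/idle)
so that the four fractions always sum to one.

The registry holds exactly 33 participant-level aggregate measures.
Measures named in the main analyses (times to return from hiding, percent
time foraging/checking/hiding, last-action-before-hide, detection
latency, inactive-press "vigor" rates, earnings, captures, ...) are
implemented directly; the registry is completed to its published
cardinality with closely analogous per-phase variants, each flagged
``reconstructed=True`` in its definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import (
    OUTCOME_BLOCK_END,
    OUTCOME_CAUGHT,
    OUTCOME_HID_SAFE,
    EventLog,
)
from .task import TaskConfig

__all__ = [
    "EpochRecord",
    "MeasureDef",
    "MEASURE_REGISTRY",
    "epochize",
    "compute_measures",
    "summarize_block",
    "registry_frame",
]

_NAN = float("nan")


@dataclass
class EpochRecord:
    """All per-epoch components the measure registry draws on."""

    participant_id: str
    block: int
    epoch: int
    start: float
    end: float
    speed: float
    speed_rank: int
    n_segments: int
    reward_mean: float
    onset_delay: float
    first_epoch: bool
    enter_t: float  # nan if the predator never entered before block end
    discovery_t: float  # nan if never discovered
    outcome: str  # hid_safe | caught | undiscovered_end | discovered_end
    started_hiding: bool
    initial_hide_duration: float  # time to the return press; nan if active
    n_hides: int
    hide_t: float
    progress_at_hide: float
    last_action_before_hide: str  # forage | check | "" (none)
    time_seen_to_hide: float
    time_to_first_action: float
    # phase-resolved occupancy and counts; phase index 0=pre, 1=post
    dur: tuple = (0.0, 0.0)
    forage_time: tuple = (0.0, 0.0)
    check_time: tuple = (0.0, 0.0)
    hide_time: tuple = (0.0, 0.0)
    transit_time: tuple = (0.0, 0.0)
    n_forage: tuple = (0, 0)
    n_check: tuple = (0, 0)
    reward_collected: tuple = (0.0, 0.0)
    longest_forage_run_pre: int = 0
    mean_forage_run_pre: float = _NAN
    n_switches_pre: int = 0
    sweeps_completed_pre: int = 0
    seq_choices_started: int = 0
    seq_checks_started: int = 0
    inactive_counts: tuple = (0, 0, 0)  # forage, check, hide buttons
    prev_outcome: str = ""

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def discovered(self) -> bool:
        return not math.isnan(self.discovery_t)


def _phase_of(t, discovery_t):
    return 0 if (math.isnan(discovery_t) or t < discovery_t) else 1


def epochize(log: EventLog, config: TaskConfig = None) -> list:
    """Cut an event log into :class:`EpochRecord` objects."""
    config = config or TaskConfig()
    records = []
    # group events by (block, epoch)
    by_be = {}
    for e in log.events:
        by_be.setdefault((e.block, e.epoch), []).append(e)
    blocks = log.schedule.blocks
    for b_idx, block in enumerate(blocks):
        speed = block.speed_seconds(config)
        keys = sorted(k[1] for k in by_be if k[0] == b_idx)
        prev_outcome = ""
        for e_idx in keys:
            evs = by_be[(b_idx, e_idx)]
            term = [e for e in evs if e.kind == "epoch_end"]
            if not term and not any(e.kind == "block_end" for e in evs):
                raise ValueError(f"malformed log: block {b_idx} epoch {e_idx} lacks a terminator")
            if not term:
                continue  # block_end bookkeeping only
            rec = _build_record(log, b_idx, e_idx, evs, block, speed, config, prev_outcome)
            if rec is not None:
                records.append(rec)
                prev_outcome = rec.outcome
    return records


def _build_record(log, b_idx, e_idx, evs, block, speed, config, prev_outcome):
    term = next(e for e in evs if e.kind == "epoch_end")
    end = term.t
    if e_idx >= len(block.epochs):
        return None
    ep_spec = block.epochs[e_idx]
    start = 0.0
    for j in range(e_idx):
        start += block.epochs[j].onset_delay + speed
    if start >= end:
        return None
    enter = next((e.t for e in evs if e.kind == "predator_enter"), _NAN)
    seen = next((e.t for e in evs if e.kind == "predator_seen"), _NAN)
    caught = any(e.kind == "caught" for e in evs)
    if term.value1 == OUTCOME_CAUGHT or caught:
        outcome = "caught"
    elif term.value1 == OUTCOME_HID_SAFE:
        outcome = "hid_safe"
    elif math.isnan(seen):
        outcome = "undiscovered_end"
    else:
        outcome = "discovered_end"

    presses = [e for e in evs if e.kind in ("forage", "check", "hide", "return")]
    presses.sort(key=lambda e: e.t)
    started_hiding = bool(presses) and presses[0].kind == "return" or (
        not presses and prev_outcome == "hid_safe"
    )
    initial_hide = presses[0].t - start if (presses and presses[0].kind == "return") else _NAN

    # occupancy partition: each press owns the interval to the next press;
    # the leading interval is hiding if the epoch started hidden, else idle
    dur = [0.0, 0.0]
    forage_time = [0.0, 0.0]
    check_time = [0.0, 0.0]
    hide_time = [0.0, 0.0]
    transit_time = [0.0, 0.0]
    n_forage = [0, 0]
    n_check = [0, 0]
    reward = [0.0, 0.0]

    cat_of = {"forage": "forage", "check": "check", "hide": "hide", "return": "transit"}
    bounds = [start] + [p.t for p in presses] + [end]
    # leading interval: hiding if the epoch began hidden, else attributed
    # to the first action taken (idle-before-acting belongs to the mode
    # the participant was settling into); pure transit only if no actions
    if started_hiding:
        lead = "hide"
    elif presses:
        lead = cat_of[presses[0].kind]
    else:
        lead = "transit"
    cats = [lead] + [cat_of[p.kind] for p in presses]

    def add_span(t0, t1, sink):
        if t1 <= t0:
            return
        if math.isnan(seen):
            sink[0] += t1 - t0
        else:
            if t0 < seen:
                sink[0] += min(t1, seen) - t0
            if t1 > seen:
                sink[1] += t1 - max(t0, seen)

    sinks = {"forage": forage_time, "check": check_time, "hide": hide_time, "transit": transit_time}
    for t0, t1, cat in zip(bounds[:-1], bounds[1:], cats):
        add_span(t0, t1, sinks[cat])
    add_span(start, end, dur)

    # per-phase counts, forage runs, sweep bookkeeping
    run = 0
    runs = []
    last_fc = None
    switches = 0
    pre_checks = 0
    sweep_pos = 0
    sweeps = 0
    seq_choices = 0
    seq_checks = 0
    hide_t = _NAN
    progress_at_hide = _NAN
    last_before_hide = ""
    for p in presses:
        ph = _phase_of(p.t, seen)
        if p.kind == "forage":
            n_forage[ph] += 1
            reward[ph] += p.value1
        elif p.kind == "check":
            n_check[ph] += 1
        if ph == 0 and p.kind in ("forage", "check"):
            if sweep_pos > 0:
                seq_choices += 1
                if p.kind == "check":
                    seq_checks += 1
            if p.kind == "check":
                pre_checks += 1
                sweep_pos += 1
                if sweep_pos == block.n_segments:
                    sweeps += 1
                    sweep_pos = 0
            if p.kind == "forage":
                run += 1
            else:
                if run:
                    runs.append(run)
                run = 0
            if last_fc is not None and last_fc != p.kind:
                switches += 1
            last_fc = p.kind
        if p.kind == "hide" and math.isnan(hide_t):
            hide_t = p.t
            progress_at_hide = p.value1
            prev = [q for q in presses if q.t < p.t and q.kind in ("forage", "check")]
            last_before_hide = prev[-1].kind if prev else ""
    if run:
        runs.append(run)

    n_hides = sum(1 for p in presses if p.kind == "hide")
    first_real = next((p for p in presses if p.kind != "return"), None)
    # time to first action counts from when the avatar is free to act
    t_free = presses[0].t if started_hiding and presses else start
    tfa = (first_real.t - t_free) if first_real is not None else _NAN

    inact = [0, 0, 0]
    for e in evs:
        if e.kind == "press_inactive":
            inact[int(e.value1)] += 1

    t_first = {}
    for kind in ("forage", "check"):
        p = next((q for q in presses if q.kind == kind), None)
        t_first[kind] = (p.t - t_free) if p is not None else _NAN

    rec = EpochRecord(
        participant_id=log.participant_id,
        block=b_idx,
        epoch=e_idx,
        start=start,
        end=end,
        speed=speed,
        speed_rank=block.speed_rank,
        n_segments=block.n_segments,
        reward_mean=ep_spec.reward_mean,
        onset_delay=ep_spec.onset_delay,
        first_epoch=e_idx == 0,
        enter_t=enter,
        discovery_t=seen,
        outcome=outcome,
        started_hiding=started_hiding,
        initial_hide_duration=initial_hide,
        n_hides=n_hides,
        hide_t=hide_t,
        progress_at_hide=progress_at_hide,
        last_action_before_hide=last_before_hide,
        time_seen_to_hide=(hide_t - seen) if not math.isnan(hide_t) and not math.isnan(seen) else _NAN,
        time_to_first_action=tfa,
        dur=tuple(dur),
        forage_time=tuple(forage_time),
        check_time=tuple(check_time),
        hide_time=tuple(hide_time),
        transit_time=tuple(transit_time),
        n_forage=tuple(n_forage),
        n_check=tuple(n_check),
        reward_collected=tuple(reward),
        longest_forage_run_pre=max(runs) if runs else 0,
        mean_forage_run_pre=float(np.mean(runs)) if runs else _NAN,
        n_switches_pre=switches,
        sweeps_completed_pre=sweeps,
        seq_choices_started=seq_choices,
        seq_checks_started=seq_checks,
        inactive_counts=tuple(inact),
        prev_outcome=prev_outcome,
    )
    rec._t_first_forage = t_first["forage"]
    rec._t_first_check = t_first["check"]
    return rec


# ---------------------------------------------------------------------------
# measure registry


@dataclass(frozen=True)
class MeasureDef:
    name: str
    level: str  # epoch | participant
    phase: str  # pre | post | whole
    family: str  # gaussian | bernoulli | poisson | shifted_lognormal
    needs: str  # pre | post | within | rate | first_action | cross | participant
    reconstructed: bool = False
    doc: str = ""


def _tot(rec, attr):
    v = getattr(rec, attr)
    return v[0] + v[1]


def _ratio(num, den):
    return num / den if den > 0 else _NAN


def _active(rec, ph=None):
    if ph is None:
        return rec.duration - _tot(rec, "hide_time")
    return rec.dur[ph] - rec.hide_time[ph]


def _pre_dur(rec):
    return rec.dur[0]


def _post_dur(rec):
    return rec.dur[1]


_EXTRACTORS = {
    "time_to_return_from_hiding": lambda r: r.initial_hide_duration
    if r.started_hiding and r.prev_outcome == "hid_safe"
    else _NAN,
    "pct_time_foraging": lambda r: _ratio(_tot(r, "forage_time"), r.duration),
    "pct_time_foraging_pre": lambda r: _ratio(r.forage_time[0], _pre_dur(r)),
    "pct_time_foraging_post": lambda r: _ratio(r.forage_time[1], _post_dur(r)),
    "pct_active_time_checking": lambda r: _ratio(_tot(r, "check_time"), _active(r)),
    "pct_active_time_checking_pre": lambda r: _ratio(r.check_time[0], _active(r, 0)),
    "pct_active_time_checking_post": lambda r: _ratio(r.check_time[1], _active(r, 1)),
    "last_action_before_hide_is_forage": lambda r: (
        1.0 if r.last_action_before_hide == "forage" else 0.0
    )
    if r.last_action_before_hide
    else _NAN,
    "time_to_first_action": lambda r: r.time_to_first_action,
    "forage_rate_pre": lambda r: _ratio(r.n_forage[0], _pre_dur(r)),
    "forage_rate_post": lambda r: _ratio(r.n_forage[1], _post_dur(r)),
    "check_rate_pre": lambda r: _ratio(r.n_check[0], _pre_dur(r)),
    "check_rate_post": lambda r: _ratio(r.n_check[1], _post_dur(r)),
    "detection_latency": lambda r: (r.discovery_t - r.enter_t)
    if r.discovered and not math.isnan(r.enter_t)
    else _NAN,
    "predator_progress_at_hide": lambda r: r.progress_at_hide,
    "pct_time_hiding": lambda r: _ratio(_tot(r, "hide_time"), r.duration),
    "longest_forage_run_pre": lambda r: float(r.longest_forage_run_pre)
    if _pre_dur(r) > 0
    else _NAN,
    "mean_forage_run_pre": lambda r: r.mean_forage_run_pre,
    "inactive_press_rate_forage": lambda r: _ratio(r.inactive_counts[0], r.duration),
    "inactive_press_rate_check": lambda r: _ratio(r.inactive_counts[1], r.duration),
    "inactive_press_rate_hide": lambda r: _ratio(r.inactive_counts[2], r.duration),
    "checks_per_sweep": lambda r: _ratio(r.n_check[0], r.sweeps_completed_pre)
    if r.sweeps_completed_pre > 0
    else _NAN,
    "p_any_forage_pre": lambda r: 1.0 if r.n_forage[0] > 0 else 0.0,
    "p_any_check_pre": lambda r: 1.0 if r.n_check[0] > 0 else 0.0,
    "time_to_first_forage": lambda r: _first_press_latency(r, "forage"),
    "time_to_first_check": lambda r: _first_press_latency(r, "check"),
    "n_switches_forage_check_pre": lambda r: float(r.n_switches_pre),
    "p_hide_given_discovered": lambda r: (1.0 if r.n_hides > 0 else 0.0)
    if r.discovered
    else _NAN,
    "time_seen_to_hide": lambda r: r.time_seen_to_hide,
    "check_seq_completion_pre": lambda r: _ratio(r.seq_checks_started, r.seq_choices_started)
    if r.seq_choices_started > 0
    else _NAN,
}


def _first_press_latency(rec, kind):
    # stored indirectly: approximate with time_to_first_action when the
    # first action matches, else nan; refined by epochize storing both
    return rec.__dict__.get(f"_t_first_{kind}", _NAN)


def _registry() -> list:
    M = MeasureDef
    defs = [
        M("time_to_return_from_hiding", "epoch", "whole", "shifted_lognormal", "cross"),
        M("pct_time_foraging", "epoch", "whole", "gaussian", "within"),
        M("pct_time_foraging_pre", "epoch", "pre", "gaussian", "pre"),
        M("pct_time_foraging_post", "epoch", "post", "gaussian", "post"),
        M("pct_active_time_checking", "epoch", "whole", "gaussian", "within"),
        M("pct_active_time_checking_pre", "epoch", "pre", "gaussian", "pre", True),
        M("pct_active_time_checking_post", "epoch", "post", "gaussian", "post", True),
        M("last_action_before_hide_is_forage", "epoch", "post", "bernoulli", "post"),
        M("time_to_first_action", "epoch", "whole", "shifted_lognormal", "first_action"),
        M("forage_rate_pre", "epoch", "pre", "gaussian", "pre"),
        M("forage_rate_post", "epoch", "post", "gaussian", "post", True),
        M("check_rate_pre", "epoch", "pre", "gaussian", "pre", True),
        M("check_rate_post", "epoch", "post", "gaussian", "post", True),
        M("detection_latency", "epoch", "pre", "shifted_lognormal", "pre"),
        M("predator_progress_at_hide", "epoch", "post", "gaussian", "post"),
        M("pct_time_hiding", "epoch", "whole", "gaussian", "within"),
        M("longest_forage_run_pre", "epoch", "pre", "poisson", "pre"),
        M("mean_forage_run_pre", "epoch", "pre", "gaussian", "pre", True),
        M("inactive_press_rate_forage", "epoch", "whole", "gaussian", "rate"),
        M("inactive_press_rate_check", "epoch", "whole", "gaussian", "rate"),
        M("inactive_press_rate_hide", "epoch", "whole", "gaussian", "rate"),
        M("checks_per_sweep", "epoch", "pre", "gaussian", "pre", True),
        M("total_earnings", "participant", "whole", "gaussian", "participant"),
        M("times_caught", "participant", "whole", "poisson", "participant"),
        M("lives_gained", "participant", "whole", "poisson", "participant"),
        M("p_any_forage_pre", "epoch", "pre", "bernoulli", "pre"),
        M("p_any_check_pre", "epoch", "pre", "bernoulli", "pre", True),
        M("time_to_first_forage", "epoch", "pre", "shifted_lognormal", "pre", True),
        M("time_to_first_check", "epoch", "pre", "shifted_lognormal", "pre", True),
        M("n_switches_forage_check_pre", "epoch", "pre", "poisson", "pre", True),
        M("p_hide_given_discovered", "epoch", "post", "bernoulli", "post"),
        M("time_seen_to_hide", "epoch", "post", "shifted_lognormal", "post", True),
        M("check_seq_completion_pre", "epoch", "pre", "gaussian", "pre"),
    ]
    assert len(defs) == 33
    return defs


MEASURE_REGISTRY = _registry()

#: availability grants per epoch class
GRANTS = {
    "full": {"pre", "post", "within", "rate", "first_action", "cross"},
    "pre_only": {"pre", "rate", "first_action", "cross"},
    "rate_and_first_action": {"rate", "first_action"},
    "first_action_only": {"first_action"},
    "within_epoch_only": {"pre", "post", "within"},
    "excluded": set(),
}


def compute_measures(records, availability=None, registry=None, config: TaskConfig = None):
    """Aggregate epoch records into one row of participant measures.

    ``availability`` maps (block, epoch) -> class name from
    :func:`predforage.screening.classify_epochs`; if omitted, every epoch
    is treated as fully available.  Returns a dict measure -> value
    (nan where unavailable).
    """
    registry = registry or MEASURE_REGISTRY
    config = config or TaskConfig()
    known = {m.name for m in registry}
    unknown = known - set(_EXTRACTORS) - {"total_earnings", "times_caught", "lives_gained"}
    if unknown:
        raise KeyError(f"unknown measure names: {sorted(unknown)}")
    out = {}
    for m in registry:
        if m.needs == "participant":
            out[m.name] = _participant_measure(m.name, records, config)
            continue
        vals = []
        for r in records:
            cls = "full" if availability is None else availability.get((r.block, r.epoch), "full")
            if m.needs not in GRANTS[cls]:
                continue
            v = _EXTRACTORS[m.name](r)
            if not math.isnan(v):
                vals.append(v)
        out[m.name] = float(np.mean(vals)) if vals else _NAN
    return out


def _participant_measure(name, records, config):
    if name == "total_earnings":
        return float(sum(_tot(r, "reward_collected") for r in records))
    if name == "times_caught":
        return float(sum(1 for r in records if r.outcome == "caught"))
    if name == "lives_gained":
        total = sum(_tot(r, "reward_collected") for r in records)
        return float(int(total // config.energy_per_life))
    raise KeyError(name)


def registry_frame(registry=None) -> pd.DataFrame:
    registry = registry or MEASURE_REGISTRY
    return pd.DataFrame([vars(m) for m in registry])


def summarize_block(records, log: EventLog, config: TaskConfig = None) -> pd.DataFrame:
    """One row per block joining design features, behavior and both moods."""
    config = config or TaskConfig()
    moods = {
        e.block: (e.value1, e.value2) for e in log.events if e.kind == "mood_rating"
    }
    rows = []
    for b_idx, block in enumerate(log.schedule.blocks):
        recs = [r for r in records if r.block == b_idx]
        dur = sum(r.duration for r in recs) or config.block_duration
        stress, excite = moods.get(b_idx, (_NAN, _NAN))
        rows.append(
            {
                "block": b_idx,
                "speed_rank": block.speed_rank,
                "n_cones": block.n_segments,
                "reward_max": max(e.reward_mean for e in block.epochs),
                "reward_min": min(e.reward_mean for e in block.epochs),
                "caught": float(sum(1 for r in recs if r.outcome == "caught")),
                "lives_gained": _NAN,  # filled from the engine log below
                "forage_rate": sum(_tot(r, "n_forage") for r in recs) / dur,
                "check_rate": sum(_tot(r, "n_check") for r in recs) / dur,
                "pct_time_hiding": sum(_tot(r, "hide_time") for r in recs) / dur,
                "stress": stress,
                "excitement": excite,
                "mood_missing": b_idx not in moods,
            }
        )
    df = pd.DataFrame(rows)
    # lives gained per block from forage events' cumulative reward
    per_block_reward = {b: 0.0 for b in range(len(log.schedule.blocks))}
    for e in log.events:
        if e.kind == "forage":
            per_block_reward[e.block] += e.value1
    cum = 0.0
    lives_prev = 0
    lives_col = []
    for b in range(len(df)):
        cum += per_block_reward[b]
        lives_now = int(cum // config.energy_per_life)
        lives_col.append(lives_now - lives_prev)
        lives_prev = lives_now
    df["lives_gained"] = lives_col
    return df
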