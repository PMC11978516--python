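"""Event-driven simulator of the foraging-under-threat task.

Continuous time within each 90 s block.  An agent is polled whenever its
controls unlock (plus an exponential decision latency); each action locks
the controls for its time cost (forage 1.5 s, check 0.5 s, hide 0.5 s,
return 2.0 s).  Predators approach linearly, taking the block's speed
(10/15/20 s) from entry to the center; at arrival the avatar is caught
unless fully hidden.  The on-screen reward sample refreshes on 1-second
boundaries as a draw from Normal(epoch mean, sd), clipped at zero.

The module exposes the low-level :func:`step` / :func:`advance` pair that
applies a single action or rolls world time forward through predator
milestones, and :func:`run_session` which drives a full 20-block session
with an agent and returns the complete :class:`~predforage.events.EventLog`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .events import (
    OUTCOME_BLOCK_END,
    OUTCOME_CAUGHT,
    OUTCOME_HID_SAFE,
    Event,
    EventLog,
)
from .features import position_uncertainty, proximity, time_pressure
from .task import BlockSpec, Schedule, TaskConfig

__all__ = ["WorldState", "init_block_state", "advance", "step", "sample_reward", "run_session"]

_INF = float("inf")
_BUTTON_CODE = {"forage": 0.0, "check": 1.0, "hide": 2.0, "return": 2.0}


def sample_reward(epoch, config: TaskConfig, rng) -> float:
    """One per-second reward draw: Normal(mean, sd) clipped at zero."""
    return max(0.0, float(rng.normal(epoch.reward_mean, config.reward_sd)))


@dataclass
class WorldState:
    """Mutable world state for one block."""

    block_index: int
    # scheduled epoch timeline: parallel lists of start/enter/arrival times
    starts: list
    enters: list
    arrivals: list
    reward_by_sec: np.ndarray
    t: float = 0.0
    avatar_mode: str = "active"  # active | hiding | transit_hide | transit_return
    mode_until: float = _INF
    lockout_until: float = 0.0
    epoch_index: int = 0
    enter_emitted: bool = False
    seen: bool = False
    last_seen_t: float = math.nan
    last_full_check_t: float = 0.0
    next_segment: int = 1
    sweep_progress: int = 0
    energy: float = 0.0
    lives: int = 0
    lives_gained: int = 0
    caught_count: int = 0
    events: list = field(default_factory=list)

    # -- read-only helpers -------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return len(self.starts)

    def epoch_start(self, i=None):
        i = self.epoch_index if i is None else i
        return self.starts[i] if i < self.n_epochs else self.arrivals[-1]

    def epoch_enter(self):
        return self.enters[self.epoch_index] if self.epoch_index < self.n_epochs else _INF

    def epoch_arrival(self):
        return self.arrivals[self.epoch_index] if self.epoch_index < self.n_epochs else _INF

    def reward_now(self) -> float:
        idx = min(int(self.t), len(self.reward_by_sec) - 1)
        return float(self.reward_by_sec[idx])

    def predator_progress(self, speed: float) -> float:
        enter = self.epoch_enter()
        if self.t < enter:
            return math.nan
        return min(1.0, (self.t - enter) / speed)


def init_block_state(block: BlockSpec, block_index: int, config: TaskConfig, rng) -> WorldState:
    starts, enters, arrivals = [], [], []
    speed = block.speed_seconds(config)
    t = 0.0
    for ep in block.epochs:
        starts.append(t)
        enters.append(t + ep.onset_delay)
        arrivals.append(t + ep.onset_delay + speed)
        t = arrivals[-1]
    n_sec = int(math.ceil(config.block_duration))
    means = np.empty(n_sec)
    j = 0
    for s in range(n_sec):
        while j < len(arrivals) - 1 and s >= arrivals[j]:
            j += 1
        means[s] = block.epochs[j].reward_mean
    rew = np.clip(means + config.reward_sd * rng.standard_normal(n_sec), 0.0, None)
    return WorldState(
        block_index=block_index,
        starts=starts,
        enters=enters,
        arrivals=arrivals,
        reward_by_sec=rew,
    )


def _emit(state, t, kind, v1=math.nan, v2=math.nan):
    state.events.append(Event(t, state.block_index, state.epoch_index, kind, v1, v2))


def _end_epoch(state, t, outcome):
    _emit(state, t, "epoch_end", outcome)
    state.epoch_index += 1
    state.enter_emitted = False
    state.seen = False
    state.last_seen_t = math.nan
    # predator exit certifies an empty environment: the sweep clock resets
    state.last_full_check_t = t
    state.sweep_progress = 0


def advance(state: WorldState, block: BlockSpec, config: TaskConfig, to_t: float) -> None:
    """Roll world time forward to ``to_t``, processing predator milestones
    and avatar transit completions in time order."""
    n_ep = len(state.starts)
    while True:
        t_mode = state.mode_until
        i = state.epoch_index
        if i < n_ep:
            t_enter = state.enters[i] if not state.enter_emitted else _INF
            t_arr = state.arrivals[i]
        else:
            t_enter = t_arr = _INF
        t_next = min(t_mode, t_enter, t_arr)
        if t_next > to_t:
            break
        if t_next == t_mode:
            state.avatar_mode = "hiding" if state.avatar_mode == "transit_hide" else "active"
            state.mode_until = _INF
            state.t = max(state.t, t_next)
            continue
        if t_next == t_enter:
            state.t = max(state.t, t_enter)
            ep = block.epochs[state.epoch_index]
            _emit(state, t_enter, "predator_enter", float(ep.entry_segment))
            state.enter_emitted = True
            continue
        # predator reaches the center
        state.t = t_arr
        hidden = state.avatar_mode == "hiding"
        _emit(state, t_arr, "predator_reach", 1.0 if hidden else 0.0)
        if hidden:
            _end_epoch(state, t_arr, OUTCOME_HID_SAFE)
        else:
            state.caught_count += 1
            state.lives = max(0, state.lives - 1)
            state.avatar_mode = "active"
            state.mode_until = _INF
            _emit(state, t_arr, "caught", float(state.lives))
            _end_epoch(state, t_arr, OUTCOME_CAUGHT)
    state.t = max(state.t, to_t)


def step(state: WorldState, block: BlockSpec, action, config: TaskConfig):
    """Apply one action at the current time; returns the events it emitted.

    Presses while controls are locked or the avatar is in transit (or
    hidden, for buttons other than return) are recorded as
    ``press_inactive`` and change nothing.
    """
    if action is None:
        return []
    t = state.t
    mark = len(state.events)
    legal = (
        t >= state.lockout_until
        and state.avatar_mode in ("active", "hiding")
        and not (state.avatar_mode == "hiding" and action != "return")
        and not (state.avatar_mode == "active" and action == "return")
    )
    if not legal:
        _emit(state, t, "press_inactive", _BUTTON_CODE[action])
        return state.events[mark:]
    costs = config.action_costs
    rew = state.reward_now()
    if action == "forage":
        state.energy += rew
        while state.energy >= config.energy_per_life:
            state.energy -= config.energy_per_life
            state.lives += 1
            state.lives_gained += 1
        _emit(state, t, "forage", rew, rew)
        state.lockout_until = t + costs["forage"]
    elif action == "check":
        speed = block.speed_seconds(config)
        entered = t >= state.epoch_enter()
        if state.seen:
            seg = block.epochs[state.epoch_index].entry_segment
            state.last_seen_t = t
            _emit(state, t, "check", float(seg), rew)
        else:
            seg = state.next_segment
            _emit(state, t, "check", float(seg), rew)
            if (
                entered
                and state.epoch_index < state.n_epochs
                and seg == block.epochs[state.epoch_index].entry_segment
            ):
                state.seen = True
                state.last_seen_t = t
                _emit(state, t, "predator_seen", state.predator_progress(speed))
            else:
                state.next_segment = seg % block.n_segments + 1
                state.sweep_progress += 1
                if state.sweep_progress == block.n_segments:
                    state.sweep_progress = 0
                    state.last_full_check_t = t + costs["check"]
        state.lockout_until = t + costs["check"]
    elif action == "hide":
        prog = state.predator_progress(block.speed_seconds(config)) if state.seen else math.nan
        _emit(state, t, "hide", prog, rew)
        state.avatar_mode = "transit_hide"
        state.mode_until = t + costs["hide"]
        state.lockout_until = t + costs["hide"]
    elif action == "return":
        _emit(state, t, "return", math.nan, rew)
        state.avatar_mode = "transit_return"
        state.mode_until = t + costs["return"]
        state.lockout_until = t + costs["return"]
    else:
        raise ValueError(f"unknown action {action!r}")
    return state.events[mark:]


def _decision_view(state: WorldState, block: BlockSpec, config: TaskConfig) -> dict:
    speed = config.speed_levels[block.speed_level]
    t = state.t
    rew = state.reward_by_sec[int(t) if t < len(state.reward_by_sec) else -1]
    view = {
        "t": t,
        "phase": "post" if state.seen else "pre",
        "reward": float(rew),
        "speed_rank": float(block.speed_rank),
        "n_cones": float(block.n_segments),
        "env_index": float(state.block_index),
        "first_epoch": 1.0 if state.epoch_index == 0 else 0.0,
        "check_seq_started": 1.0 if state.sweep_progress > 0 else 0.0,
        "time_pressure": (t - state.last_full_check_t) / (config.min_delay_const + speed),
    }
    if state.seen:
        i = state.epoch_index
        view["position_uncertainty"] = (t - state.last_seen_t) / speed
        view["proximity"] = t - state.arrivals[i]
    return view


class SessionError(RuntimeError):
    pass


def run_session(
    schedule: Schedule,
    agent,
    seed: int,
    config: TaskConfig = None,
    participant_id: str = "p0",
) -> EventLog:
    """Play a full session: every block, with mood ratings in between."""
    config = config or TaskConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    duration = config.block_duration
    all_events = []
    lives = 0
    energy = 0.0  # the energy bar carries over between blocks
    lives_gained_total = 0
    caught_total = 0
    valid = True

    _jit_buf = []

    def jitter():
        if not _jit_buf:
            _jit_buf.extend(rng.exponential(1.0 / agent.decision_rate, size=256))
        return _jit_buf.pop()

    for b_idx, block in enumerate(schedule.blocks):
        state = init_block_state(block, b_idx, config, rng)
        state.lives = lives
        state.energy = energy
        if hasattr(agent, "begin_block"):
            agent.begin_block(b_idx, block, config)
        pending_inactive = None  # (t0, t1, button) of the last lockout
        forage_n = check_n = hide_n = 0
        lives_at_start = state.lives_gained
        caught_at_start = state.caught_count
        while True:
            if state.avatar_mode in ("hiding", "transit_hide"):
                t_arr = state.epoch_arrival()
                if t_arr >= duration:
                    break
                t_press = t_arr + jitter()
                if t_press >= duration:
                    advance(state, block, config, duration)
                    break
                if pending_inactive is not None:
                    _poisson_presses(state, rng, agent, *pending_inactive)
                    pending_inactive = None
                advance(state, block, config, t_press)
                if state.avatar_mode == "hiding":
                    step(state, block, "return", config)
                    cost = config.action_costs["return"]
                    pending_inactive = (t_press, min(t_press + cost, duration), "return")
                continue
            t_press = max(state.t, state.lockout_until) + jitter()
            if t_press >= duration:
                advance(state, block, config, duration)
                break
            if pending_inactive is not None:
                _poisson_presses(state, rng, agent, *pending_inactive)
                pending_inactive = None
            advance(state, block, config, t_press)
            if state.avatar_mode != "active":
                continue
            view = _decision_view(state, block, config)
            try:
                action = agent.decide(view, rng)
            except Exception as exc:  # noqa: BLE001 - abort with partial log
                valid = False
                all_events.extend(state.events)
                log = EventLog(participant_id, schedule, all_events, valid=False)
                log.error = repr(exc)
                return log
            step(state, block, action, config)
            if action == "forage":
                forage_n += 1
            elif action == "check":
                check_n += 1
            elif action == "hide":
                hide_n += 1
            cost = config.action_costs[action]
            pending_inactive = (t_press, min(t_press + cost, duration), action)
        if pending_inactive is not None:
            _poisson_presses(state, rng, agent, *pending_inactive)
        if state.epoch_index < state.n_epochs:
            _emit(state, duration, "epoch_end", OUTCOME_BLOCK_END)
        _emit(state, duration, "block_end")
        state.events.sort(key=lambda e: e.t)
        lives = state.lives
        energy = state.energy
        lives_gained_total += state.lives_gained - lives_at_start
        caught_total += state.caught_count - caught_at_start
        summary = {
            "block_index": b_idx,
            "speed_rank": float(block.speed_rank),
            "n_cones": float(block.n_segments),
            "reward_max": max(e.reward_mean for e in block.epochs),
            "reward_min": min(e.reward_mean for e in block.epochs),
            "caught": float(state.caught_count - caught_at_start),
            "lives_gained": float(state.lives_gained - lives_at_start),
            "forage_rate": forage_n / duration,
            "check_rate": check_n / duration,
            "hide_count": float(hide_n),
        }
        if hasattr(agent, "end_block"):
            mood = agent.end_block(summary, rng)
            if mood is not None:
                state.events.append(
                    Event(duration, b_idx, state.epoch_index, "mood_rating", mood[0], mood[1])
                )
        all_events.extend(state.events)
    log = EventLog(participant_id, schedule, all_events, valid=valid)
    log.final_lives = lives
    log.lives_gained = lives_gained_total
    log.caught_total = caught_total
    return log


def _poisson_presses(state, rng, agent, t0, t1, action):
    rate = getattr(agent, "inactive_press_rate", 0.0)
    if rate <= 0 or t1 <= t0:
        return
    n = rng.poisson(rate * (t1 - t0))
    if n == 0:
        return
    code = _BUTTON_CODE[action]
    for t in sorted(rng.uniform(t0, t1, size=n)):
        _emit(state, float(t), "press_inactive", code)
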