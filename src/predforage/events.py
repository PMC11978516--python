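"""Event log container and tidy CSV / JSON round-trip IO.

An :class:`EventLog` is the complete timestamped record of one simulated
session: every button press (forage / check / hide / return), every press
made while controls were locked out (``press_inactive``), predator
milestones (enter / seen / reach / caught), epoch and block terminators and
the two post-block mood ratings.  Timestamps are seconds since block start;
rows carry the block and epoch index.

``value1`` / ``value2`` are kind-specific:

==============  ========================  =========================
kind            value1                    value2
==============  ========================  =========================
forage          reward credited           on-screen reward sample
check           segment inspected         on-screen reward sample
hide            predator progress (0-1,   on-screen reward sample
                nan if undiscovered)
return          nan                       on-screen reward sample
press_inactive  button (0=forage,         nan
                1=check, 2=hide)
predator_enter  entry segment             nan
predator_seen   predator progress         nan
predator_reach  1 if avatar hidden        nan
caught          lives after capture       nan
epoch_end       outcome code              nan
block_end       nan                       nan
mood_rating     stress (0-100)            excitement (0-100)
==============  ========================  =========================
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

from .task import BlockSpec, EpochSpec, Schedule

SCHEMA_VERSION = 1

#: epoch_end outcome codes
OUTCOME_HID_SAFE = 0.0
OUTCOME_CAUGHT = 1.0
OUTCOME_BLOCK_END = 2.0

ACTION_KINDS = ("forage", "check", "hide", "return")


class Event(NamedTuple):
    t: float
    block: int
    epoch: int
    kind: str
    value1: float = float("nan")
    value2: float = float("nan")


@dataclass
class EventLog:
    participant_id: str
    schedule: Schedule
    events: list
    valid: bool = True

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.events, columns=Event._fields)
        df.insert(0, "participant_id", self.participant_id)
        return df

    def actions(self):
        return [e for e in self.events if e.kind in ACTION_KINDS]


def write_csv(log: EventLog, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# predforage eventlog schema v{SCHEMA_VERSION}\n")
        log.to_frame().to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _schedule_to_dict(s: Schedule) -> dict:
    return {
        "seed": s.seed,
        "blocks": [
            {
                "speed_level": b.speed_level,
                "n_segments": b.n_segments,
                "epochs": [dataclasses.asdict(e) for e in b.epochs],
            }
            for b in s.blocks
        ],
    }


def _schedule_from_dict(d: dict) -> Schedule:
    return Schedule(
        seed=d["seed"],
        blocks=tuple(
            BlockSpec(
                speed_level=b["speed_level"],
                n_segments=b["n_segments"],
                epochs=tuple(EpochSpec(**e) for e in b["epochs"]),
            )
            for b in d["blocks"]
        ),
    )


def write_json(log: EventLog, path) -> None:
    obj = {
        "schema_version": SCHEMA_VERSION,
        "participant_id": log.participant_id,
        "valid": log.valid,
        "schedule": _schedule_to_dict(log.schedule),
        "events": [list(e) for e in log.events],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def read_json(path) -> EventLog:
    with open(path) as fh:
        obj = json.load(fh)
    events = [
        Event(t, int(b), int(e), k, _f(v1), _f(v2))
        for t, b, e, k, v1, v2 in obj["events"]
    ]
    return EventLog(
        participant_id=obj["participant_id"],
        schedule=_schedule_from_dict(obj["schedule"]),
        events=events,
        valid=obj["valid"],
    )


def _f(x):
    return float("nan") if x is None else float(x)


def logs_equal(a: EventLog, b: EventLog) -> bool:
    """Equality up to NaN payloads (NaN == NaN for round-trip checks)."""
    if (a.participant_id, a.valid, a.schedule) != (b.participant_id, b.valid, b.schedule):
        return False
    if len(a.events) != len(b.events):
        return False
    for x, y in zip(a.events, b.events):
        if x.kind != y.kind or (x.block, x.epoch) != (y.block, y.epoch):
            return False
        for u, v in ((x.t, y.t), (x.value1, y.value1), (x.value2, y.value2)):
            if math.isnan(u) and math.isnan(v):
                continue
            if u != v:
                return False
    return True
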