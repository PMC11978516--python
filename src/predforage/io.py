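"""Config and cohort-bundle IO (YAML task config, tidy CSV bundles)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .cohort import TRAITS
from .measures import registry_frame
from .task import TaskConfig

__all__ = ["config_to_yaml", "config_from_yaml", "write_cohort_bundle", "registry_to_yaml"]


def config_to_yaml(config: TaskConfig, path) -> None:
    d = dataclasses.asdict(config)
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def config_from_yaml(path) -> TaskConfig:
    d = yaml.safe_load(Path(path).read_text())
    for k in ("check_segments_range", "onset_delay_range", "reward_mean_range",
              "predators_per_block_range"):
        if k in d:
            d[k] = tuple(d[k])
    cfg = TaskConfig(**d)
    cfg.validate()
    return cfg


def registry_to_yaml(path, registry=None) -> None:
    df = registry_frame(registry)
    Path(path).write_text(yaml.safe_dump(df.to_dict("records"), sort_keys=False))


def write_cohort_bundle(participants, out_dir) -> None:
    """events.csv / moods.csv / traits.csv / debrief.csv / items.csv +
    manifest.json for a sampled cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    moods = []
    traits = []
    debrief = []
    items = []
    for p in participants:
        frames.append(p.log.to_frame())
        for e in p.log.events:
            if e.kind == "mood_rating":
                moods.append({"participant_id": p.participant_id, "block": e.block,
                              "stress": e.value1, "excitement": e.value2})
        row = {"participant_id": p.participant_id, "gender": p.traits.gender,
               "age": p.traits.age, "education": p.traits.education}
        row.update({t: p.traits.scores[t] for t in TRAITS})
        traits.append(row)
        debrief.append({"participant_id": p.participant_id,
                        **{f"q{i}": v for i, v in enumerate(p.debrief)}})
        items.append({"participant_id": p.participant_id,
                      **{f"item{i}": v for i, v in enumerate(p.traits.items)}})
    pd.concat(frames, ignore_index=True).to_csv(out / "events.csv", index=False)
    pd.DataFrame(moods).to_csv(out / "moods.csv", index=False)
    pd.DataFrame(traits).to_csv(out / "traits.csv", index=False)
    pd.DataFrame(debrief).to_csv(out / "debrief.csv", index=False)
    pd.DataFrame(items).to_csv(out / "items.csv", index=False)
    manifest = {
        "n_participants": len(participants),
        "schedule_seed": participants[0].log.schedule.seed if participants else None,
        "participants": [p.participant_id for p in participants],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
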