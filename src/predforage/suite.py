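"""Per-participant analysis suites: single-choice policy fits and the
four directional regression families.

The four directions are (a/b) task features -> behavior (per-epoch
regressions, pre- and post-discovery, with monotonic coding of predator
speed and cone count), (c) task features -> mood (per-block regressions
of stress/excitement ratings), (d) mood -> behavior (the residuals of
the behavior regressions, averaged per block, regressed on pre-block
stress and excitement), and (e) behavior -> mood (the residuals of the
mood regressions regressed on a block-level behavioral measure,
controlling for pre-block mood).  Residualizing before crossing
directions ensures each analysis measures influence beyond what the
task design explains.

Behavior-model regressors are z-scored within participant; mood-model
regressors are z-scored across participants (pass ``scaling`` computed
cohort-wide, e.g. via :func:`mood_design_scaling`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import POST_REGRESSORS, PRE_REGRESSORS
from .events import EventLog
from .features import FEATURE_SCALING
from .glm import encode_monotonic, fit_glm
from .measures import _EXTRACTORS, GRANTS, epochize, summarize_block
from .screening import classify_epochs
from .task import TaskConfig

__all__ = [
    "FormulaSpec",
    "extract_choices",
    "fit_choice_models",
    "fit_direction_suite",
    "mood_design_scaling",
    "MOOD_REGRESSORS",
]

MOOD_REGRESSORS = (
    "reward_max",
    "reward_min",
    "lives_gained",
    "block",
    "caught",
)  # + mo(speed), mo(cones)

MIN_CHOICES = 20
MIN_EPOCHS = 15


@dataclass(frozen=True)
class FormulaSpec:
    """Declarative regression description (outcome, regressors, family).

    ``regressors`` is a list of (name, role, coding) with role in
    {interest, control} and coding in {linear, monotonic}; monotonic
    coding is only valid for the ordinal task factors.
    """

    outcome: str
    regressors: tuple
    family: str = "gaussian"
    standardization: str = "within_participant"

    def __post_init__(self):
        for name, role, coding in self.regressors:
            if coding == "monotonic" and name not in ("speed_rank", "n_cones"):
                raise ValueError("monotonic coding is reserved for ordinal task factors")


# ---------------------------------------------------------------------------
# single-choice models


def extract_choices(log: EventLog, config: TaskConfig = None) -> pd.DataFrame:
    """Replay a log into one row per choice with the policy features.

    Pre-discovery rows hold forage/check choices; post-discovery rows
    hold all actions, labeled for the hide-vs-not and forage-vs-check
    stages.
    """
    config = config or TaskConfig()
    rows = []
    by_block = {}
    for e in log.events:
        by_block.setdefault(e.block, []).append(e)
    for b_idx, block in enumerate(log.schedule.blocks):
        speed = block.speed_seconds(config)
        arrivals = []
        t = 0.0
        for ep in block.epochs:
            arrivals.append(t + ep.onset_delay + speed)
            t = arrivals[-1]
        seen = False
        last_seen = math.nan
        last_full = 0.0
        sweep = 0
        epoch = 0
        for e in by_block.get(b_idx, []):
            if e.kind == "predator_seen":
                seen = True
                last_seen = e.t
            elif e.kind == "epoch_end":
                epoch += 1
                seen = False
                last_seen = math.nan
                last_full = e.t
                sweep = 0
            elif e.kind in ("forage", "check", "hide"):
                row = {
                    "block": b_idx,
                    "epoch": epoch,
                    "t": e.t,
                    "action": e.kind,
                    "phase": "post" if seen else "pre",
                    "reward": e.value2,
                    "time_pressure": (e.t - last_full) / (config.min_delay_const + speed),
                    "check_seq_started": 1.0 if sweep > 0 else 0.0,
                    "speed_rank": float(block.speed_rank),
                    "n_cones": float(block.n_segments),
                    "env_index": float(b_idx),
                    "first_epoch": 1.0 if epoch == 0 else 0.0,
                    "position_uncertainty": (e.t - last_seen) / speed if seen else math.nan,
                    "proximity": (e.t - arrivals[epoch]) if epoch < len(arrivals) else math.nan,
                }
                rows.append(row)
                if e.kind == "check":
                    if seen:
                        last_seen = e.t
                    else:
                        sweep += 1
                        if sweep == block.n_segments:
                            sweep = 0
                            last_full = e.t + config.action_costs["check"]
    return pd.DataFrame(rows)


def _bernoulli_fit(df, y, regressors, prefix):
    """Standardize with the fixed reference scaling, drop degenerate
    columns, fit a prior-regularized logistic model."""
    out = {f"{prefix}_{r}": np.nan for r in ("intercept",) + tuple(regressors)}
    if len(df) < MIN_CHOICES or y.nunique() < 2:
        return out, f"too few {prefix} choices" if len(df) < MIN_CHOICES else f"constant {prefix} outcome"
    cols, names = [], []
    for r in regressors:
        v = df[r].to_numpy(dtype=float)
        if np.nanstd(v) < 1e-12:
            continue  # degenerate regressor: weight skipped
        m, s = FEATURE_SCALING[r]
        cols.append((v - m) / s)
        names.append(r)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    fit = fit_glm(X, y.to_numpy(dtype=float), "bernoulli", prior_sd=3.0, names=names)
    out[f"{prefix}_intercept"] = fit.coef["intercept"]
    for r in names:
        out[f"{prefix}_{r}"] = fit.coef[r]
    return out, ""


def fit_choice_models(log: EventLog, config: TaskConfig = None):
    """Three logistic fits per participant (pre check-vs-forage,
    post hide-vs-not, post forage-vs-check); returns (row dict, reasons)."""
    config = config or TaskConfig()
    choices = extract_choices(log, config)
    reasons = {}
    if choices.empty:
        return {}, {"all": "no choices"}
    pre = choices[(choices.phase == "pre") & choices.action.isin(["forage", "check"])]
    post = choices[choices.phase == "post"]
    row = {}
    r1, why = _bernoulli_fit(pre, (pre.action == "check").astype(float), PRE_REGRESSORS, "pre")
    row.update(r1)
    if why:
        reasons["pre"] = why
    r2, why = _bernoulli_fit(post, (post.action == "hide").astype(float), POST_REGRESSORS, "hide")
    row.update(r2)
    if why:
        reasons["hide"] = why
    fc = post[post.action != "hide"]
    r3, why = _bernoulli_fit(fc, (fc.action == "forage").astype(float), POST_REGRESSORS, "fc")
    row.update(r3)
    if why:
        reasons["fc"] = why
    return row, reasons


# ---------------------------------------------------------------------------
# directional suites


def _z(v):
    v = np.asarray(v, dtype=float)
    s = np.nanstd(v)
    return (v - np.nanmean(v)) / s if s > 0 else v * 0.0


def mood_design_scaling(block_tables) -> dict:
    """Across-participant (mean, sd) for every mood-model regressor."""
    allb = pd.concat(block_tables, ignore_index=True)
    out = {}
    for c in ("reward_max", "reward_min", "lives_gained", "block", "caught",
              "stress", "excitement", "forage_rate", "check_rate", "pct_time_hiding"):
        col = allb["block"] if c == "block" else allb[c]
        out[c] = (float(np.nanmean(col)), float(np.nanstd(col)) or 1.0)
    return out


def _epoch_design(records, availability, outcome, post_phase=False):
    """Per-epoch outcome + regressors for the task->behavior models."""
    need = "post" if post_phase else "pre"
    ys, rows, mono_sp, mono_nc = [], [], [], []
    for r in records:
        cls = availability.get((r.block, r.epoch), "full") if availability else "full"
        if need not in GRANTS[cls]:
            continue
        y = _EXTRACTORS[outcome](r)
        if math.isnan(y):
            continue
        row = [r.reward_mean, r.onset_delay, float(r.block), 1.0 if r.first_epoch else 0.0]
        if post_phase:
            t_remaining = (r.enter_t + r.speed) - r.discovery_t
            row.append(t_remaining)
        ys.append(y)
        rows.append(row)
        mono_sp.append(r.speed_rank)
        mono_nc.append(r.n_segments - 1)
    return np.array(ys), np.array(rows), np.array(mono_sp, int), np.array(mono_nc, int)


def _eligible(ys, mono_sp, mono_nc):
    if len(ys) <= MIN_EPOCHS:
        return "15 or fewer epochs available"
    if np.std(ys) < 1e-12:
        return "constant outcome"
    combos = set(zip(mono_sp.tolist(), mono_nc.tolist()))
    if len(combos) < 12:
        return "missing speed x cones conditions"
    return ""


def fit_behavior_model(records, availability, outcome, post_phase=False, compute_sd=True):
    """One task->behavior regression; returns (fit, per-epoch residual df)."""
    ys, rows, mono_sp, mono_nc = _epoch_design(records, availability, outcome, post_phase)
    why = _eligible(ys, mono_sp, mono_nc)
    if why:
        return None, why, None
    X = rows.copy()
    for j in range(X.shape[1]):
        X[:, j] = _z(X[:, j])
    names = ["reward", "delay", "block", "first_epoch"] + (
        ["time_remaining"] if post_phase else []
    )
    fam = "gaussian"
    fit = fit_glm(X, ys, fam, prior_sd=3.0,
                  mono={"speed": (mono_sp, 3), "cones": (mono_nc, 4)}, names=names,
                  compute_sd=compute_sd, tol="coarse")
    eta = fit.coef["intercept"] + X @ np.array([fit.coef[n] for n in names])
    eta = eta + encode_monotonic(mono_sp, fit.mono["speed"])
    eta = eta + encode_monotonic(mono_nc, fit.mono["cones"])
    resid = pd.DataFrame({"block": rows[:, 2].astype(int), "resid": ys - eta})
    return fit, "", resid


def fit_mood_model(block_table, mood, scaling, caught_as_count=False, compute_sd=True):
    """Task->mood regression for one rating (stress or excitement)."""
    bt = block_table[~block_table["mood_missing"]]
    y = bt[mood].to_numpy(dtype=float)
    if len(y) < 5 or np.std(y) < 1e-12:
        return None, "too few or constant mood ratings", None
    caught = bt["caught"].to_numpy(dtype=float)
    if not caught_as_count:
        caught = (caught > 0).astype(float)
    cols = {
        "reward_max": bt["reward_max"].to_numpy(float),
        "reward_min": bt["reward_min"].to_numpy(float),
        "lives_gained": bt["lives_gained"].to_numpy(float),
        "block": bt["block"].to_numpy(float),
        "caught": caught,
    }
    names, Xc = [], []
    dropped = []
    for nm, v in cols.items():
        m, s = scaling.get(nm, (float(np.mean(v)), float(np.std(v)) or 1.0))
        vz = (v - m) / (s or 1.0)
        if np.std(vz) < 1e-12:
            dropped.append(nm)  # e.g. never caught: weight not extracted
            continue
        names.append(nm)
        Xc.append(vz)
    X = np.column_stack(Xc)
    mono_sp = bt["speed_rank"].to_numpy(int)
    mono_nc = bt["n_cones"].to_numpy(int) - 1
    fit = fit_glm(X, y, "gaussian", prior_sd=3.0,
                  mono={"speed": (mono_sp, 3), "cones": (mono_nc, 4)}, names=names,
                  compute_sd=compute_sd, tol="coarse")
    fit.dropped = dropped
    eta = fit.coef["intercept"] + X @ np.array([fit.coef[n] for n in names])
    eta = eta + encode_monotonic(mono_sp, fit.mono["speed"])
    eta = eta + encode_monotonic(mono_nc, fit.mono["cones"])
    resid = pd.DataFrame({"block": bt["block"].to_numpy(int), "resid": y - eta})
    return fit, "", resid


def _ols(X, y):
    Xa = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    return beta


def fit_direction_suite(
    log: EventLog = None,
    config: TaskConfig = None,
    records=None,
    availability=None,
    block_table=None,
    pre_outcomes=("forage_rate_pre", "pct_active_time_checking_pre"),
    post_outcomes=(),
    behaviors_for_mood=("forage_rate", "pct_time_hiding"),
    moods=("stress", "excitement"),
    scaling=None,
    caught_as_count=False,
    compute_sd=True,
) -> pd.DataFrame:
    """All four directions for one participant; tidy weight table."""
    config = config or TaskConfig()
    if records is None:
        records = epochize(log, config)
    if availability is None:
        availability = classify_epochs(records)
    if block_table is None:
        block_table = summarize_block(records, log, config)
    scaling = scaling or {}
    rows = []

    def emit(model, outcome, regressor, est, sd, n, why=""):
        rows.append(
            {
                "model": model,
                "outcome": outcome,
                "regressor": regressor,
                "estimate": est,
                "sd": sd,
                "n": n,
                "skip_reason": why,
            }
        )

    # pre-block mood (rating given after the previous block), z across cohort
    bt = block_table
    for m in ("stress", "excitement"):
        mu, s = scaling.get(m, (float(np.nanmean(bt[m])), float(np.nanstd(bt[m])) or 1.0))
        bt = bt.assign(**{f"pre_{m}": ((bt[m].shift(1) - mu) / (s or 1.0))})
    behav_resids = {}

    for post_phase, outcomes in ((False, pre_outcomes), (True, post_outcomes)):
        model = "behavior_task_post" if post_phase else "behavior_task_pre"
        for outcome in outcomes:
            fit, why, resid = fit_behavior_model(records, availability, outcome, post_phase, compute_sd)
            if why:
                emit(model, outcome, "*", np.nan, np.nan, 0, why)
                continue
            for k, v in fit.coef.items():
                emit(model, outcome, k, v, fit.sd.get(k, np.nan), fit.n)
            behav_resids[(model, outcome)] = resid

    mood_resids = {}
    for mood in moods:
        fit, why, resid = fit_mood_model(block_table, mood, scaling, caught_as_count, compute_sd)
        if why:
            emit("mood_task", mood, "*", np.nan, np.nan, 0, why)
            continue
        for k, v in fit.coef.items():
            emit("mood_task", mood, k, v, fit.sd.get(k, np.nan), fit.n)
        for nm in fit.dropped:
            emit("mood_task", mood, nm, np.nan, np.nan, fit.n, "constant regressor")
        mood_resids[mood] = resid

    # (d) mood -> behavior: block-averaged behavior residuals ~ pre-block moods
    for (model, outcome), resid in behav_resids.items():
        blk = resid.groupby("block")["resid"].mean()
        dd = bt.set_index("block").join(blk.rename("y"), how="inner").dropna(
            subset=["y", "pre_stress", "pre_excitement"]
        )
        if len(dd) < 5:
            emit("mood_to_behavior", outcome, "*", np.nan, np.nan, len(dd), "too few blocks")
            continue
        beta = _ols(dd[["pre_stress", "pre_excitement"]].to_numpy(float), dd["y"].to_numpy(float))
        emit("mood_to_behavior", outcome, "preblock_stress", beta[1], np.nan, len(dd))
        emit("mood_to_behavior", outcome, "preblock_excitement", beta[2], np.nan, len(dd))

    # (e) behavior -> mood: mood residuals ~ behavior + pre-block same mood
    for mood, resid in mood_resids.items():
        dd = bt.set_index("block").join(
            resid.set_index("block")["resid"].rename("y"), how="inner"
        )
        for behav in behaviors_for_mood:
            m, s = scaling.get(behav, (float(np.nanmean(dd[behav])), float(np.nanstd(dd[behav])) or 1.0))
            sub = dd.dropna(subset=["y", behav, f"pre_{mood}"])
            if len(sub) < 5:
                emit("behavior_to_mood", mood, behav, np.nan, np.nan, len(sub), "too few blocks")
                continue
            X = np.column_stack(
                [(sub[behav].to_numpy(float) - m) / (s or 1.0), sub[f"pre_{mood}"].to_numpy(float)]
            )
            beta = _ols(X, sub["y"].to_numpy(float))
            emit("behavior_to_mood", mood, behav, beta[1], np.nan, len(sub))
    return pd.DataFrame(rows)
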