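"""Choice-model fits, the directional regression suites and residualization."""

import numpy as np
import pandas as pd
import pytest

from predforage import (
    LogisticPolicyAgent,
    PolicyParams,
    TaskConfig,
    epochize,
    fit_choice_models,
    generate_schedule,
    run_session,
    summarize_block,
)
from predforage.screening import classify_epochs
from predforage.suite import extract_choices, fit_behavior_model, fit_direction_suite, fit_mood_model


@pytest.fixture(scope="module")
def choice_fit(default_log, config):
    return fit_choice_models(default_log, config)


def test_generative_weights_recovered_by_choice_models(choice_fit):
    row, reasons = choice_fit
    assert reasons == {}
    truth = dict(zip(PolicyParams.names(), PolicyParams.default().as_vector()))
    # strongly identified pre-discovery weights land near the truth
    for k, tol in [("pre_time_pressure", 0.8), ("pre_check_seq_started", 0.5),
                   ("pre_reward", 0.35)]:
        assert row[k] == pytest.approx(truth[k], abs=tol)
    assert np.sign(row["hide_proximity"]) == 1.0


def test_zero_reward_weight_estimates_near_zero(schedule, config):
    params = PolicyParams.default()
    params.pre[1] = 0.0
    log = run_session(schedule, LogisticPolicyAgent(params), seed=21, config=config)
    row, _ = fit_choice_models(log, config)
    assert abs(row["pre_reward"]) < 0.3


def test_degenerate_regressor_weight_skipped(config):
    one_seg = config.replace(check_segments_range=(1, 1))
    sched = generate_schedule(one_seg, seed=2, max_attempts=5000)
    log = run_session(sched, LogisticPolicyAgent(PolicyParams.default()), seed=5, config=one_seg)
    row, _ = fit_choice_models(log, one_seg)
    # single-segment blocks never start a multi-check sweep
    assert np.isnan(row["pre_check_seq_started"])
    assert np.isfinite(row["pre_reward"])


def test_choice_features_match_engine_formulas(default_log, config):
    ch = extract_choices(default_log, config)
    assert {"pre", "post"} == set(ch.phase.unique())
    pre = ch[ch.phase == "pre"]
    assert (pre.time_pressure >= -1e-9).all()
    assert pre.position_uncertainty.isna().all()
    post = ch[ch.phase == "post"]
    assert (post.proximity <= 1e-9).all()  # choices happen before arrival
    assert (post.position_uncertainty >= -1e-9).all()
    assert ch.reward.between(0, 150).all()


def test_behavior_model_eligibility_rules(records, availability):
    fit, why, resid = fit_behavior_model(records, availability, "forage_rate_pre")
    assert why == "" and fit.n > 15
    few = records[:10]
    _, why, _ = fit_behavior_model(few, {}, "forage_rate_pre")
    assert "epochs" in why


def test_behavior_residuals_are_orthogonal_to_features(records, availability):
    """Regressing the residuals back on the task features gives ~0."""
    fit, why, resid = fit_behavior_model(records, availability, "forage_rate_pre")
    merged = []
    need = [r for r in records if True]
    from predforage.suite import _epoch_design

    ys, rows, sp, nc = _epoch_design(records, availability, "forage_rate_pre")
    X = rows.copy()
    for j in range(X.shape[1]):
        s = X[:, j].std()
        X[:, j] = (X[:, j] - X[:, j].mean()) / (s if s > 0 else 1.0)
    r = resid["resid"].to_numpy()
    for j in range(X.shape[1]):
        assert abs(np.corrcoef(X[:, j], r)[0, 1]) < 0.06


def test_mood_model_regressor_set(records, default_log, config):
    bt = summarize_block(records, default_log, config)
    fit, why, resid = fit_mood_model(bt, "stress", {})
    assert why == ""
    linear = {k for k in fit.coef if not k.startswith("mo(")} - {"intercept"}
    mono = {k for k in fit.coef if k.startswith("mo(")}
    assert linear | mono == {
        "reward_max", "reward_min", "lives_gained", "block", "caught",
        "mo(speed)", "mo(cones)",
    }
    assert len(linear | mono) == 7  # seven regressors plus the intercept


def test_mood_model_caught_weight_not_extracted_when_never_caught(
    records, default_log, config
):
    bt = summarize_block(records, default_log, config).copy()
    bt["caught"] = 0.0
    fit, why, _ = fit_mood_model(bt, "stress", {})
    assert "caught" not in fit.coef
    assert "caught" in fit.dropped


def test_direction_suite_produces_all_four_directions(default_log, config, records, availability):
    bt = summarize_block(records, default_log, config)
    w = fit_direction_suite(
        records=records, availability=availability, block_table=bt, config=config,
        compute_sd=False,
    )
    assert set(w.model.unique()) >= {
        "behavior_task_pre", "mood_task", "mood_to_behavior", "behavior_to_mood",
    }
    ok = w[w.skip_reason == ""]
    assert not ok.estimate.isna().any()


def test_zero_homeostasis_cohort_directional_weights_center_on_zero(config):
    """Without a planted loop, mood->behavior weights scatter around 0."""
    from predforage.agents import MoodGenParams
    from predforage.pipeline import _homeostasis_weights
    from predforage.suite import mood_design_scaling

    sched = generate_schedule(config, seed=4)
    d_ws, e_ws = [], []
    tables, parts = [], []
    for i in range(12):
        params = PolicyParams.default()
        agent = LogisticPolicyAgent(params, MoodGenParams())  # gains all zero
        log = run_session(sched, agent, seed=400 + i, config=config)
        recs = epochize(log, config)
        av = classify_epochs(recs)
        bt = summarize_block(recs, log, config)
        tables.append(bt)
        parts.append((recs, av, bt))
    scaling = mood_design_scaling(tables)
    for recs, av, bt in parts:
        d, e = _homeostasis_weights(recs, av, bt, scaling)
        if d is not None:
            d_ws.append(d)
        if e is not None:
            e_ws.append(e)
    t_d = np.mean(d_ws) / (np.std(d_ws, ddof=1) / np.sqrt(len(d_ws)))
    t_e = np.mean(e_ws) / (np.std(e_ws, ddof=1) / np.sqrt(len(e_ws)))
    assert abs(t_d) < 4.0 and abs(t_e) < 4.0
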