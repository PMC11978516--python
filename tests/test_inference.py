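"""Statistical kernels: Wilcoxon, gating, prediction scores, BFs, horseshoe."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from predforage import (
    HypothesisNode,
    bayes_factor,
    compound_group_test,
    fit_horseshoe,
    max_p_pair,
    permutation_test,
    run_gated_tree,
    score_prediction,
    train_trait_model,
    wilcoxon_one_tailed,
)
from predforage.inference import TraitModel, fisher_z_mean, select_measures_by_bf


def _exact_wilcoxon_oracle(x):
    """Brute-force one-tailed p by enumerating every sign pattern."""
    x = np.asarray(x, dtype=float)
    x = x[x != 0]
    ranks = stats.rankdata(np.abs(x))
    w_obs = ranks[x > 0].sum()
    n = len(x)
    ge = sum(
        1
        for signs in itertools.product((0, 1), repeat=n)
        if np.dot(signs, ranks) >= w_obs - 1e-12
    )
    return ge / 2.0**n


def test_wilcoxon_small_sample_example():
    w, p, _, _ = wilcoxon_one_tailed([1.0, 2.0, 3.0])
    assert w == 6.0
    assert p == pytest.approx(0.125)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.integers(min_value=-6, max_value=6).filter(lambda v: v != 0),
        min_size=2,
        max_size=12,
    )
)
def test_wilcoxon_matches_exact_enumeration(xs):
    """For n <= 12 (ties included, via midranks) the p value equals the
    brute-force enumeration of all 2^n sign patterns."""
    _, p, _, _ = wilcoxon_one_tailed(xs)
    assert p == pytest.approx(_exact_wilcoxon_oracle(xs), abs=1e-12)


def test_wilcoxon_sign_symmetry(rng):
    x = rng.standard_normal(25) + 0.4
    _, p_greater, _, _ = wilcoxon_one_tailed(x, "greater")
    _, p_flip, _, _ = wilcoxon_one_tailed(-x, "less")
    assert p_greater == pytest.approx(p_flip)


def test_wilcoxon_agrees_with_scipy_at_moderate_n(rng):
    x = rng.standard_normal(40) + 0.3
    _, p, _, _ = wilcoxon_one_tailed(x)
    ref = stats.wilcoxon(x, alternative="greater", correction=False, method="approx").pvalue
    assert p == pytest.approx(ref, rel=0.05)


def test_max_p_pair():
    assert max_p_pair(0.001, 0.03) == 0.03
    assert max_p_pair(0.2, 0.01) == 0.2
    assert max_p_pair(0.07, 0.07) == 0.07


def _weight_table(values, model="m", outcome="o", regressor="x"):
    return pd.DataFrame(
        {
            "participant": [f"p{i}" for i in range(len(values))],
            "model": model,
            "outcome": outcome,
            "regressor": regressor,
            "estimate": values,
        }
    )


def test_compound_test_sign_alignment(rng):
    vals = rng.standard_normal(30) + 0.8
    tab = _weight_table(vals)
    node_pos = HypothesisNode("h", components=(("m", "o", "x", 1),))
    node_neg = HypothesisNode("h", components=(("m", "o", "x", -1),))
    res_pos = compound_group_test(tab, node_pos)
    tab_neg = _weight_table(-vals)
    res_neg = compound_group_test(tab_neg, node_neg)
    assert res_pos["p"] == pytest.approx(res_neg["p"])
    with pytest.raises(ValueError):
        HypothesisNode("bad", components=(("m", "o", "x", 2),))


def test_gated_tree_blocks_children_of_null_parents(rng):
    null_tab = _weight_table(rng.standard_normal(40))
    child = HypothesisNode("child", components=(("m", "o", "x", 1),))
    parent = HypothesisNode("parent", components=(("m", "o", "x", 1),), children=(child,))
    res = run_gated_tree(parent, null_tab)
    if res["parent"]["p"] >= 0.05:
        assert res["child"]["status"] == "not tested (gated)"
    strong = _weight_table(rng.standard_normal(40) + 2.0)
    res2 = run_gated_tree(parent, strong)
    assert res2["parent"]["p"] < 0.05
    assert res2["child"]["status"] == "tested"


def test_gated_tree_rejects_cycles():
    a = HypothesisNode("a", components=(("m", "o", "x", 1),))
    a.children = (a,)
    with pytest.raises(ValueError, match="cycle"):
        run_gated_tree(a, _weight_table([1.0, 2.0]))


def test_gating_bounds_follow_up_tests_under_global_null(rng):
    """Under the null, children are examined in at most ~alpha of cohorts."""
    tested = 0
    for i in range(200):
        tab = _weight_table(rng.standard_normal(20))
        node = HypothesisNode("p", components=(("m", "o", "x", 1),))
        res = compound_group_test(tab, node)
        tested += res["p"] < 0.05
    assert tested / 200 < 0.11


def _toy_model(coef, measures=("m1",), y_mean=0.0):
    return TraitModel(
        trait="t", outcome_type="continuous", measures=measures,
        coef=coef, x_mean=np.zeros(len(measures)), x_sd=np.ones(len(measures)),
        y_mean=y_mean, n_train=10,
    )


def test_r2_oos_identities(rng):
    y = rng.standard_normal(50)
    table = pd.DataFrame({"m1": y, "t": y})
    perfect = _toy_model({"intercept": 0.0, "m1": 1.0})
    s = score_prediction(perfect, table)
    assert s.r2_oos == pytest.approx(1.0)
    assert s.r == pytest.approx(1.0)
    null_like = _toy_model({"intercept": 0.0, "m1": 0.0})
    s0 = score_prediction(null_like, table)
    assert s0.r2_oos == pytest.approx(0.0, abs=1e-12)
    assert s0.flag == "constant predictions" and s0.r == 0.0


def test_binary_scoring_likelihood_ratio_form(rng):
    y = np.where(rng.random(200) < 0.5, 1.0, 2.0)
    x = (y == 2.0) * 2.0 - 1.0 + rng.standard_normal(200) * 0.5
    table = pd.DataFrame({"m1": x, "gender": y})
    model = TraitModel(
        trait="gender", outcome_type="binary", measures=("m1",),
        coef={"intercept": 0.0, "m1": 2.0}, x_mean=np.array([0.0]),
        x_sd=np.array([1.0]), y_mean=0.0, n_train=100,
    )
    s = score_prediction(model, table)
    assert 50.0 < s.accuracy <= 100.0
    assert 0.0 < s.r2_oos <= 1.0


def test_fisher_z_mean_analytic_value():
    assert fisher_z_mean([0.0, 0.8]) == pytest.approx(0.5)
    assert fisher_z_mean([0.3, 0.3]) == pytest.approx(0.3)


def test_train_score_split_sample_null_and_determinism(rng):
    n = 400
    table = pd.DataFrame(
        {"m1": rng.standard_normal(n), "m2": rng.standard_normal(n), "t": rng.standard_normal(n)}
    )
    train, test = table.iloc[:250], table.iloc[250:]
    m = train_trait_model(train, "t", ("m1", "m2"))
    m2 = train_trait_model(train, "t", ("m1", "m2"))
    assert m.coef == m2.coef  # deterministic
    s = score_prediction(m, test)
    assert abs(s.r) < 3.0 / np.sqrt(len(test))
    # frozen scaling: constants come from the training sample only
    assert m.x_mean == pytest.approx(train[["m1", "m2"]].mean().to_numpy())


def test_permutation_p_bounds_and_median(rng):
    y = np.arange(100, dtype=float)

    def top(labels):
        return float(labels[0])

    p_lo = permutation_test(lambda lab: 1.0 if lab[0] == 99 else 0.0, y, n_perm=500, rng=1)
    assert p_lo >= 1.0 / 501
    vals = rng.standard_normal(60)
    p_mid = permutation_test(lambda lab: float(np.mean(lab[:30]) - np.mean(lab[30:])), vals,
                             n_perm=400, rng=2)
    assert 0.2 < p_mid < 0.8


def test_permutation_invariant_to_monotone_transform(rng):
    x = rng.standard_normal(40)
    y = x + rng.standard_normal(40)

    def score_raw(lab):
        return float(np.corrcoef(x, lab)[0, 1])

    def score_mono(lab):
        return float(np.tanh(3.0 * np.corrcoef(x, lab)[0, 1]))

    p1 = permutation_test(score_raw, y, n_perm=300, rng=3)
    p2 = permutation_test(score_mono, y, n_perm=300, rng=3)
    assert p1 == p2


def test_correlation_bf_matches_reference_implementation():
    pg = pytest.importorskip("pingouin")
    for r, n in [(0.5, 100), (0.0, 500), (0.15, 374), (0.1, 702)]:
        ours = bayes_factor("correlation_1t", {"r": r, "n": n})
        ref = float(pg.bayesfactor_pearson(r, n, alternative="greater"))
        assert ours == pytest.approx(ref, rel=1e-3)


def test_bf_evidence_directions_and_monotonicity():
    assert bayes_factor("correlation_1t", {"r": 0.0, "n": 500}) < 1 / 3
    assert bayes_factor("correlation_1t", {"r": 0.5, "n": 100}) > 100
    bfs = [bayes_factor("correlation_1t", {"r": r, "n": 80}) for r in (0.1, 0.2, 0.3, 0.4)]
    assert all(a < b for a, b in zip(bfs, bfs[1:]))
    with pytest.raises(ValueError):
        bayes_factor("correlation_1t", {"r": 0.5, "n": 2})
    assert bayes_factor("proportion_1t", {"k": 80, "n": 100}) > 100
    assert bayes_factor("proportion_1t", {"k": 50, "n": 100}) < 1.0


def test_horseshoe_null_design_does_not_hallucinate_signal(rng):
    X = rng.standard_normal((300, 100))
    y = rng.standard_normal(300)
    beta, icpt, _ = fit_horseshoe(X, y)
    Xte = rng.standard_normal((200, 100))
    yte = rng.standard_normal(200)
    pred = icpt + Xte @ beta
    r = 0.0 if np.std(pred) < 1e-12 else np.corrcoef(pred, yte)[0, 1]
    assert abs(r) < 0.2
    with pytest.raises(ValueError):
        fit_horseshoe(X, y, p0_ratio=1.5)


def test_select_measures_by_bf_lists_planted_link(rng):
    n = 400
    t = rng.standard_normal(n)
    table = pd.DataFrame(
        {
            "apathy": t,
            "earnings": t * 0.5 + rng.standard_normal(n),
            "noise_measure": rng.standard_normal(n),
            "other_trait": rng.standard_normal(n),
        }
    )
    out = select_measures_by_bf(
        table, ["apathy"], ["earnings", "noise_measure"], threshold=3.0,
        controls={"apathy": ["other_trait"]},
    )
    assert ("earnings" in set(out.measure)) and out[out.measure == "earnings"].direction.iloc[0] == 1
    assert "noise_measure" not in set(out.measure)
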