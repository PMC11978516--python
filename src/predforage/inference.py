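"""Hypothesis-testing machinery: compound sign-aligned group tests with
hierarchical gating, split-sample trait prediction with permutation
nulls, Bayes factors, sparse (regularized-horseshoe) prediction and the
parameter-recovery experiment.

Group tests follow the compound scheme: the per-participant weights
entering a hypothesis are sign-aligned (flipped according to the
pre-registered expected direction) and summed, and the sums are tested
against zero with a one-tailed Wilcoxon signed-rank or one-sample t
test.  Hypotheses are arranged in a tree; children are tested only when
the parent is significant, which bounds the family-wise error the way
an omnibus test followed by post hocs does.

Trait prediction is strictly split-sample: models (Normal(0,1)-prior
MAP regressions) are trained on one sample, frozen (including the
z-scoring constants), and scored on the other via Pearson r / percent
correct and out-of-sample R^2 (1 - MSE_m/MSE_null for continuous
targets, 1 - LL_m/LL_null for binary).  Significance comes from
one-tailed permutation tests of the score (label shuffling, smoothed
p = (1 + #{perm >= obs}) / (n_perm + 1)).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .glm import fit_glm

__all__ = [
    "wilcoxon_one_tailed",
    "HypothesisNode",
    "compound_group_test",
    "max_p_pair",
    "run_gated_tree",
    "TraitModel",
    "PredictionScore",
    "train_trait_model",
    "score_prediction",
    "permutation_test",
    "bayes_factor",
    "fit_horseshoe",
    "select_measures_by_bf",
    "RecoveryReport",
    "run_parameter_recovery",
]


# ---------------------------------------------------------------------------
# group tests


def wilcoxon_one_tailed(x, alternative: str = "greater"):
    """One-tailed Wilcoxon signed-rank test of median(x) vs 0.

    Zeros are dropped, ties get midranks.  For n <= 12 the p value is
    computed by exact enumeration of all 2^n sign patterns; otherwise by
    the tie-corrected normal approximation.  Returns
    (W_plus, p, z, effect_r) with effect_r = |z| / sqrt(n).
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if alternative == "less":
        x = -x
    x = x[x != 0]
    n = len(x)
    if n == 0:
        return 0.0, 1.0, 0.0, 0.0
    ranks = stats.rankdata(np.abs(x))
    w_plus = float(ranks[x > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    z = (w_plus - mu) / math.sqrt(var) if var > 0 else 0.0
    if n <= 12:
        ge = 0
        for signs in itertools.product((0.0, 1.0), repeat=n):
            if float(np.dot(signs, ranks)) >= w_plus - 1e-12:
                ge += 1
        p = ge / 2.0**n
    else:
        p = float(stats.norm.sf(z))
    return w_plus, float(p), float(z), float(abs(z) / math.sqrt(n))


def _t_one_tailed(x, alternative="greater"):
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    t, p = stats.ttest_1samp(x, 0.0, alternative=alternative)
    d = float(np.mean(x) / np.std(x, ddof=1)) if np.std(x, ddof=1) > 0 else 0.0
    return float(t), float(p), float(t), d


@dataclass
class HypothesisNode:
    id: str
    test: str = "wilcoxon_1t"  # wilcoxon_1t | ttest_1t | max_p_pair
    components: tuple = ()  # (model, outcome, regressor, sign[, group])
    children: tuple = ()

    def __post_init__(self):
        for comp in self.components:
            if comp[3] not in (1, -1):
                raise ValueError("component signs must be +1 or -1")


def _component_matrix(weight_table: pd.DataFrame, components):
    """participants x components matrix of sign-aligned weights."""
    wide = weight_table.pivot_table(
        index="participant",
        columns=["model", "outcome", "regressor"],
        values="estimate",
        aggfunc="first",
    )
    cols = []
    for comp in components:
        model, outcome, regressor, sign = comp[:4]
        key = (model, outcome, regressor)
        if key not in wide.columns:
            raise KeyError(f"component {key} not in weight table")
        cols.append(sign * wide[key])
    return pd.concat(cols, axis=1)


def compound_group_test(weight_table: pd.DataFrame, node: HypothesisNode):
    """Sign-aligned compound test for one hypothesis node.

    Returns a dict with statistic, one-tailed p, effect size and n.
    """
    if node.test == "max_p_pair":
        groups = sorted({(c[4] if len(c) > 4 else 0) for c in node.components})
        ps, stats_, ns, effs = [], [], [], []
        for g in groups:
            comps = [c for c in node.components if (c[4] if len(c) > 4 else 0) == g]
            mat = _component_matrix(weight_table, comps).dropna()
            sums = mat.sum(axis=1).to_numpy()
            w, p, z, r = wilcoxon_one_tailed(sums)
            ps.append(p)
            stats_.append(w)
            ns.append(len(sums))
            effs.append(r)
        p = max_p_pair(*ps) if len(ps) == 2 else max(ps)
        return {
            "statistic": float("nan"),
            "p": p,
            "effect_size": min(effs),
            "n": min(ns),
            "test": node.test,
        }
    mat = _component_matrix(weight_table, node.components).dropna()
    if len(mat) < 2:
        return {"statistic": float("nan"), "p": 1.0, "effect_size": 0.0, "n": len(mat),
                "test": node.test, "warning": "fewer than 2 complete participants"}
    sums = mat.sum(axis=1).to_numpy()
    if np.all(sums == 0):
        return {"statistic": 0.0, "p": 1.0, "effect_size": 0.0, "n": len(sums),
                "test": node.test, "warning": "all-zero compound sums"}
    fn = wilcoxon_one_tailed if node.test == "wilcoxon_1t" else _t_one_tailed
    statistic, p, z, eff = fn(sums)
    return {"statistic": statistic, "p": p, "effect_size": eff, "n": len(sums),
            "test": node.test}


def max_p_pair(p1: float, p2: float) -> float:
    """Compound rule for a two-part hypothesis: the least significant of
    the two component p values."""
    return max(p1, p2)


def run_gated_tree(root: HypothesisNode, weight_table: pd.DataFrame, alpha: float = 0.05):
    """Test a hypothesis tree depth-first, honoring significance gates."""
    results = {}
    _check_acyclic(root, set())

    def visit(node, gated):
        if gated:
            results[node.id] = {"status": "not tested (gated)"}
            for ch in node.children:
                visit(ch, True)
            return
        res = compound_group_test(weight_table, node)
        res["status"] = "tested"
        results[node.id] = res
        child_gated = res["p"] >= alpha
        for ch in node.children:
            visit(ch, child_gated)

    visit(root, False)
    return results


def _check_acyclic(node, seen):
    if id(node) in seen:
        raise ValueError("hypothesis tree contains a cycle")
    seen = seen | {id(node)}
    for ch in node.children:
        _check_acyclic(ch, seen)


def default_hypothesis_tree() -> HypothesisNode:
    """The stock mood-hypothesis registry: task -> mood effects with a
    valence-specific capture effect, and the stress-foraging homeostasis
    loop.  Component addresses refer to the weight tables produced by
    :func:`predforage.suite.fit_direction_suite`; edit or extend freely
    (the tree round-trips through YAML via :func:`tree_to_dict`)."""
    h1a = HypothesisNode(
        "H1A_environment_affects_excitement",
        components=(
            ("mood_task", "excitement", "reward_max", 1),
            ("mood_task", "excitement", "mo(speed)", 1),
            ("mood_task", "excitement", "mo(cones)", 1),
        ),
    )
    h1b = HypothesisNode(
        "H1B_environment_affects_stress",
        components=(
            ("mood_task", "stress", "reward_max", 1),
            ("mood_task", "stress", "mo(speed)", 1),
            ("mood_task", "stress", "mo(cones)", 1),
        ),
    )
    h1c = HypothesisNode(
        "H1C_caught_opposite_valence",
        test="max_p_pair",
        components=(
            ("mood_task", "stress", "caught", 1, 0),
            ("mood_task", "excitement", "caught", -1, 1),
        ),
    )
    h1 = HypothesisNode(
        "H1_environment_linked_with_mood",
        components=h1a.components + h1b.components,
        children=(h1a, h1b, h1c),
    )
    h2i = HypothesisNode(
        "H2Ai_stress_increases_foraging",
        components=(("mood_to_behavior", "forage_rate_pre", "preblock_stress", 1),),
    )
    h2ii = HypothesisNode(
        "H2Aii_foraging_reduces_stress",
        components=(("behavior_to_mood", "stress", "forage_rate", -1),),
    )
    h2 = HypothesisNode(
        "H2_stress_behavior_homeostasis",
        components=h2i.components + h2ii.components,
        children=(h2i, h2ii),
    )
    return HypothesisNode("root", components=h1.components + h2.components,
                          children=(h1, h2))


def tree_to_dict(node: HypothesisNode) -> dict:
    return {
        "id": node.id,
        "test": node.test,
        "components": [list(c) for c in node.components],
        "children": [tree_to_dict(c) for c in node.children],
    }


def tree_from_dict(d: dict) -> HypothesisNode:
    return HypothesisNode(
        id=d["id"],
        test=d.get("test", "wilcoxon_1t"),
        components=tuple(tuple(c) for c in d.get("components", ())),
        children=tuple(tree_from_dict(c) for c in d.get("children", ())),
    )


# ---------------------------------------------------------------------------
# split-sample trait prediction


@dataclass
class TraitModel:
    trait: str
    outcome_type: str  # continuous | binary
    measures: tuple
    coef: dict
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float  # null-model prediction (train mean / train log-odds)
    n_train: int


@dataclass
class PredictionScore:
    r: float
    accuracy: float
    r2_oos: float
    p_perm: float = float("nan")
    bf: float = float("nan")
    n: int = 0
    flag: str = ""


def _design(table, measures, x_mean=None, x_sd=None):
    X = table[list(measures)].to_numpy(dtype=float)
    if x_mean is None:
        x_mean = np.nanmean(X, axis=0)
        x_sd = np.nanstd(X, axis=0)
        x_sd[x_sd == 0] = 1.0
    # mean-impute missing cells with the *training* means
    idx = np.where(np.isnan(X))
    X[idx] = np.take(x_mean, idx[1])
    return (X - x_mean) / x_sd, x_mean, x_sd


def train_trait_model(train_table: pd.DataFrame, trait: str, measures) -> TraitModel:
    """Normal(0,1)-prior MAP regression of a trait on z-scored measures.

    Gender (binary) targets use a Bernoulli model on rows coded 1/2
    ("other" omitted); everything else is gaussian.  Scaling constants
    are frozen from the training sample.
    """
    measures = tuple(measures)
    binary = trait == "gender"
    tab = train_table
    if binary:
        tab = tab[tab[trait].isin([1.0, 2.0])]
        y = (tab[trait].to_numpy(dtype=float) == 2.0).astype(float)
    else:
        tab = tab[~tab[trait].isna()]
        y = tab[trait].to_numpy(dtype=float)
    X, x_mean, x_sd = _design(tab, measures)
    fam = "bernoulli" if binary else "gaussian"
    fit = fit_glm(X, y, fam, prior_sd=1.0, names=measures, compute_sd=False)
    if binary:
        p1 = float(np.mean(y))
        null = math.log(p1 / (1 - p1)) if 0 < p1 < 1 else 0.0
    else:
        null = float(np.mean(y))
    return TraitModel(
        trait=trait,
        outcome_type="binary" if binary else "continuous",
        measures=measures,
        coef=fit.coef,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=null,
        n_train=len(y),
    )


def predict(model: TraitModel, table: pd.DataFrame) -> np.ndarray:
    X, *_ = _design(table, model.measures, model.x_mean, model.x_sd)
    beta = np.array([model.coef[m] for m in model.measures])
    eta = model.coef["intercept"] + X @ beta
    return eta


def score_prediction(model: TraitModel, test_table: pd.DataFrame) -> PredictionScore:
    """Score frozen predictions on a held-out sample."""
    if model.outcome_type == "binary":
        tab = test_table[test_table[model.trait].isin([1.0, 2.0])]
        y = (tab[model.trait].to_numpy(dtype=float) == 2.0).astype(float)
    else:
        tab = test_table[~test_table[model.trait].isna()]
        y = tab[model.trait].to_numpy(dtype=float)
    eta = predict(model, tab)
    n = len(y)
    if model.outcome_type == "continuous":
        if np.std(eta) < 1e-14 or np.std(y) < 1e-14:
            r, flag = 0.0, "constant predictions"
        else:
            r, flag = float(np.corrcoef(eta, y)[0, 1]), ""
        mse_m = float(np.mean((y - eta) ** 2))
        mse_null = float(np.mean((y - model.y_mean) ** 2))
        return PredictionScore(r=r, accuracy=float("nan"),
                               r2_oos=1.0 - mse_m / mse_null, n=n, flag=flag)
    p_hat = 1.0 / (1.0 + np.exp(-eta))
    acc = 100.0 * float(np.mean((p_hat >= 0.5) == (y == 1)))
    eps = 1e-12
    ll_m = float(np.sum(y * np.log(p_hat + eps) + (1 - y) * np.log(1 - p_hat + eps)))
    p0 = 1.0 / (1.0 + math.exp(-model.y_mean))
    ll_null = float(np.sum(y * math.log(p0 + eps) + (1 - y) * math.log(1 - p0 + eps)))
    return PredictionScore(r=float("nan"), accuracy=acc,
                           r2_oos=1.0 - ll_m / ll_null, n=n)


def fisher_z_mean(rs) -> float:
    """Average correlations on the variance-stabilized arctanh scale."""
    rs = np.asarray(rs, dtype=float)
    return float(np.tanh(np.mean(np.arctanh(rs))))


def permutation_test(score_fn, labels, n_perm: int = 10000, rng=None) -> float:
    """One-tailed permutation p for any score of exchangeable labels.

    p = (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    observed = score_fn(labels)
    ge = 0
    for _ in range(n_perm):
        if score_fn(rng.permutation(labels)) >= observed - 1e-15:
            ge += 1
    return (1 + ge) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Bayes factors


def _corr_density(r, rho, n):
    # density of the sample correlation given rho (Fisher's exact form),
    # evaluated in log space to stay finite at large n
    log_d = (
        math.log(n - 2) - 0.5 * math.log(2 * math.pi)
        + math.lgamma(n - 1) - math.lgamma(n - 0.5)
        + (n - 1) / 2.0 * math.log1p(-rho**2)
        + (n - 4) / 2.0 * math.log1p(-r**2)
        + (3 - 2 * n) / 2.0 * math.log1p(-rho * r)
    )
    return math.exp(log_d) * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2.0)


def bayes_factor(kind: str, stats_: dict) -> float:
    """BF10 by numeric integration.

    ``correlation_1t``: one-tailed test of a positive correlation with a
    stretched-beta (rscale = 1, i.e. uniform) prior on rho in (0, 1);
    pass ``{"r": sample_r, "n": n}``.  ``proportion_1t``: one-tailed test
    of p > 0.5 with a uniform prior on (0.5, 1); pass ``{"k": successes,
    "n": trials}``.
    """
    if kind == "correlation_1t":
        r, n = float(stats_["r"]), int(stats_["n"])
        if n < 3:
            raise ValueError("correlation BF requires n >= 3")
        num, err = integrate.quad(lambda rho: _corr_density(r, rho, n), 0.0, 1.0)
        den = _corr_density(r, 0.0, n)
        if not np.isfinite(num) or den <= 0 or err > abs(num) * 1e-3 + 1e-12:
            raise RuntimeError(f"BF integration failed (num={num}, err={err})")
        return num / den
    if kind == "proportion_1t":
        k, n = int(stats_["k"]), int(stats_["n"])
        num, _ = integrate.quad(lambda p: stats.binom.pmf(k, n, p) * 2.0, 0.5, 1.0)
        den = stats.binom.pmf(k, n, 0.5)
        return float(num / den)
    raise ValueError(kind)


# ---------------------------------------------------------------------------
# regularized horseshoe


def fit_horseshoe(X, y, p0_ratio: float = 0.2, slab_scale: float = 2.0, n_iter: int = 60):
    """Sparse regression under the regularized-horseshoe prior.

    The global scale follows the expected-relevant-fraction convention:
    tau0 = p0/(D - p0) * sigma/sqrt(n) with p0 = p0_ratio * D.  Local
    scales are updated by alternating conditional maximization: given
    the local scales, beta is a weighted ridge solution; given beta,
    each local scale maximizes its half-Cauchy-conditioned posterior.
    Returns (beta, intercept, info).
    """
    if not 0 < p0_ratio < 1:
        raise ValueError("p0_ratio must lie in (0, 1)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    p0 = p0_ratio * d
    y_mean = float(np.mean(y))
    yc = y - y_mean
    sigma = float(np.std(yc)) or 1.0
    tau0 = p0 / (d - p0) * sigma / math.sqrt(n)
    lam2 = np.ones(d)
    beta = np.zeros(d)
    c2 = slab_scale**2
    XtX = X.T @ X
    Xty = X.T @ yc
    for _ in range(n_iter):
        # regularized-horseshoe effective variance per coefficient
        v = c2 * tau0**2 * lam2 / (c2 + tau0**2 * lam2)
        A = XtX / sigma**2 + np.diag(1.0 / np.maximum(v, 1e-12))
        beta_new = np.linalg.solve(A, Xty / sigma**2)
        resid = yc - X @ beta_new
        sigma = math.sqrt(max(float(resid @ resid) / n, 1e-12))
        # conditional update of local scales given beta (half-Cauchy prior):
        # maximize -b^2/(2 tau^2 l^2) - log(1 + l^2) - log l  => closed form
        b2 = (beta_new / tau0) ** 2
        lam2 = (b2 - 2.0 + np.sqrt((b2 - 2.0) ** 2 + 12.0 * b2)) / 6.0
        lam2 = np.maximum(lam2, 1e-10)
        if np.allclose(beta_new, beta, atol=1e-10):
            beta = beta_new
            break
        beta = beta_new
    info = {"sigma": sigma, "tau0": tau0, "lambda2": lam2}
    return beta, y_mean, info


# ---------------------------------------------------------------------------
# BF-based association listing


def select_measures_by_bf(measure_table: pd.DataFrame, traits, measures,
                          threshold: float = 3.0, controls: dict = None) -> pd.DataFrame:
    """Associations with at least moderate evidence (BF strictly > threshold).

    For each (trait, measure) pair, the BF for a positive/negative link is
    computed on the (partial) correlation, optionally controlling for the
    other clinical dimensions listed in ``controls[trait]``.
    """
    rows = []
    for trait in traits:
        ctrl = (controls or {}).get(trait, [])
        for m in measures:
            sub = measure_table[[trait, m] + list(ctrl)].dropna()
            if len(sub) < 10:
                continue
            x = sub[m].to_numpy(float)
            t = sub[trait].to_numpy(float)
            if ctrl:
                C = np.column_stack([np.ones(len(sub)), sub[list(ctrl)].to_numpy(float)])
                x = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
                t = t - C @ np.linalg.lstsq(C, t, rcond=None)[0]
            if np.std(x) < 1e-12 or np.std(t) < 1e-12:
                continue
            r = float(np.corrcoef(x, t)[0, 1])
            bf = bayes_factor("correlation_1t", {"r": abs(r), "n": len(sub)})
            if bf > threshold:
                rows.append({"trait": trait, "measure": m, "direction": np.sign(r),
                             "bf": bf, "controlled": bool(ctrl)})
    return pd.DataFrame(rows, columns=["trait", "measure", "direction", "bf", "controlled"])


# ---------------------------------------------------------------------------
# parameter recovery


@dataclass
class RecoveryReport:
    per_parameter: pd.DataFrame
    n_sets: int
    n_skipped: int = 0


def run_parameter_recovery(config=None, n_sets: int = 200, seed: int = 0,
                           pilot_n: int = 40) -> RecoveryReport:
    """Simulate-and-refit recovery of the single-choice policy weights.

    A pilot cohort supplies the fitted-parameter pool; ``n_sets``
    parameter sets are drawn marginally from the pool, each set plays a
    full session, and the session is refit with the same choice models.
    """
    from .agents import LogisticPolicyAgent, PolicyParams
    from .cohort import CohortSpec, sample_cohort, sample_recovery_params
    from .engine import run_session
    from .suite import fit_choice_models
    from .task import TaskConfig, generate_schedule

    config = config or TaskConfig()
    rng = np.random.default_rng(seed)
    spec = CohortSpec(n_participants=pilot_n, seed=seed, links={}, homeostasis=False,
                      config=config)
    pilot = sample_cohort(spec, config)
    pool_rows = []
    for p in pilot:
        row, _ = fit_choice_models(p.log, config)
        if row:
            pool_rows.append(row)
    pool = pd.DataFrame(pool_rows)
    sets = sample_recovery_params(n_sets, pool, rng)
    truths, fits = [], []
    n_skipped = 0
    sched = generate_schedule(config, seed + 1)
    for i, params in enumerate(sets):
        log = run_session(sched, LogisticPolicyAgent(params), int(rng.integers(2**31)), config)
        row, reasons = fit_choice_models(log, config)
        if not row or len(reasons) == 3:
            n_skipped += 1
            continue
        truths.append(dict(zip(PolicyParams.names(), params.as_vector())))
        fits.append(row)
    tru = pd.DataFrame(truths)
    est = pd.DataFrame(fits)
    rows = []
    for c in est.columns:
        if c not in tru.columns:
            continue
        ok = (~est[c].isna()) & (~tru[c].isna())
        if ok.sum() < 3 or tru.loc[ok, c].std() < 1e-12:
            continue
        r = float(np.corrcoef(tru.loc[ok, c], est.loc[ok, c])[0, 1])
        rows.append({"parameter": c, "r": r,
                     "bias": float((est.loc[ok, c] - tru.loc[ok, c]).mean()),
                     "n": int(ok.sum())})
    return RecoveryReport(per_parameter=pd.DataFrame(rows), n_sets=len(sets),
                          n_skipped=n_skipped)
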