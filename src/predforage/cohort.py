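"""Synthetic cohorts: traits, planted trait->behavior links, full sessions.

A cohort couples three layers, mimicking an online sample with a broad
spread of clinical scores:

1. latent trait factors (apathy behavioral/emotional, anhedonia, somatic
   and cognitive anxiety, compulsive checking, prospective and inhibitory
   intolerance of uncertainty) drawn from a correlated multivariate
   normal, observed through questionnaire items generated from a factor
   model (subscale scores are standardized item means);
2. agent parameters: each participant's policy weights, decision rates
   and mood parameters are population defaults plus planted standardized
   trait effects (``links``) plus independent noise;
3. behavior: every participant plays the task through the event-driven
   simulator, yielding an event log, block-wise mood ratings, a post-task
   debrief (0-6 scales) and repeated "consistency" questionnaire items.

The default link sizes are calibrated so the flagship planted effect
(behavioral apathy -> less checking / more foraging) shows up in the
measure table at roughly r = 0.3, the magnitude used throughout the
planted-effect recovery experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import LogisticPolicyAgent, MoodGenParams, PolicyParams
from .engine import run_session
from .task import TaskConfig, generate_schedule

__all__ = [
    "TRAITS",
    "TraitProfile",
    "CohortSpec",
    "SyntheticParticipant",
    "default_trait_cov",
    "simulate_items",
    "sample_cohort",
    "sample_recovery_params",
]

TRAITS = (
    "ami_behavioral",
    "ami_emotional",
    "shaps",
    "sticsa_somatic",
    "sticsa_cognitive",
    "oci_rc",
    "ius_prospective",
    "ius_inhibitory",
)

N_DEBRIEF = 29


@dataclass
class TraitProfile:
    scores: dict  # subscale -> standardized score
    gender: float  # 1 = male, 2 = female, 1.5 = other
    age: float
    education: int
    items: np.ndarray = None

    def __post_init__(self):
        if self.gender not in (1.0, 2.0, 1.5):
            raise ValueError("gender must be coded 1, 2 or 1.5")


def default_trait_cov() -> np.ndarray:
    """Correlated trait structure: generally positive, anxiety subscales
    tightly coupled, emotional apathy nearly independent."""
    k = len(TRAITS)
    C = np.full((k, k), 0.30)
    np.fill_diagonal(C, 1.0)
    idx = {t: i for i, t in enumerate(TRAITS)}

    def set_(a, b, v):
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = v

    set_("sticsa_somatic", "sticsa_cognitive", 0.72)
    set_("ius_prospective", "ius_inhibitory", 0.60)
    set_("ami_behavioral", "shaps", 0.45)
    for t in TRAITS:
        if t != "ami_emotional":
            set_("ami_emotional", t, 0.05)
    # ensure positive definiteness
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 1e-6, None)
    C = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


#: planted standardized effects: (trait, parameter path) -> coefficient.
#: Paths address PolicyParams weights (model_regressor), log-rates, and
#: mood parameters.  The ami_behavioral -> pre_intercept size is the
#: calibrated flagship link (target r ~ 0.3 on checking/foraging
#: measures).
DEFAULT_LINKS = {
    ("ami_behavioral", "pre_intercept"): -0.55,
    ("ami_behavioral", "hide_intercept"): -0.25,
    ("ami_behavioral", "log_inactive_rate"): 0.20,
    ("oci_rc", "pre_intercept"): 0.35,
    ("oci_rc", "hide_intercept"): 0.30,
    ("sticsa_somatic", "pre_intercept"): -0.20,
    ("sticsa_somatic", "stress_base"): 4.0,
    ("shaps", "fc_reward"): 0.20,
    ("shaps", "excite_base"): -5.0,
    ("ius_prospective", "stress_base"): 3.0,
    ("gender_female", "pre_intercept"): 0.40,
    ("gender_female", "log_inactive_rate"): -0.30,
    ("gender_female", "stress_base"): 3.0,
}

#: independent between-participant noise on agent parameters
DEFAULT_PARAM_NOISE = {
    "pre_intercept": 0.45,
    "pre_weights": 0.35,
    "hide_intercept": 0.40,
    "hide_weights": 0.35,
    "fc_intercept": 0.35,
    "fc_weights": 0.30,
    "log_decision_rate": 0.25,
    "log_inactive_rate": 0.40,
    "stress_base": 9.0,
    "excite_base": 9.0,
}

#: debrief items with planted trait loadings (item index -> trait -> w);
#: remaining items are pure noise around the scale midpoint.
DEBRIEF_LINKS = {
    2: {"shaps": -0.8},  # "I tried to gather as much food as possible"
    5: {"shaps": -0.7, "ami_emotional": -0.3},  # felt excitement
    8: {"oci_rc": 0.9},  # checked again although just checked
    11: {"oci_rc": 0.6, "sticsa_somatic": 0.7},  # avoided checking (decision)
    14: {"sticsa_somatic": 0.8},  # more nervous after seeing predator
    17: {"ami_behavioral": 0.7},  # kept diving for food instead of checking
    20: {"ius_prospective": 0.8},  # tried to find predator asap
    23: {"oci_rc": 0.5},  # hid longer than necessary
}


@dataclass
class CohortSpec:
    n_participants: int = 100
    seed: int = 0
    trait_cov: np.ndarray = None
    links: dict = None
    param_noise: dict = None
    debrief_noise_sd: float = 1.0
    items_per_scale: int = 5
    item_loading: float = 0.65
    share_schedule: bool = True
    homeostasis: bool = True
    config: TaskConfig = None

    def __post_init__(self):
        self.trait_cov = (
            default_trait_cov() if self.trait_cov is None else np.asarray(self.trait_cov)
        )
        w = np.linalg.eigvalsh(self.trait_cov)
        if w.min() < -1e-8:
            raise ValueError("trait covariance must be positive semi-definite")
        self.links = dict(DEFAULT_LINKS) if self.links is None else dict(self.links)
        self.param_noise = (
            dict(DEFAULT_PARAM_NOISE) if self.param_noise is None else dict(self.param_noise)
        )
        self.config = self.config or TaskConfig()


@dataclass
class SyntheticParticipant:
    participant_id: str
    traits: TraitProfile
    factor_scores: dict
    policy: PolicyParams
    mood: MoodGenParams
    log: object
    debrief: np.ndarray
    repeat_diffs: np.ndarray


def simulate_items(n: int, loadings, phi, rng, return_factors: bool = False):
    """Items from a factor model: X = F L' + E with F ~ N(0, phi)."""
    loadings = np.asarray(loadings, dtype=float)
    if np.any(np.abs(loadings) > 1):
        raise ValueError("loadings must lie in [-1, 1]")
    k = loadings.shape[1]
    F = rng.multivariate_normal(np.zeros(k), phi, size=n, method="cholesky")
    uniq = np.sqrt(np.clip(1.0 - np.sum(loadings**2, axis=1), 0.05, 1.0))
    E = rng.standard_normal((n, loadings.shape[0])) * uniq
    X = F @ loadings.T + E
    return (X, F) if return_factors else X


def _policy_vector_default():
    d = PolicyParams.default()
    return d


def _apply_links(spec, F_row, gender, rng):
    """Population defaults + planted trait effects + noise -> one agent."""
    d = _policy_vector_default()
    pre = d.pre.copy()
    hide = d.post_hide.copy()
    fc = d.post_fc.copy()
    noise = spec.param_noise
    pre[0] += rng.normal(0, noise["pre_intercept"])
    pre[1:] += rng.normal(0, noise["pre_weights"], 7)
    hide[0] += rng.normal(0, noise["hide_intercept"])
    hide[1:] += rng.normal(0, noise["hide_weights"], 7)
    fc[0] += rng.normal(0, noise["fc_intercept"])
    fc[1:] += rng.normal(0, noise["fc_weights"], 7)
    log_dr = np.log(d.decision_rate) + rng.normal(0, noise["log_decision_rate"])
    log_ir = np.log(d.inactive_press_rate) + rng.normal(0, noise["log_inactive_rate"])
    mood = MoodGenParams()
    if spec.homeostasis:
        mood.gain_stress_to_forage = 0.6
        mood.gain_stress_to_hide = 0.3
        mood.gain_forage_to_stress = -4.0
    mood.stress_base += rng.normal(0, noise["stress_base"])
    mood.excite_base += rng.normal(0, noise["excite_base"])

    idx = {t: i for i, t in enumerate(TRAITS)}
    targets = {
        "pre_intercept": (pre, 0),
        "pre_reward": (pre, 1),
        "pre_time_pressure": (pre, 2),
        "hide_intercept": (hide, 0),
        "hide_reward": (hide, 1),
        "fc_intercept": (fc, 0),
        "fc_reward": (fc, 1),
    }
    for (trait, path), w in spec.links.items():
        x = (gender - 1.5) * 2.0 if trait == "gender_female" else F_row[idx[trait]]
        if path in targets:
            vec, j = targets[path]
            vec[j] += w * x
        elif path == "log_decision_rate":
            log_dr += w * x
        elif path == "log_inactive_rate":
            log_ir += w * x
        elif path == "stress_base":
            mood.stress_base += w * x
        elif path == "excite_base":
            mood.excite_base += w * x
        else:
            raise KeyError(f"unknown link target {path!r}")
    policy = PolicyParams(
        pre=pre,
        post_hide=hide,
        post_fc=fc,
        decision_rate=float(np.exp(log_dr)),
        inactive_press_rate=float(np.exp(log_ir)),
    )
    return policy, mood


def sample_cohort(spec: CohortSpec, config: TaskConfig = None) -> list:
    """Sample a full synthetic cohort, deterministic per ``spec.seed``."""
    config = config or spec.config
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    k = len(TRAITS)

    # questionnaire items from the trait factor model
    lam = np.zeros((k * spec.items_per_scale, k))
    for j in range(k):
        lam[j * spec.items_per_scale : (j + 1) * spec.items_per_scale, j] = spec.item_loading
    items, F = simulate_items(n, lam, spec.trait_cov, rng, return_factors=True)
    # subscale scores: standardized mean of each scale's items
    scores = np.stack(
        [
            items[:, j * spec.items_per_scale : (j + 1) * spec.items_per_scale].mean(axis=1)
            for j in range(k)
        ],
        axis=1,
    )
    scores = (scores - scores.mean(0)) / scores.std(0)

    genders = rng.choice([1.0, 2.0, 1.5], size=n, p=[0.49, 0.49, 0.02])
    ages = np.clip(rng.normal(35.0, 11.0, size=n), 18, 75)
    education = rng.integers(1, 6, size=n)

    shared = generate_schedule(config, spec.seed) if spec.share_schedule else None
    seeds = rng.integers(0, 2**31 - 1, size=2 * n)

    out = []
    for i in range(n):
        policy, mood = _apply_links(spec, F[i], genders[i], rng)
        schedule = shared or generate_schedule(config, int(seeds[2 * i]))
        agent = LogisticPolicyAgent(policy, mood)
        log = run_session(schedule, agent, int(seeds[2 * i + 1]), config, f"p{i:04d}")
        debrief = _debrief(F[i], spec, rng)
        repeat_diffs = np.abs(np.round(rng.normal(0.0, 0.55, size=3)))
        out.append(
            SyntheticParticipant(
                participant_id=f"p{i:04d}",
                traits=TraitProfile(
                    scores=dict(zip(TRAITS, scores[i])),
                    gender=float(genders[i]),
                    age=float(ages[i]),
                    education=int(education[i]),
                    items=items[i],
                ),
                factor_scores=dict(zip(TRAITS, F[i])),
                policy=policy,
                mood=mood,
                log=log,
                debrief=debrief,
                repeat_diffs=repeat_diffs,
            )
        )
    return out


def _debrief(F_row, spec, rng):
    idx = {t: i for i, t in enumerate(TRAITS)}
    vals = np.full(N_DEBRIEF, 3.0)
    for item, ws in DEBRIEF_LINKS.items():
        for trait, w in ws.items():
            vals[item] += w * F_row[idx[trait]]
    vals += rng.normal(0, spec.debrief_noise_sd, size=N_DEBRIEF)
    return np.clip(np.round(vals), 0, 6).astype(int)


def sample_recovery_params(n_sets: int, fitted_pool: pd.DataFrame, rng) -> list:
    """Parameter sets for the recovery experiment: each scalar parameter is
    drawn independently from its marginal pool of fitted values (ignoring
    between-parameter correlations)."""
    if len(fitted_pool) == 0:
        raise ValueError("empty fitted parameter pool")
    cols = {c: fitted_pool[c].dropna().to_numpy() for c in fitted_pool.columns}
    names = PolicyParams.names()
    d = PolicyParams.default()
    out = []
    for _ in range(n_sets):
        draw = {}
        for c, pool in cols.items():
            draw[c] = float(pool[rng.integers(len(pool))]) if len(pool) else np.nan
        pre = [draw.get(n_, 0.0) for n_ in names[0:8]]
        hide = [draw.get(n_, 0.0) for n_ in names[8:16]]
        fc = [draw.get(n_, 0.0) for n_ in names[16:24]]
        out.append(
            PolicyParams(
                pre=pre,
                post_hide=hide,
                post_fc=fc,
                decision_rate=draw.get("decision_rate", d.decision_rate),
                inactive_press_rate=draw.get("inactive_press_rate", d.inactive_press_rate),
            )
        )
    return out
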