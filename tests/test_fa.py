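"""Factor analysis: parallel analysis, rotation, pruning, Bartlett scores."""

import numpy as np
import pandas as pd
import pytest

from predforage import bartlett_scores, fit_fa, parallel_analysis, prune_and_refit, simulate_items
from predforage.fa import align_loadings, oblimin_rotate, tucker_congruence


def _planted(n=700, loading=0.6, per=10, k=3, phi_off=0.4, seed=0):
    lam = np.zeros((per * k, k))
    for j in range(k):
        lam[j * per : (j + 1) * per, j] = loading
    phi = np.full((k, k), phi_off)
    np.fill_diagonal(phi, 1.0)
    X = simulate_items(n, lam, phi, np.random.default_rng(seed))
    return X, lam, phi


def test_parallel_analysis_rejects_pure_noise(rng):
    X = rng.standard_normal((700, 40))
    pa = parallel_analysis(X, n_iter=500, rng=1)
    assert pa.n_factors == 0
    assert np.all(np.diff(pa.thresholds) <= 1e-9)


def test_parallel_analysis_finds_planted_factors():
    X, _, _ = _planted()
    pa = parallel_analysis(X, n_iter=500, rng=2)
    assert pa.n_factors == 3


def test_parallel_analysis_deterministic_per_seed():
    X, _, _ = _planted(n=300)
    a = parallel_analysis(X, n_iter=200, rng=7)
    b = parallel_analysis(X, n_iter=200, rng=7)
    assert np.allclose(a.thresholds, b.thresholds)
    with pytest.raises(TypeError):
        parallel_analysis(pd.DataFrame({"a": ["x", "y"]}))


def test_fit_fa_recovers_planted_structure():
    X, lam, phi = _planted()
    fa = fit_fa(X, 3)
    aligned, congs = align_loadings(fa.loadings.to_numpy(), lam)
    assert congs.min() > 0.95
    off = fa.phi[~np.eye(3, dtype=bool)]
    assert off == pytest.approx(0.4, abs=0.1)


def test_reconstruction_rmsr_small_on_well_specified_model():
    X, _, _ = _planted()
    fa = fit_fa(X, 3)
    L = fa.loadings.to_numpy()
    R_hat = L @ fa.phi @ L.T + np.diag(fa.uniquenesses)
    Xz = (X - X.mean(0)) / X.std(0)
    R = np.corrcoef(Xz, rowvar=False)
    off = ~np.eye(R.shape[0], dtype=bool)
    assert np.sqrt(np.mean((R_hat - R)[off] ** 2)) < 0.05


def test_single_factor_rotation_is_identity_up_to_sign():
    X, _, _ = _planted(k=1, per=12, phi_off=0.0)
    fa = fit_fa(X, 1)
    A, phi = oblimin_rotate(fa.loadings.to_numpy())
    assert phi == pytest.approx(np.ones((1, 1)))
    assert abs(tucker_congruence(A[:, 0], fa.loadings.to_numpy()[:, 0])) > 0.9999


def test_orthogonal_planted_factors_yield_small_factor_correlations():
    X, _, _ = _planted(phi_off=0.0, loading=0.7)
    fa = fit_fa(X, 3)
    off = fa.phi[~np.eye(3, dtype=bool)]
    assert np.abs(off).max() < 0.12


@pytest.mark.parametrize(
    "loads,kept",
    [((0.6, 0.45), False), ((0.6, 0.1), True), ((0.35, 0.2), False)],
)
def test_pruning_rule_on_crafted_items(loads, kept, rng):
    """An item survives only with one clear loading (> 0.4) and no
    cross-loading above 0.4."""
    n = 800
    lam = np.zeros((21, 2))
    lam[:10, 0] = 0.75
    lam[10:20, 1] = 0.75
    lam[20, :] = loads
    phi = np.eye(2)
    X = simulate_items(n, lam, phi, np.random.default_rng(5))
    fa = prune_and_refit(X, n_iter_pa=200, rng=6)
    assert (20 in fa.retained_items) == kept


def test_pruning_terminates_and_shrinks():
    X, _, _ = _planted()
    fa = prune_and_refit(X, n_iter_pa=200, rng=8)
    sizes = [h["n_items"] for h in fa.pruning_history]
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))
    with pytest.raises(ValueError):
        prune_and_refit(np.random.default_rng(0).standard_normal((300, 1)))


def test_bartlett_scores_preserve_factor_correlation():
    # strong loadings keep score noise small, so the score correlation
    # approaches the planted factor correlation
    X, lam, phi = _planted(loading=0.85, phi_off=0.4)
    fa = fit_fa(X, 3)
    sc = bartlett_scores(X, fa)
    c = np.corrcoef(sc.to_numpy().T)
    off = c[~np.eye(3, dtype=bool)]
    assert off == pytest.approx(0.4, abs=0.07)


def test_bartlett_scores_flip_with_loading_signs():
    X, _, _ = _planted(k=2, per=8, phi_off=0.0)
    fa = fit_fa(X, 2)
    sc = bartlett_scores(X, fa)
    fa.loadings.iloc[:, 0] *= -1.0
    sc_flipped = bartlett_scores(X, fa)
    assert np.allclose(sc_flipped.iloc[:, 0], -sc.iloc[:, 0], atol=1e-8)


def test_bartlett_scores_identity_loadings_zero_uniqueness_limit():
    """With identity loadings and vanishing uniqueness the WLS scores are
    exactly the standardized data."""
    from predforage.fa import FAResult

    rng = np.random.default_rng(3)
    X = rng.standard_normal((200, 2))
    fa = FAResult(
        loadings=pd.DataFrame(np.eye(2), index=[0, 1], columns=["F1", "F2"]),
        phi=np.eye(2),
        uniquenesses=pd.Series([1e-6, 1e-6], index=[0, 1]),
        n_factors=2,
        retained_items=[0, 1],
    )
    sc = bartlett_scores(pd.DataFrame(X), fa)
    Z = (X - X.mean(0)) / X.std(0)
    assert np.allclose(sc.to_numpy(), Z, atol=1e-8)
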