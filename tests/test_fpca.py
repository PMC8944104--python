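"""Fourier basis, curve fitting and functional PCA correctness."""

import numpy as np
import pandas as pd
import pytest

from actirhythm import FourierBasis, FunctionalPCA, fit_curve, fit_curves
from actirhythm.errors import ConfigurationError
from actirhythm.fpca import N_EPOCHS, epoch_midpoints


GRID = epoch_midpoints()


def dense_grid_pca_scores(profiles: np.ndarray, n_components: int) -> np.ndarray:
    """Independent oracle: plain PCA on the raw 288-point grid, scores scaled
    by sqrt(dt) so they carry the same L2 normalization as functional scores."""
    dt = 24.0 / N_EPOCHS
    centered = profiles - profiles.mean(axis=0)
    cov = centered.T @ centered / (profiles.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    scores = centered @ evecs[:, order] * np.sqrt(dt)
    return scores


def test_basis_gram_is_identity():
    basis = FourierBasis(n_harmonics=9)
    gram = basis.gram()
    assert np.abs(gram - np.eye(basis.n_basis)).max() < 1e-8


@pytest.mark.parametrize(
    "profile, expected",
    [
        # constant 7 projects onto the constant basis function only: c0 = 7*sqrt(24)
        (np.full(N_EPOCHS, 7.0), {0: 7.0 * np.sqrt(24.0)}),
        # 5 + 3 sin(2 pi t / 24): c0 = 5 sqrt(24), c1 = 3 sqrt(12)
        (
            5.0 + 3.0 * np.sin(2 * np.pi * GRID / 24.0),
            {0: 5.0 * np.sqrt(24.0), 1: 3.0 * np.sqrt(12.0)},
        ),
    ],
)
def test_curve_fit_matches_closed_form_projection(profile, expected):
    fit = fit_curve(profile, FourierBasis())
    for k, value in expected.items():
        assert fit.coefficients[k] == pytest.approx(value, abs=1e-9)
    others = np.delete(fit.coefficients, list(expected))
    assert np.abs(others).max() < 1e-9
    assert fit.fit_rmse < 1e-9


def test_basis_function_self_projects_to_unit_vector():
    basis = FourierBasis()
    y = basis.design(GRID)[:, 4]
    fit = fit_curve(y, basis)
    expected = np.zeros(basis.n_basis)
    expected[4] = 1.0
    assert np.abs(fit.coefficients - expected).max() < 1e-9


def test_fit_curve_rejects_missing_epochs_and_oversized_basis():
    y = np.full(N_EPOCHS, 1.0)
    y[10] = np.nan
    with pytest.raises(ValueError, match="missing epochs"):
        fit_curve(y, FourierBasis())
    with pytest.raises(ConfigurationError):
        fit_curve(np.ones(N_EPOCHS), FourierBasis(n_harmonics=150))


def test_two_point_pca_matches_hand_computation():
    """Two curves at mu +/- delta: one component, lambda1 = n/(n-1) |delta|^2."""
    basis = FourierBasis(n_harmonics=2)
    mu = np.array([3.0, 1.0, 0.0, -1.0, 0.5])
    delta = np.array([0.5, -0.25, 1.0, 0.0, 0.0])
    coef = np.vstack([mu + delta, mu - delta])
    res = FunctionalPCA(coef, basis).fit(n_components=1)
    assert res.eigenvalues[0] == pytest.approx(2 * delta @ delta, rel=1e-12)
    assert np.abs(res.eigenvalues[1:]).max() < 1e-12
    cos = np.abs(res.eigenvectors[:, 0] @ delta) / np.linalg.norm(delta)
    assert cos == pytest.approx(1.0, abs=1e-12)


def test_scores_of_mean_and_shifted_curves(rng):
    basis = FourierBasis(n_harmonics=3)
    coef = rng.normal(size=(40, basis.n_basis))
    res = FunctionalPCA(coef, basis).fit(n_components=3)
    mu = res.mean_coefficients
    b1 = res.eigen_coefficients[:, 0]
    probes = np.vstack([mu, mu + 2 * b1])
    s = res.scores(probes).to_numpy()
    assert np.abs(s[0, :3]).max() < 1e-10          # curve at the mean: all zero
    assert s[1, 0] == pytest.approx(2.0, abs=1e-10)
    assert np.abs(s[1, 1:3]).max() < 1e-10


def test_score_columns_have_zero_mean_and_variance_lambda(rng):
    coef = rng.normal(size=(60, 19)) * np.linspace(3, 0.1, 19)
    res = FunctionalPCA(coef, FourierBasis()).fit(n_components=5)
    s = res.scores()
    raw = s[[f"score_{m}" for m in range(1, 6)]].to_numpy()
    assert np.abs(raw.mean(axis=0)).max() < 1e-8
    assert np.abs(raw.var(axis=0, ddof=1) - res.component_variances).max() < 1e-8
    std = s[[f"std_score_{m}" for m in range(1, 6)]].to_numpy()
    assert np.abs(std.var(axis=0, ddof=1) - 1.0).max() < 1e-8


def test_fpca_scores_match_dense_grid_pca_oracle(rng):
    """In-span profiles: functional scores equal sqrt(dt)-scaled grid PCA."""
    basis = FourierBasis(n_harmonics=9)
    phi = basis.design(GRID)
    coef = rng.normal(size=(200, basis.n_basis)) * np.linspace(2.0, 0.05, basis.n_basis)
    profiles = coef @ phi.T
    fits = fit_curves(
        pd.DataFrame(profiles, index=pd.RangeIndex(200, name="participant_id")), basis
    )
    res = FunctionalPCA(fits, basis).fit(n_components=4)
    ours = res.scores()[[f"score_{m}" for m in range(1, 5)]].to_numpy()
    oracle = dense_grid_pca_scores(profiles, 4)
    for m in range(4):  # align the oracle's arbitrary eigenvector signs
        if np.dot(ours[:, m], oracle[:, m]) < 0:
            oracle[:, m] = -oracle[:, m]
    assert np.abs(ours - oracle).max() < 1e-6


def test_variance_explained_uses_all_eigenvalues(rng):
    coef = rng.normal(size=(50, 7)) * np.array([3.0, 2.0, 1.0, 0.5, 0.3, 0.2, 0.1])
    res = FunctionalPCA(coef, FourierBasis(n_harmonics=3)).fit(n_components=2)
    ve = res.variance_explained()
    expected = 100 * res.eigenvalues[:2] / res.eigenvalues.sum()
    assert np.allclose(ve["pct_variance"], expected)
    assert ve["cum_pct_variance"].iloc[-1] < 100.0


def test_single_direction_variation_explains_everything():
    basis = FourierBasis(n_harmonics=2)
    direction = np.array([1.0, 2.0, 0.0, -1.0, 0.5])
    coef = np.outer(np.linspace(-2, 2, 9), direction)
    res = FunctionalPCA(coef, basis).fit(n_components=1)
    assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)


def test_scree_elbow_suggestion():
    """A (10, 1, 0.9, ...) spectrum has its dominant ratio drop after 1."""
    basis = FourierBasis(n_harmonics=3)
    coef = np.random.default_rng(0).normal(size=(300, 7))
    coef *= np.sqrt(np.array([10.0, 1.0, 0.9, 0.8, 0.7, 0.6, 0.5]))
    fitted = FunctionalPCA(coef, basis).fit(n_components=2)
    lam, suggested = fitted.scree()
    assert suggested == 1
    assert lam.shape == (7,)
    assert np.all(np.diff(lam) <= 1e-12)


def test_sign_convention_flip_invariance(rng):
    """Negating all curves flips scores but leaves variances unchanged."""
    basis = FourierBasis(n_harmonics=4)
    coef = rng.normal(size=(80, basis.n_basis))
    res_pos = FunctionalPCA(coef, basis).fit(n_components=3)
    res_neg = FunctionalPCA(-coef, basis).fit(n_components=3)
    assert np.allclose(res_pos.eigenvalues, res_neg.eigenvalues)
    s_pos = res_pos.scores().to_numpy()[:, :3]
    s_neg = res_neg.scores().to_numpy()[:, :3]
    # the deterministic sign convention keeps eigenvectors fixed, so the
    # negated data's scores are the negated scores
    assert np.allclose(res_pos.eigenvectors, res_neg.eigenvectors)
    assert np.allclose(s_pos, -s_neg, atol=1e-10)


def test_weighted_fpca_with_equal_weights_is_unweighted(rng):
    coef = rng.normal(size=(50, 19))
    res_u = FunctionalPCA(coef, FourierBasis()).fit(4)
    res_w = FunctionalPCA(coef, FourierBasis(), weights=np.full(50, 3.7)).fit(4)
    assert np.allclose(res_u.eigenvalues, res_w.eigenvalues)
    assert np.allclose(res_u.mean_coefficients, res_w.mean_coefficients)
    assert np.allclose(res_u.eigenvectors, res_w.eigenvectors)


def test_reconstruction_residual_equals_unexplained_variance(rng):
    coef = rng.normal(size=(100, 19)) * np.linspace(2, 0.1, 19)
    res = FunctionalPCA(coef, FourierBasis()).fit(n_components=4)
    centered = coef - res.mean_coefficients
    recon = res.scores().to_numpy()[:, :4] @ res.eigen_coefficients.T
    residual_var = ((centered - recon) ** 2).sum() / (coef.shape[0] - 1)
    expected = (1 - res.variance_fractions.sum()) * res.total_variance
    assert residual_var == pytest.approx(expected, rel=1e-8)


def test_group_mean_curves_split_at_median(rng):
    basis = FourierBasis(n_harmonics=2)
    coef = rng.normal(size=(30, 5))
    res = FunctionalPCA(coef, basis).fit(n_components=2)
    hi, lo = res.group_mean_curves(1)
    assert hi.shape == lo.shape == (N_EPOCHS,)
    # the high and low halves bracket the overall mean curve along component 1
    s = res.scores()["score_1"]
    assert s[s > np.median(s)].mean() > s[s <= np.median(s)].mean()
    # all-equal scores (probe curves identical): both halves collapse onto
    # the common curve
    same = np.tile(coef[0], (6, 1))
    hi2, lo2 = res.group_mean_curves(1, coefficients=same)
    assert np.allclose(hi2, lo2)
    assert np.allclose(hi2, basis.design(GRID) @ coef[0])
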