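"""Whitening CCA: shrinkage, oracle equivalence, invariances, loadings."""

import numpy as np
import pandas as pd
import pytest

from eegmediation import (COG_SCORES, DEFAULT_SEED, TruthParams,
                          generate_cohort)
from eegmediation.cca import (DataBlockPair, WhiteningModel,
                              fit_cca_whitening, loading_summaries,
                              shrinkage_covariance, shrinkage_intensity,
                              transform)


def _shared_latent_blocks(rng, n=200, p=3, q=2, noise=0.4):
    z = rng.normal(size=n)
    X = np.outer(z, rng.uniform(0.5, 1.5, p)) + noise * rng.normal(size=(n, p))
    Y = np.outer(z, rng.uniform(0.5, 1.5, q)) + noise * rng.normal(size=(n, q))
    return X, Y


def _classical_cca(X, Y):
    """Independent oracle: SVD of Sx^-1/2 Sxy Sy^-1/2 on standardized data."""
    from scipy.linalg import fractional_matrix_power
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    n = len(Xs)
    Sx = Xs.T @ Xs / (n - 1)
    Sy = Ys.T @ Ys / (n - 1)
    Sxy = Xs.T @ Ys / (n - 1)
    K = (fractional_matrix_power(Sx, -0.5) @ Sxy
         @ fractional_matrix_power(Sy, -0.5))
    return np.linalg.svd(K, compute_uv=False).real


# ---------------------------------------------------------------------------
# shrinkage covariance
# ---------------------------------------------------------------------------

def test_shrinkage_vanishes_at_large_n_with_real_correlation(rng):
    """With a nonzero true correlation the estimated intensity goes to 0
    as n grows (the sampling variance of r vanishes while r^2 does not),
    and the shrunken matrix approaches the true correlation matrix."""
    z = rng.normal(size=1000)
    M = np.column_stack([z + 0.5 * rng.normal(size=1000),
                         z + 0.5 * rng.normal(size=1000)])
    cov, lam = shrinkage_covariance(M)
    assert lam < 0.05
    assert cov[0, 1] == pytest.approx(0.8, abs=0.05)


def test_shrinkage_full_for_independent_columns(rng):
    """For truly independent columns the identity target is correct and
    the analytic intensity is large; the output stays near identity."""
    cov, lam = shrinkage_covariance(rng.normal(size=(1000, 2)))
    assert lam > 0.3
    np.testing.assert_allclose(cov, np.eye(2), atol=0.05)


def test_shrinkage_keeps_fat_matrix_positive_definite(rng):
    M = rng.normal(size=(10, 50))
    cov, lam = shrinkage_covariance(M)
    assert lam > 0
    assert np.linalg.eigvalsh(cov).min() > 0


def test_forced_full_shrinkage_returns_target(rng):
    cov, lam = shrinkage_covariance(rng.normal(size=(20, 4)), lambda_override=1.0)
    np.testing.assert_array_equal(cov, np.eye(4))
    assert lam == 1.0


def test_constant_column_rejected_with_index(rng):
    M = rng.normal(size=(10, 3))
    M[:, 1] = 7.0
    with pytest.raises(ValueError, match=r"\[1\]"):
        shrinkage_covariance(M)


def test_gram_trick_matches_naive_pairwise_formula(rng):
    """The O(n^2 p) intensity equals the direct pairwise-sum estimator."""
    M = rng.normal(size=(20, 5))
    M[:, 1] += 0.8 * M[:, 0]
    Ms = (M - M.mean(0)) / M.std(0, ddof=1)
    n, d = Ms.shape
    num = den = 0.0
    for i in range(d):
        for j in range(d):
            if i == j:
                continue
            w = Ms[:, i] * Ms[:, j]
            num += n / (n - 1) ** 3 * np.sum((w - w.mean()) ** 2)
            den += (np.sum(w) / (n - 1)) ** 2
    expected = min(1.0, max(0.0, num / den))
    assert shrinkage_intensity(Ms) == pytest.approx(expected, rel=1e-10)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_self_correlation_single_columns(rng):
    x = rng.normal(size=60)
    pair = DataBlockPair(X=x, Y=x.copy())
    model = fit_cca_whitening(pair, lambda_x=0.0, lambda_y=0.0)
    assert model.rho[0] == pytest.approx(1.0, abs=1e-10)
    sc = transform(model, pair).scores
    np.testing.assert_allclose(sc.qEEG1, sc.Cog1, atol=1e-10)
    z = (x - x.mean()) / x.std(ddof=1)
    np.testing.assert_allclose(sc.qEEG1, z, atol=1e-8)


def test_zero_shrinkage_matches_classical_cca(rng):
    X, Y = _shared_latent_blocks(rng)
    model = fit_cca_whitening(DataBlockPair(X=X, Y=Y),
                              lambda_x=0.0, lambda_y=0.0)
    sv = _classical_cca(X, Y)
    np.testing.assert_allclose(np.abs(model.rho), sv, atol=1e-8)


def test_score_correlation_equals_rho_at_zero_shrinkage(rng):
    X, Y = _shared_latent_blocks(rng)
    pair = DataBlockPair(X=X, Y=Y)
    model = fit_cca_whitening(pair, lambda_x=0.0, lambda_y=0.0)
    sc = transform(model, pair).scores
    corr = np.corrcoef(sc.qEEG1, sc.Cog1)[0, 1]
    assert corr == pytest.approx(model.rho[0], abs=1e-8)
    assert model.score_corr[0] == pytest.approx(model.rho[0], abs=1e-8)


def test_independent_blocks_small_rho(rng):
    X = rng.normal(size=(2000, 3))
    Y = rng.normal(size=(2000, 2))
    model = fit_cca_whitening(DataBlockPair(X=X, Y=Y))
    assert abs(model.rho[0]) < 0.1


def test_whitening_contract_identity_covariance(rng):
    """lambda=0, n > p+q: whitened variables have identity covariance and
    a diagonal cross-correlation."""
    X, Y = _shared_latent_blocks(rng, n=500, p=4, q=3)
    pair = DataBlockPair(X=X, Y=Y)
    m = fit_cca_whitening(pair, lambda_x=0.0, lambda_y=0.0)
    sc = transform(m, pair, n_components=3).scores
    Zx = sc[[c for c in sc.columns if c.startswith("qEEG")]].to_numpy()
    Zy = sc[[c for c in sc.columns if c.startswith("Cog")]].to_numpy()
    n = len(Zx)
    np.testing.assert_allclose(Zx.T @ Zx / (n - 1), np.eye(3), atol=1e-8)
    np.testing.assert_allclose(Zy.T @ Zy / (n - 1), np.eye(3), atol=1e-8)
    cross = Zx.T @ Zy / (n - 1)
    np.testing.assert_allclose(cross, np.diag(np.diag(cross)), atol=1e-8)
    np.testing.assert_allclose(np.abs(np.diag(cross)), np.abs(m.rho[:3]),
                               atol=1e-8)


def test_column_scaling_leaves_rho_unchanged(rng):
    X, Y = _shared_latent_blocks(rng)
    m1 = fit_cca_whitening(DataBlockPair(X=X, Y=Y))
    X2 = X.copy()
    X2[:, 0] *= 37.0
    m2 = fit_cca_whitening(DataBlockPair(X=X2, Y=Y))
    np.testing.assert_allclose(m1.rho, m2.rho, atol=1e-10)


def test_sign_convention_under_y_negation(rng):
    """Negating every Y column flips Cog1 but leaves |rho| and the
    convention-fixed loadings unchanged."""
    X, Y = _shared_latent_blocks(rng)
    p1 = DataBlockPair(X=X, Y=Y)
    p2 = DataBlockPair(X=X, Y=-Y)
    m1 = fit_cca_whitening(p1, lambda_x=0.0, lambda_y=0.0)
    m2 = fit_cca_whitening(p2, lambda_x=0.0, lambda_y=0.0)
    np.testing.assert_allclose(np.abs(m1.rho), np.abs(m2.rho), atol=1e-10)
    np.testing.assert_allclose(m1.y_weights, m2.y_weights, atol=1e-8)
    s1 = transform(m1, p1).scores
    s2 = transform(m2, p2).scores
    np.testing.assert_allclose(s2.Cog1, -s1.Cog1, atol=1e-8)


def test_misaligned_blocks_rejected(rng):
    with pytest.raises(ValueError, match="misaligned"):
        DataBlockPair(X=rng.normal(size=(10, 2)), Y=rng.normal(size=(9, 2)))


def test_transform_dimension_mismatch_rejected(rng):
    X, Y = _shared_latent_blocks(rng)
    model = fit_cca_whitening(DataBlockPair(X=X, Y=Y))
    with pytest.raises(ValueError, match="columns"):
        transform(model, DataBlockPair(X=X[:, :2], Y=Y))


def test_transform_deterministic_on_duplicated_rows(rng):
    X, Y = _shared_latent_blocks(rng, n=40)
    model = fit_cca_whitening(DataBlockPair(X=X, Y=Y))
    dup = transform(model, DataBlockPair(X=np.vstack([X, X]),
                                         Y=np.vstack([Y, Y]))).scores
    np.testing.assert_array_equal(dup.qEEG1[:40], dup.qEEG1[40:])


def test_scores_standardized_on_fit_data(rng):
    X, Y = _shared_latent_blocks(rng)
    pair = DataBlockPair(X=X, Y=Y)
    sc = transform(fit_cca_whitening(pair), pair).scores
    for col in ("qEEG1", "Cog1"):
        assert sc[col].mean() == pytest.approx(0.0, abs=1e-8)
        assert sc[col].std(ddof=1) == pytest.approx(1.0, abs=1e-8)


def test_in_sample_correlation_overfits_when_p_huge(rng):
    """With p >> n even independent blocks reach near-perfect in-sample
    score correlation: the fitted first-pair correlation is not evidence
    of generalization.  With weak shrinkage (as estimated on strongly
    inter-correlated real spectra) the whitened features can reproduce
    any target in sample; the full-shrinkage limit suppresses this."""
    X = rng.normal(size=(50, 9800))
    Y = rng.normal(size=(50, 6))
    weak = fit_cca_whitening(DataBlockPair(X=X, Y=Y), lambda_x=0.05)
    assert abs(weak.score_corr[0]) > 0.9
    est = fit_cca_whitening(DataBlockPair(X=X, Y=Y))
    assert est.lambda_x > 0.9              # independent noise -> full shrinkage


def test_latent_recovery_on_calibrated_bundle(default_bundle):
    """The first spectra variate tracks the true mediator latent."""
    X = default_bundle.spectra_matrix()
    X = X - X.mean(axis=1, keepdims=True)
    pair = DataBlockPair(X=X,
                         Y=default_bundle.cohort[list(COG_SCORES)].to_numpy(),
                         y_names=list(COG_SCORES))
    model = fit_cca_whitening(pair)
    sc = transform(model, pair).scores
    med = default_bundle.latents_true["mediator"].to_numpy()
    assert abs(np.corrcoef(sc.qEEG1, med)[0, 1]) > 0.8


def test_model_json_roundtrip(tmp_path, rng):
    X, Y = _shared_latent_blocks(rng)
    pair = DataBlockPair(X=X, Y=Y, y_names=["a", "b"])
    model = fit_cca_whitening(pair)
    model.to_json(tmp_path / "model.json")
    back = WhiteningModel.from_json(tmp_path / "model.json")
    np.testing.assert_allclose(back.rho, model.rho)
    np.testing.assert_allclose(
        transform(back, pair).scores.qEEG1,
        transform(model, pair).scores.qEEG1, atol=1e-12)


# ---------------------------------------------------------------------------
# loading summaries
# ---------------------------------------------------------------------------

def test_loading_summary_single_column(rng):
    x = rng.normal(size=50)
    pair = DataBlockPair(X=x, Y=x + 0.1 * rng.normal(size=50))
    model = fit_cca_whitening(pair)
    geom = pd.DataFrame({"source": [0], "frequency": [10.0]})
    summ = loading_summaries(model, geom)
    assert summ.freq_minmax.min_loading.iloc[0] == summ.freq_minmax.max_loading.iloc[0]
    assert summ.freq_minmax.min_loading.iloc[0] == pytest.approx(
        model.x_weights[0, 0])


def test_top_percent_sets_size_and_tiebreak(rng):
    """All-equal loadings: sets have ceil(0.01 p) members, ties broken by
    lowest column index."""
    n, p = 30, 250
    z = rng.normal(size=n)
    X = np.outer(z, np.ones(p)) + 1e-6 * rng.normal(size=(n, p))
    Y = z + 0.1 * rng.normal(size=n)
    model = fit_cca_whitening(DataBlockPair(X=X, Y=Y))
    # force exactly equal loadings to exercise the documented tie-break
    model.x_weights[:, 0] = 1.0
    geom = pd.DataFrame({"source": np.arange(p), "frequency": np.zeros(p)})
    summ = loading_summaries(model, geom)
    k = int(np.ceil(0.01 * p))
    assert len(summ.top_positive) == len(summ.top_negative) == k
    np.testing.assert_array_equal(summ.top_positive, np.arange(k))
    np.testing.assert_array_equal(summ.top_negative, np.arange(k))


def test_planted_support_recovered_in_top_percent():
    """Spectra loadings supported on 10 known columns put those columns
    at the top of the positive loading ranking."""
    truth = TruthParams()
    load = np.zeros((truth.n_sources, truth.n_freqs))
    planted = np.arange(10) * 37          # spread over the vectorized columns
    load.reshape(-1)[planted] = 1.0
    bundle = generate_cohort(truth.replace(load_qeeg=load), DEFAULT_SEED)
    X = bundle.spectra_matrix()
    pair = DataBlockPair(X=X, Y=bundle.cohort[list(COG_SCORES)].to_numpy(),
                         y_names=list(COG_SCORES))
    model = fit_cca_whitening(pair)
    geom = bundle.geometry()
    summ = loading_summaries(model, geom)
    top = (summ.top_positive if model.x_weights[planted, 0].sum() > 0
           else summ.top_negative)
    assert len(set(planted) & set(top)) >= 8


def test_geometry_size_mismatch_rejected(rng):
    X, Y = _shared_latent_blocks(rng)
    model = fit_cca_whitening(DataBlockPair(X=X, Y=Y))
    with pytest.raises(ValueError, match="geometry"):
        loading_summaries(model, pd.DataFrame({"source": [0], "frequency": [1.0]}))
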