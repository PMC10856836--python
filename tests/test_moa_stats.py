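import numpy as np
import pandas as pd
import pytest

from phenoscan.errors import ConfigurationError, UnbalancedDesignError
from phenoscan.moa_stats import (
    correlation_pca,
    first_separation_hat,
    pivot_parameter_matrix,
    run_pooled_pca,
    separation_report,
    two_way_anova,
)


# -- two-way ANOVA oracle ------------------------------------------------------


def _anova_oracle(df):
    """Balanced two-way fixed-effects SS from cell and marginal means."""
    y = df.pivot_table(index="treatment", columns="hat", values="value",
                       aggfunc=list)
    a_levels, b_levels = y.index, y.columns
    n = len(y.iloc[0, 0])
    data = np.array([[y.loc[a, b] for b in b_levels] for a in a_levels])
    grand = data.mean()
    a_means = data.mean(axis=(1, 2))
    b_means = data.mean(axis=(0, 2))
    cell = data.mean(axis=2)
    ss_a = len(b_levels) * n * ((a_means - grand) ** 2).sum()
    ss_b = len(a_levels) * n * ((b_means - grand) ** 2).sum()
    ss_ab = n * ((cell - a_means[:, None] - b_means[None, :] + grand) ** 2
                 ).sum()
    ss_e = ((data - cell[..., None]) ** 2).sum()
    ss_t = ((data - grand) ** 2).sum()
    return ss_a, ss_b, ss_ab, ss_e, ss_t


def _random_design(rng, n_a=4, n_b=3, reps=5, effect_a=1.0, effect_b=1.0,
                   interaction=0.5, noise=1.0):
    rows = []
    a_eff = rng.normal(0, effect_a, n_a)
    b_eff = rng.normal(0, effect_b, n_b)
    ab = rng.normal(0, interaction, (n_a, n_b))
    for i in range(n_a):
        for j in range(n_b):
            for _ in range(reps):
                rows.append(dict(treatment=f"t{i}", hat=j,
                                 value=10 + a_eff[i] + b_eff[j] + ab[i, j]
                                 + rng.normal(0, noise)))
    return pd.DataFrame(rows)


def test_anova_matches_cell_means_oracle_on_random_designs(rng):
    for _ in range(10):
        df = _random_design(rng, n_a=int(rng.integers(2, 6)),
                            n_b=int(rng.integers(2, 5)),
                            reps=int(rng.integers(2, 7)))
        res = two_way_anova(df, parameter="any", value_column="value")
        ss_a, ss_b, ss_ab, ss_e, ss_t = _anova_oracle(df)
        assert res.ss_herbicide == pytest.approx(ss_a, abs=1e-8, rel=1e-10)
        assert res.ss_time == pytest.approx(ss_b, abs=1e-8, rel=1e-10)
        assert res.ss_interaction == pytest.approx(ss_ab, abs=1e-8, rel=1e-10)
        assert res.ss_residual == pytest.approx(ss_e, abs=1e-8, rel=1e-10)
        # SS decomposition is exact on a balanced design
        total = (res.ss_herbicide + res.ss_time + res.ss_interaction
                 + res.ss_residual)
        assert total == pytest.approx(ss_t, rel=1e-10)


def test_anova_hand_computed_2x2():
    # residual-free, interaction-free layout: values are A-effect + B-effect
    df = pd.DataFrame([
        ("a1", 0, 1.0), ("a1", 0, 1.0), ("a1", 1, 2.0), ("a1", 1, 2.0),
        ("a2", 0, 3.0), ("a2", 0, 3.0), ("a2", 1, 4.0), ("a2", 1, 4.0),
    ], columns=["treatment", "hat", "value"])
    res = two_way_anova(df, parameter="any", value_column="value")
    assert res.ss_residual == pytest.approx(0.0, abs=1e-12)
    assert res.ss_interaction == pytest.approx(0.0, abs=1e-12)
    assert res.ss_herbicide == pytest.approx(8.0)   # 2*2*((1)^2+(1)^2)/... = 8
    assert res.ss_time == pytest.approx(2.0)
    assert res.df_herbicide == 1 and res.df_time == 1
    assert res.df_residual == 4


def test_anova_strong_herbicide_weak_time_effect(rng):
    df = _random_design(rng, n_a=5, n_b=4, reps=6, effect_a=8.0,
                        effect_b=0.5, interaction=0.0, noise=1.0)
    res = two_way_anova(df, parameter="any", value_column="value")
    assert res.F_herbicide > res.F_time


def test_anova_rejects_unbalanced_design(rng):
    df = _random_design(rng)
    res_ok = two_way_anova(df, parameter="any", value_column="value")
    assert np.isfinite(res_ok.F_herbicide)
    with pytest.raises(UnbalancedDesignError):
        two_way_anova(df.iloc[:-1], parameter="any", value_column="value")


# -- correlation PCA -----------------------------------------------------------


def test_pca_matches_eigendecomposition_oracle(rng):
    X = rng.normal(size=(40, 6)) @ rng.normal(size=(6, 6))
    res = correlation_pca(X)
    corr = np.corrcoef(X, rowvar=False)
    eig = np.linalg.eigvalsh(corr)[::-1]
    np.testing.assert_allclose(res.eigenvalues, eig, atol=1e-9)
    assert res.eigenvalues.sum() == pytest.approx(X.shape[1])
    # loadings orthonormal, explained fractions non-increasing
    np.testing.assert_allclose(res.loadings.T @ res.loadings,
                               np.eye(6), atol=1e-9)
    assert (np.diff(res.explained_variance_fraction) <= 1e-12).all()


def test_pca_reconstruction_with_full_components(rng):
    X = rng.normal(size=(25, 4))
    res = correlation_pca(X)
    Z = (X - X.mean(0)) / X.std(0, ddof=1)
    np.testing.assert_allclose(res.scores @ res.loadings.T, Z, atol=1e-9)


def test_pca_two_perfectly_correlated_columns():
    x = np.linspace(0, 1, 30)
    res = correlation_pca(np.c_[x, 3 * x + 1])
    assert res.explained_variance_fraction[0] == pytest.approx(1.0)


def test_pca_uncorrelated_equal_variance_splits_evenly(rng):
    n = 20000
    X = rng.normal(size=(n, 2))
    X[:, 1] -= X[:, 0] * np.corrcoef(X.T)[0, 1]  # orthogonalize approximately
    res = correlation_pca(X)
    assert res.explained_variance_fraction[0] == pytest.approx(0.5, abs=0.02)


def test_pca_sign_convention_largest_loading_positive(rng):
    X = rng.normal(size=(30, 5))
    res = correlation_pca(X)
    for j in range(res.loadings.shape[1]):
        col = res.loadings[:, j]
        assert col[np.argmax(np.abs(col))] > 0


def test_pca_drops_constant_columns_with_warning(rng):
    X = rng.normal(size=(20, 3))
    X[:, 1] = 7.0
    with pytest.warns(UserWarning, match="constant"):
        res = correlation_pca(X, feature_names=["a", "b", "c"])
    assert res.feature_names == ("a", "c")


def test_pca_too_few_samples_raises():
    with pytest.raises(ConfigurationError):
        correlation_pca(np.ones((1, 3)))


# -- separation scoring ----------------------------------------------------------


def _two_group_scores(rng, delta, n=8, sd=1.0):
    a = rng.normal(0, sd, (n, 2))
    b = rng.normal(delta, sd, (n, 2))
    X = np.vstack([a, b])
    labels = np.array(["g1"] * n + ["g2"] * n)
    from phenoscan.moa_stats import PCAResult
    pca = PCAResult(scores=X, loadings=np.eye(2), eigenvalues=np.ones(2),
                    explained_variance_fraction=np.array([0.5, 0.5]),
                    feature_names=("p1", "p2"))
    return separation_report(pca, labels=labels)


def test_identical_distributions_rarely_separate(rng):
    hits = sum(_two_group_scores(rng, 0.0).separated.any()
               for _ in range(100))
    assert hits <= 5     # >= 95% of null simulations below threshold


def test_far_separated_groups_flagged(rng):
    rep = _two_group_scores(rng, 10.0)
    assert rep.separated.all()
    assert (rep.separation_score > 2).all()


def test_singleton_group_flagged(rng):
    X = np.vstack([rng.normal(0, 1, (5, 2)), [[9.0, 9.0]]])
    labels = np.array(["a"] * 5 + ["b"])
    from phenoscan.moa_stats import PCAResult
    pca = PCAResult(scores=X, loadings=np.eye(2), eigenvalues=np.ones(2),
                    explained_variance_fraction=np.array([0.5, 0.5]),
                    feature_names=("p1", "p2"))
    rep = separation_report(pca, labels=labels)
    assert rep[rep.treatment == "b"].singleton.all()
    assert np.isnan(rep[rep.treatment == "b"].separation_score).all()


# -- pooled PCA + pipeline-level behaviour --------------------------------------


def test_pooled_pca_single_hat_equals_per_hat(measured_6hat):
    pooled = run_pooled_pca(measured_6hat)
    matrix, _ = pivot_parameter_matrix(measured_6hat)
    direct = correlation_pca(matrix)
    np.testing.assert_allclose(pooled.eigenvalues, direct.eigenvalues,
                               atol=1e-9)


def test_pivot_missing_parameter_errors(measured_6hat):
    broken = measured_6hat[measured_6hat.parameter != "FdFm"]
    with pytest.raises(ConfigurationError, match="FdFm"):
        pivot_parameter_matrix(broken)


def test_label_shuffling_destroys_separation(measured_6hat, rng):
    matrix, ann = pivot_parameter_matrix(measured_6hat)
    pca = correlation_pca(matrix, sample_annotations=ann)
    hits = 0
    for _ in range(40):
        shuffled = rng.permutation(ann["treatment"].to_numpy())
        rep = separation_report(pca, labels=shuffled)
        hits += rep.separated.any()
    assert hits <= 2     # >= 95% of shuffles show no separation


def test_first_separation_hat_extraction():
    tl = pd.DataFrame({
        "hat": [3, 6, 3, 6],
        "treatment": ["x", "x", "y", "y"],
        "separated": [False, True, False, False],
        "separation_score": [1.0, 3.0, 0.5, 0.6],
    })
    first = first_separation_hat(tl)
    assert first["x"] == 6.0
    assert np.isnan(first["y"])
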