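import numpy as np
import pandas as pd
import pytest

from wearcon import imputation as imp


def test_monotone_pattern_recognised():
    mask = np.array([[False, False, False],
                     [False, False, True],
                     [False, True, True]])
    ok, order = imp.monotonicity_check(mask)
    assert ok
    assert list(order) == [0, 1, 2]


def test_non_monotone_pattern_recognised():
    mask = np.array([[True, False],
                     [False, True]])
    ok, _ = imp.monotonicity_check(mask)
    assert not ok


def frame(seed=0, n=40, p=4, miss=6, monotone=False):
    rng = np.random.default_rng(seed)
    cov = 0.6 * np.ones((p, p)) + 0.4 * np.eye(p)
    X = rng.multivariate_normal(np.arange(p, dtype=float) + 5.0, cov, size=n)
    df = pd.DataFrame(X, columns=[f"c{i}" for i in range(p)])
    if monotone:
        for i in range(miss):
            df.iloc[i, p - 1] = np.nan
        for i in range(miss // 2):
            df.iloc[i, p - 2] = np.nan
    else:
        flat = rng.choice(n * p, size=miss, replace=False)
        for k in flat:
            df.iloc[k // p, k % p] = np.nan
    return df


def test_observed_cells_never_altered():
    df = frame(miss=10)
    result = imp.impute(df, m=3, seed=1, burn_in=20, thinning=2)
    mask = df.isna().to_numpy()
    for ds in result.datasets:
        assert np.allclose(ds.to_numpy()[~mask], df.to_numpy()[~mask])
        assert np.isfinite(ds.to_numpy()).all()


def test_imputation_is_deterministic_in_the_seed():
    df = frame(miss=8)
    a = imp.impute(df, m=2, seed=5, burn_in=20, thinning=2)
    b = imp.impute(df, m=2, seed=5, burn_in=20, thinning=2)
    c = imp.impute(df, m=2, seed=6, burn_in=20, thinning=2)
    assert a.datasets[0].equals(b.datasets[0])
    assert not a.datasets[0].equals(c.datasets[0])


def test_monotone_branch_selected_for_monotone_pattern():
    result = imp.impute(frame(monotone=True), m=2, seed=2)
    assert result.pattern == "monotone"


def test_random_branch_selected_for_scattered_pattern():
    result = imp.impute(frame(miss=8, seed=3), m=2, seed=2,
                        burn_in=20, thinning=2)
    assert result.pattern == "random"


def test_bounds_constrain_imputed_values():
    df = frame(miss=10, seed=4)
    bounds = {c: (4.0, 12.0) for c in df.columns}
    result = imp.impute(df, m=3, seed=2, bounds=bounds, burn_in=20, thinning=2)
    mask = df.isna().to_numpy()
    for ds in result.datasets:
        filled = ds.to_numpy()[mask]
        assert np.all(filled >= 4.0) and np.all(filled <= 12.0)


def test_log_scale_columns_stay_positive():
    df = frame(miss=10, seed=7)
    result = imp.impute(df, m=3, seed=2, log_columns=("c0", "c3"),
                        burn_in=20, thinning=2)
    for ds in result.datasets:
        assert (ds[["c0", "c3"]].to_numpy() > 0).all()


def test_entirely_missing_column_rejected():
    df = frame()
    df["c1"] = np.nan
    with pytest.raises(imp.ImputationError):
        imp.impute(df, m=2)


def test_column_with_one_observed_value_rejected():
    df = frame(n=10)
    df.loc[df.index[1:], "c2"] = np.nan
    with pytest.raises(imp.ImputationError):
        imp.impute(df, m=2)


def test_pooled_variance_never_below_within_variance():
    rng = np.random.default_rng(0)
    q = rng.normal(size=(5, 3))
    u = rng.uniform(0.5, 2.0, size=(5, 3))
    pooled = imp.pool(q, u)
    assert np.all(pooled.total_variance >= pooled.within_variance)
    assert np.all(pooled.ci_low <= pooled.estimate)
    assert np.all(pooled.ci_high >= pooled.estimate)


def test_pooling_requires_multiple_imputations():
    with pytest.raises(imp.ImputationError):
        imp.pool(np.array([[1.0]]), np.array([[1.0]]))
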