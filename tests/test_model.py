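import numpy as np
import pandas as pd
import pytest

from wearcon import model as M
from wearcon.imputation import ImputedSet


def logistic_data(n=300, beta=(1.0, -0.8), intercept=0.2, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, len(beta))),
                     columns=[f"f{i}" for i in range(len(beta))])
    eta = intercept + X.to_numpy() @ np.asarray(beta)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return X, y


def test_two_symptom_items_and_modest_fall_is_controlled():
    gina = M.GinaSymptoms(True, True, False, False)
    out = M.label_control(gina, M.BPTResult(8.0))
    assert out.label == M.CONTROLLED


def test_label_basis_reports_both_clauses():
    gina = M.GinaSymptoms(True, True, True, True)
    out = M.label_control(gina, M.BPTResult(30.0))
    assert out.label == M.UNCONTROLLED and out.basis == "both"


def test_provocation_fall_out_of_range_rejected():
    with pytest.raises(M.ModelError):
        M.BPTResult(150.0)


def test_logistic_fit_recovers_planted_coefficients():
    X, y = logistic_data(n=2000, beta=(1.0, -0.8), intercept=0.2, seed=1)
    model = M.fit_logistic(X, y, ["f0", "f1"])
    assert model.coefficients[0] == pytest.approx(1.0, abs=0.2)
    assert model.coefficients[1] == pytest.approx(-0.8, abs=0.2)
    assert not model.firth


def test_separated_data_falls_back_to_penalised_fit():
    X = pd.DataFrame({"f0": np.concatenate([np.full(20, -1.0), np.full(20, 1.0)])})
    y = np.concatenate([np.zeros(20), np.ones(20)])
    model = M.fit_logistic(X, y, ["f0"])
    assert model.firth
    assert np.isfinite(model.coefficients).all()


def test_nagelkerke_bounds_and_ordering():
    X, y = logistic_data(n=500, beta=(2.5,), seed=2)
    strong = M.fit_logistic(X, y, ["f0"])
    Xn = X.copy()
    Xn["noise"] = np.random.default_rng(3).normal(size=len(X))
    weak = M.fit_logistic(Xn, y, ["noise"])
    assert 0.0 <= weak.nagelkerke <= strong.nagelkerke <= 1.0
    assert weak.nagelkerke < 0.05


def test_collinearity_screen_is_strict_at_the_threshold():
    rng = np.random.default_rng(4)
    a = rng.normal(size=400)
    X = pd.DataFrame({"a": a, "b": a + 0.01 * rng.normal(size=400),
                      "c": rng.normal(size=400)})
    flagged = M.collinearity_screen(X, threshold=0.8)
    assert ("a", "b") in flagged
    assert all("c" not in pair for pair in flagged)
    # |r| exactly at the threshold is not flagged
    assert M.collinearity_screen(X, threshold=1.0) == []


def test_stepwise_selects_informative_features_only():
    X, y = logistic_data(n=400, beta=(1.5, -1.2, 0.0, 0.0), seed=5)
    imputed = ImputedSet([X.copy(), X.copy()], [0, 0], "none")
    model = M.stepwise_logistic(imputed, y)
    assert "f0" in model.features and "f1" in model.features


def test_stepwise_without_signal_returns_intercept_only():
    rng = np.random.default_rng(6)
    X = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
    y = (rng.random(200) < 0.4).astype(float)
    imputed = ImputedSet([X.copy(), X.copy()], [0, 0], "none")
    model = M.stepwise_logistic(imputed, y, entry=0.001)
    assert model.features == []
    assert model.intercept == pytest.approx(np.log(y.mean() / (1 - y.mean())))


def test_odds_ratios_exponentiate_coefficients():
    model = M.LogisticModel(["a", "b"], np.array([0.5, -0.3]), 0.0,
                            covariance=np.diag([0.1, 0.04, 0.09]))
    table = M.odds_ratios(model)
    assert table.loc["a", "odds_ratio"] == pytest.approx(np.exp(0.5))
    assert table.loc["b", "inverse_odds_ratio"] == pytest.approx(np.exp(0.3))
    assert table.loc["a", "ci_low"] < table.loc["a", "odds_ratio"] < table.loc["a", "ci_high"]


def test_probability_at_threshold_is_not_called_positive():
    model = M.LogisticModel(["x"], np.array([1.0]), 0.0)
    X = pd.DataFrame({"x": [0.0, 0.1]})
    out = M.score(model, X, threshold=0.5)
    assert list(out["predicted"]) == [M.CONTROLLED, M.UNCONTROLLED]


def test_model_json_round_trip(tmp_path):
    model = M.LogisticModel(["a"], np.array([0.7]), -1.0,
                            covariance=np.diag([0.2, 0.1]), nagelkerke=0.5)
    path = tmp_path / "model.json"
    model.to_json(path)
    loaded = M.LogisticModel.from_json(path)
    assert loaded.features == ["a"]
    assert loaded.coefficients[0] == pytest.approx(0.7)
    assert loaded.intercept == pytest.approx(-1.0)


def test_confusion_matrix_counts_from_label_pairs():
    true = ["uncontrolled", "uncontrolled", "controlled", "controlled"]
    pred = ["uncontrolled", "controlled", "controlled", "uncontrolled"]
    m = M.classification_metrics(true, pred)
    assert (m.tp, m.fn, m.fp, m.tn) == (1, 1, 1, 1)
    assert m.sensitivity == pytest.approx(0.5)


def test_univariate_report_detects_a_shifted_group():
    rng = np.random.default_rng(7)
    values = np.concatenate([rng.normal(0, 1, 30), rng.normal(0, 1, 30),
                             rng.normal(3, 1, 30)])
    features = pd.DataFrame({"param": values})
    groups = pd.Series(["controlled"] * 30 + ["non_asthmatic"] * 30 +
                       ["uncontrolled"] * 30)
    table = M.univariate_report(features, groups)
    row = table.loc["param"]
    assert row["p_value"] < 0.001
    assert "uncontrolled" in row["significant_pairs"]
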