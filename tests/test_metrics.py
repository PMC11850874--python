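"""Regression fit, outlier rule, and the validation metric battery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cwqsar.metrics import (
    c_rp2,
    ccc,
    compute_metrics,
    detect_outliers,
    fit_regression,
    loo_q2,
    rm2,
    validation_report,
    y_scramble,
)


# ---- regression ------------------------------------------------------------
def test_exact_line():
    model = fit_regression([0, 1, 2], [1, 3, 5])
    assert model.c0 == pytest.approx(1.0)
    assert model.c1 == pytest.approx(2.0)
    assert model.s == pytest.approx(0.0, abs=1e-12)


def test_normal_equations_oracle():
    """OLS matches the closed-form normal equations to 1e-10."""
    rng = np.random.default_rng(0)
    for _ in range(10):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        model = fit_regression(x, y)
        sxx = ((x - x.mean()) ** 2).sum()
        c1 = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        c0 = y.mean() - c1 * x.mean()
        assert model.c1 == pytest.approx(c1, abs=1e-10)
        assert model.c0 == pytest.approx(c0, abs=1e-10)


def test_pure_noise_slope_insignificant():
    rng = np.random.default_rng(1)
    x = rng.normal(size=200)
    y = 5.0 + rng.normal(size=200) * 0.1
    model = fit_regression(x, y)
    assert abs(model.c1) < 2 * model.se_c1


def test_degenerate_design_rejected():
    with pytest.raises(ValueError):
        fit_regression([1.0, 1.0, 1.0], [1, 2, 3])
    with pytest.raises(ValueError):
        fit_regression([1.0, 2.0], [1, 2])


def test_predict():
    model = fit_regression([0, 1, 2], [1, 3, 5])
    assert model.predict(0) == pytest.approx(1.0)
    assert model.predict(3) == pytest.approx(7.0)


# ---- outliers --------------------------------------------------------------
def test_no_outliers_on_clean_line():
    rng = np.random.default_rng(2)
    x = rng.normal(size=50)
    y = 2 + 3 * x + rng.normal(size=50) * 0.01
    ids = [f"c{i}" for i in range(50)]
    outliers, _ = detect_outliers(x, y, ids)
    assert outliers == []


def test_planted_outlier_detected():
    rng = np.random.default_rng(3)
    x = rng.normal(size=50)
    y = 2 + 3 * x + rng.normal(size=50) * 0.05
    y[17] += 10 * 0.05 * 20  # enormous residual
    ids = [f"c{i}" for i in range(50)]
    outliers, refit = detect_outliers(x, y, ids)
    assert outliers == ["c17"]
    assert refit.s < fit_regression(x, y).s


# ---- leave-one-out Q2 ------------------------------------------------------
def test_loo_q2_matches_explicit_refits():
    rng = np.random.default_rng(4)
    x = rng.normal(size=25)
    y = 1 + 0.5 * x + rng.normal(size=25) * 0.3
    press = 0.0
    for i in range(25):
        mask = np.ones(25, bool)
        mask[i] = False
        m = fit_regression(x[mask], y[mask])
        press += (y[i] - m.predict(x[i])) ** 2
    expected = 1 - press / ((y - y.mean()) ** 2).sum()
    assert loo_q2(x, y) == pytest.approx(expected, abs=1e-10)


# ---- metric battery --------------------------------------------------------
def test_perfect_predictions():
    obs = np.array([1.0, 2.0, 3.0, 4.0])
    m = compute_metrics(obs, obs, train_mean=2.5, train_n=4)
    assert m["r2"] == pytest.approx(1.0)
    assert m["q2_f1"] == pytest.approx(1.0)
    assert m["q2_f2"] == pytest.approx(1.0)
    assert m["ccc"] == pytest.approx(1.0)
    assert m["mae"] == 0.0


def test_ccc_anticorrelated():
    assert ccc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)


def test_ccc_one_iff_identical():
    rng = np.random.default_rng(5)
    x = rng.normal(size=20)
    assert ccc(x, x) == pytest.approx(1.0)
    assert ccc(x, x + 0.5) < 1.0
    assert ccc(x, 1.1 * x) < 1.0


def test_predictions_at_train_mean_give_zero_qf1():
    obs = np.array([1.0, 2.0, 3.0])
    pred = np.full(3, 2.0)
    m = compute_metrics(obs, pred, train_mean=2.0, train_n=10)
    assert m["q2_f1"] == pytest.approx(0.0)


def test_qf1_qf2_mean_identity():
    """Q2F1 = Q2F2 when the external mean equals the training mean,
    Q2F1 >= Q2F2 otherwise."""
    rng = np.random.default_rng(6)
    for shift in (0.0, 0.7, -1.3):
        obs = rng.normal(size=30)
        pred = obs + rng.normal(size=30) * 0.2
        m = compute_metrics(obs, pred, train_mean=float(obs.mean()) + shift, train_n=30)
        if shift == 0.0:
            assert m["q2_f1"] == pytest.approx(m["q2_f2"])
        else:
            assert m["q2_f1"] >= m["q2_f2"]


def test_rm2_equals_r2_for_proportional_fit():
    obs = np.array([1.0, 2.0, 3.0, 4.0])
    assert rm2(obs, obs) == pytest.approx(1.0)


def test_zero_variance_flagged_not_nan_crash():
    obs = np.full(5, 2.0)
    pred = np.arange(5.0)
    m = compute_metrics(obs, pred, train_mean=2.0, train_n=5)
    assert m["degenerate"]
    assert np.isnan(m["r2"])


# ---- Y-scrambling ----------------------------------------------------------
def test_c_rp2_formula():
    assert c_rp2(0.9, 0.0) == pytest.approx(0.81)
    assert c_rp2(0.9, 0.81) == 0.0
    assert c_rp2(0.8, 0.9) == 0.0  # clipped when scrambled beats real


def test_y_scramble_planted_linear():
    rng = np.random.default_rng(7)
    x = rng.normal(size=100)
    y = 2 + x + rng.normal(size=100) * 0.05
    r2 = np.corrcoef(x, y)[0, 1] ** 2
    value = y_scramble(x, y, n_permutations=100, seed=1)
    assert value == pytest.approx(r2, abs=0.05)


def test_y_scramble_requires_enough_permutations():
    with pytest.raises(ValueError):
        y_scramble([1, 2, 3], [1, 2, 3], n_permutations=5)


# ---- report ----------------------------------------------------------------
def test_validation_report_shape():
    rng = np.random.default_rng(8)
    frames = {}
    for label in ("TRN", "iTRN", "CAL", "VAL"):
        obs = rng.normal(5, 0.5, size=30)
        frames[label] = (obs, obs + rng.normal(0, 0.2, size=30))
    report = validation_report(frames)
    assert list(report.index) == ["TRN", "iTRN", "CAL", "VAL"]
    assert {"r2", "ccc", "iic", "q2", "q2_f1", "s", "mae", "rm2"} <= set(report.columns)
    assert (report["n"] == 30).all()
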