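import numpy as np
import pandas as pd
import pytest

from pkdpeptidome.core import IntensityMatrix
from pkdpeptidome.severity import (
    evaluate_severity,
    fit_severity,
    predict_severity,
    screen_spearman,
)
from tests.conftest import make_matrix


def _response(matrix, values):
    return pd.Series(np.asarray(values, float), index=matrix.values.index)


def test_screen_matches_rank_formula(rng):
    """Spearman r equals 1 - 6*sum(d^2)/(n(n^2-1)) for tie-free data."""
    n = 12
    x = np.exp(rng.normal(2, 1, size=n))  # positive, tie-free
    y = rng.permutation(n).astype(float) + 1
    m = make_matrix(x[:, None])
    r = screen_spearman(m, _response(m, y), r_threshold=-1.0)
    rank_x = np.argsort(np.argsort(x)) + 1
    d2 = np.sum((rank_x - y) ** 2)
    expected = 1 - 6 * d2 / (n * (n**2 - 1))
    assert r.set_index("peptide_id")["r"][1] == pytest.approx(expected, abs=1e-12)


def test_screen_monotone_pair_is_one(rng):
    x = np.sort(rng.uniform(1, 100, size=12))
    m = make_matrix(x[:, None])
    r = screen_spearman(m, _response(m, np.arange(12.0)), r_threshold=0.5)
    assert r["r"].iloc[0] == pytest.approx(1.0)


def test_screen_threshold_one_keeps_only_perfect(rng):
    x = rng.uniform(1, 100, size=(12, 3))
    x[:, 0] = np.arange(1, 13)  # perfectly monotone with response
    m = make_matrix(x)
    hits = screen_spearman(m, _response(m, np.arange(12.0)), r_threshold=1.0 - 1e-12)
    assert list(hits["peptide_id"]) == [1]


def test_screen_invariant_to_monotone_transform(rng):
    x = np.exp(rng.normal(2, 1, size=(20, 4)))
    x[rng.random((20, 4)) < 0.2] = 0.0  # absences as lowest ties
    y = rng.normal(size=20)
    m1 = make_matrix(x)
    m2 = make_matrix(x**3)
    a = screen_spearman(m1, _response(m1, y), r_threshold=-1.0)
    b = screen_spearman(m2, _response(m2, y), r_threshold=-1.0)
    np.testing.assert_allclose(
        a.set_index("peptide_id")["r"], b.set_index("peptide_id")["r"], atol=1e-12
    )


def test_screen_errors():
    m = make_matrix(np.ones((12, 1)) * 5)
    with pytest.raises(ValueError, match="constant response"):
        screen_spearman(m, _response(m, np.ones(12)))
    small = make_matrix(np.ones((5, 1)))
    with pytest.raises(ValueError, match="10"):
        screen_spearman(small, _response(small, np.arange(5.0)))


def test_constant_peptide_excluded(rng):
    x = np.column_stack([np.full(12, 7.0), rng.uniform(1, 9, 12)])
    m = make_matrix(x)
    hits = screen_spearman(m, _response(m, rng.normal(size=12)), r_threshold=-1.0)
    assert 1 not in set(hits["peptide_id"])


def test_single_linear_peptide_recovered_exactly(rng):
    x = np.exp(rng.normal(3, 1, size=25))
    y = 4.0 + 2.5 * np.log1p(x)
    m = make_matrix(x[:, None])
    model = fit_severity(m, _response(m, y), [1], ridge_lambda=0)
    assert model.train_pearson == pytest.approx(1.0, abs=1e-9)
    # coefficient on standardized ln(1+x) equals 2.5 * sd(ln(1+x))
    sd = np.log1p(x).std()
    assert model.coef[0] == pytest.approx(2.5 * sd, rel=1e-9)
    pred = predict_severity(model, m)
    np.testing.assert_allclose(pred, y, rtol=1e-9)


def test_fit_reduces_to_simple_regression(rng):
    x = np.exp(rng.normal(2, 0.8, size=30))
    y = 1.0 + 0.5 * np.log1p(x) + rng.normal(0, 0.1, 30)
    m = make_matrix(x[:, None])
    model = fit_severity(m, _response(m, y), [1], ridge_lambda=0)
    z = np.log1p(x)
    slope = np.cov(z, y, ddof=0)[0, 1] / np.var(z)
    assert model.coef[0] / np.log1p(x).std() == pytest.approx(slope, abs=1e-10)


def test_underdetermined_ols_refused(rng):
    x = np.exp(rng.normal(size=(10, 15)))
    m = make_matrix(x)
    with pytest.raises(ValueError, match="under-determined"):
        fit_severity(m, _response(m, rng.normal(size=10)), list(range(1, 16)),
                     ridge_lambda=0)


def test_ridge_engages_when_p_large(rng):
    x = np.exp(rng.normal(size=(30, 20)))
    y = rng.normal(size=30)
    m = make_matrix(x)
    model = fit_severity(m, _response(m, y), list(range(1, 21)))
    assert model.ridge_lambda > 0


def test_predict_self_consistency_and_extra_columns(rng):
    x = np.exp(rng.normal(size=(25, 6)))
    y = np.log1p(x[:, 0]) + rng.normal(0, 0.3, 25)
    m = make_matrix(x)
    screened = screen_spearman(m, _response(m, y), r_threshold=0.1)
    model = fit_severity(m, _response(m, y), screened)
    ev = evaluate_severity(model, m, _response(m, y))
    assert ev["pearson_r"] == pytest.approx(model.train_pearson, abs=1e-12)
    wider = make_matrix(np.column_stack([x, rng.uniform(size=25)]))
    np.testing.assert_allclose(
        predict_severity(model, wider), predict_severity(model, m), atol=0
    )
    with pytest.raises(KeyError):
        predict_severity(model, make_matrix(x[:, :2]))


def test_signed_sum_variant(rng):
    x = np.exp(rng.normal(size=(40, 5)))
    y = np.log1p(x[:, 0]) - np.log1p(x[:, 1]) + rng.normal(0, 0.2, 40)
    m = make_matrix(x)
    screened = screen_spearman(m, _response(m, y), r_threshold=0.1)
    model = fit_severity(m, _response(m, y), screened, method="signed-sum")
    signs = np.sign(model.coef)
    expected = np.sign(screened["r"].to_numpy()) * np.sign(model.coef).prod() ** 0  # same orientation
    assert model.train_pearson > 0.3
    # coefficients are a common rescaling of the screening signs
    ratio = model.coef / np.sign(screened["r"].to_numpy())
    assert np.allclose(ratio, ratio[0])


def test_heldout_not_better_than_training_usually(rng):
    wins = 0
    reps = 20
    for k in range(reps):
        r = np.random.default_rng(k)
        n, p = 100, 20
        x = np.exp(r.normal(size=(n, p)))
        y = np.log1p(x[:, 0]) + 0.5 * np.log1p(x[:, 1]) + r.normal(0, 1.2, n)
        tr, te = np.arange(0, 40), np.arange(40, 100)
        mtr = make_matrix(x[tr])
        model = fit_severity(mtr, _response(mtr, y[tr]), list(range(1, p + 1)))
        mte = IntensityMatrix(
            pd.DataFrame(x[te], index=[f"t{i}" for i in range(len(te))],
                         columns=range(1, p + 1))
        )
        ev = evaluate_severity(model, mte, pd.Series(y[te], index=mte.values.index))
        if ev["pearson_r"] <= model.train_pearson:
            wins += 1
    assert wins / reps >= 0.9


def test_permuted_response_gives_weak_heldout(rng):
    weak = 0
    for k in range(10):
        r = np.random.default_rng(100 + k)
        n = 80
        x = np.exp(r.normal(size=(n, 10)))
        y = r.normal(size=n)  # unrelated response
        tr, te = np.arange(0, 50), np.arange(50, 80)
        mtr = make_matrix(x[tr])
        model = fit_severity(mtr, _response(mtr, y[tr]), list(range(1, 11)))
        mte = IntensityMatrix(
            pd.DataFrame(x[te], index=[f"t{i}" for i in range(30)], columns=range(1, 11))
        )
        ev = evaluate_severity(model, mte, pd.Series(y[te], index=mte.values.index))
        if abs(ev["spearman_r"]) < 0.35:
            weak += 1
    assert weak >= 9
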