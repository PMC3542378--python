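import numpy as np
import pandas as pd
import pytest

from pkdpeptidome.diagnostic import (
    DiagnosticModel,
    choose_cutoff,
    cv_auc_from_scores,
    score_samples,
    take_one_out_prune,
    train_svm,
)
from pkdpeptidome.evaluation import roc_auc
from tests.conftest import make_matrix


def _separable(n=10, gap=4.0, rng=None):
    rng = rng or np.random.default_rng(1)
    X = np.exp(rng.normal(3.0, 0.3, size=(2 * n, 2)))
    X[:n] *= np.exp(gap)
    labels = ["ADPKD"] * n + ["healthy"] * n
    return make_matrix(X, labels)


def test_separable_training_auc_one():
    m = _separable()
    model, cv_scores = train_svm(
        m, C_grid=[1.0, 10.0], gamma_grid=["scale"], cv=5
    )
    scores = score_samples(model, m)
    case = scores[m.labels == "ADPKD"]
    ctrl = scores[m.labels == "healthy"]
    assert case.min() > ctrl.max()
    auc, _, _ = roc_auc(scores, m.labels)
    assert auc == 1.0


def test_label_negation_negates_scores():
    rng = np.random.default_rng(5)
    m = _separable(n=10, gap=1.0, rng=rng)
    flipped = pd.Series(
        np.where(m.labels == "ADPKD", "healthy", "ADPKD"), index=m.labels.index
    )
    kw = dict(C_grid=[10.0], gamma_grid=[0.5], cv=5)
    model_a, _ = train_svm(m, **kw)
    model_b, _ = train_svm(m, labels=flipped, positive="healthy", **kw)
    # same optimization with classes renamed: identical hyperplane, but the
    # "positive" side is the other class
    sa = score_samples(model_a, m)
    sb = score_samples(model_b, m)
    np.testing.assert_allclose(sa, sb, atol=1e-6)
    model_c, _ = train_svm(m, labels=flipped, positive="ADPKD", **kw)
    sc = score_samples(model_c, m)
    np.testing.assert_allclose(sa, -sc, atol=1e-6)


def test_scores_invariant_to_extra_columns_and_marker_order():
    m = _separable()
    model, _ = train_svm(m, C_grid=[10.0], gamma_grid=[0.5], cv=5)
    base = score_samples(model, m)
    extra = m.values.copy()
    extra[99] = 123.0  # unrelated peptide column
    m2 = make_matrix(extra.to_numpy(), list(m.labels))
    m2.values.columns = list(extra.columns)
    np.testing.assert_allclose(score_samples(model, m2), base, atol=0)

    model_rev, _ = train_svm(
        m, markers=list(m.peptide_ids)[::-1], C_grid=[10.0], gamma_grid=[0.5], cv=5
    )
    np.testing.assert_allclose(score_samples(model_rev, m), base, atol=1e-9)


def test_missing_marker_column_errors():
    m = _separable()
    model, _ = train_svm(m, C_grid=[10.0], gamma_grid=[0.5], cv=5)
    short = make_matrix(m.values[[1]].to_numpy(), list(m.labels))
    with pytest.raises(KeyError, match="2"):
        score_samples(model, short)


def test_training_scores_match_stored_decision_values():
    m = _separable(gap=1.0)
    model, _ = train_svm(m, C_grid=[10.0], gamma_grid=[0.5], cv=5)
    Xt = model.transform(m)
    np.testing.assert_allclose(
        score_samples(model, m).to_numpy(),
        model.decision_values(Xt) / model.w_norm,
        atol=1e-12,
    )


def test_boundary_crossing_scores_zero():
    """The score is a signed hyperplane distance: on a segment between a
    positive- and a negative-scoring point there is a zero crossing."""
    m = _separable(gap=1.5)
    model, _ = train_svm(m, C_grid=[10.0], gamma_grid=[0.5], cv=5)
    Xt = model.transform(m)
    s = model.score_transformed(Xt)
    hi, lo = Xt[np.argmax(s)], Xt[np.argmin(s)]
    f = lambda t: model.score_transformed(((1 - t) * lo + t * hi)[None, :])[0]
    a, b = 0.0, 1.0
    for _ in range(80):
        mid = (a + b) / 2
        if f(mid) < 0:
            a = mid
        else:
            b = mid
    assert abs(f((a + b) / 2)) < 1e-9


def test_model_json_round_trip(tmp_path):
    m = _separable()
    model, _ = train_svm(m, C_grid=[10.0], gamma_grid=[0.5], cv=5)
    model.cutoff = 0.12
    path = tmp_path / "model.json"
    model.to_json(path)
    back = DiagnosticModel.from_json(path)
    np.testing.assert_allclose(
        score_samples(back, m), score_samples(model, m), atol=0
    )
    assert back.cutoff == model.cutoff


def test_single_class_errors():
    X = np.ones((12, 2))
    m = make_matrix(X, ["ADPKD"] * 12)
    with pytest.raises(ValueError):
        train_svm(m, C_grid=[1.0], gamma_grid=[0.1], cv=5)


def test_choose_cutoff_midpoint_example():
    scores = np.array([0.8, 0.9, 0.1, 0.2])
    labels = ["ADPKD", "ADPKD", "healthy", "healthy"]
    assert choose_cutoff(scores, labels) == pytest.approx(0.5)


def test_choose_cutoff_matches_exhaustive_scan(rng):
    for _ in range(25):
        n = int(rng.integers(6, 25))
        scores = rng.normal(size=n).round(2)  # force ties sometimes
        y = rng.integers(0, 2, size=n)
        if y.sum() in (0, n):
            continue
        cut = choose_cutoff(scores, y)
        n1, n0 = y.sum(), n - y.sum()

        def j_at(c):
            call = scores >= c
            return (call & (y == 1)).sum() / n1 + (~call & (y == 0)).sum() / n0 - 1

        best = max(j_at(c) for c in np.concatenate([scores - 1e-9, scores + 1e-9]))
        assert j_at(cut) == pytest.approx(best, abs=1e-12)


def test_perfect_separation_cutoff():
    scores = np.array([1.0, 2.0, 3.0, -1.0, -2.0])
    y = [1, 1, 1, 0, 0]
    cut = choose_cutoff(scores, y)
    call = scores >= cut
    assert call.tolist() == [True, True, True, False, False]


def test_prune_target_size_equal_panel_returns_input(small_matrix):
    matrix, truth = small_matrix
    markers = [int(i) for i in truth.marker_ids[:5]]
    panel, traj = take_one_out_prune(
        matrix, markers=markers, target_size=len(markers), cv=5
    )
    assert panel == markers
    assert len(traj) == 1


def test_prune_target_too_large_errors(small_matrix):
    matrix, truth = small_matrix
    markers = [int(i) for i in truth.marker_ids[:4]]
    with pytest.raises(ValueError):
        take_one_out_prune(matrix, markers=markers, target_size=10, cv=5)


def test_prune_duplicated_feature_removed_first():
    rng = np.random.default_rng(3)
    n = 30
    y = ["ADPKD"] * 12 + ["healthy"] * 18
    base = np.exp(rng.normal(4, 0.7, size=(n, 3)))
    base[:12, :3] *= np.exp(1.5)
    X = np.column_stack([base, base[:, 0]])  # column 4 duplicates column 1
    m = make_matrix(X, y)
    panel, _ = take_one_out_prune(m, markers=[1, 2, 3, 4], target_size=3, cv=5)
    assert not {1, 4} <= set(panel)  # at most one copy survives


def test_prune_trajectory_monotone_without_target(small_matrix):
    matrix, truth = small_matrix
    markers = [int(i) for i in truth.marker_ids[:6]]
    _, traj = take_one_out_prune(matrix, markers=markers, cv=5)
    aucs = [a for _, a in traj]
    assert all(b >= a for a, b in zip(aucs, aucs[1:]))


def test_pruner_auc_consistent_with_evaluation_auc():
    from pkdpeptidome.diagnostic import _fit_transform, cross_val_scores, resolve_gamma

    m = _separable(gap=0.8)
    y = (m.labels == "ADPKD").astype(int).to_numpy()
    Xt, *_ = _fit_transform(m.values.to_numpy())
    g = resolve_gamma("scale", Xt)
    scores = cross_val_scores(Xt, y, 10.0, g, cv="loo")
    assert cv_auc_from_scores(scores, y) == pytest.approx(
        roc_auc(scores, y)[0], abs=1e-12
    )
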