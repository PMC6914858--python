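"""LDA, leave-one-repetition-out CV, and the paired t-test."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from fmg_chansel import loocv_accuracy, paired_t_test
from fmg_chansel.classification import (
    discriminant_scores,
    fit_count,
    lda_fit,
    lda_predict,
    reset_fit_counter,
)
from conftest import make_gesture_coded_dataset
from oracles import sign_flip_p


def test_well_separated_1d_classes():
    rng = np.random.default_rng(0)
    X = np.concatenate([rng.normal(0, 1, 200), rng.normal(10, 1, 200)])[:, None]
    y = np.array(["a"] * 200 + ["b"] * 200, dtype=object)
    model = lda_fit(X[::2], y[::2])
    acc = np.mean(lda_predict(model, X[1::2]) == y[1::2])
    assert acc >= 0.99


def test_equal_class_means_accuracy_near_max_prior():
    accs = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, size=(300, 3))
        y = np.array(["a"] * 200 + ["b"] * 100, dtype=object)  # prior 2/3
        model = lda_fit(X[::2], y[::2])
        accs.append(np.mean(lda_predict(model, X[1::2]) == y[1::2]))
    assert abs(np.mean(accs) - 2 / 3) < 0.05


def test_collinear_duplicate_channel_fits_with_ridge():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(100, 2))
    X = np.hstack([X, X[:, :1]])  # duplicate column
    y = np.array(["a", "b"] * 50, dtype=object)
    model = lda_fit(X, y, reg=1e-6)
    assert np.all(np.isfinite(model.precision))


def test_single_class_and_constant_input_error():
    X = np.ones((10, 2))
    with pytest.raises(ValueError, match="two classes"):
        lda_fit(X, ["a"] * 10)
    with pytest.raises(ValueError, match="all-constant"):
        lda_fit(X, ["a", "b"] * 5)


def test_predict_matches_hand_computed_discriminant():
    """2-class 2-D worked example against the explicit Gaussian formula."""
    Xa = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    Xb = Xa + np.array([3.0, 1.0])
    X = np.vstack([Xa, Xb])
    y = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
    model = lda_fit(X, y, reg=0.0)
    # hand computation: pooled covariance of the two shifted grids
    mu_a, mu_b = Xa.mean(0), Xb.mean(0)
    S = ((Xa - mu_a).T @ (Xa - mu_a) + (Xb - mu_b).T @ (Xb - mu_b)) / (8 - 2)
    W = np.linalg.inv(S)
    q = np.array([2.0, 0.3])
    g_a = q @ W @ mu_a - 0.5 * mu_a @ W @ mu_a + np.log(0.5)
    g_b = q @ W @ mu_b - 0.5 * mu_b @ W @ mu_b + np.log(0.5)
    scores = discriminant_scores(model, q)
    np.testing.assert_allclose(scores[0], [g_a, g_b], atol=1e-10)
    assert lda_predict(model, q)[0] == ("a" if g_a >= g_b else "b")


def test_prediction_tie_breaks_to_lowest_class_index():
    X = np.array([[0.0], [2.0]] * 5)
    y = np.array(["a", "b"] * 5, dtype=object)
    model = lda_fit(X, y)
    assert lda_predict(model, np.array([[1.0]]))[0] == "a"  # exact midpoint


def test_permuting_rows_permutes_predictions():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(60, 3))
    y = np.array(["a", "b", "c"] * 20, dtype=object)
    model = lda_fit(X, y)
    Q = rng.normal(size=(20, 3))
    perm = rng.permutation(20)
    np.testing.assert_array_equal(lda_predict(model, Q)[perm], lda_predict(model, Q[perm]))


def test_agrees_with_sklearn_lda_on_well_conditioned_data():
    """Independent cross-check: same decision rule up to regularization."""
    rng = np.random.default_rng(3)
    X = np.vstack([rng.normal(m, 1.0, size=(150, 4)) for m in (0.0, 2.5, 5.0)])
    y = np.array(["a"] * 150 + ["b"] * 150 + ["c"] * 150, dtype=object)
    model = lda_fit(X, y, reg=1e-9)
    ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y.astype(str))
    Q = rng.normal(2.5, 2.0, size=(300, 4))
    agree = np.mean(lda_predict(model, Q) == ref.predict(Q))
    assert agree >= 0.98


def test_loocv_separable_channel(separable_toy):
    res = loocv_accuracy(separable_toy, [2])
    assert res.mean >= 0.99
    assert len(res.fold_accuracies) == 5  # one fold per repetition


def test_loocv_invariant_to_channel_order_and_row_shuffle(separable_toy):
    a = loocv_accuracy(separable_toy, [2, 0, 4])
    b = loocv_accuracy(separable_toy, [4, 2, 0])
    assert a.fold_accuracies == b.fold_accuracies
    # shuffle rows within repetitions
    rng = np.random.default_rng(0)
    order = np.concatenate(
        [rng.permutation(np.flatnonzero(separable_toy.repetition == r))
         for r in separable_toy.repetition_ids]
    )
    shuffled = separable_toy.select_rows(order)
    c = loocv_accuracy(shuffled, [2, 0, 4])
    assert np.allclose(sorted(a.fold_accuracies), sorted(c.fold_accuracies))


def test_loocv_permutation_null_is_chance():
    accs = []
    for seed in range(10):
        ds = make_gesture_coded_dataset(4, {1: 2.0}, seed=seed, samples_per_gesture=20)
        rng = np.random.default_rng(100 + seed)
        gest = ds.gesture.copy()
        for r in ds.repetition_ids:
            idx = np.flatnonzero(ds.repetition == r)
            gest[idx] = gest[rng.permutation(idx)]
        from dataclasses import replace
        shuffled = replace(ds, gesture=gest)
        accs.append(loocv_accuracy(shuffled, range(4)).mean)
    assert abs(np.mean(accs) - 1 / 6) < 0.05


def test_pure_noise_channel_barely_moves_accuracy(separable_toy):
    with_noise = loocv_accuracy(separable_toy, [2, 3])  # 3 is pure noise
    without = loocv_accuracy(separable_toy, [2])
    assert abs(with_noise.mean - without.mean) < 0.03


def test_loocv_confusion_row_sums_match_test_counts(small_synth):
    ds, _ = small_synth
    res = loocv_accuracy(ds, range(ds.n_channels))
    from fmg_chansel.dataio import GESTURES
    for gi, g in enumerate(GESTURES):
        assert res.confusion[gi].sum() == int(np.sum(ds.gesture == g))
    assert res.confusion.sum() == ds.n_samples


def test_loocv_empty_channels_rejected(small_synth):
    ds, _ = small_synth
    with pytest.raises(ValueError, match="empty"):
        loocv_accuracy(ds, [])


def test_fit_counter_counts_loocv_fits(separable_toy):
    reset_fit_counter()
    loocv_accuracy(separable_toy, [2])
    assert fit_count() == 5  # one fit per held-out repetition


def test_paired_t_identical_inputs_never_reject():
    a = [0.9, 0.8, 0.85, 0.95, 0.9]
    t, p, reject, degenerate = paired_t_test(a, a)
    assert not reject and degenerate and p == 1.0


def test_paired_t_large_shift_rejects():
    a = np.array([0.9, 0.8, 0.85, 0.95, 0.9])
    perturb = np.array([0.01, -0.01, 0.01, -0.01, 0.01])
    b = a - 0.30 + perturb
    t, p, reject, _ = paired_t_test(a, b)
    # mean diff ~0.3, sd ~0.011 -> t far beyond t_{0.975,4} = 2.776
    assert t > 2.776 and reject


def test_paired_t_close_to_sign_flip_oracle():
    rng = np.random.default_rng(7)
    for _ in range(5):
        a = rng.uniform(0.6, 0.9, size=5)
        b = a + rng.normal(0.05, 0.05, size=5)
        _, p, _, _ = paired_t_test(a, b)
        assert abs(p - sign_flip_p(a - b)) < 0.25  # 2^5 sign-flips: coarse grid


def test_paired_t_input_validation():
    with pytest.raises(ValueError):
        paired_t_test([0.5], [0.4])
    with pytest.raises(ValueError):
        paired_t_test([0.5, 0.6], [0.4])
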