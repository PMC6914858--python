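"""Discretization, mutual information, and the mRMR (MIQ) ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fmg_chansel import discretize, mrmr_rank, mutual_information
from fmg_chansel.classification import fit_count, reset_fit_counter
from conftest import make_gesture_coded_dataset
from oracles import mi_bruteforce, mrmr_bruteforce


def test_constant_channel_codes_all_ones():
    codes = discretize(np.full((20, 1), 3.7))
    assert np.all(codes == 1)


def test_three_point_channel_spans_all_codes():
    x = np.array([-10.0, 0.0, 10.0])[:, None]
    # mu = 0, sigma = sqrt(200/3) ~ 8.16: -10 < -sigma, 10 > +sigma
    np.testing.assert_array_equal(discretize(x)[:, 0], [0, 1, 2])


@given(
    scale=st.floats(0.1, 100.0),
    shift=st.floats(-50.0, 50.0),
)
@settings(max_examples=30, deadline=None, derandomize=True)
def test_coding_invariant_under_affine_rescaling(scale, shift):
    rng = np.random.default_rng(0)
    x = rng.normal(size=(100, 2))
    np.testing.assert_array_equal(discretize(x), discretize(scale * x + shift))


def test_quantile_scheme_balanced_bins():
    x = np.arange(90, dtype=float)[:, None]
    codes = discretize(x, scheme="quantile", n_bins=3)
    assert sorted(np.bincount(codes[:, 0])) == [30, 30, 30]


def test_mi_independent_is_zero():
    x = np.repeat([0, 0, 1, 1], 25)
    y = np.tile([0, 1, 0, 1], 25)  # exact product of marginals
    assert mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)


def test_mi_identical_fair_coin_is_one_bit():
    x = np.array([0, 1] * 50)
    assert mutual_information(x, x) == pytest.approx(1.0, abs=1e-12)


def test_mi_matches_bruteforce_on_3x3_joint():
    rng = np.random.default_rng(5)
    x = rng.integers(0, 3, size=200)
    y = (x + rng.integers(0, 2, size=200)) % 3
    assert mutual_information(x, y) == pytest.approx(mi_bruteforce(x, y), abs=1e-12)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_mi_nonnegative_and_symmetric(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 4, size=60)
    y = rng.integers(0, 3, size=60)
    mi = mutual_information(x, y)
    assert mi >= -1e-12
    assert mi == pytest.approx(mutual_information(y, x), abs=1e-12)


def test_mi_length_mismatch_errors():
    with pytest.raises(ValueError):
        mutual_information([0, 1], [0, 1, 2])


def test_informative_channel_ranked_first():
    ds = make_gesture_coded_dataset(6, {3: 3.0}, noise=0.3, seed=1)
    state = mrmr_rank(ds)
    assert state.selected[0] == 3


def test_duplicate_of_top_channel_ranked_behind_informatives():
    """A redundant copy scores zero quotient advantage once its twin is in."""
    ds = make_gesture_coded_dataset(4, {0: 3.0, 2: 2.0, 3: 1.5}, noise=0.3, seed=2)
    dup_values = ds.values.copy()
    dup_values[:, 1] = dup_values[:, 0]  # channel 1 = exact duplicate of 0
    from dataclasses import replace
    ds = replace(ds, values=dup_values)
    state = mrmr_rank(ds)
    assert state.selected[0] == 0
    assert state.selected.index(1) > max(state.selected.index(c) for c in (2, 3))
    # exhaustive re-evaluation of the greedy quotient rule agrees
    codes = discretize(ds.values)
    assert state.selected == mrmr_bruteforce(codes, ds.gesture.astype(str))


def test_ranking_matches_bruteforce_oracle(tiny_synth):
    ds, _ = tiny_synth
    state = mrmr_rank(ds)
    codes = discretize(ds.values)
    assert state.selected == mrmr_bruteforce(codes, ds.gesture.astype(str))
    assert len(state.selected) == ds.n_channels
    assert len(set(state.selected)) == ds.n_channels


def test_ranking_base_invariant():
    """MIQ is a quotient: the MI log base cancels out of the ranking."""
    import math

    ds = make_gesture_coded_dataset(5, {0: 2.5, 2: 1.5}, noise=0.4, seed=3)
    state = mrmr_rank(ds)
    codes = discretize(ds.values)
    nats = mrmr_bruteforce(
        codes, ds.gesture.astype(str), mi=lambda x, y: mi_bruteforce(x, y, base=math.e)
    )
    assert state.selected == nats


def test_mrmr_performs_zero_classifier_fits(tiny_synth):
    ds, _ = tiny_synth
    reset_fit_counter()
    mrmr_rank(ds)
    assert fit_count() == 0


def test_permuting_columns_permutes_ranking(tiny_synth):
    from dataclasses import replace

    ds, _ = tiny_synth
    perm = [3, 0, 5, 1, 4, 2]  # new column j holds old channel perm[j]
    permuted = replace(
        ds,
        values=ds.values[:, perm],
        channel_ids=tuple(ds.channel_ids[p] for p in perm),
    )
    orig = mrmr_rank(ds).selected
    new = mrmr_rank(permuted).selected
    assert [perm[j] for j in new] == orig


def test_training_reps_restriction(small_synth):
    ds, _ = small_synth
    full = mrmr_rank(ds)
    partial = mrmr_rank(ds, reps=[1, 2])
    assert len(partial.selected) == ds.n_channels
    assert full.relevance.shape == partial.relevance.shape


def test_single_channel_rejected(separable_toy):
    from dataclasses import replace

    ds = replace(separable_toy, values=separable_toy.values[:, :1], channel_ids=("c0",))
    with pytest.raises(ValueError, match="two channels"):
        mrmr_rank(ds)
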