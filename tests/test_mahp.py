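import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mahpselect import (AlignmentError, DegenerateDataError,
                        build_comparison_matrix, family_scores,
                        principal_eigenpair, select_top, trait_weights,
                        transform_lower_better)

nonzero_floats = st.floats(
    min_value=0.05, max_value=50, allow_nan=False, allow_infinity=False
)


# -- direction transform ----------------------------------------------


def test_transform_reflects_about_maximum():
    np.testing.assert_allclose(transform_lower_better([3.0, 1.0, 2.0]), [0.0, 2.0, 1.0])


def test_transform_constant_vector_all_zero():
    np.testing.assert_allclose(transform_lower_better([4.0, 4.0]), [0.0, 0.0])


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(-100, 100), min_size=1, max_size=10))
def test_transform_output_max_is_input_range(values):
    out = transform_lower_better(values)
    assert out.min() == 0.0
    assert out.max() == pytest.approx(max(values) - min(values), abs=1e-9)


# -- comparison matrices ----------------------------------------------


def test_equal_values_give_all_ones_matrix():
    cm = build_comparison_matrix([1.0, 1.0, 1.0])
    np.testing.assert_allclose(cm.matrix, np.ones((3, 3)))


def test_ratio_entries():
    cm = build_comparison_matrix([1.0, 2.0, 4.0])
    a = cm.matrix
    assert a[0, 1] == pytest.approx(0.5)
    assert a[0, 2] == pytest.approx(0.25)
    assert a[1, 2] == pytest.approx(0.5)
    np.testing.assert_allclose(a * a.T, np.ones((3, 3)))  # reciprocal
    np.testing.assert_allclose(np.diag(a), 1.0)


@settings(derandomize=True, max_examples=40)
@given(st.lists(nonzero_floats, min_size=2, max_size=6))
def test_cascade_consistency(values):
    """A_ij * A_jk == A_ik for every generated matrix (ratio algebra)."""
    a = build_comparison_matrix(values).matrix
    n = len(values)
    for i, j, k in itertools.product(range(n), repeat=3):
        assert a[i, j] * a[j, k] == pytest.approx(a[i, k], rel=1e-9)


def test_zero_entry_rejected():
    with pytest.raises(ZeroDivisionError):
        build_comparison_matrix([1.0, 0.0, 2.0])


# -- principal eigenpair ----------------------------------------------


def test_all_ones_matrix_eigenpair():
    lam, x = principal_eigenpair(np.ones((4, 4)))
    assert lam == 4.0
    np.testing.assert_allclose(x, np.full(4, 0.5))


def test_zero_vector_is_degenerate():
    with pytest.raises(DegenerateDataError):
        principal_eigenpair(np.zeros(3))


@settings(derandomize=True, max_examples=40)
@given(
    st.lists(
        st.floats(0.05, 50).flatmap(
            lambda m: st.sampled_from([m, -m])
        ),
        min_size=2,
        max_size=8,
    )
)
def test_eigenpair_matches_dense_solver(values):
    """The direct path (normalize the generating vector) agrees with a
    generic eigendecomposition of the materialized matrix to 1e-9."""
    v = np.asarray(values)
    cm = build_comparison_matrix(v)
    lam, x = principal_eigenpair(cm)
    w, vecs = np.linalg.eig(cm.matrix)
    k = int(np.argmax(w.real))
    assert lam == pytest.approx(w[k].real, abs=1e-9)
    ref = vecs[:, k].real
    ref = ref / np.linalg.norm(ref)
    if ref @ v < 0:
        ref = -ref
    np.testing.assert_allclose(x, ref, atol=1e-9)
    assert np.linalg.norm(x) == pytest.approx(1.0, abs=1e-12)


def test_eigenpair_accepts_matrix_and_vector_equivalently():
    v = np.array([3.0, 1.5, 0.5])
    lam_v, x_v = principal_eigenpair(v)
    lam_m, x_m = principal_eigenpair(build_comparison_matrix(v).matrix)
    assert lam_v == lam_m == 3.0
    np.testing.assert_allclose(x_v, x_m, atol=1e-12)


# -- trait weights ----------------------------------------------------


def test_single_parameter_345_normalization():
    table = pd.DataFrame({"p": [3.0, 4.0]}, index=["a", "b"])
    wt = trait_weights(table)
    np.testing.assert_allclose(wt.eigen_entries["p"], [0.6, 0.8])
    np.testing.assert_allclose(wt.final_weight, [0.6, 0.8])


def test_columns_unit_norm_and_weights_are_row_sums():
    rng = np.random.default_rng(2)
    table = pd.DataFrame(
        rng.normal(0, 2, size=(6, 4)) + 0.1,
        index=list("abcdef"),
        columns=list("wxyz"),
    )
    wt = trait_weights(table)
    norms = np.linalg.norm(wt.eigen_entries.values, axis=0)
    np.testing.assert_allclose(norms, 1.0, atol=1e-9)
    np.testing.assert_allclose(
        wt.final_weight.values, wt.eigen_entries.values.sum(axis=1), atol=1e-9
    )


def test_lower_better_parameter_is_reflected():
    table = pd.DataFrame({"p": [1.0, 3.0]}, index=["a", "b"])
    wt = trait_weights(table, directions={"p": "lower_better"})
    # (1,3) -> (2,0) -> (1,0)
    np.testing.assert_allclose(wt.eigen_entries["p"], [1.0, 0.0])


def test_negative_parameter_values_pass_through():
    table = pd.DataFrame({"p": [-3.0, 4.0]}, index=["a", "b"])
    wt = trait_weights(table)
    np.testing.assert_allclose(wt.eigen_entries["p"], [-0.6, 0.8])


def test_zero_parameter_column_is_error():
    table = pd.DataFrame({"p": [0.0, 0.0]}, index=["a", "b"])
    with pytest.raises(DegenerateDataError):
        trait_weights(table)


def test_weight_monotone_in_own_parameter_value():
    """Raising one trait's value for one positive parameter never lowers
    that trait's final weight."""
    rng = np.random.default_rng(3)
    base = pd.DataFrame(
        rng.uniform(0.5, 5, size=(5, 3)), index=list("abcde"), columns=list("xyz")
    )
    w0 = trait_weights(base).final_weight["c"]
    for bump in (0.5, 1.0, 3.0):
        table = base.copy()
        table.loc["c", "y"] += bump
        assert trait_weights(table).final_weight["c"] >= w0 - 1e-12


# -- family scores and selection --------------------------------------


def test_single_trait_unit_weight_scores():
    tm = pd.DataFrame({"t": [3.0, 4.0]}, index=["f1", "f2"])
    wt = trait_weights(pd.DataFrame({"p": [1.0]}, index=["t"]))
    st_ = family_scores(tm, wt)
    np.testing.assert_allclose(st_.score, [0.6, 0.8])


def test_scores_match_weighted_sum_oracle():
    tm = pd.DataFrame(
        {"t1": [1.0, 2.0, 3.0], "t2": [5.0, 1.0, 2.0]}, index=["f1", "f2", "f3"]
    )
    weights = pd.Series({"t1": 2.0, "t2": -1.0})
    st_ = family_scores(tm, weights)
    e1 = tm["t1"] / np.linalg.norm(tm["t1"])
    e2 = tm["t2"] / np.linalg.norm(tm["t2"])
    np.testing.assert_allclose(st_.score, 2.0 * e1 - 1.0 * e2, atol=1e-12)


def test_scores_invariant_to_trait_column_scaling():
    tm = pd.DataFrame(
        {"t1": [1.0, 2.0, 3.0], "t2": [5.0, 1.0, 2.0]}, index=["f1", "f2", "f3"]
    )
    weights = pd.Series({"t1": 1.0, "t2": 0.5})
    base = family_scores(tm, weights).score
    scaled = family_scores(tm.assign(t1=tm["t1"] * 7.5), weights).score
    np.testing.assert_allclose(base, scaled, atol=1e-12)


def test_lower_better_trait_reflected_in_scoring():
    tm = pd.DataFrame({"t": [1.0, 3.0]}, index=["f1", "f2"])
    weights = pd.Series({"t": 1.0})
    st_ = family_scores(tm, weights, {"t": "lower_better"})
    np.testing.assert_allclose(st_.score, [1.0, 0.0])


def test_misaligned_traits_is_error():
    tm = pd.DataFrame({"t1": [1.0, 2.0]}, index=["f1", "f2"])
    with pytest.raises(AlignmentError):
        family_scores(tm, pd.Series({"t2": 1.0}))


def test_select_all_with_fraction_one():
    s = pd.Series({"f1": 0.2, "f2": 0.9, "f3": 0.5})
    out = select_top(s, fraction=1.0)
    assert out["selected"].all()
    assert out["family"].tolist() == ["f2", "f3", "f1"]
    assert out["rank"].tolist() == [1, 2, 3]


def test_fraction_count_is_ceiling():
    s = pd.Series({f"f{i}": float(i) for i in range(7)})
    assert int(select_top(s, fraction=0.3)["selected"].sum()) == 3  # ceil(2.1)


def test_tie_policy_exhaustive_on_three_families():
    """Ties are broken by input order, checked for every score triple over
    a two-value alphabet and both selection counts."""
    for scores in itertools.product([1.0, 2.0], repeat=3):
        s = pd.Series(dict(zip(["a", "b", "c"], scores)))
        for count in (1, 2, 3):
            out = select_top(s, count=count)
            # sorted stably by descending score: among equal scores input
            # order is preserved
            expected = sorted(
                ["a", "b", "c"], key=lambda f: (-s[f], ["a", "b", "c"].index(f))
            )
            assert out["family"].tolist() == expected
            assert int(out["selected"].sum()) == count
            # two equal top scores both retained when count >= 2
            top_score = max(scores)
            n_top = scores.count(top_score)
            if count >= n_top:
                sel = set(out.loc[out["selected"], "family"])
                assert {f for f in "abc" if s[f] == top_score} <= sel


def test_select_parameter_validation():
    s = pd.Series({"a": 1.0, "b": 2.0})
    with pytest.raises(ValueError):
        select_top(s)
    with pytest.raises(ValueError):
        select_top(s, fraction=0.5, count=1)
    with pytest.raises(ValueError):
        select_top(s, fraction=1.5)
    with pytest.raises(ValueError):
        select_top(s, count=3)
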