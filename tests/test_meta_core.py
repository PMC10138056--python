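"""Unit and property tests for the pooling layer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest, norm
from statsmodels.stats.meta_analysis import combine_effects

from metapick import (
    InputError,
    Study,
    StudySet,
    compute_weights,
    dersimonian_laird_tau2,
    i_squared_typical,
    pool,
    pooled_p_value,
    study_p_value,
)

RTOL = 1e-9


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "variances, tau2, expected",
    [
        ([0.25], 0.0, [4.0]),
        ([0.25], 0.25, [2.0]),
        ([0.1, 0.2, 0.4], 0.0, [10.0, 5.0, 2.5]),
    ],
)
def test_inverse_variance_weights(variances, tau2, expected):
    ss = StudySet.from_arrays(np.zeros(len(variances)), variances)
    w = compute_weights(ss, tau2)
    assert list(w) == list(ss.labels)
    np.testing.assert_allclose(list(w.values()), expected, rtol=RTOL)


def test_zero_tau2_reproduces_fixed_weights_exactly(rng):
    var = rng.uniform(0.01, 2.0, 20)
    ss = StudySet.from_arrays(np.zeros(20), var)
    assert compute_weights(ss, 0.0) == compute_weights(ss)


def test_nonpositive_variance_rejected_with_label():
    with pytest.raises(InputError, match="bad"):
        StudySet([Study("ok", 0.0, 1.0), Study("bad", 0.0, -1.0)])
    with pytest.raises(InputError, match="s2"):
        StudySet.from_arrays([0.0, 0.0], [1.0, 0.0])


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def test_pool_single_study(single_study):
    res = pool(single_study, model="fixed", alpha=0.05)
    assert res.theta_hat == pytest.approx(0.5, rel=RTOL)
    assert res.se == pytest.approx(0.5, rel=RTOL)
    assert res.ci_low == pytest.approx(-0.48, abs=0.01)
    assert res.ci_high == pytest.approx(1.48, abs=0.01)
    assert res.tau2 == 0.0


def test_pool_equal_weight_mean():
    ss = StudySet.from_arrays([0.2, 0.4], [1.0, 1.0])
    assert pool(ss).theta_hat == pytest.approx(0.3, rel=RTOL)


def test_pool_weighted_average():
    ss = StudySet.from_arrays([1.0, 0.0, -0.5], [0.1, 0.2, 0.4])
    assert pool(ss).theta_hat == pytest.approx(8.75 / 17.5, rel=RTOL)


def test_pool_matches_statsmodels_fixed(rng):
    eff = rng.normal(0, 1, 8)
    var = rng.uniform(0.05, 1.0, 8)
    ours = pool(StudySet.from_arrays(eff, var))
    sm = combine_effects(eff, var, method_re="dl")
    assert ours.theta_hat == pytest.approx(float(sm.mean_effect_fe), rel=1e-8)


def test_pool_rejects_bad_inputs(single_study):
    with pytest.raises(InputError):
        pool(single_study, model="bayes")
    with pytest.raises(InputError):
        pool(single_study, alpha=0.0)
    with pytest.raises(InputError):
        pool(single_study, model="fixed", tau2_override=0.3)
    with pytest.raises(InputError):
        StudySet([])


# ---------------------------------------------------------------------------
# p-values
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "effect, weight, expected, tol",
    [
        (0.0, 4.0, 0.5, 1e-12),
        (1.6449, 1.0, 0.05, 1e-4),
        (0.98, 4.0, 0.025, 1e-4),
    ],
)
def test_single_study_p_value(effect, weight, expected, tol):
    p = study_p_value(Study("x", effect, 1.0), weight)
    assert p == pytest.approx(expected, abs=tol)


def test_study_p_value_decreasing_in_effect():
    effs = np.linspace(-2, 2, 21)
    ps = [study_p_value(Study("x", e, 1.0), 2.5) for e in effs]
    assert all(a > b for a, b in zip(ps, ps[1:]))


def test_pooled_p_examples():
    # zero pooled estimate -> one half
    ss = StudySet.from_arrays([1.0, -1.0], [0.5, 0.5])
    assert pool(ss).p_one_sided == pytest.approx(0.5, rel=RTOL)
    # equal unit weights, both effects 1: Phi(-sqrt(2))
    ss2 = StudySet.from_arrays([1.0, 1.0], [1.0, 1.0])
    assert pool(ss2).p_one_sided == pytest.approx(float(norm.cdf(-np.sqrt(2))), rel=RTOL)
    assert pool(ss2).p_one_sided == pytest.approx(0.0786, abs=5e-4)


def test_pooled_p_reduces_to_study_p_for_single_study(single_study):
    res = pool(single_study)
    w = 1.0 / single_study.variances[0]
    assert res.p_one_sided == pytest.approx(
        study_p_value(single_study[0], w), rel=RTOL
    )


def test_sided_variants(single_study):
    res = pool(single_study)
    right = pooled_p_value(res, "right")
    left = pooled_p_value(res, "left")
    two = pooled_p_value(res, "two")
    assert right + left == pytest.approx(1.0, rel=RTOL)
    assert two == pytest.approx(2 * min(right, left), rel=RTOL)
    with pytest.raises(InputError):
        pooled_p_value(res, "both")


# ---------------------------------------------------------------------------
# DerSimonian-Laird
# ---------------------------------------------------------------------------

def test_dl_identical_effects_give_zero():
    ss = StudySet.from_arrays([0.7, 0.7, 0.7], [0.3, 0.5, 0.2])
    assert dersimonian_laird_tau2(ss) == 0.0


def test_dl_truncation_at_zero():
    ss = StudySet.from_arrays([0.0, 1.0], [1.0, 1.0])
    assert dersimonian_laird_tau2(ss) == 0.0


def test_dl_hand_example():
    ss = StudySet.from_arrays([0.0, 2.0], [1.0, 1.0])
    assert dersimonian_laird_tau2(ss) == 1.0


def test_dl_single_study_is_zero_with_warning(single_study, caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="metapick.meta_core"):
        assert dersimonian_laird_tau2(single_study) == 0.0
    assert any("single study" in r.message for r in caplog.records)


def test_dl_matches_statsmodels(rng):
    for _ in range(20):
        k = int(rng.integers(2, 10))
        eff = rng.normal(0, 1.5, k)
        var = rng.uniform(0.05, 1.0, k)
        ours = dersimonian_laird_tau2(StudySet.from_arrays(eff, var))
        sm = combine_effects(eff, var, method_re="dl")
        assert ours == pytest.approx(max(0.0, float(sm.tau2)), abs=1e-10)


# ---------------------------------------------------------------------------
# heterogeneity fraction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "tau2, s2, expected",
    [(0.0, 0.17, 0.0), (0.70, 0.17, 0.8046), (0.17, 0.17, 0.5)],
)
def test_i_squared_typical(tau2, s2, expected):
    assert i_squared_typical(tau2, s2) == pytest.approx(expected, abs=5e-5)


def test_i_squared_increasing_and_validated():
    vals = [i_squared_typical(t, 0.17) for t in (0.0, 0.1, 0.5, 0.7, 2.0)]
    assert all(a < b for a, b in zip(vals, vals[1:]))
    with pytest.raises(InputError):
        i_squared_typical(0.1, 0.0)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

study_lists = st.lists(
    st.tuples(
        st.floats(-10, 10, allow_nan=False),
        st.floats(0.01, 10, allow_nan=False),
    ),
    min_size=1,
    max_size=8,
)


@given(study_lists)
@settings(derandomize=True, max_examples=60, deadline=None)
def test_pooled_estimate_is_convex_combination(data):
    eff = [e for e, _ in data]
    ss = StudySet.from_arrays(eff, [v for _, v in data])
    th = pool(ss).theta_hat
    assert min(eff) - 1e-9 <= th <= max(eff) + 1e-9


@given(study_lists)
@settings(derandomize=True, max_examples=60, deadline=None)
def test_random_model_with_zero_tau2_equals_fixed(data):
    ss = StudySet.from_arrays([e for e, _ in data], [v for _, v in data])
    fixed = pool(ss, model="fixed")
    rand = pool(ss, model="random", tau2_override=0.0)
    assert rand.theta_hat == fixed.theta_hat
    assert rand.se == fixed.se
    assert rand.p_one_sided == fixed.p_one_sided


def test_null_pooled_p_values_are_uniform(rng):
    """Pooled one-sided p under theta=0, tau2=0, known variances ~ U(0,1)."""
    n, k = 10_000, 6
    var = rng.uniform(0.05, 0.5, (n, k))
    y = rng.normal(0.0, np.sqrt(var))
    w = 1.0 / var
    theta = (w * y).sum(axis=1) / w.sum(axis=1)
    p = norm.cdf(-theta * np.sqrt(w.sum(axis=1)))
    assert kstest(p, "uniform").pvalue > 0.001


def test_ci_coverage_under_null(rng):
    """95% CI covers the true effect in 95% +/- 1% of null replicates."""
    n, k = 10_000, 6
    var = rng.uniform(0.05, 0.5, (n, k))
    y = rng.normal(0.0, np.sqrt(var))
    w = 1.0 / var
    sw = w.sum(axis=1)
    theta = (w * y).sum(axis=1) / sw
    half = norm.ppf(0.975) / np.sqrt(sw)
    cover = ((theta - half <= 0) & (0 <= theta + half)).mean()
    assert cover == pytest.approx(0.95, abs=0.01)


def test_studyset_roundtrip_and_labels():
    ss = StudySet.from_arrays([0.1, 0.2], [1.0, 2.0])
    assert ss.labels == ("s1", "s2")
    assert [s.effect for s in ss] == [0.1, 0.2]
    sub = ss.subset([1])
    assert len(sub) == 1 and sub[0].variance == 2.0
    with pytest.raises(InputError, match="dup"):
        StudySet([Study("dup", 0.0, 1.0), Study("dup", 0.1, 1.0)])
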