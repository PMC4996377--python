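from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_pm
from taacgh.stats import (CONTROL_DRIVEN, TEST_DRIVEN, clone_level_test,
                          com_arm_test, compare_cohort_sections,
                          dominance_filter, fdr_adjust, mean_curve,
                          permutation_test, s_exp, truncation_K)


# ---------------------------------------------------------------- mean curve

def test_mean_curve_arithmetic_and_idempotence():
    assert np.array_equal(mean_curve(np.array([[3, 1, 1], [1, 1, 1]])), [2, 1, 1])
    c = np.array([4.0, 2.0, 1.0])
    assert np.array_equal(mean_curve(np.tile(c, (5, 1))), c)


def test_mean_curve_rejects_empty():
    with pytest.raises(ValueError):
        mean_curve([])


# ------------------------------------------------------------ K, S, direction

@pytest.mark.parametrize("t,c,K", [
    ((3, 1, 1), (2, 1, 1), 1),
    ((1, 1), (1, 1), 0),
    ((3, 2, 1.5), (2, 1.5, 1.2), 2),  # never jointly 1 -> last index
])
def test_truncation_index(t, c, K):
    assert truncation_K(np.array(t, float), np.array(c, float)) == K


def test_s_exp_direct_arithmetic():
    t = np.array([3.0, 2.0, 1.0, 1.0])
    c = np.array([2.0, 1.0, 1.0, 1.0])
    assert s_exp(t, c, 2) == pytest.approx(2.0)
    assert s_exp(t, t, 3) == 0.0


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.lists(st.floats(-5, 5, allow_nan=False, width=32), min_size=2,
                max_size=10), st.floats(0.5, 4))
def test_s_exp_quadratic_homogeneity(diffs, a):
    c = np.zeros(len(diffs))
    t = np.array(diffs)
    K = len(diffs) - 1
    assert s_exp(c + a * t, c, K) == pytest.approx(a * a * s_exp(t, c, K), rel=1e-9)


def test_dominance_direction():
    assert dominance_filter(np.array([3., 2, 1]), np.array([2., 1, 1]), 2) == TEST_DRIVEN
    assert dominance_filter(np.array([2., 1, 1]), np.array([3., 2, 1]), 2) == CONTROL_DRIVEN
    t = np.array([2.0, 1.0])
    assert dominance_filter(t, t, 1) == TEST_DRIVEN  # tie convention


# ------------------------------------------------------------------------ BH

def bh_closed_form(p):
    """min_{j>=i} m*p_(j)/j, capped at 1, mapped back to input order."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_bh_step_up_example():
    q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_single_and_tied_pvalues():
    assert fdr_adjust([0.3]) == pytest.approx([0.3])
    assert np.allclose(fdr_adjust([0.2, 0.2, 0.2]), 0.2)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.2])


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(0, 1, allow_nan=False, width=32), min_size=1,
                max_size=20))
def test_bh_matches_closed_form(pvals):
    assert np.allclose(fdr_adjust(pvals), bh_closed_form(pvals), atol=1e-12)
    assert np.all(fdr_adjust(pvals) >= np.asarray(pvals) - 1e-12)  # q >= p


# ----------------------------------------------------------- permutation test

def enumeration_oracle(curves, mask):
    """Brute-force exact permutation p with plain python loops."""
    nt = int(mask.sum())
    P = curves.shape[0]

    def stat(test_idx):
        t = curves[list(test_idx)].mean(axis=0)
        c = curves[[i for i in range(P) if i not in test_idx]].mean(axis=0)
        both = [k for k in range(t.size) if t[k] == 1 and c[k] == 1]
        K = both[0] if both else t.size - 1
        return sum((t[k] - c[k]) ** 2 for k in range(K + 1))

    s_obs = stat(tuple(np.flatnonzero(mask)))
    splits = list(combinations(range(P), nt))
    count = sum(stat(s) >= s_obs for s in splits)
    return s_obs, count / len(splits)


def test_exhaustive_permutation_matches_enumeration():
    rng = np.random.default_rng(0)
    curves = np.column_stack([rng.integers(1, 5, size=6).astype(float),
                              rng.integers(1, 3, size=6).astype(float),
                              np.ones(6)])
    mask = np.array([True] * 3 + [False] * 3)
    s_obs, p = permutation_test(curves, mask, exhaustive=True)
    s_ref, p_ref = enumeration_oracle(curves, mask)
    assert s_obs == pytest.approx(s_ref)
    assert p == pytest.approx(p_ref)


def test_identical_cohorts_give_zero_statistic_and_p_one():
    curves = np.tile(np.array([4.0, 2.0, 1.0]), (8, 1))
    mask = np.array([True] * 4 + [False] * 4)
    s_obs, p = permutation_test(curves, mask, B=99, seed=1)
    assert s_obs == 0.0
    assert p == 1.0


def test_sampled_p_never_zero_and_at_most_one():
    rng = np.random.default_rng(2)
    curves = rng.integers(1, 6, size=(10, 4)).astype(float)
    curves[:, -1] = 1.0
    mask = np.array([True] * 5 + [False] * 5)
    for seed in range(5):
        _, p = permutation_test(curves, mask, B=50, seed=seed)
        assert 0 < p <= 1


def test_degenerate_labels_rejected():
    curves = np.ones((4, 3))
    with pytest.raises(ValueError):
        permutation_test(curves, np.array([True] * 4), B=10)


# -------------------------------------------------------------- cohort engine

def test_null_fdr_controls_family_error_rate():
    """Under the global null, few runs show any q<0.05 test-driven section."""
    rng = np.random.default_rng(5)
    flagged = 0
    runs = 30
    for r in range(runs):
        values = rng.normal(0, 0.5, size=(40, 20))
        mask = np.array([True] * 10 + [False] * 10)
        sections = [np.arange(s, s + 10) for s in (0, 10, 20, 30)]
        table, _ = compare_cohort_sections(values, mask, sections, B=200,
                                           seed=rng)
        flagged += int(table["significant"].any())
    assert flagged / runs <= 0.15  # nominal ~2.5%, generous sampling margin


# ---------------------------------------------------------- clone-level test

def _sep_pm(delta):
    rng = np.random.default_rng(8)
    vals = rng.normal(0, 0.05, size=(5, 20))
    vals[2, :10] += delta  # clone 2 shifted in the test cohort
    return make_pm("1", "q", np.arange(5) * 1000, vals,
                   labels=["test"] * 10 + ["control"] * 10)


def test_complete_separation_called_gain_at_minimal_p():
    pm = _sep_pm(+1.0)
    res = clone_level_test(pm, np.arange(5), pm.label_mask("test"), B=999,
                           alpha=0.05, seed=0)
    assert res[2].call == "gain"
    assert res[2].p == pytest.approx(1 / 1000, abs=5e-3)
    assert res[2].mean_test > res[2].mean_control


def test_negative_shift_called_loss():
    pm = _sep_pm(-1.0)
    res = clone_level_test(pm, np.arange(5), pm.label_mask("test"), B=999,
                           alpha=0.05, seed=0)
    assert res[2].call == "loss"


def test_null_clones_rarely_called():
    rng = np.random.default_rng(9)
    pm = make_pm("1", "q", np.arange(20) * 1000,
                 rng.normal(0, 0.5, size=(20, 12)),
                 labels=["test"] * 6 + ["control"] * 6)
    res = clone_level_test(pm, np.arange(20), pm.label_mask("test"), B=400,
                           alpha=0.05, seed=1)
    called = sum(r.call != "not-significant" for r in res)
    assert called <= 4  # ~1 expected at alpha=0.05 over 20 clones


# ------------------------------------------------------------- arm COM test

def _arm_pm(test_shift, control_shift):
    rng = np.random.default_rng(10)
    vals = rng.normal(0, 0.1, size=(12, 16))
    vals[:, :8] += test_shift
    vals[:, 8:] += control_shift
    return make_pm("16", "q", np.arange(12) * 1000, vals,
                   labels=["test"] * 8 + ["control"] * 8)


def test_whole_arm_loss_detected():
    pm = _arm_pm(-0.5, 0.0)
    r = com_arm_test(pm, "16q", pm.label_mask("test"), B=999, seed=0)
    assert r.significant
    assert r.mean_com_test < r.mean_com_control


def test_origin_guard_drops_control_driven_displacement():
    pm = _arm_pm(0.0, -0.5)
    r = com_arm_test(pm, "16q", pm.label_mask("test"), B=999, seed=0)
    assert r.p_diff < 0.05 and r.p_origin > 0.05
    assert not r.significant


def test_no_displacement_not_significant():
    pm = _arm_pm(0.0, 0.0)
    r = com_arm_test(pm, "16q", pm.label_mask("test"), B=999, seed=0)
    assert not r.significant
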