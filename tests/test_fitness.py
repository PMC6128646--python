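"""GI scoring, robust standardization, tail-FDR and mutant calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from toxprof.fitness import (
    call_sensitive,
    classify_expressivity,
    gi_scores,
    relative_abundance,
    robust_z,
    score_screen,
    tail_fdr,
)
from toxprof.synthetic import PoolSimConfig, simulate_pool, simulate_screen_counts


# ---------------------------------------------------------------------------
# relative_abundance


@pytest.mark.parametrize(
    "counts, pc, expected",
    [
        ([10, 10, 20], 0.0, [0.25, 0.25, 0.5]),
        ([0, 10], 0.5, [0.5 / 11, 10.5 / 11]),
        ([7, 7, 7, 7], 0.0, [0.25] * 4),
    ],
)
def test_relative_abundance_examples(counts, pc, expected):
    np.testing.assert_allclose(relative_abundance(counts, pc), expected, rtol=1e-12)


def test_relative_abundance_rejects_all_zero_without_pseudocount():
    with pytest.raises(ValueError):
        relative_abundance([0, 0, 0], pseudocount=0.0)


# ---------------------------------------------------------------------------
# gi_scores


def test_gi_identity_and_hand_arithmetic():
    assert gi_scores([0.001], [0.001], 5.0)[0] == 0.0
    # an 8-fold depletion over 5 doublings is 0.6 per doubling
    np.testing.assert_allclose(gi_scores([0.001], [0.000125], 5.0), [0.6])


def test_gi_of_dead_mutant_is_near_one():
    """A non-grower at trace abundance scores ~1 over five pool doublings."""
    rho = np.ones(1000)
    rho[0] = 0.0
    c, t = simulate_pool(PoolSimConfig(n_mutants=1000, relative_growth_rates=rho))
    gi = gi_scores(c, t, 5.0)
    assert abs(gi[0] - 1.0) < 0.01


def test_gi_antisymmetry_and_doubling_rescale(rng):
    c = rng.dirichlet(np.ones(50))
    t = rng.dirichlet(np.ones(50))
    gi = gi_scores(c, t, 5.0)
    np.testing.assert_allclose(gi_scores(t, c, 5.0), -gi, atol=1e-14)
    np.testing.assert_allclose(gi_scores(c, t, 10.0), gi / 2.0, rtol=1e-12)


def test_gi_rejects_zero_frequency():
    with pytest.raises(ValueError, match="pseudocount"):
        gi_scores([0.5, 0.5], [0.0, 1.0], 5.0)


# ---------------------------------------------------------------------------
# robust_z


def test_robust_z_quantile_oracle():
    """(1..5): median 3, IQR 2, NIQR 2/1.349, so z(5) = 1.349."""
    z = robust_z(np.array([1.0, 2, 3, 4, 5]))
    np.testing.assert_allclose(z, [-1.349, -0.6745, 0.0, 0.6745, 1.349], rtol=1e-12)


@given(
    a=st.floats(min_value=0.01, max_value=100),
    b=st.floats(min_value=-50, max_value=50),
)
@settings(deadline=None, derandomize=True)
def test_robust_z_affine_invariance(a, b):
    x = np.array([0.1, -0.4, 2.2, 0.9, -1.3, 0.0, 3.1])
    np.testing.assert_allclose(robust_z(a * x + b), robust_z(x), atol=1e-8)


def test_robust_z_degenerate_inputs():
    with pytest.raises(ValueError):
        robust_z([1.0, 2.0, 3.0])  # too few values
    with pytest.raises(ValueError, match="degenerate"):
        robust_z([1.0, 1.0, 1.0, 1.0, 9.0])  # IQR zero


def test_robust_z_propagates_nan():
    z = robust_z([1.0, 2, 3, 4, 5, np.nan])
    assert np.isnan(z[-1]) and np.isfinite(z[:-1]).all()


# ---------------------------------------------------------------------------
# tail_fdr


def _bh_oracle(p, pi0=1.0):
    """Literal step-up envelope: q_i = min over p_j >= p_i of pi0*M*p_j/rank_j."""
    p = np.asarray(p)
    m = len(p)
    ranks = stats.rankdata(p, method="max")
    q = np.empty(m)
    for i in range(m):
        mask = p >= p[i]
        q[i] = np.min(pi0 * m * p[mask] / ranks[mask])
    return np.clip(q, 0, 1)


def test_tail_fdr_single_outlier():
    """One z=4 among 100: q = 100 * (1 - Phi(4)) / 1."""
    z = np.zeros(100)
    z[0] = 4.0
    q = tail_fdr(z)
    np.testing.assert_allclose(q[0], 100 * stats.norm.sf(4.0), rtol=1e-12)
    assert abs(q[0] - 3.17e-3) < 1e-4


def test_tail_fdr_full_tail_approaches_pi0():
    """The largest p (most-negative z) gets q = pi0 * p -> pi0 as p -> 1."""
    z = np.array([-8.0, 0.0, 1.0, 2.0])
    assert tail_fdr(z, pi0=0.8)[0] == pytest.approx(0.8, rel=1e-9)
    assert tail_fdr(z, pi0=1.0)[0] == pytest.approx(1.0, rel=1e-9)


@pytest.mark.parametrize("seed", range(10))
@pytest.mark.parametrize("size", [1, 2, 7, 23, 50])
def test_tail_fdr_matches_bruteforce_bh(seed, size):
    rng = np.random.default_rng(seed)
    z = rng.normal(0, 1.5, size)
    q = tail_fdr(z)
    np.testing.assert_allclose(q, _bh_oracle(stats.norm.sf(z)), rtol=1e-12)


def test_tail_fdr_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    z = np.random.default_rng(42).normal(0, 2, 200)
    q = tail_fdr(z)
    _, q_sm, _, _ = multipletests(stats.norm.sf(z), method="fdr_bh")
    np.testing.assert_allclose(q, q_sm, rtol=1e-10)


def test_tail_fdr_monotone_in_p():
    z = np.random.default_rng(1).normal(0, 1, 300)
    q = tail_fdr(z)
    order = np.argsort(stats.norm.sf(z))
    assert (np.diff(q[order]) >= -1e-15).all()


# ---------------------------------------------------------------------------
# calling and expressivity


def test_call_sensitive_rules():
    q = pd.DataFrame(
        {
            "s1": [0.05, 0.05, 0.5, 0.05, np.nan],
            "s2": [0.08, 0.5, 0.5, np.nan, np.nan],
        },
        index=list("abcde"),
    )
    q.loc["e", "s1"] = 0.01
    calls = call_sensitive(q, cutoff=0.1)
    assert calls.loc["a", "call"] == "sensitive_both"
    assert calls.loc["b", "call"] == "sensitive_one"
    assert calls.loc["c", "call"] == "not_sensitive"
    # single-screen coverage can at best be sensitive_one
    assert calls.loc["d", "call"] == "sensitive_one"
    assert calls.loc["e", "call"] == "sensitive_one"
    assert calls.loc["a", "selected"] and not calls.loc["b", "selected"]
    any_rule = call_sensitive(q, cutoff=0.1, rule="any")
    assert any_rule.loc["b", "selected"]


def test_classify_expressivity_thresholds():
    calls = pd.DataFrame({"call": ["sensitive_both", "sensitive_one", "not_sensitive"]})
    gi = pd.Series([0.9, 0.4, 0.8], index=calls.index)
    labels = classify_expressivity(calls, gi, thresholds=(0.3, 0.6))
    assert list(labels[:2]) == ["high", "medium"]
    assert pd.isna(labels[2])
    with pytest.raises(ValueError, match="ordered"):
        classify_expressivity(calls, gi, thresholds=(0.6, 0.3))


def test_classify_expressivity_default_tertiles():
    calls = pd.DataFrame({"call": ["sensitive_both"] * 9 + ["not_sensitive"]})
    gi = pd.Series(np.linspace(0.1, 0.9, 10), index=calls.index)
    labels = classify_expressivity(calls, gi)
    assert set(labels[:9]) == {"low", "medium", "high"}


# ---------------------------------------------------------------------------
# parameter recovery on a simulated screen


def test_planted_mutants_recovered_with_clean_margins():
    """30 planted half-fitness mutants among 2000 are called in both screens."""
    rng = np.random.default_rng(2024)
    rho = np.ones(2000)
    planted = rng.choice(2000, 30, replace=False)
    rho[planted] = 0.5
    pool = PoolSimConfig(n_mutants=2000, relative_growth_rates=rho)
    q_cols = {}
    for s in range(2):
        ctrl, trt = simulate_screen_counts(pool, 2_000_000, rng)
        scores = score_screen(ctrl, trt)
        q_cols[f"s{s}"] = scores["q"]
    calls = call_sensitive(pd.DataFrame(q_cols))
    hits = set(np.flatnonzero(calls["selected"].values))
    assert len(hits & set(planted)) >= 27  # >= 90% recall
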