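"""Unit and property tests for the exact 2x2 inference kernel.

Oracles: exact rational-arithmetic hypergeometric enumeration (math.comb +
Fraction), scipy's independent noncentral hypergeometric, dense grid search
on the conditional likelihood, and hand-computed reference values.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher
from scipy.stats import nchypergeom_fisher

from pgxdili.exact_stats import (
    Table2x2,
    bh_fdr,
    cmle_or,
    cochran_armitage_trend,
    exact_ci,
    exact_result,
    fisher_exact_two_sided,
    hwe_exact_p,
    nchg_logpmf_vector,
    nchg_mean,
    nchg_pmf,
    nchg_support,
    predictive_values,
)

# ---------------------------------------------------------------- oracles


def exact_hypergeom_pmf(n1, n2, m):
    """Central hypergeometric pmf over the support, in exact rationals."""
    lo, hi = max(0, m - n2), min(n1, m)
    weights = [Fraction(math.comb(n1, k) * math.comb(n2, m - k)) for k in range(lo, hi + 1)]
    total = sum(weights)
    return lo, [w / total for w in weights]


def fisher_p_oracle(t: Table2x2) -> Fraction:
    lo, probs = exact_hypergeom_pmf(t.n_cases, t.n_controls, t.n_exposed)
    p_obs = probs[t.a - lo]
    return sum(p for p in probs if p <= p_obs)


def hwe_p_oracle(n_aa, n_ab, n_bb) -> Fraction:
    """Exact HWE P by enumerating heterozygote counts of matching parity."""
    n = n_aa + n_ab + n_bb
    nb = 2 * n_bb + n_ab
    na = 2 * n - nb
    probs = {}
    for het in range(nb % 2, min(na, nb) + 1, 2):
        bb = (nb - het) // 2
        aa = (na - het) // 2
        probs[het] = Fraction(
            math.factorial(n) * 2**het,
            math.factorial(aa) * math.factorial(het) * math.factorial(bb),
        )
    total = sum(probs.values())
    p_obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= p_obs) / total


# ------------------------------------------------------------ pmf kernel


@pytest.mark.parametrize("psi", [0.1, 1.0, 10.0])
def test_nchg_pmf_normalizes_and_matches_scipy(psi):
    n1, n2, m = 14, 23, 11
    ks, logp = nchg_logpmf_vector(n1, n2, m, psi)
    assert np.exp(logp).sum() == pytest.approx(1.0, abs=1e-12)
    total = n1 + n2
    ref = nchypergeom_fisher.pmf(ks, total, m, n1, psi)
    np.testing.assert_allclose(np.exp(logp), ref, rtol=1e-9)


def test_nchg_pmf_central_reduces_to_binomial_arithmetic():
    # all 6 exposed among the 35 cases out of 112: C(35,6)/C(112,6)
    expected = math.comb(35, 6) / math.comb(112, 6)
    assert nchg_pmf(6, 35, 77, 6, 1.0) == pytest.approx(expected, rel=1e-10)
    assert expected == pytest.approx(6.79e-4, rel=5e-3)


def test_nchg_pmf_outside_support_is_zero():
    assert nchg_pmf(7, 5, 5, 6, 2.0) == 0.0
    assert nchg_pmf(0, 5, 5, 6, 2.0) == 0.0  # below support min of 1


# ------------------------------------------------------------ fisher p


def test_fisher_symmetric_table_is_one():
    assert fisher_exact_two_sided(Table2x2(5, 5, 5, 5)) == pytest.approx(1.0)


def test_fisher_small_table_matches_enumeration():
    t = Table2x2(3, 2, 1, 4)
    assert fisher_exact_two_sided(t) == pytest.approx(float(fisher_p_oracle(t)), rel=1e-9)


def test_fisher_degenerate_margin():
    assert fisher_exact_two_sided(Table2x2(0, 5, 0, 5)) == 1.0


@given(
    a=st.integers(0, 12), b=st.integers(0, 12), c=st.integers(0, 12), d=st.integers(0, 12)
)
@settings(max_examples=200, derandomize=True, deadline=None)
def test_fisher_matches_scipy_and_transpose_invariant(a, b, c, d):
    if a + b == 0 or c + d == 0:
        return
    t = Table2x2(a, b, c, d)
    p = fisher_exact_two_sided(t)
    assert p == pytest.approx(scipy_fisher([[a, b], [c, d]])[1], rel=1e-7)
    if a + c > 0 and b + d > 0:
        assert p == pytest.approx(fisher_exact_two_sided(t.transpose()), rel=1e-9)


# ------------------------------------------------------------ CMLE


def test_cmle_symmetric_table_is_one():
    assert cmle_or(Table2x2(10, 10, 10, 10)) == pytest.approx(1.0, abs=1e-9)


def test_cmle_matches_conditional_likelihood_grid():
    t = Table2x2(10, 62, 1, 204)
    est = cmle_or(t)
    grid = np.exp(np.linspace(np.log(est) - 1.0, np.log(est) + 1.0, 4001))
    lo, _ = nchg_support(t.n_cases, t.n_controls, t.n_exposed)

    def cond_loglik(psi):
        ks, logp = nchg_logpmf_vector(t.n_cases, t.n_controls, t.n_exposed, psi)
        return logp[t.a - lo]

    best = grid[np.argmax([cond_loglik(p) for p in grid])]
    assert est == pytest.approx(best, rel=1e-3)


def test_cmle_boundary_tables():
    assert cmle_or(Table2x2(6, 29, 0, 77)) == math.inf
    assert cmle_or(Table2x2(0, 35, 6, 71)) == 0.0


def test_cmle_approaches_sample_or_for_large_cells():
    t = Table2x2(20 * 100, 52 * 100, 13 * 100, 192 * 100)
    assert cmle_or(t) == pytest.approx(t.sample_or(), rel=2e-3)


@given(a=st.integers(1, 10), b=st.integers(1, 10), c=st.integers(1, 10), d=st.integers(1, 10))
@settings(max_examples=100, derandomize=True, deadline=None)
def test_cmle_symmetries(a, b, c, d):
    t = Table2x2(a, b, c, d)
    est = cmle_or(t)
    # exposure relabeling inverts the odds ratio ...
    assert cmle_or(Table2x2(b, a, d, c)) == pytest.approx(1.0 / est, rel=1e-6)
    # ... while swapping the roles of exposure and outcome preserves it
    assert cmle_or(t.transpose()) == pytest.approx(est, rel=1e-6)


# ------------------------------------------------------------ exact CI


def test_ci_brackets_cmle_for_interior_count():
    t = Table2x2(9, 28, 10, 118)
    lo, hi = exact_ci(t)
    assert lo < cmle_or(t) < hi


def test_ci_defining_equations():
    # bound solves the tail equation; verified with scipy's independent cdf
    t = Table2x2(20, 52, 13, 192)
    lo, hi = exact_ci(t, 0.05)
    total, m, n1 = t.total, t.n_exposed, t.n_cases
    assert nchypergeom_fisher.cdf(t.a, total, m, n1, hi) == pytest.approx(0.025, abs=1e-7)
    assert nchypergeom_fisher.sf(t.a - 1, total, m, n1, lo) == pytest.approx(0.025, abs=1e-7)


def test_ci_boundary_counts():
    lo, hi = exact_ci(Table2x2(6, 29, 0, 77))
    assert hi == math.inf
    assert lo == pytest.approx(2.8717, abs=1e-3)  # frozen from converged R inversion
    lo0, hi0 = exact_ci(Table2x2(0, 35, 6, 71))
    assert lo0 == 0.0 and hi0 < math.inf


def test_exact_result_bundles_consistently():
    res = exact_result(Table2x2(11, 24, 3, 74))
    assert res.ci_low < res.or_cmle < res.ci_high
    assert 0 < res.p_two_sided <= 1


# ------------------------------------------------------------ trend test


def test_trend_null_identical_distributions():
    z, p = cochran_armitage_trend((10, 20, 10), (10, 20, 10))
    assert z == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_trend_longhand_formula():
    r = np.array([10.0, 20.0, 10.0])
    s = np.array([20.0, 20.0, 0.0])
    w = np.array([0.0, 1.0, 2.0])
    n_i = r + s
    N, R = n_i.sum(), r.sum()
    t_stat = float((w * (r - n_i * R / N)).sum())
    var = (R / N) * (1 - R / N) * ((w**2 * n_i).sum() - (w * n_i).sum() ** 2 / N)
    z_expected = t_stat / math.sqrt(var)
    z, p = cochran_armitage_trend((10, 20, 10), (20, 20, 0))
    assert z == pytest.approx(z_expected, rel=1e-12)
    assert 0 < p < 1


def test_trend_invariant_under_affine_weights():
    z1, p1 = cochran_armitage_trend((5, 12, 8), (10, 9, 3), weights=(0, 1, 2))
    z2, p2 = cochran_armitage_trend((5, 12, 8), (10, 9, 3), weights=(10, 15, 20))
    assert abs(z1) == pytest.approx(abs(z2), rel=1e-10)
    assert p1 == pytest.approx(p2, rel=1e-10)


def test_trend_monomorphic_returns_null():
    z, p = cochran_armitage_trend((30, 0, 0), (40, 0, 0))
    assert (z, p) == (0.0, 1.0)


# ------------------------------------------------------------ HWE


@pytest.mark.parametrize(
    "counts",
    [(57, 14, 50), (20, 0, 20), (25, 50, 25), (3, 5, 2), (40, 10, 1)],
)
def test_hwe_matches_enumeration_oracle(counts):
    assert hwe_exact_p(counts) == pytest.approx(float(hwe_p_oracle(*counts)), rel=1e-9)


def test_hwe_trivial_configurations():
    assert hwe_exact_p((0, 2, 0)) == pytest.approx(1.0)
    assert hwe_exact_p((100, 0, 0)) == 1.0  # monomorphic
    assert hwe_exact_p((25, 50, 25)) == pytest.approx(1.0, rel=1e-9)


# ------------------------------------------------------------ BH fdr


def test_bh_hand_computed_step_up():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
    np.testing.assert_allclose(bh_fdr([0.05]), [0.05])
    np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
    assert bh_fdr([]).size == 0


@given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
@settings(max_examples=100, derandomize=True, deadline=None)
def test_bh_monotone_in_p_rank(ps):
    q = bh_fdr(ps)
    order = np.argsort(ps)
    assert np.all(np.diff(q[order]) >= -1e-12)


# ------------------------------------------------------------ predictive values


def test_predictive_values_perfect_specificity():
    pv = predictive_values(Table2x2(5, 5, 0, 10), prevalence=0.01)
    assert pv.ppv == pytest.approx(1.0)


def test_predictive_values_closed_form():
    pv = predictive_values(Table2x2(10, 62, 1, 204), prevalence=0.05)
    sens, spec = 10 / 72, 204 / 205
    assert pv.sensitivity == pytest.approx(sens)
    expected_ppv = sens * 0.05 / (sens * 0.05 + (1 - spec) * 0.95)
    assert pv.ppv == pytest.approx(expected_ppv, rel=1e-12)


def test_predictive_values_undefined_flag():
    pv = predictive_values(Table2x2(0, 10, 0, 10), prevalence=0.1)
    assert not pv.ppv_defined
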