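"""Exact inference on 2x2 tables and related small-sample statistics.

All exact 2x2 machinery conditions on both margins of the table

    a (exposed cases)     b (unexposed cases)     | n1 = a + b cases
    c (exposed controls)  d (unexposed controls)  | n2 = c + d controls
    m = a + c exposed

so the exposed-case count X follows Fisher's noncentral hypergeometric
distribution with odds-ratio parameter psi.  The point estimate is the
conditional MLE (the psi solving E_psi[X] = a) and the confidence interval is
the Cornfield-type tail inversion; both match what R's ``fisher.test``
reports.  The module also provides the two-sided Fisher exact P, the
Cochran-Armitage trend test, the exact Hardy-Weinberg deviation test used for
genotype QC, Benjamini-Hochberg q-values, and prevalence-standardized
predictive values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Table2x2",
    "ExactResult",
    "PredictiveValues",
    "nchg_pmf",
    "nchg_support",
    "nchg_logpmf_vector",
    "nchg_mean",
    "fisher_exact_two_sided",
    "cmle_or",
    "exact_ci",
    "exact_result",
    "cochran_armitage_trend",
    "hwe_exact_p",
    "bh_fdr",
    "predictive_values",
    "ppv_comparison_p",
]

# relative tolerance on the "probability <= observed" cutoff for two-sided
# exact tests; matches the convention used by R and scipy
_P_CUTOFF_RTOL = 1e-7


@dataclass(frozen=True)
class Table2x2:
    """Case-control 2x2 contingency table.

    a/b are exposed/unexposed cases, c/d exposed/unexposed controls.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")
        if self.n_cases == 0:
            raise ValueError("table has no cases (a + b == 0)")
        if self.n_controls == 0:
            raise ValueError("table has no controls (c + d == 0)")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def n_exposed(self) -> int:
        return self.a + self.c

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "Table2x2":
        """Swap the roles of exposure and outcome."""
        return Table2x2(self.a, self.c, self.b, self.d)

    def sample_or(self) -> float:
        """Unconditional cross-product ratio ad/bc (may be 0 or inf)."""
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class ExactResult:
    """Conditional-MLE odds ratio with exact CI and Fisher P for one table."""

    table: Table2x2
    or_cmle: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    alpha: float = 0.05
    mid_p: bool = False


@dataclass(frozen=True)
class PredictiveValues:
    sensitivity: float
    specificity: float
    prevalence: float
    ppv: float
    npv: float
    ppv_defined: bool = True


def nchg_support(n1: int, n2: int, m: int) -> tuple[int, int]:
    """Inclusive support bounds of the exposed-case count X."""
    return max(0, m - n2), min(n1, m)


def nchg_logpmf_vector(n1: int, n2: int, m: int, psi: float) -> tuple[np.ndarray, np.ndarray]:
    """Log-pmf of Fisher's noncentral hypergeometric over its full support.

    Returns (ks, logp) where ks are the support points.  psi=0 puts all mass
    on the support minimum.  Everything is computed in log space so that
    tables as extreme as psi ~ e^60 remain finite.
    """
    if psi < 0:
        raise ValueError("psi must be nonnegative")
    lo, hi = nchg_support(n1, n2, m)
    ks = np.arange(lo, hi + 1)
    if psi == 0.0:
        logp = np.full(ks.shape, -np.inf)
        logp[0] = 0.0
        return ks, logp
    log_comb1 = gammaln(n1 + 1) - gammaln(ks + 1) - gammaln(n1 - ks + 1)
    log_comb2 = gammaln(n2 + 1) - gammaln(m - ks + 1) - gammaln(n2 - m + ks + 1)
    logw = log_comb1 + log_comb2 + ks * math.log(psi)
    return ks, logw - logsumexp(logw)


def nchg_pmf(k: int, n1: int, n2: int, m: int, psi: float) -> float:
    """P(X = k) under the noncentral hypergeometric; 0 outside the support."""
    lo, hi = nchg_support(n1, n2, m)
    if k < lo or k > hi:
        return 0.0
    ks, logp = nchg_logpmf_vector(n1, n2, m, psi)
    return float(np.exp(logp[k - lo]))


def nchg_mean(n1: int, n2: int, m: int, psi: float) -> float:
    ks, logp = nchg_logpmf_vector(n1, n2, m, psi)
    return float(np.exp(logsumexp(logp, b=ks.astype(float))))


def _tail_log_prob(t: Table2x2, psi: float, upper: bool) -> float:
    """log P_psi(X >= a) if upper else log P_psi(X <= a)."""
    lo, _ = nchg_support(t.n_cases, t.n_controls, t.n_exposed)
    ks, logp = nchg_logpmf_vector(t.n_cases, t.n_controls, t.n_exposed, psi)
    idx = t.a - lo
    sel = logp[idx:] if upper else logp[: idx + 1]
    return float(logsumexp(sel))


def fisher_exact_two_sided(t: Table2x2) -> float:
    """Two-sided Fisher exact P: total central-hypergeometric probability of
    all tables with the observed margins no more probable than the observed
    one (small relative slack on the cutoff for float safety)."""
    lo, hi = nchg_support(t.n_cases, t.n_controls, t.n_exposed)
    if lo == hi:  # degenerate margin, only one table possible
        return 1.0
    ks, logp = nchg_logpmf_vector(t.n_cases, t.n_controls, t.n_exposed, 1.0)
    p = np.exp(logp)
    p_obs = p[t.a - lo]
    return float(min(1.0, p[p <= p_obs * (1.0 + _P_CUTOFF_RTOL)].sum()))


_LOG_PSI_MAX = 80.0  # bisection bracket on log psi; e^80 is beyond any finite CMLE here


def _solve_monotone(f, increasing: bool, tol: float = 1e-10) -> float:
    """Root of a monotone function of log(psi) by bisection on [-80, 80].

    Returns the root in psi space; caller handles boundary cases before.
    """
    lo, hi = -_LOG_PSI_MAX, _LOG_PSI_MAX
    flo = f(lo)
    fhi = f(hi)
    if not increasing:
        flo, fhi = fhi, flo
        # bisect on the increasing reflection
        g = lambda x: f(-x)  # noqa: E731
    else:
        g = f
    if flo > 0:
        return math.exp(lo if increasing else -lo)
    if fhi < 0:
        return math.exp(hi if increasing else -hi)
    a, b = -_LOG_PSI_MAX, _LOG_PSI_MAX
    while b - a > tol:
        mid = 0.5 * (a + b)
        if g(mid) < 0:
            a = mid
        else:
            b = mid
    x = 0.5 * (a + b)
    return math.exp(x if increasing else -x)


def cmle_or(t: Table2x2) -> float:
    """Conditional maximum-likelihood odds ratio: the psi with E_psi[X] = a.

    Returns 0.0 when a sits at the support minimum and +inf at the maximum
    (the conditional likelihood is then maximized at the boundary).
    """
    lo, hi = nchg_support(t.n_cases, t.n_controls, t.n_exposed)
    if lo == hi:
        return math.nan  # margin degenerate: psi not identifiable
    if t.a == hi:
        return math.inf
    if t.a == lo:
        return 0.0
    n1, n2, m = t.n_cases, t.n_controls, t.n_exposed
    return _solve_monotone(lambda x: nchg_mean(n1, n2, m, math.exp(x)) - t.a, increasing=True)


def exact_ci(t: Table2x2, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Cornfield tail-inversion) CI for the conditional odds ratio.

    ci_low solves P_psi(X >= a) = alpha/2; ci_high solves P_psi(X <= a) =
    alpha/2.  Boundary counts give 0 / +inf on the corresponding side.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    lo, hi = nchg_support(t.n_cases, t.n_controls, t.n_exposed)
    target = math.log(alpha / 2.0)
    if t.a == lo:
        ci_low = 0.0
    else:
        # P(X >= a) increases with psi
        ci_low = _solve_monotone(
            lambda x: _tail_log_prob(t, math.exp(x), upper=True) - target, increasing=True
        )
    if t.a == hi:
        ci_high = math.inf
    else:
        # P(X <= a) decreases with psi
        ci_high = _solve_monotone(
            lambda x: _tail_log_prob(t, math.exp(x), upper=False) - target, increasing=False
        )
    return ci_low, ci_high


def exact_result(t: Table2x2, alpha: float = 0.05) -> ExactResult:
    """Bundle CMLE OR, exact CI and two-sided Fisher P for one table."""
    low, high = exact_ci(t, alpha)
    return ExactResult(
        table=t,
        or_cmle=cmle_or(t),
        ci_low=low,
        ci_high=high,
        p_two_sided=fisher_exact_two_sided(t),
        alpha=alpha,
    )


def cochran_armitage_trend(
    case_counts, control_counts, weights=(0.0, 1.0, 2.0)
) -> tuple[float, float]:
    """Cochran-Armitage trend test on genotype counts.

    case_counts/control_counts are (hom-ref, het, hom-alt) counts; default
    weights are the additive allele-dosage scores.  Returns (Z, two-sided
    normal P).  Monomorphic input (zero score variance) returns (0, 1).
    """
    r = np.asarray(case_counts, dtype=float)
    s = np.asarray(control_counts, dtype=float)
    if r.shape != s.shape or r.ndim != 1:
        raise ValueError("case and control count vectors must be 1-D and equal length")
    if np.any(r < 0) or np.any(s < 0):
        raise ValueError("counts must be nonnegative")
    w = np.asarray(weights, dtype=float)
    n_i = r + s
    big_n = n_i.sum()
    big_r = r.sum()
    if big_r == 0 or big_r == big_n:
        raise ValueError("need at least one case and one control")
    t_stat = float(np.sum(w * (r - n_i * big_r / big_n)))
    var = (big_r / big_n) * (1.0 - big_r / big_n) * (
        np.sum(w**2 * n_i) - np.sum(w * n_i) ** 2 / big_n
    )
    if var <= 0:
        return 0.0, 1.0
    from scipy.stats import norm

    z = t_stat / math.sqrt(var)
    return z, float(2.0 * norm.sf(abs(z)))


def hwe_exact_p(genotype_counts) -> float:
    """Exact Hardy-Weinberg deviation test (two-sided, probability ordering).

    genotype_counts is (n_AA, n_AB, n_BB).  Conditional on the allele counts,
    the heterozygote count ranges over values of fixed parity; P is the total
    probability of configurations no more probable than the observed one.
    Monomorphic samples return 1.
    """
    n_aa, n_ab, n_bb = (int(x) for x in genotype_counts)
    if min(n_aa, n_ab, n_bb) < 0 or n_aa + n_ab + n_bb == 0:
        raise ValueError("genotype counts must be nonnegative with positive total")
    n = n_aa + n_ab + n_bb
    n_b = 2 * n_bb + n_ab  # allele-B count; orientation is irrelevant
    n_minor = min(n_b, 2 * n - n_b)
    if n_minor == 0:
        return 1.0
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    homs_minor = (n_minor - hets) // 2
    homs_major = n - hets - homs_minor
    logp = (
        gammaln(n + 1)
        - gammaln(homs_minor + 1)
        - gammaln(hets + 1)
        - gammaln(homs_major + 1)
        + hets * math.log(2.0)
    )
    # normalizing constant cancels in the probability ordering
    logp -= logsumexp(logp)
    p = np.exp(logp)
    obs_het = n_ab
    p_obs = p[np.nonzero(hets == obs_het)[0][0]]
    return float(min(1.0, p[p <= p_obs * (1.0 + _P_CUTOFF_RTOL)].sum()))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def predictive_values(t: Table2x2, prevalence: float) -> PredictiveValues:
    """Prevalence-standardized PPV/NPV from a case-control table.

    Sensitivity and specificity come from the table; PPV and NPV are then
    standardized to the assumed population prevalence via Bayes' rule (the
    case:control ratio of a retrospective cohort carries no prevalence
    information).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    sens = t.a / t.n_cases
    spec = t.d / t.n_controls
    fpr = 1.0 - spec
    num_p = sens * prevalence
    den_p = num_p + fpr * (1.0 - prevalence)
    ppv_defined = den_p > 0
    ppv = num_p / den_p if ppv_defined else math.nan
    num_n = spec * (1.0 - prevalence)
    den_n = num_n + (1.0 - sens) * prevalence
    npv = num_n / den_n if den_n > 0 else math.nan
    return PredictiveValues(
        sensitivity=sens,
        specificity=spec,
        prevalence=prevalence,
        ppv=ppv,
        npv=npv,
        ppv_defined=ppv_defined,
    )


def ppv_comparison_p(t_marker1: Table2x2, t_marker2: Table2x2) -> float:
    """Exact P comparing the case fraction among predicted positives of two
    markers scored on the same cohort (a Fisher test on the predicted-positive
    compositions).  This is the working definition used for the 'PPV improved'
    significance claim; it treats the two carrier sets as independent, which
    is an approximation when one marker nests the other."""
    comp = Table2x2(t_marker1.a, t_marker1.c, t_marker2.a, t_marker2.c)
    return fisher_exact_two_sided(comp)
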