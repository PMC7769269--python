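"""A-priori and sensitivity power analyses.

Two families of calculations:

* Repeated-measures ANOVA, group x measurement interaction. Power is
  computed from the noncentral F distribution with noncentrality
  lambda = f^2 * N * m * eps / (1 - rho), numerator df (k-1)(m-1)eps and
  denominator df (N-k)(m-1)eps, where f is Cohen's effect size, N the
  total sample, k the number of groups, m the number of repeated
  measures, rho the assumed correlation among repeated measures, and eps
  the nonsphericity correction.

* Two-tailed test of a Pearson correlation against zero under the
  bivariate-normal model. The default routine integrates the exact
  density of the sample correlation coefficient; a bias-corrected
  Fisher-z approximation (z_rho + rho / (2(n-1)), SE 1/sqrt(n-3)) is
  available as a documented fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special
from scipy import stats as st


@dataclass(frozen=True)
class RMAnovaPowerSpec:
    """Inputs of the repeated-measures interaction power calculation."""

    f: float = 0.25
    alpha: float = 0.05
    target_power: float = 0.80
    k: int = 2
    m: int = 6
    rho: float = 0.5
    epsilon: float = 1.0

    def validate(self) -> None:
        if self.f <= 0:
            raise ValueError("effect size f must be positive")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if not 1.0 / (self.m - 1) < self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in (1/(m-1), 1]")
        if not (0 < self.alpha < 1 and 0 < self.target_power < 1):
            raise ValueError("alpha and target_power must lie in (0, 1)")


def rm_interaction_power(n_total: int, spec: RMAnovaPowerSpec) -> float:
    """Power of the within-between interaction F test at total sample N."""
    spec.validate()
    if n_total <= spec.k:
        return 0.0
    lam = spec.f**2 * n_total * spec.m * spec.epsilon / (1.0 - spec.rho)
    df1 = (spec.k - 1) * (spec.m - 1) * spec.epsilon
    df2 = (n_total - spec.k) * (spec.m - 1) * spec.epsilon
    fcrit = st.f.isf(spec.alpha, df1, df2)
    return float(st.ncf.sf(fcrit, df1, df2, lam))


def rm_interaction_sample_size(spec: RMAnovaPowerSpec = RMAnovaPowerSpec(),
                               n_max: int = 10**6) -> int:
    """Smallest total N (equal groups, so a multiple of k) whose
    interaction power reaches the target."""
    spec.validate()
    n = 2 * spec.k
    while n <= n_max:
        if rm_interaction_power(n, spec) >= spec.target_power:
            return n
        n += spec.k
    raise ValueError(f"target power not attainable with N <= {n_max}")


# ---------------------------------------------------------------------------
# Pearson correlation power (exact bivariate-normal sample-r distribution)

@dataclass(frozen=True)
class CorrelationPowerSpec:
    """Inputs of the correlation sample-size calculation."""

    rho1: float = 0.31
    alpha: float = 0.05
    target_power: float = 0.80
    tails: int = 2

    def validate(self) -> None:
        if not 0 < abs(self.rho1) < 1:
            raise ValueError("rho1 must satisfy 0 < |rho1| < 1")
        if self.tails != 2:
            raise ValueError("only the two-tailed test is implemented")
        if not (0 < self.alpha < 1 and 0 < self.target_power < 1):
            raise ValueError("alpha and target_power must lie in (0, 1)")


def sample_r_pdf(r, rho: float, n: int):
    """Exact density of the sample correlation under bivariate normality."""
    r = np.asarray(r, dtype=float)
    log_f = (np.log(n - 2) + special.gammaln(n - 1)
             + (n - 1) / 2.0 * np.log1p(-rho**2)
             + (n - 4) / 2.0 * np.log1p(-r**2)
             - 0.5 * np.log(2 * np.pi) - special.gammaln(n - 0.5)
             + (1.5 - n) * np.log1p(-rho * r))
    return np.exp(log_f) * special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0)


def correlation_power(rho1: float, n: int, alpha: float = 0.05,
                      method: str = "exact") -> float:
    """Two-tailed power of the test of r = 0 at true correlation rho1.

    ``method='exact'`` integrates the sample-r density over the rejection
    region |r| > r_crit (r_crit from the t test on n-2 df);
    ``method='fisher-z'`` uses the bias-corrected normal approximation.
    """
    if n <= 3:
        raise ValueError("need n > 3")
    if method == "fisher-z":
        za = st.norm.isf(alpha / 2.0)
        zr = (np.arctanh(rho1) + rho1 / (2.0 * (n - 1))) * np.sqrt(n - 3)
        return float(st.norm.sf(za - zr) + st.norm.cdf(-za - zr))
    if method != "exact":
        raise ValueError("method must be 'exact' or 'fisher-z'")
    tcrit = st.t.isf(alpha / 2.0, n - 2)
    rc = tcrit / np.sqrt(tcrit**2 + n - 2)
    # the density peaks near rho1; give quad the breakpoint explicitly
    def _piece(a, b):
        pts = [p for p in (rho1, -rho1) if a < p < b]
        val, _ = integrate.quad(sample_r_pdf, a, b, args=(rho1, n),
                                points=pts or None, limit=200)
        return val
    return float(_piece(-1.0, -rc) + _piece(rc, 1.0))


def correlation_sample_size(spec: CorrelationPowerSpec = CorrelationPowerSpec(),
                            method: str = "exact", n_max: int = 10**6) -> int:
    """Smallest n whose two-tailed power reaches the target."""
    spec.validate()
    n = 4
    while n <= n_max:
        if correlation_power(spec.rho1, n, spec.alpha, method) >= spec.target_power:
            return n
        n += 1
    raise ValueError(f"target power not attainable with n <= {n_max}")


def correlation_sensitivity(n: int = 30, alpha: float = 0.05,
                            target_power: float = 0.80,
                            method: str = "exact", tol: float = 1e-4) -> float:
    """Minimum detectable correlation at fixed n (bisection on rho1)."""
    if n <= 3:
        raise ValueError("need n > 3")
    lo, hi = tol, 0.999
    if correlation_power(hi, n, alpha, method) < target_power:
        raise ValueError("target power not attainable even at rho1 ~ 1")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if correlation_power(mid, n, alpha, method) >= target_power:
            hi = mid
        else:
            lo = mid
    # return the upper bracket so the reported rho really attains the power
    return hi
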