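"""A priori power and sample size for linear-model F-tests (Cohen's f²).

The design question: how many participants are needed so that an F-test
of ``u`` predictors in a general linear model detects an effect of size
f² with the target power at level α?  Power is computed from the
noncentral F distribution: with denominator df v = N − u − 1 and
noncentrality λ = f²·(u + v + 1) = f²·N, the power is
P(F' > F_crit) where F_crit is the (1 − α) quantile of the central
F(u, v) and F' ~ F(u, v, λ).  The required N is the smallest integer
achieving the target ("at least N participants" semantics).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerSpec", "glm_ftest_power", "required_sample_size"]


@dataclass(frozen=True)
class PowerSpec:
    u: int = 1            # numerator df: number of tested predictors
    f2: float = 0.15      # Cohen's effect size f²
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.u < 1:
            raise ValueError("u must be at least 1")
        if self.f2 <= 0:
            raise ValueError("f2 must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must lie in (0, 1)")


def glm_ftest_power(spec: PowerSpec, n_total: int) -> float:
    """Achieved power of the F-test at total sample size ``n_total``."""
    v = n_total - spec.u - 1
    if v < 1:
        raise ValueError("sample too small: denominator df must be positive")
    lam = spec.f2 * (spec.u + v + 1)  # = f2 * N
    f_crit = stats.f.ppf(1.0 - spec.alpha, spec.u, v)
    return float(stats.ncf.sf(f_crit, spec.u, v, lam))


def required_sample_size(spec: PowerSpec) -> int:
    """Smallest integer N with power(N) ≥ the target power.

    Bracketed search: double an upper bound until the target is met,
    then bisect down to the unique crossing point (power is increasing
    in N for a fixed spec).
    """
    lo = spec.u + 2  # smallest N with v >= 1
    if glm_ftest_power(spec, lo) >= spec.power:
        return lo
    hi = max(2 * lo, 16)
    while glm_ftest_power(spec, hi) < spec.power:
        hi *= 2
        if hi > 10_000_000:
            raise RuntimeError("sample size search did not converge")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if glm_ftest_power(spec, mid) >= spec.power:
            hi = mid
        else:
            lo = mid
    return hi
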