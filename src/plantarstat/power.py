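"""A priori power and sample-size computation for the per-cell t tests.

The number of stance phases (steps) that must be recorded per foot is set
by power analysis of the framework's two per-cell tests:

* one-sample t of a cell's mean peak pressure against the 200 kPa
  threshold (one-tailed) — at d = 0.6, α = 0.05, power 0.80 this requires
  19 steps;
* paired t between two insole conditions (two-tailed) — at the same
  settings this requires 24 steps, the stricter and therefore governing
  requirement.  At 24 steps the one-sample test resolves effect sizes down
  to d ≈ 0.52.

Power is computed from the noncentral t distribution with noncentrality
δ = d·√n and n − 1 degrees of freedom (for the paired family, d is the
standardized mean difference and n the number of pairs, so the arithmetic
coincides with the one-sample case).  Two-tailed power counts both
rejection regions.

For the cohort design, :func:`required_n_rm_anova` gives the
within-subject repeated-measures F-test sample size under an explicit
repeated-measures correlation ρ and nonsphericity ε, and
:func:`nonparametric_inflate` applies the rule-of-thumb 15% inflation used
when the final analysis is nonparametric (Friedman).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import stats

__all__ = [
    "PowerSpec",
    "achieved_power_t",
    "required_n_t",
    "detectable_d",
    "nonparametric_inflate",
    "achieved_power_rm_anova",
    "required_n_rm_anova",
]

_T_FAMILIES = ("one_sample_t", "paired_t")


@dataclass(frozen=True)
class PowerSpec:
    """Specification of a power computation.

    family : "one_sample_t", "paired_t" or "rm_anova_within".
    tails : 1 or 2 (t families only).
    alpha, power : type-I level and target power, both in (0, 1).
    d : Cohen's d (t families); f : Cohen's f (rm_anova_within).
    k_measurements, corr_rho, epsilon_nonsphericity : rm_anova_within only —
        number of repeated measurements, their assumed correlation, and the
        Greenhouse–Geisser sphericity correction (1 = perfect sphericity).
    """

    family: str = "one_sample_t"
    tails: int = 1
    alpha: float = 0.05
    power: float = 0.80
    d: float = 0.6
    f: float = 0.25
    k_measurements: int = 3
    corr_rho: float = 0.5
    epsilon_nonsphericity: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in (*_T_FAMILIES, "rm_anova_within"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")


def achieved_power_t(n: int, spec: PowerSpec) -> float:
    """Power of a one-sample/paired t test at sample size *n*.

    Noncentral-t power: with ncp δ = d√n and ν = n − 1,
    one-tailed  P(T'_{ν,δ} > t_{1−α,ν});
    two-tailed  P(T'_{ν,δ} > t_{1−α/2,ν}) + P(T'_{ν,δ} < −t_{1−α/2,ν})
    (both rejection regions counted).
    """
    if n < 2:
        return 0.0
    df = n - 1
    ncp = spec.d * math.sqrt(n)
    tail_alpha = spec.alpha if spec.tails == 1 else spec.alpha / 2.0
    tcrit = stats.t.ppf(1.0 - tail_alpha, df)
    power = stats.nct.sf(tcrit, df, ncp)
    if spec.tails == 2:
        power += stats.nct.cdf(-tcrit, df, ncp)
    return float(power)


def required_n_t(spec: PowerSpec, n_max: int = 100_000) -> tuple[int, float]:
    """Smallest n whose achieved noncentral-t power meets ``spec.power``.

    Returns ``(n, achieved_power)``.  The search starts at n = 2 and walks
    upward; t-test power is monotone in n for fixed d > 0.
    """
    if spec.family not in _T_FAMILIES:
        raise ValueError(f"required_n_t needs a t family, got {spec.family!r}")
    if spec.d <= 0:
        raise ValueError("effect size d must be positive")
    # geometric bracket then linear scan keeps this fast even for tiny d
    hi = 2
    while achieved_power_t(hi, spec) < spec.power:
        hi *= 2
        if hi > n_max:
            raise ValueError(f"no n <= {n_max} reaches power {spec.power}")
    lo = max(2, hi // 2)
    for n in range(lo, hi + 1):
        p = achieved_power_t(n, spec)
        if p >= spec.power:
            return n, p
    raise AssertionError("unreachable: power is monotone in n")


def detectable_d(
    n: int, spec: PowerSpec, tol: float = 1e-6, d_max: float = 100.0
) -> float:
    """Smallest effect size d reaching ``spec.power`` at fixed *n*.

    Solved by bisection on d (power is monotone increasing in d) to a
    power tolerance of *tol*.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    lo, hi = 0.0, 1.0
    while achieved_power_t(n, replace(spec, d=hi)) < spec.power:
        hi *= 2.0
        if hi > d_max:
            raise ValueError("required effect size unreasonably large")
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if achieved_power_t(n, replace(spec, d=mid)) >= spec.power:
            hi = mid
        else:
            lo = mid
    return hi


def nonparametric_inflate(n_parametric: float) -> tuple[float, int]:
    """Rule-of-thumb sample-size inflation for nonparametric analysis.

    Adds 15% to the parametric requirement; returns ``(raw, ceiling)``
    (e.g. 41 → 47.15, 48).
    """
    if n_parametric <= 0:
        raise ValueError("n must be positive")
    raw = n_parametric * 1.15
    return raw, math.ceil(raw)


def achieved_power_rm_anova(n: int, spec: PowerSpec) -> float:
    """Power of the within-subject repeated-measures F test at *n* subjects.

    Conventional within-factor parameterization with explicit repeated-
    measures correlation ρ and nonsphericity ε:
    λ = n·k·f²·ε / (1 − ρ),  df1 = (k − 1)·ε,  df2 = (n − 1)(k − 1)·ε.
    """
    k = spec.k_measurements
    eps = spec.epsilon_nonsphericity
    rho = spec.corr_rho
    if n < 2:
        return 0.0
    df1 = (k - 1) * eps
    df2 = (n - 1) * (k - 1) * eps
    lam = n * k * spec.f**2 * eps / (1.0 - rho)
    fcrit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def required_n_rm_anova(spec: PowerSpec, n_max: int = 100_000) -> tuple[int, float]:
    """Smallest subject count meeting ``spec.power`` for the within-RM F test."""
    if spec.family != "rm_anova_within":
        raise ValueError("required_n_rm_anova needs family='rm_anova_within'")
    if spec.k_measurements < 2:
        raise ValueError("k_measurements must be >= 2")
    if spec.f <= 0:
        raise ValueError("effect size f must be positive")
    if not 0 < spec.corr_rho < 1:
        raise ValueError("corr_rho must be in (0, 1)")
    if not 0 < spec.epsilon_nonsphericity <= 1:
        raise ValueError("epsilon_nonsphericity must be in (0, 1]")
    n = 2
    while achieved_power_rm_anova(n, spec) < spec.power:
        n += 1
        if n > n_max:
            raise ValueError(f"no n <= {n_max} reaches power {spec.power}")
    return n, achieved_power_rm_anova(n, spec)
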