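"""Prior power analysis for the repeated-measures within-factor ANOVA.

Implements the noncentral-F power computation for the "ANOVA: repeated
measures, within factors" design as popularised by G*Power 3.1: with Cohen
effect size f, total sample N across ``groups`` groups, m within-factor
levels, mean correlation rho among the repeated measures, and
nonsphericity epsilon, the noncentrality parameter is

    lambda = f^2 * N * m * epsilon / (1 - rho)

with numerator df (m-1)*epsilon and denominator df (N-groups)*(m-1)*epsilon.
Power is the survival probability of the noncentral F at the central-F
critical value.  An alternative "as in SPSS" flag treats f^2 as already
incorporating the correlation term.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = ["PowerSpec", "f_from_eta2", "rm_within_power", "min_n"]


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the repeated-measures power computation."""

    f: float
    alpha: float = 0.05
    target_power: float = 0.95
    m: int = 8
    rho: float = 0.1
    epsilon: float = 1.0
    groups: int = 2
    n_per_group: int = 2
    gpower_convention: bool = True  # False: "as in SPSS" effect size

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must lie in (0, 1)")
        if self.m < 2:
            raise ValueError("need at least two within-factor levels")
        if not -1.0 / (self.m - 1) < self.rho < 1:
            raise ValueError("rho outside the valid correlation range")
        if not 1.0 / (self.m - 1) <= self.epsilon <= 1:
            raise ValueError("epsilon outside [1/(m-1), 1]")
        if self.groups < 1 or self.n_per_group < 1:
            raise ValueError("groups and n_per_group must be positive")
        if self.f < 0:
            raise ValueError("effect size must be non-negative")

    @classmethod
    def from_eta2(cls, eta2: float, **kwargs) -> "PowerSpec":
        return cls(f=f_from_eta2(eta2), **kwargs)


def f_from_eta2(eta2: float) -> float:
    """Cohen's f from partial eta squared: f = sqrt(eta2 / (1 - eta2))."""
    if not 0 <= eta2 < 1:
        raise ValueError("eta2 must lie in [0, 1)")
    return float(np.sqrt(eta2 / (1.0 - eta2)))


def rm_within_power(spec: PowerSpec) -> float:
    """Power of the within-factor F test for the given spec."""
    if spec.n_per_group < 2:
        raise ValueError("need at least two subjects per group")
    N = spec.groups * spec.n_per_group
    df1 = (spec.m - 1) * spec.epsilon
    df2 = (N - spec.groups) * (spec.m - 1) * spec.epsilon
    if df2 <= 0:
        raise ValueError("degenerate denominator degrees of freedom")
    f2 = spec.f**2
    if spec.gpower_convention:
        f2 = f2 * spec.m * spec.epsilon / (1.0 - spec.rho)
    lam = f2 * N
    fcrit = stats.f.isf(spec.alpha, df1, df2)
    if lam == 0:
        return float(spec.alpha)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def min_n(spec: PowerSpec, cap: int = 10_000) -> int:
    """Smallest n per group whose power reaches ``target_power``.

    Linear scan from 2; raises if the target is unreachable below ``cap``.
    """
    for n in range(2, cap + 1):
        if rm_within_power(replace(spec, n_per_group=n)) >= spec.target_power:
            return n
    raise ValueError(f"target power {spec.target_power} unreachable below n = {cap}")
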