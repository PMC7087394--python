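"""Analytic power calculations for instrumental-variable replication analyses.

Uses the standard two-stage least-squares asymptotics: the noncentrality of
the causal-effect test is sqrt(n * R2_xz) * beta, where R2_xz is the fraction
of exposure variance explained by the instrument. The minimal detectable
effect at two-sided level alpha and target power 1 - beta_err is

    MDE = (z_{1-alpha/2} + z_{power}) / sqrt(n * R2_xz)

in SD-of-outcome per SD-of-exposure units for continuous outcomes; binary
designs divide the effective sample size by the case-fraction variance
p(1 - p), giving the MDE on the log-odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError


@dataclass(frozen=True)
class PowerResult:
    n: int
    r2_xz: float
    alpha: float
    power: float
    mde: float
    binary: bool = False
    case_fraction: float | None = None

    @property
    def odds_ratio(self) -> float | None:
        """The MDE as an odds ratio, for binary designs."""
        return float(np.exp(self.mde)) if self.binary else None


def _check(n, r2_xz, alpha, power):
    if n < 10:
        raise ParameterError("n must be >= 10")
    if not 0.0 < r2_xz < 1.0:
        raise ParameterError("r2_xz must be in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must be in (0, 1)")
    if not 0.0 < power < 1.0:
        raise ParameterError("power must be in (0, 1)")


def mde_continuous(n: int, r2_xz: float, alpha: float = 0.05,
                   power: float = 0.80) -> PowerResult:
    """Minimal detectable standardized effect for a continuous outcome."""
    _check(n, r2_xz, alpha, power)
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    mde = float((z_a + z_b) / np.sqrt(n * r2_xz))
    return PowerResult(int(n), float(r2_xz), float(alpha), float(power), mde)


def mde_binary(n: int, r2_xz: float, case_fraction: float,
               alpha: float = 0.05, power: float = 0.80) -> PowerResult:
    """Minimal detectable log-odds effect for a binary outcome."""
    _check(n, r2_xz, alpha, power)
    if not 0.0 < case_fraction < 1.0:
        raise ParameterError("case_fraction must be in (0, 1)")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    mde = float((z_a + z_b) / np.sqrt(n * r2_xz * case_fraction * (1.0 - case_fraction)))
    return PowerResult(int(n), float(r2_xz), float(alpha), float(power), mde,
                       binary=True, case_fraction=float(case_fraction))


def power_at_effect(n: int, r2_xz: float, effect: float,
                    alpha: float = 0.05) -> float:
    """Achieved power at a given true standardized effect.

    Phi(sqrt(n * R2_xz) * |effect| - z_{1-alpha/2}); exact round-trip with
    :func:`mde_continuous`.
    """
    if effect < 0:
        raise ParameterError("effect must be >= 0")
    if not 0.0 < r2_xz < 1.0:
        raise ParameterError("r2_xz must be in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must be in (0, 1)")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(np.sqrt(n * r2_xz) * effect - z_a))
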