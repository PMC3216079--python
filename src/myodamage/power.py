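"""A-priori power and sample size for a two-sample comparison of means.

The study's sample size rests on a two-group t-test calculation: with a
common standard deviation sigma and a true difference in means delta, the
two-sided pooled-variance t-test with n per group has noncentrality

    lambda = delta / (sigma * sqrt(2 / n))

and 2n − 2 degrees of freedom. Power is the probability mass of the
noncentral t distribution outside the central-t critical values, both
rejection tails included. The default significance level is two-sided
alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """Design of a two-group mean comparison (percentage-point units)."""

    n_per_group: int
    delta: float
    sd: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError(f"n_per_group must be at least 2, got {self.n_per_group}")
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def t_test_power(
    spec: PowerSpec | None = None,
    *,
    n_per_group: int | None = None,
    delta: float | None = None,
    sd: float | None = None,
    alpha: float = 0.05,
) -> float:
    """Power of the two-sided two-sample pooled-variance t-test.

    Accepts either a :class:`PowerSpec` or keyword arguments. Power depends
    on ``delta`` and ``sd`` only through their ratio.
    """
    if spec is None:
        spec = PowerSpec(n_per_group=n_per_group, delta=delta, sd=sd, alpha=alpha)
    n = spec.n_per_group
    df = 2 * n - 2
    nc = spec.delta / (spec.sd * sqrt(2.0 / n))
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    # both rejection tails of the noncentral t
    power = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    return float(power)


def sample_size_for_power(
    target_power: float,
    delta: float,
    sd: float,
    alpha: float = 0.05,
    max_n: int = 1_000_000,
) -> int:
    """Smallest per-group n whose t-test power reaches ``target_power``.

    Found by increment search from n = 2 (power is monotone in n). Raises if
    the target is unreachable, e.g. delta = 0 or an absurd target.
    """
    if not alpha < target_power < 1:
        raise ValueError(
            f"target_power must lie in (alpha, 1) = ({alpha}, 1), got {target_power}"
        )
    if delta == 0:
        raise ValueError("delta = 0: power never exceeds alpha, target unreachable")
    n = 2
    while n <= max_n:
        if t_test_power(PowerSpec(n, delta, sd, alpha)) >= target_power:
            return n
        n += 1
    raise ValueError(f"target power {target_power} not reached by n = {max_n}")
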