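"""Sample size and power for Bland-Altman limits of agreement.

A method-comparison study is powered to show that both 95% limits of
agreement (LoA), together with their two-sided confidence bounds, lie inside
a prespecified clinically acceptable band (-delta, +delta).  Under a normal
model for the paired differences (mean mu_d, SD sd_d) the study succeeds
when

    d_bar + 1.96 s + t_{1-alpha/2, n-1} * s * sqrt(1/n + 1.96^2 / (2(n-1))) <  delta
    d_bar - 1.96 s - t_{1-alpha/2, n-1} * s * sqrt(1/n + 1.96^2 / (2(n-1))) > -delta

where d_bar and s are the sample mean and SD of the n differences and
``sqrt(1/n + 1.96^2 / (2(n-1)))`` is the standard approximate SE factor of
an estimated LoA.  ``loa_power`` evaluates the probability of that joint
event exactly under the normal model (integrating over the chi-square
distribution of s and the normal distribution of d_bar);
``power_by_simulation`` is an independent Monte-Carlo oracle applying the
same decision rule to simulated studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SampleSizeConfig",
    "SampleSizeResult",
    "loa_power",
    "loa_sample_size",
    "power_by_simulation",
]

Z_LOA = 1.96
_N_MAX = 1 << 20  # search ceiling; beyond this a config is declared infeasible


@dataclass(frozen=True)
class SampleSizeConfig:
    """Inputs of the LoA power calculation.

    mu_d, sd_d: expected mean and SD of the paired differences (mL);
    delta: the clinically acceptable bound on either limit (mL);
    alpha: two-sided level of the LoA confidence bounds;
    target_power: required probability that both bounds fall inside
    (-delta, +delta).
    """

    mu_d: float
    sd_d: float
    delta: float
    alpha: float = 0.05
    target_power: float = 0.8

    def __post_init__(self) -> None:
        if self.sd_d <= 0:
            raise ValueError("sd_d must be positive")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must lie in (0, 1)")

    @property
    def feasible(self) -> bool:
        """Both population LoA lie strictly inside the acceptable band."""
        return abs(self.mu_d) + Z_LOA * self.sd_d < self.delta


def _se_factor(n: int) -> float:
    """Approximate SE of an estimated LoA, in units of the sample SD."""
    return float(np.sqrt(1.0 / n + Z_LOA**2 / (2.0 * (n - 1))))


def loa_power(n: int, config: SampleSizeConfig, _grid: int = 4000) -> float:
    """Probability that both LoA confidence bounds lie inside (-delta, delta).

    Exact under the normal model: conditioning on the sample SD ``s``
    (chi-square), the event requires ``|d_bar| < delta - c(s)`` with
    ``c(s) = s * (1.96 + t_crit * se_factor)``, whose probability is a normal
    interval; the result is the chi-square-weighted average over ``s``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    df = n - 1
    tcrit = stats.t.ppf(1.0 - config.alpha / 2.0, df)
    c_mult = Z_LOA + tcrit * _se_factor(n)
    # midpoint quadrature on the probability scale of s
    u = (np.arange(_grid) + 0.5) / _grid
    s = config.sd_d * np.sqrt(stats.chi2.ppf(u, df) / df)
    margin = config.delta - c_mult * s
    se_mean = config.sd_d / np.sqrt(n)
    upper = stats.norm.cdf((margin - config.mu_d) / se_mean)
    lower = stats.norm.cdf((-margin - config.mu_d) / se_mean)
    prob = np.where(margin > 0, upper - lower, 0.0)
    return float(prob.mean())


def power_by_simulation(n: int, config: SampleSizeConfig, reps: int = 20000,
                        seed: int = 0) -> float:
    """Monte-Carlo oracle: fraction of simulated studies whose LoA confidence
    bounds both land inside (-delta, delta)."""
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for a stable estimate")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    df = n - 1
    tcrit = stats.t.ppf(1.0 - config.alpha / 2.0, df)
    sef = _se_factor(n)
    ok = 0
    chunk = max(1, min(reps, int(5e6) // n))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        x = rng.normal(config.mu_d, config.sd_d, size=(m, n))
        mean = x.mean(axis=1)
        s = x.std(axis=1, ddof=1)
        hw = tcrit * s * sef
        hi = mean + Z_LOA * s + hw
        lo = mean - Z_LOA * s - hw
        ok += int(np.count_nonzero((hi < config.delta) & (lo > -config.delta)))
        done += m
    return ok / reps


@dataclass(frozen=True)
class SampleSizeResult:
    """Minimal n meeting the power target, or an infeasibility marker."""

    n: int | None
    achieved_power: float
    config: SampleSizeConfig
    feasible: bool


def loa_sample_size(config: SampleSizeConfig) -> SampleSizeResult:
    """Minimal n with ``loa_power(n) >= target_power`` by bracketed search.

    Configs whose population LoA already touch or exceed the acceptable band
    can never reach the target (power tends to 0 as n grows) and are
    reported as infeasible instead of as an absurd n.
    """
    if not config.feasible:
        return SampleSizeResult(n=None, achieved_power=0.0, config=config,
                                feasible=False)
    lo, hi = 2, 2
    while loa_power(hi, config) < config.target_power:
        lo = hi
        hi *= 2
        if hi > _N_MAX:
            return SampleSizeResult(n=None, achieved_power=loa_power(lo, config),
                                    config=config, feasible=False)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if loa_power(mid, config) >= config.target_power:
            hi = mid
        else:
            lo = mid
    n = hi
    return SampleSizeResult(n=n, achieved_power=loa_power(n, config),
                            config=config, feasible=True)
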