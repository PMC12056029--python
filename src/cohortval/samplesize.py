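"""Two-group sample-size planning under effect-size uncertainty.

The fixed-design per-group size uses the normal-approximation closed form

    n = ceil( 2 * sd^2 * (z_{1-alpha/sides} + z_{power})^2 / delta^2 )

with a common standard deviation between the groups.  Uncertainty in the
effect size is propagated by scenario simulation: multipliers are drawn
between a lower and upper bound in [0, 1], shrink the nominal mean
difference, and yield a distribution of required sizes plus a table of
power-shortfall probabilities at candidate sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

SIDES_ONE = "one"
SIDES_TWO = "two"
MODE_UNIFORM = "uniform_random"
MODE_GRID = "grid"


class SampleSizeError(ValueError):
    pass


class ZeroEffectError(SampleSizeError):
    """Zero mean difference: the required sample size is unbounded."""


@dataclass(frozen=True)
class SampleSizeInputs:
    mean1: float
    mean2: float
    sd: float
    alpha: float = 0.05
    target_power: float = 0.8
    sides: str = SIDES_TWO

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise SampleSizeError("common standard deviation must be > 0")
        if not 0 < self.alpha < 1:
            raise SampleSizeError("alpha must lie in (0, 1)")
        if not 0 < self.target_power < 1:
            raise SampleSizeError("target power must lie in (0, 1)")
        if self.sides not in (SIDES_ONE, SIDES_TWO):
            raise SampleSizeError("sides must be 'one' or 'two'")

    @property
    def effect(self) -> float:
        return abs(self.mean1 - self.mean2)

    @property
    def z_alpha(self) -> float:
        divisor = 1 if self.sides == SIDES_ONE else 2
        return float(stats.norm.ppf(1 - self.alpha / divisor))

    def to_dict(self) -> dict:
        return {
            "mean1": self.mean1,
            "mean2": self.mean2,
            "sd": self.sd,
            "alpha": self.alpha,
            "target_power": self.target_power,
            "sides": self.sides,
        }


def required_n_fixed(inputs: SampleSizeInputs, effect: float | None = None) -> int:
    """Per-group sample size for the two-group comparison of means.

    ``effect`` overrides |mean1 - mean2| (used by scenario simulation).
    A floor of 2 per group is enforced.
    """
    delta = inputs.effect if effect is None else abs(effect)
    if delta == 0:
        raise ZeroEffectError(
            "zero effect size: the required sample size is unbounded"
        )
    z_beta = float(stats.norm.ppf(inputs.target_power))
    n = math.ceil(2.0 * inputs.sd**2 * (inputs.z_alpha + z_beta) ** 2 / delta**2)
    return max(n, 2)


def achieved_power(
    inputs: SampleSizeInputs, n: int, effect: float | None = None
) -> float:
    """Normal-approximation power of the two-group test at per-group size n
    (dominant tail): Phi(|delta| / (sd * sqrt(2/n)) - z_{1-alpha/sides})."""
    if n < 2:
        raise SampleSizeError("per-group size must be at least 2")
    delta = inputs.effect if effect is None else abs(effect)
    ncp = delta / (inputs.sd * math.sqrt(2.0 / n))
    return float(stats.norm.cdf(ncp - inputs.z_alpha))


@dataclass
class SampleSizeScenarioResult:
    """Distribution of required sizes under effect-size uncertainty."""

    inputs: SampleSizeInputs
    lower: float
    upper: float
    n_scenarios: int
    mode: str
    scenario_multipliers: np.ndarray
    scenario_effects: np.ndarray
    scenario_n: np.ndarray
    summary: dict  # minimum, median, mean, maximum of scenario_n
    power_table: list[dict] = field(default_factory=list)
    power_threshold: float = 0.90
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "inputs": self.inputs.to_dict(),
            "lower": self.lower,
            "upper": self.upper,
            "n_scenarios": self.n_scenarios,
            "mode": self.mode,
            "scenario_multipliers": self.scenario_multipliers.tolist(),
            "scenario_effects": self.scenario_effects.tolist(),
            "scenario_n": self.scenario_n.tolist(),
            "summary": dict(self.summary),
            "power_table": [dict(row) for row in self.power_table],
            "power_threshold": self.power_threshold,
            "seed": self.seed,
        }


def scenario_sample_sizes(
    inputs: SampleSizeInputs,
    lower: float,
    upper: float,
    n_scenarios: int,
    mode: str = MODE_UNIFORM,
    seed: int = 0,
    power_threshold: float = 0.90,
) -> SampleSizeScenarioResult:
    """Propagate effect-size uncertainty into a required-size distribution.

    Scenario multipliers are drawn uniformly on [lower, upper] (or equally
    spaced in ``grid`` mode); each scenario's effect is the multiplier
    times |mean1 - mean2|, and its required per-group size comes from
    :func:`required_n_fixed`.  The summary reports the minimum, median,
    mean and maximum of the per-group sizes; the power table reports, for
    candidate sizes, the fraction of scenarios whose achieved power falls
    below ``power_threshold``.
    """
    if inputs.effect == 0:
        raise ZeroEffectError("zero nominal effect size")
    if not 0 <= lower <= upper <= 1:
        raise SampleSizeError("bounds must satisfy 0 <= lower <= upper <= 1")
    if lower == 0:
        raise SampleSizeError(
            "lower bound 0 gives a zero-effect scenario with unbounded "
            "sample size; choose lower > 0"
        )
    if n_scenarios < 1:
        raise SampleSizeError("need at least one scenario")
    if mode == MODE_UNIFORM:
        rng = np.random.default_rng(seed)
        multipliers = rng.uniform(lower, upper, n_scenarios)
    elif mode == MODE_GRID:
        multipliers = np.linspace(lower, upper, n_scenarios)
    else:
        raise SampleSizeError(f"unknown scenario mode {mode!r}")
    effects = multipliers * inputs.effect
    scenario_n = np.array(
        [required_n_fixed(inputs, effect=e) for e in effects], dtype=int
    )
    summary = {
        "minimum": int(scenario_n.min()),
        "median": float(np.median(scenario_n)),
        "mean": float(scenario_n.mean()),
        "maximum": int(scenario_n.max()),
    }
    result = SampleSizeScenarioResult(
        inputs=inputs,
        lower=lower,
        upper=upper,
        n_scenarios=n_scenarios,
        mode=mode,
        scenario_multipliers=multipliers,
        scenario_effects=effects,
        scenario_n=scenario_n,
        summary=summary,
        power_threshold=power_threshold,
        seed=seed,
    )
    result.power_table = power_probability_table(result, inputs)
    return result


def power_probability_table(
    result: SampleSizeScenarioResult,
    inputs: SampleSizeInputs,
    candidate_ns: Sequence[int] | None = None,
) -> list[dict]:
    """Fraction of scenarios with achieved power below the threshold, per
    candidate per-group size.

    Default candidates are the deciles of the scenario sizes (deduplicated,
    ascending).  The fractions are non-increasing in the candidate size.
    """
    if result.scenario_n.size == 0:
        raise SampleSizeError("empty scenario set")
    if candidate_ns is None:
        deciles = np.percentile(
            result.scenario_n, np.arange(0, 101, 10), method="nearest"
        )
        candidate_ns = sorted(set(int(v) for v in deciles))
    else:
        candidate_ns = sorted(set(int(v) for v in candidate_ns))
        if any(n < 2 for n in candidate_ns):
            raise SampleSizeError("candidate sizes must be at least 2")
    rows = []
    previous = 1.0
    for n in candidate_ns:
        powers = np.array(
            [achieved_power(inputs, n, effect=e) for e in result.scenario_effects]
        )
        fraction = float((powers < result.power_threshold).mean())
        # power is monotone in n per scenario, so this cannot increase
        assert fraction <= previous + 1e-12
        previous = fraction
        rows.append({"n": n, "fraction_below_threshold": fraction})
    return rows
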