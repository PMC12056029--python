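"""Paired real/virtual cohort generators with known ground truth.

The real cohort is drawn from a base model: a multivariate-normal
continuous block, optional independent categorical variables, and an
optional censored-exponential time-to-event variable.  The virtual cohort
is drawn from a perturbed model (mean shift and covariance scaling of the
continuous block), so deviating cohorts can be produced on demand.  The
two cohorts use disjoint child streams of one seed, so changing ``n_real``
does not perturb the virtual draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    CONTINUOUS,
    DISCRETE,
    TIME_TO_EVENT,
    Cohort,
    CohortError,
    VariableSpec,
)


@dataclass
class TimeToEventSpec:
    """Exponential event/censoring model: time = min(event, censor)."""

    rate: float
    censor_rate: float = 0.0
    name: str = "time"
    event_name: str = "event"

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("event rate must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor rate must be >= 0")


@dataclass
class SyntheticSpec:
    """Ground-truth model for a paired real/virtual cohort draw."""

    n_real: int
    n_virtual: int
    mean_vector: Sequence[float]
    covariance: Sequence[Sequence[float]]
    continuous_names: Sequence[str] | None = None
    discrete_levels: Mapping[str, Mapping[str, float]] | None = None
    tte: TimeToEventSpec | None = None
    mean_shift: Sequence[float] | None = None
    covariance_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_real <= 0 or self.n_virtual <= 0:
            raise ValueError("cohort sizes must be positive")
        self.mean_vector = np.asarray(self.mean_vector, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        p = len(self.mean_vector)
        if self.covariance.shape != (p, p):
            raise ValueError("covariance shape does not match mean vector")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(self.covariance)) <= 0:
            raise ValueError("covariance must be positive definite")
        if self.covariance_scale <= 0:
            raise ValueError("covariance_scale must be > 0")
        if self.mean_shift is None:
            self.mean_shift = np.zeros(p)
        else:
            self.mean_shift = np.asarray(self.mean_shift, dtype=float)
            if self.mean_shift.shape != (p,):
                raise ValueError("mean_shift length must match mean vector")
        if self.continuous_names is None:
            self.continuous_names = [f"x{i + 1}" for i in range(p)]
        if len(self.continuous_names) != p:
            raise ValueError("continuous_names length must match mean vector")
        if self.discrete_levels:
            for name, probs in self.discrete_levels.items():
                pv = np.asarray(list(probs.values()), dtype=float)
                if np.any(pv < 0):
                    raise ValueError(f"negative level probability for {name!r}")
                if abs(pv.sum() - 1.0) > 1e-12:
                    raise ValueError(f"level probabilities for {name!r} must sum to 1")

    @property
    def p(self) -> int:
        return len(self.mean_vector)

    def to_dict(self) -> dict:
        out = {
            "n_real": self.n_real,
            "n_virtual": self.n_virtual,
            "mean_vector": np.asarray(self.mean_vector).tolist(),
            "covariance": np.asarray(self.covariance).tolist(),
            "continuous_names": list(self.continuous_names),
            "mean_shift": np.asarray(self.mean_shift).tolist(),
            "covariance_scale": self.covariance_scale,
            "seed": self.seed,
        }
        if self.discrete_levels:
            out["discrete_levels"] = {
                k: dict(v) for k, v in self.discrete_levels.items()
            }
        if self.tte:
            out["tte"] = {
                "rate": self.tte.rate,
                "censor_rate": self.tte.censor_rate,
                "name": self.tte.name,
                "event_name": self.tte.event_name,
            }
        return out


def _draw_cohort(
    spec: SyntheticSpec,
    n: int,
    mean: np.ndarray,
    cov: np.ndarray,
    provenance: str,
    rng: np.random.Generator,
) -> Cohort:
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n, spec.p))
    block = mean + z @ chol.T

    columns: dict[str, object] = {
        name: block[:, j] for j, name in enumerate(spec.continuous_names)
    }
    variables = [VariableSpec(name, CONTINUOUS) for name in spec.continuous_names]

    if spec.discrete_levels:
        for name, probs in spec.discrete_levels.items():
            levels = list(probs.keys())
            pv = np.asarray(list(probs.values()), dtype=float)
            pv = pv / pv.sum()
            columns[name] = rng.choice(levels, size=n, p=pv).astype(object)
            variables.append(VariableSpec(name, DISCRETE))

    if spec.tte:
        t_event = rng.exponential(scale=1.0 / spec.tte.rate, size=n)
        if spec.tte.censor_rate > 0:
            t_censor = rng.exponential(scale=1.0 / spec.tte.censor_rate, size=n)
        else:
            t_censor = np.full(n, np.inf)
        time = np.minimum(t_event, t_censor)
        event = (t_event <= t_censor).astype(float)
        columns[spec.tte.name] = time
        columns[spec.tte.event_name] = event
        variables.append(
            VariableSpec(spec.tte.name, TIME_TO_EVENT, spec.tte.event_name)
        )

    data = pd.DataFrame(columns)
    for name in data.columns:
        if data[name].dtype != object:
            data[name] = data[name].astype(float)
    return Cohort(data=data, variables=variables, provenance=provenance)


def generate_pair(spec: SyntheticSpec) -> tuple[Cohort, Cohort]:
    """Draw a (real, virtual) cohort pair.

    The real cohort comes from the base model; the virtual cohort from the
    perturbed model ``N(mean + mean_shift, covariance * covariance_scale)``.
    Bit-identical for identical spec and seed.
    """
    ss_real, ss_virtual = np.random.SeedSequence(spec.seed).spawn(2)
    mean = np.asarray(spec.mean_vector, dtype=float)
    cov = np.asarray(spec.covariance, dtype=float)
    real = _draw_cohort(
        spec, spec.n_real, mean, cov, "real", np.random.default_rng(ss_real)
    )
    virtual = _draw_cohort(
        spec,
        spec.n_virtual,
        mean + np.asarray(spec.mean_shift, dtype=float),
        cov * spec.covariance_scale,
        "virtual",
        np.random.default_rng(ss_virtual),
    )
    return real, virtual


def sample_moments(
    cohort: Cohort, variables: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Sample mean vector and covariance matrix (divisor n-1) on complete rows."""
    for name in variables:
        if cohort.kind_of(name) != CONTINUOUS:
            raise CohortError(f"variable {name!r} is not continuous")
    mask = cohort.complete_mask(variables)
    if int(mask.sum()) < 2:
        raise CohortError("sample moments need at least 2 complete rows")
    block = np.column_stack(
        [cohort.data[name].to_numpy(dtype=float)[mask] for name in variables]
    )
    mean = block.mean(axis=0)
    cov = np.cov(block, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return mean, cov
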