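"""Validation views comparing a virtual cohort against a real cohort.

Four views are provided:

* univariate descriptive comparison (mean, sd, min, max; boxplot statistics;
  scatter-plot point sets),
* bivariate comparison via per-cohort Spearman correlation matrices,
* multivariate comparison via per-record standardized quadratic forms
  ``d_i = (x_i - xbar)' S^{-1} (x_i - xbar)`` against a chi-squared
  reference, with QQ pairing between the cohorts, and
* variability assessment via bootstrap pointwise confidence bands on
  nonparametric density estimates.

All stochastic operations are pure functions of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CONTINUOUS, Cohort, CohortError

DF_MODE_PAPER = "paper"       # chi-squared df = p - 1
DF_MODE_CLASSICAL = "classical"  # chi-squared df = p


class SingularCovarianceError(CohortError):
    """Sample covariance is singular; carries the offending variable pairs."""

    def __init__(self, message: str, collinear: list[tuple[str, str]]):
        super().__init__(message)
        self.collinear = collinear


# ---------------------------------------------------------------------------
# univariate
# ---------------------------------------------------------------------------


@dataclass
class UnivariateSummary:
    """Side-by-side per-variable descriptive statistics for the two cohorts."""

    table: pd.DataFrame  # columns: variable, cohort, n, mean, sd, min, max

    def to_dict(self) -> dict:
        return {"rows": self.table.to_dict(orient="records")}


def _describe(values: np.ndarray) -> dict:
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "min": float(values.min()),
        "max": float(values.max()),
    }


def summarize_univariate(
    real: Cohort, virtual: Cohort, variables: Sequence[str]
) -> UnivariateSummary:
    """Mean, standard deviation (divisor n-1), minimum and maximum per
    variable and cohort, computed on complete cases per variable."""
    rows = []
    for name in variables:
        for cohort, label in ((real, "real"), (virtual, "virtual")):
            values = cohort.numeric(name)
            if values.size < 2:
                raise CohortError(
                    f"variable {name!r} has fewer than 2 complete rows in "
                    f"the {label} cohort"
                )
            rows.append({"variable": name, "cohort": label, **_describe(values)})
    table = pd.DataFrame(
        rows, columns=["variable", "cohort", "n", "mean", "sd", "min", "max"]
    )
    return UnivariateSummary(table=table)


@dataclass
class BoxplotStats:
    """Tukey boxplot statistics for one variable in one cohort."""

    variable: str
    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "n": self.n,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "whisker_low": self.whisker_low,
            "whisker_high": self.whisker_high,
            "outliers": list(self.outliers),
        }


def boxplot_stats(cohort: Cohort, variable: str) -> BoxplotStats:
    """Quartiles by linear-interpolation quantiles; whiskers at the most
    extreme points within 1.5*IQR of the quartiles; points beyond are
    outliers."""
    values = cohort.numeric(variable)
    if values.size < 1:
        raise CohortError(f"variable {variable!r} has no complete rows")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return BoxplotStats(
        variable=variable,
        n=int(values.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=sorted(float(v) for v in outliers),
    )


@dataclass
class ScatterPair:
    """Pairwise-complete point sets of one variable pair, per cohort."""

    x: str
    y: str
    real: np.ndarray     # shape (n, 2)
    virtual: np.ndarray  # shape (n, 2)

    def to_dict(self) -> dict:
        return {
            "x": self.x,
            "y": self.y,
            "real": self.real.tolist(),
            "virtual": self.virtual.tolist(),
        }


def scatter_pairs(
    real: Cohort, virtual: Cohort, variables: Sequence[str]
) -> list[ScatterPair]:
    """Point sets for every unordered pair of the named continuous
    variables.  Rows are dropped pairwise: a row missing on one member of a
    pair is excluded from that pair only."""
    if len(variables) < 2:
        raise CohortError("scatter pairs need at least 2 variables")

    def points(cohort: Cohort, a: str, b: str) -> np.ndarray:
        xa = cohort.data[a].to_numpy(dtype=float)
        xb = cohort.data[b].to_numpy(dtype=float)
        ok = ~np.isnan(xa) & ~np.isnan(xb)
        return np.column_stack([xa[ok], xb[ok]])

    for name in variables:
        for cohort in (real, virtual):
            if cohort.kind_of(name) != CONTINUOUS:
                raise CohortError(f"variable {name!r} is not continuous")
    pairs = []
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            pairs.append(
                ScatterPair(
                    x=a, y=b, real=points(real, a, b), virtual=points(virtual, a, b)
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# bivariate
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    """Spearman correlation matrices per cohort and their difference.

    Entries involving a constant variable are undefined and stored as NaN;
    the affected variables are listed in ``undefined_real`` /
    ``undefined_virtual`` rather than silently reported as zero.
    """

    variables: list[str]
    real_matrix: np.ndarray
    virtual_matrix: np.ndarray
    difference_matrix: np.ndarray
    undefined_real: list[str]
    undefined_virtual: list[str]

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "real_matrix": self.real_matrix.tolist(),
            "virtual_matrix": self.virtual_matrix.tolist(),
            "difference_matrix": self.difference_matrix.tolist(),
            "undefined_real": list(self.undefined_real),
            "undefined_virtual": list(self.undefined_virtual),
        }


def _spearman_matrix(
    cohort: Cohort, variables: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    mask = cohort.complete_mask(variables)
    if int(mask.sum()) < 3:
        raise CohortError("Spearman matrices need at least 3 complete rows")
    block = np.column_stack(
        [cohort.data[name].to_numpy(dtype=float)[mask] for name in variables]
    )
    constant = [
        variables[j] for j in range(block.shape[1])
        if np.ptp(block[:, j]) == 0.0
    ]
    # rank transform with average ranks for ties, then Pearson on ranks
    ranks = np.column_stack(
        [stats.rankdata(block[:, j], method="average") for j in range(block.shape[1])]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = np.corrcoef(ranks, rowvar=False)
    matrix = np.atleast_2d(matrix)
    np.fill_diagonal(matrix, 1.0)
    for name in constant:
        j = list(variables).index(name)
        matrix[j, :] = np.nan
        matrix[:, j] = np.nan
        matrix[j, j] = 1.0
    return matrix, constant


def spearman_matrices(
    real: Cohort, virtual: Cohort, variables: Sequence[str]
) -> CorrelationResult:
    """Spearman rank correlation between all named variables, separately
    for the real and the virtual cohort, plus virtual - real differences."""
    if len(variables) < 2:
        raise CohortError("need at least 2 variables for correlation matrices")
    for name in variables:
        for cohort in (real, virtual):
            if cohort.kind_of(name) != CONTINUOUS:
                raise CohortError(f"variable {name!r} is not continuous")
    real_m, undef_r = _spearman_matrix(real, variables)
    virt_m, undef_v = _spearman_matrix(virtual, variables)
    return CorrelationResult(
        variables=list(variables),
        real_matrix=real_m,
        virtual_matrix=virt_m,
        difference_matrix=virt_m - real_m,
        undefined_real=undef_r,
        undefined_virtual=undef_v,
    )


# ---------------------------------------------------------------------------
# multivariate
# ---------------------------------------------------------------------------


@dataclass
class QuadraticFormResult:
    """Per-record standardized quadratic forms with chi-squared reference.

    ``d_real`` / ``d_virtual`` hold, for every record, the squared
    standardized distance from its own cohort's sample mean under the
    cohort's sample covariance (divisor n-1).  With that divisor the sum of
    d over a cohort equals ``p * (n - 1)`` exactly.
    """

    variables: list[str]
    d_real: np.ndarray
    d_virtual: np.ndarray
    p: int
    df: int
    df_mode: str
    qq_pairs: np.ndarray       # columns: (real quantile, virtual quantile)
    hist_bin_edges: np.ndarray
    hist_counts_real: np.ndarray
    hist_counts_virtual: np.ndarray

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "d_real": self.d_real.tolist(),
            "d_virtual": self.d_virtual.tolist(),
            "p": self.p,
            "df": self.df,
            "df_mode": self.df_mode,
            "qq_pairs": self.qq_pairs.tolist(),
            "hist_bin_edges": self.hist_bin_edges.tolist(),
            "hist_counts_real": self.hist_counts_real.tolist(),
            "hist_counts_virtual": self.hist_counts_virtual.tolist(),
        }


def mahalanobis_quadratic_forms(
    block: np.ndarray, variables: Sequence[str]
) -> np.ndarray:
    """d_i for every row of ``block`` against the block's own sample mean
    and sample covariance (divisor n-1)."""
    n, p = block.shape
    if n <= p:
        raise CohortError(f"need more than p={p} complete rows, got n={n}")
    centered = block - block.mean(axis=0)
    cov = np.atleast_2d(np.cov(block, rowvar=False, ddof=1))
    zero_var = [variables[j] for j in range(p) if cov[j, j] == 0.0]
    if zero_var:
        raise SingularCovarianceError(
            f"constant variables make the covariance singular: {zero_var}",
            collinear=[(v, v) for v in zero_var],
        )
    # detect exact collinearity before factorization so the error names it
    with np.errstate(invalid="ignore"):
        corr = cov / np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
    collinear = [
        (variables[i], variables[j])
        for i in range(p)
        for j in range(i + 1, p)
        if abs(corr[i, j]) > 1 - 1e-12
    ]
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise SingularCovarianceError(
            f"singular sample covariance for variables {list(variables)}"
            + (f"; collinear pairs: {collinear}" if collinear else ""),
            collinear=collinear,
        ) from None
    if collinear:
        raise SingularCovarianceError(
            f"collinear variable pairs make the covariance singular: {collinear}",
            collinear=collinear,
        )
    w = np.linalg.solve(chol, centered.T)
    return np.sum(w * w, axis=0)


def quadratic_forms(
    real: Cohort,
    virtual: Cohort,
    variables: Sequence[str],
    df_mode: str = DF_MODE_PAPER,
    n_bins: int = 30,
) -> QuadraticFormResult:
    """Standardized quadratic forms for each cohort, QQ pairing between
    them, and shared histogram bins.

    Each cohort is standardized against its own mean and covariance.  The
    chi-squared reference uses ``df = p - 1`` in ``paper`` mode and
    ``df = p`` in ``classical`` mode (the usual asymptotic for squared
    Mahalanobis distances).
    """
    if df_mode not in (DF_MODE_PAPER, DF_MODE_CLASSICAL):
        raise CohortError(f"unknown df_mode {df_mode!r}")
    if len(variables) < 1:
        raise CohortError("need at least one variable")
    for name in variables:
        for cohort in (real, virtual):
            if cohort.kind_of(name) != CONTINUOUS:
                raise CohortError(f"variable {name!r} is not continuous")

    def block(cohort: Cohort) -> np.ndarray:
        mask = cohort.complete_mask(variables)
        return np.column_stack(
            [cohort.data[name].to_numpy(dtype=float)[mask] for name in variables]
        )

    d_real = mahalanobis_quadratic_forms(block(real), variables)
    d_virtual = mahalanobis_quadratic_forms(block(virtual), variables)

    p = len(variables)
    df = max(p - 1, 1) if df_mode == DF_MODE_PAPER else p

    m = min(d_real.size, d_virtual.size)
    probs = (np.arange(1, m + 1) - 0.5) / m
    qq_pairs = np.column_stack(
        [np.quantile(d_real, probs), np.quantile(d_virtual, probs)]
    )

    hi = float(max(d_real.max(), d_virtual.max()))
    edges = np.linspace(0.0, hi if hi > 0 else 1.0, n_bins + 1)
    counts_real, _ = np.histogram(d_real, bins=edges)
    counts_virtual, _ = np.histogram(d_virtual, bins=edges)

    return QuadraticFormResult(
        variables=list(variables),
        d_real=d_real,
        d_virtual=d_virtual,
        p=p,
        df=df,
        df_mode=df_mode,
        qq_pairs=qq_pairs,
        hist_bin_edges=edges,
        hist_counts_real=counts_real,
        hist_counts_virtual=counts_virtual,
    )


def chi2_reference(df: int, probs: Sequence[float]) -> np.ndarray:
    """Chi-squared quantiles at the given probabilities, for overlaying on
    QQ displays and histograms."""
    if df < 1:
        raise CohortError("degrees of freedom must be >= 1")
    probs = np.asarray(probs, dtype=float)
    if np.any((probs <= 0) | (probs >= 1)):
        raise CohortError("probabilities must lie strictly inside (0, 1)")
    return stats.chi2.ppf(probs, df)


# ---------------------------------------------------------------------------
# variability assessment
# ---------------------------------------------------------------------------


@dataclass
class DensityBandResult:
    """Bootstrap pointwise confidence band on virtual-cohort densities.

    ``p_value`` is the fraction of grid points at which the real-data
    density falls outside the band (the out-of-band statistic normalized by
    the number of grid points); ``deviation_detected`` is true when that
    fraction exceeds ``deviation_threshold``.
    """

    variable: str
    grid: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    density_real: np.ndarray
    density_virtual: np.ndarray
    B: int
    level: float
    bandwidth_real: float
    bandwidth_virtual: float
    outside_fraction: float
    p_value: float
    deviation_threshold: float
    deviation_detected: bool
    seed: int

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "grid": self.grid.tolist(),
            "band_lower": self.band_lower.tolist(),
            "band_upper": self.band_upper.tolist(),
            "density_real": self.density_real.tolist(),
            "density_virtual": self.density_virtual.tolist(),
            "B": self.B,
            "level": self.level,
            "bandwidth_real": self.bandwidth_real,
            "bandwidth_virtual": self.bandwidth_virtual,
            "outside_fraction": self.outside_fraction,
            "p_value": self.p_value,
            "deviation_threshold": self.deviation_threshold,
            "deviation_detected": self.deviation_detected,
            "seed": self.seed,
        }


def bandwidth_rule_of_thumb(values: np.ndarray) -> float:
    """Silverman-style rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    n = values.size
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    q1, q3 = np.percentile(values, [25, 75])
    spread = min(sd, (q3 - q1) / 1.34)
    if spread <= 0:
        spread = sd
    if spread <= 0:
        spread = max(abs(float(values.mean())), 1.0)
    return 0.9 * spread * n ** (-0.2)


_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


def gaussian_kde_on_grid(
    values: np.ndarray, bandwidth: float, grid: np.ndarray
) -> np.ndarray:
    """Gaussian-kernel density of ``values`` evaluated at ``grid``."""
    z = (grid[:, None] - values[None, :]) / bandwidth
    return np.exp(-0.5 * z * z).sum(axis=1) / (values.size * bandwidth * _SQRT_2PI)


def bootstrap_density_band(
    real: Cohort,
    virtual: Cohort,
    variable: str,
    B: int = 500,
    level: float = 0.95,
    deviation_threshold: float = 0.05,
    seed: int = 0,
    grid_size: int = 512,
) -> DensityBandResult:
    """Pointwise bootstrap confidence band for the virtual-cohort density,
    with the real-cohort density as the reference.

    ``B`` resamples of size ``n_virtual`` are drawn with replacement from
    the virtual values.  Each replicate's Gaussian-kernel density (with the
    rule-of-thumb bandwidth re-estimated per replicate) is evaluated on a
    shared grid of ``grid_size`` equally spaced points spanning the pooled
    data range extended by three bandwidths.  The band is the pointwise
    ((1-level)/2, 1-(1-level)/2) percentile envelope across replicates.
    """
    if B < 100:
        raise CohortError("B must be at least 100")
    if not 0 < level < 1:
        raise CohortError("level must lie in (0, 1)")
    x_real = real.numeric(variable)
    x_virtual = virtual.numeric(variable)
    if x_real.size < 10 or x_virtual.size < 10:
        raise CohortError("need at least 10 complete rows per cohort")

    bw_real = bandwidth_rule_of_thumb(x_real)
    bw_virtual = bandwidth_rule_of_thumb(x_virtual)
    pad = 3.0 * max(bw_real, bw_virtual)
    lo = min(x_real.min(), x_virtual.min()) - pad
    hi = max(x_real.max(), x_virtual.max()) + pad
    grid = np.linspace(lo, hi, grid_size)

    rng = np.random.default_rng(seed)
    n_v = x_virtual.size
    replicate_densities = np.empty((B, grid_size))
    for b in range(B):
        sample = x_virtual[rng.integers(0, n_v, n_v)]
        replicate_densities[b] = gaussian_kde_on_grid(
            sample, bandwidth_rule_of_thumb(sample), grid
        )
    alpha = (1.0 - level) / 2.0
    band_lower, band_upper = np.percentile(
        replicate_densities, [100 * alpha, 100 * (1 - alpha)], axis=0
    )

    density_real = gaussian_kde_on_grid(x_real, bw_real, grid)
    density_virtual = gaussian_kde_on_grid(x_virtual, bw_virtual, grid)

    outside = (density_real < band_lower) | (density_real > band_upper)
    outside_fraction = float(outside.mean())
    return DensityBandResult(
        variable=variable,
        grid=grid,
        band_lower=band_lower,
        band_upper=band_upper,
        density_real=density_real,
        density_virtual=density_virtual,
        B=B,
        level=level,
        bandwidth_real=bw_real,
        bandwidth_virtual=bw_virtual,
        outside_fraction=outside_fraction,
        p_value=outside_fraction,
        deviation_threshold=deviation_threshold,
        deviation_detected=outside_fraction > deviation_threshold,
        seed=seed,
    )
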