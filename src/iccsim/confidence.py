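"""Confidence limits for the population ICC.

Two routes are provided:

* **Analytic** F-based intervals for ICC(1), ICC(C,1) and ICC(A,1), the
  standard formulas used by mainstream statistical software (the ICC(A,1)
  interval uses a Satterthwaite-approximated denominator degrees of freedom).
* **Simulation-based** limits obtained by inverting the 95% central range of
  the ICC(1) sampling distribution over a grid of population ICC values: the
  confidence interval for rho given an observed sample ICC is the set of rho
  whose central range contains that value.  Because the consistency ICC
  distribution is unaffected by column bias, the same curves serve ICC(C,1);
  they do not apply to ICC(A,1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .anova import AnovaTable, batch_mean_squares
from .estimators import IccEstimate
from .exceptions import (
    DegenerateInputError,
    GridResolutionError,
    InsufficientSampleError,
    InvalidInputError,
)

__all__ = [
    "CentralRange",
    "ConfidenceCurve",
    "central_range",
    "analytic_ci",
    "build_confidence_curve",
    "simulated_confidence_limits",
]


@dataclass(frozen=True)
class CentralRange:
    """Empirical central range of a simulated distribution.

    With N values and level 1 - alpha, the lower limit is the order statistic
    of rank m = floor(alpha/2 * N) (1-based, ascending) and the upper limit
    the order statistic of rank N - m + 1; i.e. the highest value among the m
    lowest and the lowest value among the m highest.
    """

    lower: float
    upper: float
    level: float
    n_values: int

    def to_dict(self) -> dict:
        return {
            "lower": self.lower,
            "upper": self.upper,
            "level": self.level,
            "n_values": self.n_values,
        }


def central_range(values, level: float = 0.95) -> CentralRange:
    """Order-statistic central range of a sample of simulated values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InsufficientSampleError("no values supplied")
    if not 0 < level < 1:
        raise InvalidInputError("level must be in (0, 1)")
    n = values.size
    m = math.floor((1 - level) / 2 * n)
    if m < 1:
        raise InsufficientSampleError(
            f"{n} values are too few for a {level:.0%} central range"
        )
    ordered = np.sort(values)
    return CentralRange(
        lower=float(ordered[m - 1]),
        upper=float(ordered[n - m]),
        level=level,
        n_values=n,
    )


def analytic_ci(
    estimate: IccEstimate,
    anova: AnovaTable,
    n: int | None = None,
    k: int | None = None,
    level: float = 0.95,
) -> IccEstimate:
    """Attach the standard F-based confidence interval to a sample ICC.

    Returns a new :class:`IccEstimate`; the point estimate is untouched.  A
    sample ICC of exactly 1 (zero error mean square) yields the degenerate
    interval (value, 1) with a flag.
    """
    n = anova.n if n is None else n
    k = anova.k if k is None else k
    if not 0 < level < 1:
        raise InvalidInputError("level must be in (0, 1)")
    alpha = 1 - level
    out = IccEstimate(
        estimate.formula, estimate.value, confidence_level=level, ci_method="analytic"
    )

    if estimate.value >= 1.0:
        out.ci_lower, out.ci_upper = estimate.value, 1.0
        out.ci_degenerate = True
        return out

    if estimate.formula in ("ICC1", "ICC_C1"):
        if estimate.formula == "ICC1":
            ms_err, df2 = anova.msws, n * (k - 1)
        else:
            ms_err, df2 = anova.mse, (n - 1) * (k - 1)
        if ms_err <= 0:
            out.ci_lower, out.ci_upper = estimate.value, 1.0
            out.ci_degenerate = True
            return out
        f_obs = anova.msbs / ms_err
        f_lower = f_obs / stats.f.ppf(1 - alpha / 2, n - 1, df2)
        f_upper = f_obs * stats.f.ppf(1 - alpha / 2, df2, n - 1)
        out.ci_lower = (f_lower - 1) / (f_lower + k - 1)
        out.ci_upper = (f_upper - 1) / (f_upper + k - 1)
        return out

    if estimate.formula == "ICC_A1":
        icc = estimate.value
        a = k * icc / (n * (1 - icc))
        b = 1 + k * icc * (n - 1) / (n * (1 - icc))
        num = (a * anova.msbm + b * anova.mse) ** 2
        den = (a * anova.msbm) ** 2 / (k - 1) + (b * anova.mse) ** 2 / (
            (n - 1) * (k - 1)
        )
        if den <= 0:
            out.ci_lower, out.ci_upper = estimate.value, 1.0
            out.ci_degenerate = True
            return out
        nu = num / den
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, nu)
        f2 = stats.f.ppf(1 - alpha / 2, nu, n - 1)
        c = k * anova.msbm + (k * n - k - n) * anova.mse
        out.ci_lower = n * (anova.msbs - f1 * anova.mse) / (f1 * c + n * anova.msbs)
        out.ci_upper = n * (f2 * anova.msbs - anova.mse) / (c + n * f2 * anova.msbs)
        return out

    raise InvalidInputError(f"unknown ICC formula {estimate.formula!r}")


@dataclass(frozen=True)
class ConfidenceCurve:
    """Central-range limits of the ICC(1) sampling distribution as a function
    of the population ICC, for fixed n and k.

    Read vertically (at fixed rho) the curves give the central range of the
    sample ICC; read horizontally (at a fixed sample ICC) they give the
    simulation-based confidence limits for rho.
    """

    rho_grid: np.ndarray
    lower_curve: np.ndarray
    upper_curve: np.ndarray
    n: int
    k: int
    level: float
    n_replicates: int
    seed: int

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.rho_grid, self.lower_curve, self.upper_curve])
        np.savetxt(path, arr, delimiter=",", header="rho,lower,upper", comments="", fmt="%.6f")

    def invert(self, sample_icc: float) -> tuple[float, float]:
        """Confidence limits for rho given an observed sample ICC.

        lower = smallest rho whose upper central-range limit reaches
        ``sample_icc``; upper = largest rho whose lower limit does not exceed
        it.  Linear interpolation between grid points mirrors a graphical
        reading of the curves.
        """
        if not 0 <= sample_icc < 1:
            raise InvalidInputError("sample ICC must lie in [0, 1)")
        rho, lo, up = self.rho_grid, self.lower_curve, self.upper_curve

        # lower limit: first crossing of the upper curve
        above = up >= sample_icc
        if not above.any():
            raise GridResolutionError(
                "upper central-range curve never reaches the sample ICC; extend the grid"
            )
        i = int(np.argmax(above))
        if i == 0:
            lower = float(rho[0])
        else:
            lower = float(
                np.interp(sample_icc, [up[i - 1], up[i]], [rho[i - 1], rho[i]])
            )

        # upper limit: last rho with lower curve <= sample ICC
        below = lo <= sample_icc
        if not below.any():
            raise GridResolutionError(
                "lower central-range curve exceeds the sample ICC everywhere; refine the grid"
            )
        j = int(len(rho) - 1 - np.argmax(below[::-1]))
        if j == len(rho) - 1:
            # sample ICC above the whole lower curve: rho is only bounded by 1
            upper = 1.0
        else:
            upper = float(
                np.interp(sample_icc, [lo[j], lo[j + 1]], [rho[j], rho[j + 1]])
            )
        return lower, upper


def build_confidence_curve(
    n: int,
    k: int,
    level: float = 0.95,
    grid_step: float = 0.01,
    n_replicates: int = 10000,
    seed: int = 0,
) -> ConfidenceCurve:
    """Simulate the central-range curves over a population-ICC grid.

    Each grid value rho is realised by a one-way model with sigma_r^2 = rho
    and sigma_v^2 = 1 - rho (only the ratio matters for the ICC), simulating
    ``n_replicates`` matrices and taking the central range of the ICC(1)
    values.  One seeded generator drives the whole grid.
    """
    if grid_step <= 0 or grid_step >= 1:
        raise InvalidInputError("grid_step must be in (0, 1)")
    rho_grid = np.arange(0.0, 1.0 - 1e-12, grid_step)
    rng = np.random.default_rng(seed)
    lower = np.empty_like(rho_grid)
    upper = np.empty_like(rho_grid)
    for idx, rho in enumerate(rho_grid):
        sigma_r = math.sqrt(rho)
        sigma_v = math.sqrt(1.0 - rho)
        x = rng.normal(0.0, sigma_r, (n_replicates, n, 1)) + rng.normal(
            0.0, sigma_v, (n_replicates, n, k)
        )
        ms = batch_mean_squares(x)
        icc = (ms["MSBS"] - ms["MSWS"]) / (ms["MSBS"] + (k - 1) * ms["MSWS"])
        cr = central_range(icc, level)
        lower[idx], upper[idx] = cr.lower, cr.upper
    return ConfidenceCurve(
        rho_grid=rho_grid,
        lower_curve=lower,
        upper_curve=upper,
        n=n,
        k=k,
        level=level,
        n_replicates=n_replicates,
        seed=seed,
    )


_curve_cache: dict[tuple, ConfidenceCurve] = {}


def simulated_confidence_limits(
    sample_icc: float,
    n: int,
    k: int,
    level: float = 0.95,
    grid_step: float = 0.01,
    n_replicates: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Simulation-based confidence limits for the population ICC.

    Valid for an observed ICC(1) or ICC(C,1); the curves are cached per
    (n, k, level, grid, N, seed) so repeated queries reuse one grid run.
    """
    key = (n, k, level, grid_step, n_replicates, seed)
    curve = _curve_cache.get(key)
    if curve is None:
        curve = build_confidence_curve(n, k, level, grid_step, n_replicates, seed)
        _curve_cache[key] = curve
    return curve.invert(sample_icc)
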