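"""Single-score ICC estimators, variance components and the bias F-test.

Three sample formulas are implemented, all ratios of repeated-measures ANOVA
mean squares:

* ``ICC(1)``   — one-way random model (no systematic difference between
  measurement columns): ``(MSBS - MSWS) / (MSBS + (k-1) MSWS)``.
* ``ICC(A,1)`` — absolute agreement under the two-way models:
  ``(MSBS - MSE) / (MSBS + (k-1) MSE + (k/n)(MSBM - MSE))``.
* ``ICC(C,1)`` — consistency under the two-way models:
  ``(MSBS - MSE) / (MSBS + (k-1) MSE)``.

The two-way random model (random column biases c_j ~ N(0, sigma_c^2)) and the
two-way mixed model (fixed c_j with spread theta_c^2 about their mean) lead to
exactly the same sample formulas; only the population-level interpretation of
the bias variance differs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .anova import AnovaTable
from .exceptions import DegenerateInputError, InvalidInputError

__all__ = [
    "IccEstimate",
    "VarianceComponents",
    "ModelParams",
    "BiasTest",
    "icc1",
    "icc_a1",
    "icc_c1",
    "icc_a1_alternative",
    "variance_components",
    "bias_f_test",
    "expected_bias_f",
    "population_icc",
    "biased_icc1_expectation",
    "qualitative_band",
]


@dataclass
class IccEstimate:
    """A sample ICC value with an optional confidence interval.

    Negative values are legal (an unlucky estimate, most likely when n is
    small) and are reported as-is.
    """

    formula: str  # "ICC1" | "ICC_A1" | "ICC_C1"
    value: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    confidence_level: float = 0.95
    ci_method: str | None = None
    ci_degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "value": self.value,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "confidence_level": self.confidence_level,
            "ci_method": self.ci_method,
        }


@dataclass
class VarianceComponents:
    """Method-of-moments variance component estimates (squared score units).

    ``model="oneway"`` solves the one-way expected-mean-square relations
    (``sigma_r^2 = (MSBS - MSWS)/k``, ``sigma_v^2 = MSWS``); ``model="twoway"``
    solves the two-way relations (``sigma_r^2 = (MSBS - MSE)/k``,
    ``sigma_c^2 = (MSBM - MSE)/n``, ``sigma_v^2 = MSE``).  Under the mixed
    (fixed-bias) reading the two-way ``sigma_c2`` estimates theta_c^2, the
    spread of the fixed biases about their mean.

    Estimates can come out negative by sampling accident; they are flagged,
    never truncated.
    """

    model: str
    sigma_r2: float
    sigma_v2: float
    sigma_c2: float | None = None
    negative: dict = field(default_factory=dict)

    def __post_init__(self):
        self.negative = {
            "sigma_r2": self.sigma_r2 < 0,
            "sigma_v2": self.sigma_v2 < 0,
            "sigma_c2": (self.sigma_c2 is not None and self.sigma_c2 < 0),
        }

    @staticmethod
    def _sd(var: float | None) -> float | None:
        if var is None:
            return None
        return math.sqrt(var) if var >= 0 else float("nan")

    @property
    def sigma_r(self) -> float:
        """SD of the subject true-score deviations; NaN if the variance
        estimate is negative."""
        return self._sd(self.sigma_r2)

    @property
    def sigma_v(self) -> float:
        """SD of the noise term (standard error of measurement)."""
        return self._sd(self.sigma_v2)

    @property
    def sigma_c(self) -> float | None:
        """SD of the measurement biases (two-way model only)."""
        return self._sd(self.sigma_c2)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "sigma_r2": self.sigma_r2,
            "sigma_v2": self.sigma_v2,
            "sigma_c2": self.sigma_c2,
            "sigma_r": self.sigma_r,
            "sigma_v": self.sigma_v,
            "sigma_c": self.sigma_c,
            "negative": self.negative,
        }


@dataclass(frozen=True)
class ModelParams:
    """Generative parameters for the three reliability models.

    ``model=1``: x_ij = mu + r_i + v_ij (one-way random, no bias).
    ``model=2``: adds column biases c_j ~ N(0, sigma_c^2), redrawn for every
    simulated matrix (two-way random).
    ``model=3``: adds fixed biases ``fixed_biases`` (length k), identical
    across matrices (two-way mixed).

    The interaction and residual error terms of the classical two-way
    formulation are merged into the single noise term v_ij ~ N(0, sigma_v^2)
    with sigma_v^2 = sigma_rc^2 + sigma_e^2; the merged form is
    distributionally equivalent and is used throughout.
    """

    model: int
    n: int
    k: int
    sigma_v: float
    sigma_r: float = 10.0
    mu: float = 100.0
    sigma_c: float = 0.0
    fixed_biases: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.model not in (1, 2, 3):
            raise InvalidInputError(f"model must be 1, 2 or 3, got {self.model}")
        if self.n < 2 or self.k < 2:
            raise InvalidInputError("need n >= 2 and k >= 2")
        for name in ("sigma_r", "sigma_v", "sigma_c"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if self.model == 3:
            if self.fixed_biases is None or len(self.fixed_biases) != self.k:
                raise InvalidInputError("model 3 requires exactly k fixed biases")
            object.__setattr__(self, "fixed_biases", tuple(float(c) for c in self.fixed_biases))
        elif self.fixed_biases is not None:
            raise InvalidInputError("fixed_biases only apply to model 3")
        if self.model != 2 and self.sigma_c != 0.0:
            raise InvalidInputError("sigma_c only applies to model 2")

    @property
    def theta_c2(self) -> float:
        """Spread of the fixed biases about their mean, sum((c_j - cbar)^2)/(k-1)."""
        if self.model != 3:
            raise InvalidInputError("theta_c2 is defined for model 3 only")
        c = np.asarray(self.fixed_biases)
        return float(((c - c.mean()) ** 2).sum() / (self.k - 1))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "n": self.n,
            "k": self.k,
            "mu": self.mu,
            "sigma_r": self.sigma_r,
            "sigma_c": self.sigma_c,
            "sigma_v": self.sigma_v,
            "fixed_biases": list(self.fixed_biases) if self.fixed_biases else None,
        }


@dataclass
class BiasTest:
    """F-test for systematic differences between measurement columns.

    Under the no-bias null, F = MSBM/MSE follows an F distribution with
    (k-1, (n-1)(k-1)) degrees of freedom.
    """

    F: float
    df1: int
    df2: int
    p_value: float
    alpha: float
    reject: bool

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "reject": self.reject,
        }


def _check_denominator(den: float, what: str) -> None:
    if den <= 0:
        raise DegenerateInputError(
            f"{what} denominator is {den}; the matrix carries no variance to correlate"
        )


def icc1(anova: AnovaTable, k: int | None = None) -> IccEstimate:
    """One-way random (classical) single-score ICC.

    Valid only when measurement bias is absent; in the presence of bias it
    estimates neither the absolute-agreement nor the consistency population
    ICC (see :func:`biased_icc1_expectation`).
    """
    k = anova.k if k is None else k
    den = anova.msbs + (k - 1) * anova.msws
    _check_denominator(den, "ICC(1)")
    return IccEstimate("ICC1", (anova.msbs - anova.msws) / den)


def icc_a1(anova: AnovaTable, n: int | None = None, k: int | None = None) -> IccEstimate:
    """Absolute-agreement single-score ICC (two-way random or mixed model)."""
    n = anova.n if n is None else n
    k = anova.k if k is None else k
    den = anova.msbs + (k - 1) * anova.mse + (k / n) * (anova.msbm - anova.mse)
    _check_denominator(den, "ICC(A,1)")
    return IccEstimate("ICC_A1", (anova.msbs - anova.mse) / den)


def icc_c1(anova: AnovaTable, k: int | None = None) -> IccEstimate:
    """Consistency single-score ICC (two-way random or mixed model).

    Insensitive to column biases; estimates the ICC that would be obtained if
    biases were removed or corrected for.
    """
    k = anova.k if k is None else k
    den = anova.msbs + (k - 1) * anova.mse
    _check_denominator(den, "ICC(C,1)")
    return IccEstimate("ICC_C1", (anova.msbs - anova.mse) / den)


def icc_a1_alternative(anova: AnovaTable) -> float:
    """ICC(A,1) rewritten in terms of MSWM, MSE and MSWS.

    Algebraically identical to :func:`icc_a1` on every matrix; kept as an
    internal consistency check of the ANOVA identities, not reported.
    """
    den = anova.mswm - anova.mse + anova.msws
    _check_denominator(den, "alternative ICC(A,1)")
    return (anova.mswm - anova.mse) / den


def variance_components(
    anova: AnovaTable,
    n: int | None = None,
    k: int | None = None,
    model: str = "twoway",
) -> VarianceComponents:
    """Solve the expected-mean-square relations for the variance components."""
    n = anova.n if n is None else n
    k = anova.k if k is None else k
    if model == "oneway":
        return VarianceComponents(
            model="oneway",
            sigma_r2=(anova.msbs - anova.msws) / k,
            sigma_v2=anova.msws,
        )
    if model == "twoway":
        return VarianceComponents(
            model="twoway",
            sigma_r2=(anova.msbs - anova.mse) / k,
            sigma_c2=(anova.msbm - anova.mse) / n,
            sigma_v2=anova.mse,
        )
    raise InvalidInputError(f"model must be 'oneway' or 'twoway', got {model!r}")


def bias_f_test(
    anova: AnovaTable,
    n: int | None = None,
    k: int | None = None,
    alpha: float = 0.05,
) -> BiasTest:
    """Test the null hypothesis of no systematic difference between columns."""
    n = anova.n if n is None else n
    k = anova.k if k is None else k
    if anova.mse <= 0:
        raise DegenerateInputError("MSE = 0; the bias F-test is undefined")
    if not 0 < alpha < 1:
        raise InvalidInputError("alpha must be in (0, 1)")
    f = anova.msbm / anova.mse
    df1, df2 = k - 1, (n - 1) * (k - 1)
    p = float(stats.f.sf(f, df1, df2))
    return BiasTest(F=f, df1=df1, df2=df2, p_value=p, alpha=alpha, reject=p < alpha)


def expected_bias_f(params: ModelParams) -> float:
    """Expected bias F-value 1 + n (sigma_c / sigma_v)^2 under model 2."""
    if params.model != 2:
        raise InvalidInputError("expected_bias_f applies to model 2 parameters")
    if params.sigma_v == 0:
        raise DegenerateInputError("sigma_v = 0; expected F is unbounded")
    return 1.0 + params.n * (params.sigma_c / params.sigma_v) ** 2


def population_icc(params: ModelParams, variant: str = "absolute") -> float:
    """Population ICC defined from the generative variances.

    ``variant="absolute"`` puts the bias variance (sigma_c^2 for model 2,
    theta_c^2 for model 3) in the denominator; ``variant="consistency"``
    omits it.  Model 1 has no bias term so both variants coincide.
    """
    if variant not in ("absolute", "consistency"):
        raise InvalidInputError(f"unknown variant {variant!r}")
    sr2 = params.sigma_r**2
    sv2 = params.sigma_v**2
    if variant == "absolute" and params.model == 2:
        bias2 = params.sigma_c**2
    elif variant == "absolute" and params.model == 3:
        bias2 = params.theta_c2
    else:
        bias2 = 0.0
    den = sr2 + bias2 + sv2
    if den <= 0:
        raise DegenerateInputError("all variances are zero; population ICC undefined")
    return sr2 / den


def biased_icc1_expectation(params: ModelParams) -> float:
    """Large-sample value of the (invalid) ICC(1) formula under model-2 bias.

    Substituting the two-way expected mean squares into the one-way formula
    gives ``(sigma_r^2 - sigma_c^2/k) / (sigma_r^2 + sigma_c^2 + sigma_v^2 -
    sigma_c^2/k)`` — a ratio of expected mean squares, matched in simulation
    by the ratio of averaged mean squares.  It equals neither population ICC
    unless sigma_c = 0, which is why ICC(1) should not be reported when bias
    is present.
    """
    if params.model != 2:
        raise InvalidInputError("biased_icc1_expectation applies to model 2 parameters")
    sr2, sc2, sv2 = params.sigma_r**2, params.sigma_c**2, params.sigma_v**2
    den = (sr2 + sc2 + sv2) - sc2 / params.k
    if den <= 0:
        raise DegenerateInputError("all variances are zero")
    return (sr2 - sc2 / params.k) / den


def qualitative_band(icc: float) -> str:
    """Conventional qualitative reading of an ICC value.

    Bands: poor < 0.5 <= moderate <= 0.75 < good <= 0.9 < excellent.  Boundary
    assignment is a convention; negative values are poor.
    """
    if icc < 0.5:
        return "poor"
    if icc <= 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"
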