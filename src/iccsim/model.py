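"""Model/Results interface for a single reliability analysis.

:class:`IccModel` wraps one subjects-by-measurements score matrix;
:meth:`IccModel.fit` runs the model-agnostic recipe — compute the ANOVA mean
squares, all three single-score ICCs with confidence intervals, both variance
component sets and the bias F-test — and returns an :class:`IccResults`
carrying the estimates, their uncertainties and a ``summary()`` table.

The recipe deliberately does not require choosing a statistical model up
front: near-equality of the three ICCs (ratio ICC(C,1)/ICC(A,1) close to 1)
and a non-significant bias F-test indicate that column biases are negligible,
in which case the classical ICC(1) may be reported; otherwise ICC(1) is
invalid and only ICC(A,1) and ICC(C,1) are reported, with the two-way
variance components quantifying the bias magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import confidence as conf
from .anova import AnovaTable, ScoreMatrix, compute_anova
from .estimators import (
    BiasTest,
    IccEstimate,
    VarianceComponents,
    bias_f_test,
    icc1,
    icc_a1,
    icc_c1,
    qualitative_band,
    variance_components,
)
from .exceptions import InvalidInputError

__all__ = ["IccModel", "IccResults", "analyze"]

SCHEMA_VERSION = 1


class IccModel:
    """Reliability model for one complete n x k score matrix.

    Parameters
    ----------
    data : ScoreMatrix or array-like, shape (n, k)
        Subjects in rows, repeated measurements in columns.
    measurement_labels : sequence of str, optional
        Column labels; taken from ``data.columns`` by ``from_dataframe``.
    """

    def __init__(self, data, measurement_labels=None):
        if isinstance(data, ScoreMatrix):
            self.data = data
        else:
            labels = tuple(measurement_labels) if measurement_labels else None
            self.data = ScoreMatrix(np.asarray(data, dtype=float), labels)

    @classmethod
    def from_dataframe(cls, df) -> "IccModel":
        """Build from a pandas DataFrame (one column per measurement)."""
        labels = tuple(str(c) for c in df.columns)
        return cls(np.asarray(df, dtype=float), measurement_labels=labels)

    @classmethod
    def from_csv(cls, path) -> "IccModel":
        """Build from a CSV/TSV file (see :func:`iccsim.io.read_matrix`)."""
        from .io import read_matrix

        return cls(read_matrix(path))

    @property
    def n(self) -> int:
        return self.data.n

    @property
    def k(self) -> int:
        return self.data.k

    def fit(
        self,
        alpha: float = 0.05,
        level: float = 0.95,
        ci_method: str = "analytic",
        ratio_threshold: float = 1.02,
        seed: int | None = None,
    ) -> "IccResults":
        """Run the full analysis.

        Parameters
        ----------
        alpha : significance level of the bias F-test (the deciding criterion
            for the no-bias conclusion).
        level : confidence level for the ICC intervals.
        ci_method : "analytic" (F-based formulas) or "simulated"
            (central-range inversion; applies to ICC(1) and ICC(C,1), the
            ICC(A,1) interval always comes from the analytic formula).
        ratio_threshold : advisory threshold on ICC(C,1)/ICC(A,1); ratios
            above it suggest non-negligible bias.  In the no-bias regime the
            ratio sits within a few tenths of a percent of 1, so the default
            flags anything beyond a couple of percent.
        seed : RNG seed for the simulated intervals.
        """
        if not 0 < alpha < 1:
            raise InvalidInputError("alpha must be in (0, 1)")
        if ci_method not in ("analytic", "simulated"):
            raise InvalidInputError(f"unknown ci_method {ci_method!r}")
        anova = compute_anova(self.data)
        n, k = self.n, self.k

        est1 = icc1(anova)
        est_a = icc_a1(anova)
        est_c = icc_c1(anova)

        est1 = conf.analytic_ci(est1, anova, level=level)
        est_a = conf.analytic_ci(est_a, anova, level=level)
        est_c = conf.analytic_ci(est_c, anova, level=level)
        if ci_method == "simulated":
            for est in (est1, est_c):
                if 0 <= est.value < 1:
                    lo, hi = conf.simulated_confidence_limits(
                        est.value, n, k, level=level, seed=seed or 0
                    )
                    est.ci_lower, est.ci_upper = lo, hi
                    est.ci_method = "simulated"

        test = bias_f_test(anova, alpha=alpha)
        ratio = est_c.value / est_a.value if est_a.value != 0 else float("nan")

        return IccResults(
            model=self,
            anova=anova,
            icc1=est1,
            icc_a1=est_a,
            icc_c1=est_c,
            ratio_c_over_a=ratio,
            bias_test=test,
            vc_oneway=variance_components(anova, model="oneway"),
            vc_twoway=variance_components(anova, model="twoway"),
            alpha=alpha,
            ratio_threshold=ratio_threshold,
            ci_method=ci_method,
        )


@dataclass
class IccResults:
    """Fitted reliability analysis: estimates, uncertainties, diagnostics."""

    model: IccModel
    anova: AnovaTable
    icc1: IccEstimate
    icc_a1: IccEstimate
    icc_c1: IccEstimate
    ratio_c_over_a: float
    bias_test: BiasTest
    vc_oneway: VarianceComponents
    vc_twoway: VarianceComponents
    alpha: float
    ratio_threshold: float
    ci_method: str

    @property
    def conclusion(self) -> str:
        """"no_bias" if the F-test is non-significant at alpha, else
        "bias_present".  The ICC(C,1)/ICC(A,1) ratio is advisory only."""
        return "bias_present" if self.bias_test.reject else "no_bias"

    @property
    def ratio_flags_bias(self) -> bool:
        return self.ratio_c_over_a > self.ratio_threshold

    @property
    def bands(self) -> dict[str, str]:
        """Qualitative reading (poor/moderate/good/excellent) per ICC."""
        return {
            "ICC1": qualitative_band(self.icc1.value),
            "ICC_A1": qualitative_band(self.icc_a1.value),
            "ICC_C1": qualitative_band(self.icc_c1.value),
        }

    def to_dict(self) -> dict:
        """JSON-ready report.  ICC(1) is included only under the no-bias
        conclusion, since it is not a valid estimate when bias is present."""
        out = {
            "schema_version": SCHEMA_VERSION,
            "n": self.model.n,
            "k": self.model.k,
            "anova": self.anova.to_dict(),
            "icc_a1": self.icc_a1.to_dict(),
            "icc_c1": self.icc_c1.to_dict(),
            "ratio_C_over_A": self.ratio_c_over_a,
            "bias_test": self.bias_test.to_dict(),
            "variance_components": {
                "oneway": self.vc_oneway.to_dict(),
                "twoway": self.vc_twoway.to_dict(),
            },
            "conclusion": self.conclusion,
            "ratio_threshold": self.ratio_threshold,
            "ratio_flags_bias": self.ratio_flags_bias,
            "qualitative_bands": self.bands,
        }
        if self.conclusion == "no_bias":
            out["icc1"] = self.icc1.to_dict()
        return out

    def summary(self) -> str:
        """Human-readable summary table (ICCs to 3 decimals)."""

        def ci(est: IccEstimate) -> str:
            if est.ci_lower is None:
                return ""
            return f" ({est.ci_lower:.3f}-{est.ci_upper:.3f})"

        a = self.anova
        lines = [
            "Single-score ICC reliability analysis",
            "=" * 53,
            f"subjects n = {self.model.n}, measurements k = {self.model.k}",
            "",
            "ANOVA mean squares",
            f"  MSBS = {a.msbs:.2f}   MSWS = {a.msws:.2f}",
            f"  MSBM = {a.msbm:.2f}   MSWM = {a.mswm:.2f}   MSE = {a.mse:.2f}",
            "",
            f"Intraclass correlations ({self.icc_a1.confidence_level:.0%} CI, "
            f"{self.ci_method})",
        ]
        if self.conclusion == "no_bias":
            lines.append(
                f"  ICC(1)   = {self.icc1.value:.3f}{ci(self.icc1)}  "
                f"[{self.bands['ICC1']}]"
            )
        lines += [
            f"  ICC(A,1) = {self.icc_a1.value:.3f}{ci(self.icc_a1)}  "
            f"[{self.bands['ICC_A1']}]",
            f"  ICC(C,1) = {self.icc_c1.value:.3f}{ci(self.icc_c1)}  "
            f"[{self.bands['ICC_C1']}]",
            f"  ratio ICC(C,1)/ICC(A,1) = {self.ratio_c_over_a:.3f}"
            + ("  (suggests bias)" if self.ratio_flags_bias else ""),
            "",
            "Bias F-test (between measurements)",
            f"  F({self.bias_test.df1}, {self.bias_test.df2}) = "
            f"{self.bias_test.F:.3f}, p = {self.bias_test.p_value:.3f}"
            f" -> {'reject' if self.bias_test.reject else 'do not reject'}"
            f" no-bias at alpha = {self.alpha:g}",
            "",
            "Variance components (SD scale)",
            f"  one-way: sigma_r = {self.vc_oneway.sigma_r:.2f}, "
            f"sigma_v = {self.vc_oneway.sigma_v:.2f}",
            f"  two-way: sigma_r = {self.vc_twoway.sigma_r:.2f}, "
            f"sigma_v = {self.vc_twoway.sigma_v:.2f}, "
            f"sigma_c = {self.vc_twoway.sigma_c:.2f}",
            "",
            f"Conclusion: {self.conclusion.replace('_', ' ')}"
            + (
                " - ICC(1) may be reported"
                if self.conclusion == "no_bias"
                else " - report ICC(A,1) and ICC(C,1), not ICC(1)"
            ),
        ]
        return "\n".join(lines)


def analyze(
    matrix,
    alpha: float = 0.05,
    ratio_threshold: float = 1.02,
    level: float = 0.95,
    ci_method: str = "analytic",
    seed: int | None = None,
) -> IccResults:
    """Functional shorthand for ``IccModel(matrix).fit(...)``."""
    return IccModel(matrix).fit(
        alpha=alpha,
        level=level,
        ci_method=ci_method,
        ratio_threshold=ratio_threshold,
        seed=seed,
    )
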