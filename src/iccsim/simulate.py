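"""Monte Carlo engine for the ICC sampling distributions.

Simulates N score matrices from one of the three generative models, runs the
repeated-measures ANOVA on each, and collects the per-matrix ICC values,
F-values and mean squares.  Defaults follow the convention of fixing
mu = 100 and sigma_r = 10 and varying the noise and bias SDs relative to
sigma_r, with N = 10000 replicates; only the ratios sigma_v/sigma_r and
sigma_c/sigma_r affect the ICC distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .anova import ScoreMatrix, batch_mean_squares
from .confidence import CentralRange, central_range
from .estimators import ModelParams
from .exceptions import InsufficientSampleError, InvalidInputError

__all__ = [
    "SimulationResult",
    "simulate_matrix",
    "simulate_matrices",
    "run_simulation",
    "ratio_statistics",
    "histogram",
]

DEFAULT_N_REPLICATES = 10000
_ICC_KEYS = ("ICC1", "ICC_A1", "ICC_C1")
_MS_KEYS = ("MSBS", "MSWS", "MSBM", "MSWM", "MSE", "MST")


def simulate_matrices(params: ModelParams, n_matrices: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a stack of score matrices, shape (n_matrices, n, k).

    Per matrix: one subject deviation r_i per row, one noise value v_ij per
    cell; model 2 redraws the k column biases for every matrix, model 3 adds
    the same fixed biases to every matrix.
    """
    n, k = params.n, params.k
    x = params.mu + rng.normal(0.0, params.sigma_r, (n_matrices, n, 1)) + rng.normal(
        0.0, params.sigma_v, (n_matrices, n, k)
    )
    if params.model == 2 and params.sigma_c > 0:
        x = x + rng.normal(0.0, params.sigma_c, (n_matrices, 1, k))
    elif params.model == 3:
        x = x + np.asarray(params.fixed_biases)[None, None, :]
    return x


def simulate_matrix(params: ModelParams, rng: np.random.Generator | int | None = None) -> ScoreMatrix:
    """Draw a single score matrix from the generative model."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return ScoreMatrix(simulate_matrices(params, 1, rng)[0])


@dataclass
class SimulationResult:
    """Per-replicate ICC/MS arrays and summary statistics of one run."""

    params: ModelParams
    n_replicates: int
    seed: int | None
    icc: dict[str, np.ndarray]      # per-replicate ICC1 / ICC_A1 / ICC_C1
    f_values: np.ndarray            # per-replicate MSBM/MSE
    mean_squares: dict[str, np.ndarray]
    n_degenerate: int = 0           # replicates with an undefined ICC, excluded

    def mean_icc(self, formula: str) -> float:
        return float(self.icc[formula].mean())

    def sd_icc(self, formula: str) -> float:
        return float(self.icc[formula].std(ddof=1))

    def central_range_icc(self, formula: str, level: float = 0.95) -> CentralRange:
        return central_range(self.icc[formula], level)

    def mean_ms(self, key: str) -> float:
        return float(self.mean_squares[key].mean())

    @property
    def mean_ratio(self) -> float:
        """Average per-matrix ratio ICC(C,1)/ICC(A,1)."""
        return ratio_statistics(self)[0]

    @property
    def prob_c_gt_a(self) -> float:
        """Fraction of matrices with ICC(C,1) > ICC(A,1)."""
        return ratio_statistics(self)[1]

    def icc_from_mean_ms(self, formula: str) -> float:
        """ICC recomputed from the averaged mean squares (average before the
        division).  Differs slightly from the mean per-replicate ICC; the
        averaged-MS form tracks the expected-mean-square ratios."""
        msbs = self.mean_ms("MSBS")
        mse = self.mean_ms("MSE")
        k, n = self.params.k, self.params.n
        if formula == "ICC1":
            msws = self.mean_ms("MSWS")
            return (msbs - msws) / (msbs + (k - 1) * msws)
        if formula == "ICC_A1":
            msbm = self.mean_ms("MSBM")
            return (msbs - mse) / (msbs + (k - 1) * mse + (k / n) * (msbm - mse))
        if formula == "ICC_C1":
            return (msbs - mse) / (msbs + (k - 1) * mse)
        raise InvalidInputError(f"unknown formula {formula!r}")

    def to_dict(self, include_histograms: bool = False, bins: int = 100) -> dict:
        out = {
            "params": self.params.to_dict(),
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "n_degenerate": self.n_degenerate,
            "mean_icc": {f: self.mean_icc(f) for f in _ICC_KEYS},
            "sd_icc": {f: self.sd_icc(f) for f in _ICC_KEYS},
            "central_range": {
                f: self.central_range_icc(f).to_dict() for f in _ICC_KEYS
            },
            "icc_from_mean_ms": {f: self.icc_from_mean_ms(f) for f in _ICC_KEYS},
            "mean_ms": {m: self.mean_ms(m) for m in _MS_KEYS},
            "mean_f": float(self.f_values.mean()),
            "mean_ratio_C_over_A": self.mean_ratio,
            "prob_C_gt_A": self.prob_c_gt_a,
        }
        if include_histograms:
            out["histograms"] = {
                f: histogram(self.icc[f], bins=bins) for f in _ICC_KEYS
            }
        return out


def run_simulation(
    params: ModelParams,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int | None = None,
) -> SimulationResult:
    """Simulate ``n_replicates`` matrices and collect ICC/MS distributions.

    Replicates whose ICC denominators vanish (possible only when all three
    SDs are zero) are counted and excluded with a warning.  Identical seed
    and parameters reproduce the result exactly.
    """
    if n_replicates < 100:
        raise InvalidInputError("need at least 100 replicates")
    rng = np.random.default_rng(seed)
    x = simulate_matrices(params, n_replicates, rng)
    ms = batch_mean_squares(x)
    n, k = params.n, params.k

    den1 = ms["MSBS"] + (k - 1) * ms["MSWS"]
    den_a = ms["MSBS"] + (k - 1) * ms["MSE"] + (k / n) * (ms["MSBM"] - ms["MSE"])
    den_c = ms["MSBS"] + (k - 1) * ms["MSE"]
    # a replicate is degenerate only if an ICC denominator vanishes (constant
    # matrix); MSE = 0 alone still yields a valid ICC of 1 (F becomes inf)
    valid = (den1 > 0) & (den_a > 0) & (den_c > 0)
    n_degenerate = int((~valid).sum())
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} degenerate replicate(s) (constant matrices) excluded",
            stacklevel=2,
        )
        ms = {key: val[valid] for key, val in ms.items()}
        den1, den_a, den_c = den1[valid], den_a[valid], den_c[valid]
        if not ms["MSBS"].size:
            raise InsufficientSampleError("every replicate was degenerate")

    icc = {
        "ICC1": (ms["MSBS"] - ms["MSWS"]) / den1,
        "ICC_A1": (ms["MSBS"] - ms["MSE"]) / den_a,
        "ICC_C1": (ms["MSBS"] - ms["MSE"]) / den_c,
    }
    with np.errstate(divide="ignore", invalid="ignore"):
        f_values = np.where(
            ms["MSE"] > 0, ms["MSBM"] / np.where(ms["MSE"] > 0, ms["MSE"], 1.0), np.inf
        )
    return SimulationResult(
        params=params,
        n_replicates=n_replicates,
        seed=seed,
        icc=icc,
        f_values=f_values,
        mean_squares=ms,
        n_degenerate=n_degenerate,
    )


def ratio_statistics(result: SimulationResult) -> tuple[float, float]:
    """Mean per-matrix ratio ICC(C,1)/ICC(A,1) and P[ICC(C,1) > ICC(A,1)].

    Replicates with ICC(A,1) exactly zero are excluded from the mean ratio;
    their count is reported via a warning (they essentially never occur for
    continuous data).
    """
    c = result.icc["ICC_C1"]
    a = result.icc["ICC_A1"]
    nonzero = a != 0
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} replicate(s) with ICC(A,1) = 0 excluded from the mean ratio",
            stacklevel=2,
        )
    mean_ratio = float((c[nonzero] / a[nonzero]).mean())
    prob = float((c > a).mean())
    return mean_ratio, prob


def histogram(values, bins: int = 100, value_range: tuple[float, float] = (-0.5, 1.0)) -> dict:
    """Relative-frequency histogram of simulated ICC values.

    Returns bin centers and relative frequencies N_i/N (summing to 1 over the
    occupied range; values outside ``value_range`` are clipped into the edge
    bins so nothing is dropped).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InsufficientSampleError("no values to histogram")
    if bins < 1:
        raise InvalidInputError("need at least one bin")
    lo, hi = value_range
    clipped = np.clip(values, lo, hi)
    counts, edges = np.histogram(clipped, bins=bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return {
        "bin_centers": centers.tolist(),
        "bin_edges": edges.tolist(),
        "rel_freq": (counts / values.size).tolist(),
    }
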