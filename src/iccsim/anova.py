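"""Score matrix container and the repeated-measures ANOVA decomposition.

A reliability study produces a complete n x k matrix of scores: one row per
subject (i = 1..n), one column per repeated measurement / rater / occasion
(j = 1..k).  Every intraclass-correlation estimator is a function of the mean
squares of the two-way repeated-measures ANOVA of that matrix, so the
decomposition is computed once, in full, and passed around as an
:class:`AnovaTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

__all__ = ["ScoreMatrix", "AnovaTable", "compute_anova"]


@dataclass(frozen=True)
class ScoreMatrix:
    """A complete n x k matrix of repeated measurements.

    Parameters
    ----------
    values : array-like, shape (n, k)
        Scores, subjects in rows and measurements in columns.  The orientation
        is fixed; no auto-transpose is attempted.
    measurement_labels : tuple of str, optional
        Column labels (e.g. rater names or "Day 1", "Day 2", ...).
    """

    values: np.ndarray
    measurement_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise InvalidInputError(
                f"score matrix must be two-dimensional, got shape {arr.shape}"
            )
        n, k = arr.shape
        if n < 2 or k < 2:
            raise InvalidInputError(
                f"need at least 2 subjects and 2 measurements, got {n} x {k}"
            )
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise InvalidInputError(
                f"missing or non-finite cell at row {bad[0] + 1}, column {bad[1] + 1}"
            )
        if self.measurement_labels is not None and len(self.measurement_labels) != k:
            raise InvalidInputError(
                f"{len(self.measurement_labels)} labels for {k} measurement columns"
            )
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        """Number of subjects (rows)."""
        return self.values.shape[0]

    @property
    def k(self) -> int:
        """Number of repeated measurements (columns)."""
        return self.values.shape[1]

    @property
    def subject_means(self) -> np.ndarray:
        """Row means S_i."""
        return self.values.mean(axis=1)

    @property
    def measurement_means(self) -> np.ndarray:
        """Column means M_j."""
        return self.values.mean(axis=0)

    @property
    def grand_mean(self) -> float:
        return float(self.values.mean())

    def shifted(self, constant: float) -> "ScoreMatrix":
        """Return a copy with ``constant`` added to every cell."""
        return ScoreMatrix(self.values + constant, self.measurement_labels)


@dataclass(frozen=True)
class AnovaTable:
    """Sums of squares, degrees of freedom and mean squares of the
    repeated-measures ANOVA.

    Partitions (all in squared score units):

    * between/within subjects: ``SST = SSBS + SSWS``
    * between/within measurements: ``SST = SSBM + SSWM``
    * error (interaction + residual): ``SST = SSBS + SSBM + SSE``
    """

    n: int
    k: int
    ss_total: float
    ss_between_subjects: float
    ss_within_subjects: float
    ss_between_measurements: float
    ss_within_measurements: float
    ss_error: float

    # degrees of freedom
    @property
    def df_total(self) -> int:
        return self.n * self.k - 1

    @property
    def df_between_subjects(self) -> int:
        return self.n - 1

    @property
    def df_within_subjects(self) -> int:
        return self.n * (self.k - 1)

    @property
    def df_between_measurements(self) -> int:
        return self.k - 1

    @property
    def df_within_measurements(self) -> int:
        return self.k * (self.n - 1)

    @property
    def df_error(self) -> int:
        return (self.n - 1) * (self.k - 1)

    # mean squares (four-letter names follow the between/within-subjects/
    # measurements convention; MSE is the interaction+residual mean square)
    @property
    def mst(self) -> float:
        return self.ss_total / self.df_total

    @property
    def msbs(self) -> float:
        return self.ss_between_subjects / self.df_between_subjects

    @property
    def msws(self) -> float:
        return self.ss_within_subjects / self.df_within_subjects

    @property
    def msbm(self) -> float:
        return self.ss_between_measurements / self.df_between_measurements

    @property
    def mswm(self) -> float:
        return self.ss_within_measurements / self.df_within_measurements

    @property
    def mse(self) -> float:
        return self.ss_error / self.df_error

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "k": self.k,
            "SST": self.ss_total,
            "SSBS": self.ss_between_subjects,
            "SSWS": self.ss_within_subjects,
            "SSBM": self.ss_between_measurements,
            "SSWM": self.ss_within_measurements,
            "SSE": self.ss_error,
            "dfT": self.df_total,
            "dfBS": self.df_between_subjects,
            "dfWS": self.df_within_subjects,
            "dfBM": self.df_between_measurements,
            "dfWM": self.df_within_measurements,
            "dfE": self.df_error,
            "MST": self.mst,
            "MSBS": self.msbs,
            "MSWS": self.msws,
            "MSBM": self.msbm,
            "MSWM": self.mswm,
            "MSE": self.mse,
        }


def compute_anova(matrix: ScoreMatrix | np.ndarray) -> AnovaTable:
    """Full repeated-measures ANOVA decomposition of a score matrix.

    The error sum of squares is accumulated directly from the double-centred
    residuals ``x_ij - S_i - M_j + grand`` rather than by subtraction, which
    keeps it non-negative in floating point; the additivity identities
    (``SST = SSBS + SSWS = SSBM + SSWM = SSBS + SSBM + SSE``) then hold to
    rounding error and are exercised by the test suite.
    """
    if not isinstance(matrix, ScoreMatrix):
        matrix = ScoreMatrix(matrix)
    x = matrix.values
    n, k = matrix.n, matrix.k
    grand = x.mean()
    s = x.mean(axis=1, keepdims=True)   # subject means
    m = x.mean(axis=0, keepdims=True)   # measurement means

    ss_total = float(((x - grand) ** 2).sum())
    ss_bs = float(k * ((s - grand) ** 2).sum())
    ss_bm = float(n * ((m - grand) ** 2).sum())
    ss_ws = float(((x - s) ** 2).sum())
    ss_wm = float(((x - m) ** 2).sum())
    ss_e = float(((x - s - m + grand) ** 2).sum())

    return AnovaTable(
        n=n,
        k=k,
        ss_total=ss_total,
        ss_between_subjects=ss_bs,
        ss_within_subjects=ss_ws,
        ss_between_measurements=ss_bm,
        ss_within_measurements=ss_wm,
        ss_error=ss_e,
    )


def batch_mean_squares(x: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised mean squares for a stack of matrices, shape (N, n, k).

    Returns arrays of length N for MSBS, MSWS, MSBM, MSWM, MSE and MST.  Used
    by the Monte Carlo engine; agreement with :func:`compute_anova` on single
    matrices is a tested property.
    """
    x = np.asarray(x, dtype=float)
    N, n, k = x.shape
    grand = x.mean(axis=(1, 2), keepdims=True)
    s = x.mean(axis=2, keepdims=True)
    m = x.mean(axis=1, keepdims=True)
    ss_total = ((x - grand) ** 2).sum(axis=(1, 2))
    ss_bs = k * ((s - grand) ** 2).sum(axis=(1, 2))
    ss_bm = n * ((m - grand) ** 2).sum(axis=(1, 2))
    ss_ws = ((x - s) ** 2).sum(axis=(1, 2))
    ss_wm = ((x - m) ** 2).sum(axis=(1, 2))
    ss_e = ((x - s - m + grand) ** 2).sum(axis=(1, 2))
    return {
        "MST": ss_total / (n * k - 1),
        "MSBS": ss_bs / (n - 1),
        "MSWS": ss_ws / (n * (k - 1)),
        "MSBM": ss_bm / (k - 1),
        "MSWM": ss_wm / (k * (n - 1)),
        "MSE": ss_e / ((n - 1) * (k - 1)),
    }
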