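"""Evaluation metrics and experimental-track smoothing.

The observed recombination track is exponentially smoothed (first value
preserved — unlike the model's own smoothing step, which forces it to zero)
and compared with the model's final prediction using Pearson's r and the
coefficient of determination R².

R² is computed in residual form, ``1 - SS_res / SS_tot``, comparing the
prediction directly to the observation: it can be negative when the
prediction fits worse than the observed mean (centromere-only corrections
behave exactly that way).  A regression-form variant, which first fits an
ordinary least-squares line and therefore cannot go negative, is provided
separately as :func:`r2_regression` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import lfilter

from .alignio import RecombinationTrack
from .model import PredictionTrack


@dataclass(frozen=True)
class EvaluationResult:
    """Pearson r and coefficient of determination over n windows."""

    r: float
    r2: float
    n_windows: int

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"r={self.r} outside [-1, 1]")
        if self.n_windows < 2:
            raise ValueError("need at least 2 windows to evaluate")

    def to_dict(self) -> dict:
        return {"r": self.r, "r2": self.r2, "n_windows": self.n_windows}


def smooth_track(x, alpha: float) -> np.ndarray:
    """Exponential smoothing preserving the first value.

    Xs(0) = X(0); Xs(w) = alpha * X(w) + (1 - alpha) * Xs(w - 1).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha={alpha} outside (0, 1)")
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty track")
    # initial filter state chosen so the recurrence starts at Xs(0) = X(0)
    y, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], x, zi=[(1.0 - alpha) * x[0]])
    return y


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(stats.pearsonr(x, y).statistic)


def coefficient_of_determination(observed, predicted) -> float:
    """R² = 1 - SS_res / SS_tot with predictions compared directly.

    May be negative: a prediction worse than the observed mean scores below
    zero.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if len(observed) != len(predicted):
        raise ValueError("length mismatch")
    if len(observed) < 2:
        raise ValueError("need at least 2 points")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in observed values")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def r2_regression(x, y) -> float:
    """R² of the ordinary least-squares line of y on x (never negative)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length vectors of at least 2 points")
    slope, intercept = np.polyfit(x, y, 1)
    return coefficient_of_determination(y, slope * x + intercept)


def evaluate_prediction(
    prediction: PredictionTrack,
    experimental: RecombinationTrack,
    alpha: float = 0.1,
) -> EvaluationResult:
    """Smooth the observed track and score the prediction against it.

    The same smoothing factor is used for the observation as the model used
    for its own final step.  All windows enter the metrics, centromeric zeros
    included.
    """
    grid = prediction.grid
    if len(experimental) != grid.n:
        raise ValueError(
            f"grid mismatch: prediction has {grid.n} windows, "
            f"experimental track has {len(experimental)}"
        )
    step = experimental.window_size
    if step is not None and step != grid.window_size:
        raise ValueError(
            f"grid mismatch: window size {grid.window_size} vs track step {step}"
        )
    xs = smooth_track(experimental.rates, alpha)
    return EvaluationResult(
        r=pearson_r(prediction.Id4, xs),
        r2=coefficient_of_determination(xs, prediction.Id4),
        n_windows=grid.n,
    )
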