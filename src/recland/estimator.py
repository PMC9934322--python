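"""scikit-learn estimator wrapping calibration and prediction.

:class:`RecombinationPredictor` is a regressor whose design matrix has one
row per 100 kb window and five columns::

    V, I, A, cento_ref, cento_qry

(the three divergence proportions and the CentO satellite hit counts on the
reference and query chromosome).  ``fit`` calibrates the seven case
parameters against an observed recombination track by bound-constrained
SLSQP minimising ``1 - R²``; ``predict`` runs the four-step model and returns
the final smoothed prediction Id4.  Because the case thresholds act on
finitely many windows the objective is piecewise constant in the threshold
directions, so the finite-difference step is deliberately large (1e-3) and a
seeded multistart is available; with identical seed and start count the fit
is fully deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .features import CentoTrack, FeatureTrack, WindowGrid, compute_identity
from .model import (
    DEFAULT_RAMP,
    ModelParams,
    PredictionTrack,
    predict_track,
)
from .evaluate import coefficient_of_determination, smooth_track


def stack_inputs(
    features: FeatureTrack, cento_ref: CentoTrack, cento_qry: CentoTrack
) -> np.ndarray:
    """Build the (n_windows, 5) design matrix the estimator consumes."""
    n = features.grid.n
    if len(cento_ref.counts) != n or len(cento_qry.counts) != n:
        raise ValueError("feature and CentO tracks must share one window grid")
    return np.column_stack(
        [features.V, features.I, features.A, cento_ref.counts, cento_qry.counts]
    )


def _unstack(X: np.ndarray, window_size: int, chrom: str):
    n = X.shape[0]
    grid = WindowGrid(chrom_length=n * window_size, window_size=window_size, chrom=chrom)
    V, I, A = X[:, 0], X[:, 1], X[:, 2]
    features = FeatureTrack(V=V, I=I, A=A, Id0=compute_identity(V, I, A), grid=grid)
    cento_ref = CentoTrack(counts=np.round(X[:, 3]).astype(np.int64), grid=grid)
    cento_qry = CentoTrack(counts=np.round(X[:, 4]).astype(np.int64), grid=grid)
    return features, cento_ref, cento_qry


class RecombinationPredictor(RegressorMixin, BaseEstimator):
    """Windowed recombination-rate predictor with SLSQP calibration.

    Parameters
    ----------
    alpha : float, default 0.1
        Exponential smoothing factor, applied both to the model output and to
        the observed track before scoring.  Fixed, never optimised.
    ramp : int, default 50
        Centromere-correction ramp length in windows.
    starts : int, default 1
        Number of SLSQP starts.  The first start is the centre of the
        parameter box (all 0.5); subsequent starts are uniform in [0, 1]^7
        under ``random_state``.
    random_state : int, RandomState or None
        Seeds the multistart draws.
    eps : float, default 1e-3
        Finite-difference step for the SLSQP gradient, large enough to cross
        case-threshold boundaries occasionally.
    maxiter : int, default 200
        SLSQP iteration cap per start.
    window_size : int, default 100_000
        Nominal window size used to reconstruct the coordinate frame.

    Attributes
    ----------
    params_ : ModelParams
        Calibrated parameters of the best start.
    objective_ : float
        Final ``1 - R²`` on the fitting chromosome.
    n_evaluations_ : int
        Total objective evaluations across starts.
    converged_ : bool
        Whether the best start reported SLSQP success.
    """

    def __init__(
        self,
        alpha: float = 0.1,
        ramp: int = DEFAULT_RAMP,
        starts: int = 1,
        random_state=None,
        eps: float = 1e-3,
        maxiter: int = 200,
        window_size: int = 100_000,
        chrom: str = "chr01",
    ):
        self.alpha = alpha
        self.ramp = ramp
        self.starts = starts
        self.random_state = random_state
        self.eps = eps
        self.maxiter = maxiter
        self.window_size = window_size
        self.chrom = chrom

    def _predict_from_vector(self, vec, parts) -> PredictionTrack:
        params = ModelParams.from_vector(vec, alpha=self.alpha, ramp=self.ramp)
        return predict_track(*parts, params=params)

    def fit(self, X, y):
        """Calibrate the seven case parameters against observed rates ``y``."""
        X, y = check_X_y(X, y, ensure_min_features=5)
        if X.shape[1] != 5:
            raise ValueError("X must have columns V, I, A, cento_ref, cento_qry")
        parts = _unstack(X, self.window_size, self.chrom)
        xs = smooth_track(np.asarray(y, dtype=float), self.alpha)
        if np.ptp(xs) == 0:
            raise ValueError(
                "observed recombination track is constant; R² is undefined"
            )
        if self.starts < 1:
            raise ValueError("starts must be >= 1")
        rng = check_random_state(self.random_state)

        n_eval = 0

        def objective(vec):
            nonlocal n_eval
            n_eval += 1
            track = self._predict_from_vector(np.clip(vec, 0.0, 1.0), parts)
            return 1.0 - coefficient_of_determination(xs, track.Id4)

        bounds = [(0.0, 1.0)] * 7
        best = None
        failures = []
        for s in range(self.starts):
            x0 = np.full(7, 0.5) if s == 0 else rng.uniform(0.0, 1.0, size=7)
            res = minimize(
                objective,
                x0,
                method="SLSQP",
                bounds=bounds,
                options={"maxiter": self.maxiter, "eps": self.eps, "ftol": 1e-10},
            )
            if not np.isfinite(res.fun):
                failures.append(res)
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError(
                f"SLSQP failed on all {self.starts} starts: "
                f"{[f.message for f in failures]}"
            )

        vec = np.clip(best.x, 0.0, 1.0)
        self.params_ = ModelParams.from_vector(vec, alpha=self.alpha, ramp=self.ramp)
        # re-evaluate so the reported objective is exactly reproducible
        final = self._predict_from_vector(vec, parts)
        self.objective_ = 1.0 - coefficient_of_determination(xs, final.Id4)
        self.n_evaluations_ = n_eval
        self.converged_ = bool(best.success)
        self.n_features_in_ = 5
        return self

    def predict(self, X):
        """Final smoothed prediction Id4 for each window of ``X``."""
        check_is_fitted(self, "params_")
        return self.predict_full(X).Id4

    def predict_full(self, X) -> PredictionTrack:
        """All model stages (Id1..Id4 and case labels) for ``X``."""
        check_is_fitted(self, "params_")
        X = check_array(X, ensure_min_features=5)
        parts = _unstack(X, self.window_size, self.chrom)
        return predict_track(*parts, params=self.params_)

    def score(self, X, y):
        """R² (residual form) between Id4 and the smoothed observed track."""
        xs = smooth_track(np.asarray(y, dtype=float), self.alpha)
        return coefficient_of_determination(xs, self.predict(X))
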