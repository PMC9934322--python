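"""Parameter calibration on one chromosome and transfer to others.

The seven case parameters are fitted on a single chromosome by minimising
``1 - R²`` between the model's final prediction and the smoothed observed
recombination track (bound-constrained SLSQP over [0, 1]^7, optional seeded
multistart).  The fitted parameter set is then applied unchanged to other
chromosomes — the leave-one-chromosome-in design under which the method is
meant to be used.  The smoothing factor alpha is never optimised.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignio import RecombinationTrack
from .estimator import RecombinationPredictor, stack_inputs
from .evaluate import EvaluationResult, evaluate_prediction
from .features import CentoTrack, FeatureTrack
from .model import DEFAULT_RAMP, ModelParams, PredictionTrack, predict_track


@dataclass
class CalibrationResult:
    """Outcome of one calibration run."""

    params: ModelParams
    objective: float
    n_evaluations: int
    converged: bool
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "objective": self.objective,
            "r2": 1.0 - self.objective,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "seed": self.seed,
        }


def calibrate(
    features: FeatureTrack,
    cento_ref: CentoTrack,
    cento_qry: CentoTrack,
    experimental: RecombinationTrack,
    alpha: float = 0.1,
    starts: int = 1,
    seed: int | None = None,
    ramp: int = DEFAULT_RAMP,
) -> CalibrationResult:
    """Fit the seven case parameters on one chromosome.

    The first start is the centre of the parameter box (all 0.5); further
    starts are uniform draws under ``seed``.  The best (lowest ``1 - R²``)
    start wins, and the reported objective is recomputed from the returned
    parameters so it is exactly reproducible.
    """
    grid = features.grid
    if len(experimental) != grid.n:
        raise ValueError(
            f"grid mismatch: features have {grid.n} windows, "
            f"experimental track has {len(experimental)}"
        )
    est = RecombinationPredictor(
        alpha=alpha,
        ramp=ramp,
        starts=starts,
        random_state=seed,
        window_size=grid.window_size,
        chrom=grid.chrom,
    )
    est.fit(stack_inputs(features, cento_ref, cento_qry), experimental.rates)
    return CalibrationResult(
        params=est.params_,
        objective=est.objective_,
        n_evaluations=est.n_evaluations_,
        converged=est.converged_,
        seed=seed,
    )


def transfer_predict(
    params: ModelParams,
    features: FeatureTrack,
    cento_ref: CentoTrack,
    cento_qry: CentoTrack,
    experimental: RecombinationTrack | None = None,
) -> tuple[PredictionTrack, EvaluationResult | None]:
    """Apply fitted parameters to another chromosome, optionally scoring.

    Evaluation (when an observed track is supplied) uses the same smoothing
    factor the parameters carry.
    """
    track = predict_track(features, cento_ref, cento_qry, params)
    result = None
    if experimental is not None:
        result = evaluate_prediction(track, experimental, alpha=params.alpha)
    return track, result
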