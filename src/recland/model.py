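"""The four-step recombination predictor.

Step 1 — case-based identity modification.  Three mutually exclusive cases,
tried in order with first match winning, reshape the identity track so that
valleys and peaks of observed recombination are amplified:

* case 1 (penalty): ``Id0 < t1`` and ``V > t4`` → subtract ``p1``.  Windows of
  low identity dominated by variants should recombine less.
* case 2 (reward): ``Id0 < t2`` and ``V < t4`` → add ``p2``.  Low identity
  with few variants often hides short near-perfect alignment fragments.
* case 3 (correction): ``A > t3`` and ``V < t4`` → subtract ``p3``.  Absent
  bases with few variants flag windows assembled from multiple contigs whose
  alignment over-adjusts.

All inequalities are strict, exactly as stated; a window matching no case
keeps its identity.

Step 2 zeroes negative values (recombination rates cannot be negative).
Step 3 zeroes the centromeric interval located from CentO satellite counts
and ramps linearly back to 1 over a fixed number of windows on each side;
telocentric chromosomes (centromere in the first quarter, e.g. a NOR short
arm) instead have the whole short arm zeroed.  Step 4 applies exponential
smoothing with the first window forced to zero, matching the observed tracks
which start at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .features import FeatureTrack, CentoTrack, WindowGrid

CASE1 = "case1"
CASE2 = "case2"
CASE3 = "case3"
NO_CASE = "none"
CASE_LABELS = (CASE1, CASE2, CASE3, NO_CASE)

#: windows over which the centromere correction ramps from 0 back to 1
DEFAULT_RAMP = 50


@dataclass
class ModelParams:
    """The seven calibration parameters plus the smoothing factor.

    ``p1, p2, p3`` are the case modification magnitudes, ``t1..t4`` the case
    thresholds; all seven lie in [0, 1].  ``alpha`` is the exponential
    smoothing factor (0.1 by default, the value that best de-noises 100 kb
    recombination tracks).  ``ramp`` is the centromere-correction ramp length
    in windows; it is a structural constant, not a calibrated parameter, and
    is exposed only for experimentation.
    """

    p1: float = 0.5
    p2: float = 0.5
    p3: float = 0.5
    t1: float = 0.5
    t2: float = 0.5
    t3: float = 0.5
    t4: float = 0.5
    alpha: float = 0.1
    ramp: int = DEFAULT_RAMP

    PARAM_NAMES = ("p1", "p2", "p3", "t1", "t2", "t3", "t4")

    def __post_init__(self):
        for name in self.PARAM_NAMES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha={self.alpha} outside (0, 1)")
        if self.ramp < 1:
            raise ValueError("ramp must be a positive window count")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, vec, alpha: float = 0.1, ramp: int = DEFAULT_RAMP) -> "ModelParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (7,):
            raise ValueError("parameter vector must have 7 entries")
        return cls(**dict(zip(cls.PARAM_NAMES, vec.tolist())), alpha=alpha, ramp=ramp)

    def to_dict(self) -> dict:
        d = {n: getattr(self, n) for n in self.PARAM_NAMES}
        d["alpha"] = self.alpha
        if self.ramp != DEFAULT_RAMP:
            d["ramp"] = self.ramp
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = set(cls.PARAM_NAMES) | {"alpha", "ramp"}
        return cls(**{k: v for k, v in d.items() if k in known})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class CentromereEstimate:
    """Centromere window interval [c0, c1] and chromosome class.

    ``telocentric`` is true when the interval's right edge lies within the
    first quarter of the chromosome (c1 <= n/4; the boundary case counts as
    telocentric).
    """

    c0: int
    c1: int
    telocentric: bool

    def __post_init__(self):
        if not 0 <= self.c0 <= self.c1:
            raise ValueError(f"invalid centromere interval [{self.c0}, {self.c1}]")


@dataclass
class PredictionTrack:
    """All four model stages plus the Step-1 case applied to each window."""

    Id1: np.ndarray
    Id2: np.ndarray
    Id3: np.ndarray
    Id4: np.ndarray
    case_label: np.ndarray
    grid: WindowGrid
    centromere: CentromereEstimate | None = None

    def __post_init__(self):
        n = self.grid.n
        for name in ("Id1", "Id2", "Id3", "Id4"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != grid windows {n}")
        self.case_label = np.asarray(self.case_label, dtype=object)
        if len(self.case_label) != n:
            raise ValueError("case_label length != grid windows")
        unknown = set(self.case_label) - set(CASE_LABELS)
        if unknown:
            raise ValueError(f"unknown case labels {unknown}")


def apply_cases(
    features: FeatureTrack, params: ModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Step 1: case-based identity modification.

    Returns (Id1, case label per window).  The three guards are evaluated in
    listed order and the first match wins; guards use strict inequalities, so
    e.g. ``V == t4`` matches neither case 1 nor cases 2/3.
    """
    id0, V, A = features.Id0, features.V, features.A
    p = params
    m1 = (id0 < p.t1) & (V > p.t4)
    m2 = ~m1 & (id0 < p.t2) & (V < p.t4)
    m3 = ~m1 & ~m2 & (A > p.t3) & (V < p.t4)
    id1 = np.where(m1, id0 - p.p1, np.where(m2, id0 + p.p2, np.where(m3, id0 - p.p3, id0)))
    label = np.select([m1, m2, m3], [CASE1, CASE2, CASE3], default=NO_CASE).astype(object)
    return id1, label


def clip_negative(id1: np.ndarray) -> np.ndarray:
    """Step 2: zero the negative values (Id2 = max(0, Id1))."""
    return np.maximum(0.0, np.asarray(id1, dtype=float))


def detect_centromere(
    cento_ref: CentoTrack, cento_qry: CentoTrack, grid: WindowGrid
) -> CentromereEstimate:
    """Step 3a: locate the centromere from CentO satellite hit counts.

    For each parental chromosome the peak set is the windows attaining that
    track's maximum count; ``c0``/``c1`` are the left-/right-most windows of
    the union of the two peak sets.  A track with no positive count carries
    no signal and contributes nothing; if neither track has signal the
    centromere cannot be located.
    """
    peak_windows: list[int] = []
    for track in (cento_ref, cento_qry):
        counts = track.counts
        if len(counts) and counts.max() > 0:
            peak_windows.extend(np.flatnonzero(counts == counts.max()).tolist())
    if not peak_windows:
        raise ValueError("no CentO signal: all hit counts are zero on both chromosomes")
    c0, c1 = min(peak_windows), max(peak_windows)
    return CentromereEstimate(c0=c0, c1=c1, telocentric=c1 <= grid.n / 4)


def centromere_weights(
    cent: CentromereEstimate, grid: WindowGrid, ramp: int = DEFAULT_RAMP
) -> np.ndarray:
    """Step 3b: per-window correction weights.

    Metacentric chromosomes get the piecewise-linear mask f: 0 on [c0, c1],
    ramping linearly to 1 over ``ramp`` windows on each side, 1 beyond
    (clamped into [0, 1] where a ramp runs off a chromosome end).
    Telocentric chromosomes get the binary mask g: 0 strictly left of c1,
    1 from c1 on — the whole short arm, carrying the recombination-
    suppressing NOR, is silenced.
    """
    w = np.arange(grid.n)
    if cent.telocentric:
        return (w >= cent.c1).astype(float)
    weights = np.ones(grid.n)
    left = (w > cent.c0 - ramp) & (w <= cent.c0)
    weights[left] = -(w[left] - cent.c0) / ramp
    weights[(w > cent.c0) & (w <= cent.c1)] = 0.0
    right = (w > cent.c1) & (w <= cent.c1 + ramp)
    weights[right] = (w[right] - cent.c1) / ramp
    return np.clip(weights, 0.0, 1.0)


def apply_centromere_correction(
    id2: np.ndarray,
    cent: CentromereEstimate,
    grid: WindowGrid,
    ramp: int = DEFAULT_RAMP,
) -> np.ndarray:
    """Step 3c: Id3 = Id2 x centromere weight."""
    id2 = np.asarray(id2, dtype=float)
    if len(id2) != grid.n:
        raise ValueError("Id2 length != grid windows")
    return id2 * centromere_weights(cent, grid, ramp=ramp)


def smooth_prediction(id3: np.ndarray, alpha: float) -> np.ndarray:
    """Step 4: exponential smoothing with the first window forced to zero.

    Id4(0) = 0; Id4(w) = alpha * Id3(w) + (1 - alpha) * Id4(w - 1).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha={alpha} outside (0, 1)")
    x = np.asarray(id3, dtype=float).copy()
    if len(x) == 0:
        raise ValueError("empty track")
    x[0] = 0.0
    return lfilter([alpha], [1.0, -(1.0 - alpha)], x)


def predict_track(
    features: FeatureTrack,
    cento_ref: CentoTrack,
    cento_qry: CentoTrack,
    params: ModelParams,
) -> PredictionTrack:
    """Run the four model steps in order, retaining every intermediate."""
    id1, label = apply_cases(features, params)
    id2 = clip_negative(id1)
    cent = detect_centromere(cento_ref, cento_qry, features.grid)
    id3 = apply_centromere_correction(id2, cent, features.grid, ramp=params.ramp)
    id4 = smooth_prediction(id3, params.alpha)
    return PredictionTrack(
        Id1=id1, Id2=id2, Id3=id3, Id4=id4,
        case_label=label, grid=features.grid, centromere=cent,
    )


def case_incidence(track: PredictionTrack) -> dict[str, float]:
    """Fraction of windows per Step-1 case label (all four labels reported)."""
    n = len(track.case_label)
    return {
        lab: float(np.sum(track.case_label == lab)) / n for lab in CASE_LABELS
    }
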