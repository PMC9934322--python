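"""Synthetic fixtures: alignment reports, CentO tracks, observed recombination.

Generates a parental-chromosome comparison with known ground truth so the
whole pipeline is testable without any real assembly.  Per-window feature
values are drawn as integer base counts (variants, inverted bases, absent
bases), which makes every proportion an exact rational of the window length;
the emitted ``show-coords``/``show-snps`` text therefore round-trips exactly
through the parsers and the feature extractor.  A low-identity valley is
planted around the centromere, mimicking the divergence usually seen in
centromeric regions, and the observed recombination track is the model's own
prediction under known true parameters plus optional Gaussian noise
truncated at zero.

All randomness flows from the scenario's single seed via independent
substreams; identical scenarios produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignio import AlignmentBlock, RecombinationTrack, VariantRecord
from .features import CentoTrack, FeatureTrack, WindowGrid, compute_identity
from .model import ModelParams, predict_track
from .presets import load_preset


def _default_params() -> ModelParams:
    return load_preset("chr01")


@dataclass
class ArchetypeMix:
    """Mixture weights and value ranges of the window archetypes.

    Each window is drawn from one of five archetypes whose feature ranges are
    deliberately disjoint, so every case guard of the model sees clearly
    separated low/high regimes (identity above/below the identity thresholds,
    V above/below the variant threshold, A above/below the absent threshold):

    * identical — only a low background variant rate; identity near 1;
    * variant_rich — V in ``v_range``, a little A; the penalty-case regime;
    * inverted — V in ``v_range`` plus an inversion covering ``i_range`` of
      the window; lowest identity;
    * absent_heavy — background V, A in ``a_heavy_range``; low identity with
      few variants, the reward-case regime;
    * absent_light — background V, A in ``a_light_range``; moderately high
      identity with absent bases, the correction-case regime.

    Probabilities are for the four non-identical archetypes; the remainder is
    identical windows.
    """

    p_variant: float = 0.20
    p_inverted: float = 0.05
    p_absent_heavy: float = 0.10
    p_absent_light: float = 0.08
    background_v: float = 2e-4  # variants per base in identical windows
    v_range: tuple[float, float] = (0.30, 0.45)
    i_range: tuple[float, float] = (0.30, 0.50)
    a_small_range: tuple[float, float] = (0.0, 0.05)
    a_heavy_range: tuple[float, float] = (0.50, 0.65)
    a_light_range: tuple[float, float] = (0.20, 0.30)

    def __post_init__(self):
        total = self.p_variant + self.p_inverted + self.p_absent_heavy + self.p_absent_light
        if total > 1.0:
            raise ValueError(f"archetype probabilities sum to {total} > 1")

    def expected_means(self) -> dict[str, float]:
        """Expected per-window means of V, I and A under the mixture."""
        mid = lambda r: 0.5 * (r[0] + r[1])
        p_id = 1.0 - (self.p_variant + self.p_inverted
                      + self.p_absent_heavy + self.p_absent_light)
        v = (self.p_variant + self.p_inverted) * mid(self.v_range) + (
            p_id + self.p_absent_heavy + self.p_absent_light
        ) * self.background_v
        i = self.p_inverted * mid(self.i_range)
        a = (
            self.p_variant * mid(self.a_small_range)
            + self.p_absent_heavy * mid(self.a_heavy_range)
            + self.p_absent_light * mid(self.a_light_range)
        )
        return {"V": v, "I": i, "A": a}


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic chromosome pair.

    Defaults describe a rice-like comparison at desk scale: a 20 Mb
    chromosome partitioned into 100 kb windows, a centromere in the middle
    with a CentO hit peak a few windows wide and an enforced low-identity
    valley around it, window features drawn from the archetype mixture, and
    true model parameters equal to the shipped chr01 calibration.
    """

    chrom_length: int = 20_000_000
    window_size: int = 100_000
    chrom: str = "chrS1"
    true_params: ModelParams = field(default_factory=_default_params)
    centromere_window: int | None = None  # defaults to the middle window
    cento_peak_width: int = 5
    cento_offset: int = 0  # query peak offset, in windows
    cento_peak_count: int = 5000
    mix: ArchetypeMix = field(default_factory=ArchetypeMix)
    valley_halfwidth: int = 10  # absent-heavy windows forced around the centromere
    noise_sd: float = 0.05  # cM per window
    rate_scale: float = 1.0  # cM per unit of model output
    seed: int = 0

    def __post_init__(self):
        grid = self.grid
        if self.centromere_window is None:
            self.centromere_window = grid.n // 2
        if not 0 <= self.centromere_window < grid.n:
            raise ValueError("planted centromere outside the chromosome")

    @property
    def grid(self) -> WindowGrid:
        return WindowGrid(
            chrom_length=self.chrom_length,
            window_size=self.window_size,
            chrom=self.chrom,
        )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _uniform_counts(rng, rng_range, lengths) -> np.ndarray:
    """Integer base counts uniform over a proportion range, per window."""
    lo, hi = rng_range
    lo_c = np.ceil(lo * lengths).astype(np.int64)
    hi_c = np.floor(hi * lengths).astype(np.int64)
    return rng.integers(lo_c, np.maximum(hi_c, lo_c) + 1)


def generate_feature_tracks(
    scenario: SyntheticScenario,
) -> tuple[FeatureTrack, dict]:
    """Draw per-window feature counts and build the feature track.

    Returns the track plus a ground-truth record with the archetype per
    window and the integer counts (``n_variants``, ``inv_bases``,
    ``absent_bases``) that the alignment emitter consumes.
    """
    grid = scenario.grid
    n = grid.n
    lengths = grid.window_lengths
    rng = scenario.rng(1)
    mix = scenario.mix

    probs = np.array(
        [mix.p_variant, mix.p_inverted, mix.p_absent_heavy, mix.p_absent_light]
    )
    p_id = 1.0 - probs.sum()
    kinds = rng.choice(
        np.array(["variant", "inverted", "absent_heavy", "absent_light", "identical"]),
        size=n,
        p=np.append(probs, p_id),
    )
    # low-identity valley around the planted centromere
    c = scenario.centromere_window
    if scenario.valley_halfwidth > 0:
        lo = max(0, c - scenario.valley_halfwidth)
        hi = min(n, c + scenario.valley_halfwidth + 1)
        kinds[lo:hi] = "absent_heavy"

    n_variants = np.zeros(n, dtype=np.int64)
    inv_bases = np.zeros(n, dtype=np.int64)
    absent_bases = np.zeros(n, dtype=np.int64)

    background = rng.poisson(mix.background_v * lengths)
    rich_v = _uniform_counts(rng, mix.v_range, lengths)
    inv = _uniform_counts(rng, mix.i_range, lengths)
    a_small = _uniform_counts(rng, mix.a_small_range, lengths)
    a_heavy = _uniform_counts(rng, mix.a_heavy_range, lengths)
    a_light = _uniform_counts(rng, mix.a_light_range, lengths)

    n_variants = np.where(np.isin(kinds, ["variant", "inverted"]), rich_v, background)
    inv_bases = np.where(kinds == "inverted", inv, 0)
    absent_bases = np.select(
        [kinds == "variant", kinds == "absent_heavy", kinds == "absent_light"],
        [a_small, a_heavy, a_light],
        default=0,
    )
    # an absent-base attribution needs at least 2 forward bases to split on
    cap = lengths - 2
    inv_bases = np.where(absent_bases > 0, np.minimum(inv_bases, cap), inv_bases)
    n_variants = np.minimum(n_variants, lengths)

    V = n_variants / lengths
    I = inv_bases / lengths
    A = absent_bases / lengths
    track = FeatureTrack(V=V, I=I, A=A, Id0=compute_identity(V, I, A), grid=grid)
    truth = {
        "kinds": kinds,
        "n_variants": n_variants,
        "inv_bases": inv_bases,
        "absent_bases": absent_bases,
    }
    return track, truth


def emit_alignment_reports(
    track: FeatureTrack, scenario: SyntheticScenario, with_header: bool = True
) -> tuple[str, str, int]:
    """Realise a feature track as ``show-coords``/``show-snps`` text.

    Each window becomes (at most) a reverse block carrying its inverted
    bases, then one or two forward blocks; a planned absent segment is an
    unaligned query gap inserted at a split point strictly inside the window,
    so the feature extractor attributes it back to the same window.  Variants
    are emitted as SNP rows at the start of the window.

    Returns (coords text, snps text, query length).  Raises if a window's
    proportions are not realisable as integer base counts or block layouts,
    naming the window.
    """
    grid = track.grid
    lengths = grid.window_lengths
    ref, qry = "ref_" + grid.chrom, "qry_" + grid.chrom

    blocks: list[tuple[int, int, int, int]] = []  # 1-based s1 e1 s2 e2
    snp_rows: list[tuple[int, str, str]] = []
    q = 0  # query cursor, 0-based
    for w in range(grid.n):
        L = int(lengths[w])
        start = w * grid.window_size
        for name, value in (("V", track.V[w]), ("I", track.I[w]), ("A", track.A[w])):
            scaled = value * L
            if abs(scaled - round(scaled)) > 1e-6:
                raise ValueError(
                    f"window {w}: {name}={value} is not an integer count of "
                    f"window length {L}"
                )
        v = int(round(track.V[w] * L))
        i = int(round(track.I[w] * L))
        a = int(round(track.A[w] * L))
        if i > L:
            raise ValueError(f"window {w}: inverted bases exceed window length")
        if a > 0 and L - i < 2:
            raise ValueError(
                f"window {w}: absent bases need >= 2 forward bases to anchor"
            )
        if i > 0:
            # reverse block: query coordinates listed high-to-low
            blocks.append((start + 1, start + i, q + i, q + 1))
            q += i
        fwd_start, fwd_len = start + i, L - i
        if a > 0:
            half = fwd_len // 2
            blocks.append((fwd_start + 1, fwd_start + half, q + 1, q + half))
            q += half + a  # the unaligned query segment
            blocks.append((fwd_start + half + 1, start + L, q + 1, q + (fwd_len - half)))
            q += fwd_len - half
        elif fwd_len > 0:
            blocks.append((fwd_start + 1, start + L, q + 1, q + fwd_len))
            q += fwd_len
        for k in range(v):
            snp_rows.append((start + k + 1, "A", "G"))
    qry_length = q

    coords_lines = []
    if with_header:
        coords_lines += [
            f"{ref}.fa {qry}.fa",
            "NUCMER",
            "",
            "    [S1]     [E1]  |     [S2]     [E2]  |  [LEN 1]  [LEN 2]  |  [% IDY]  | [TAGS]",
            "=" * 88,
        ]
    for s1, e1, s2, e2 in blocks:
        l1 = e1 - s1 + 1
        l2 = abs(e2 - s2) + 1
        coords_lines.append(
            f"{s1:>8} {e1:>8}  | {s2:>8} {e2:>8}  | {l1:>8} {l2:>8}  |    99.00  | {ref}\t{qry}"
        )
    coords_text = "\n".join(coords_lines) + "\n"

    snps_lines = []
    if with_header:
        snps_lines += [
            f"{ref}.fa {qry}.fa",
            "NUCMER",
            "",
            "    [P1]  [SUB]  [P2]      |   [BUFF]   [DIST]  | [FRM]  [TAGS]",
            "=" * 70,
        ]
    for p1, rb, qb in snp_rows:
        snps_lines.append(
            f"{p1:>8}   {rb}   {qb}   {p1:>8}  | {10:>8} {p1:>8}  |  1  1  | {ref}\t{qry}"
        )
    snps_text = "\n".join(snps_lines) + "\n"
    return coords_text, snps_text, qry_length


def emit_cento_tracks(scenario: SyntheticScenario) -> tuple[CentoTrack, CentoTrack]:
    """Triangular CentO hit-count peaks at the planted centromere.

    The query peak is offset by ``cento_offset`` windows; a zero offset makes
    both peak sets coincide at the planted window.
    """
    grid = scenario.grid

    def peak(center: int) -> CentoTrack:
        center = min(max(center, 0), grid.n - 1)
        w = np.arange(grid.n)
        shape = 1.0 - np.abs(w - center) / max(scenario.cento_peak_width, 1)
        counts = np.round(scenario.cento_peak_count * np.clip(shape, 0.0, None))
        return CentoTrack(counts=counts.astype(np.int64), grid=grid)

    c = scenario.centromere_window
    return peak(c), peak(c + scenario.cento_offset)


def cento_track_to_bed(track: CentoTrack) -> list[tuple[str, int, int]]:
    """Represent a count track as BED hits reproducing it exactly.

    Each window with count k (k <= window length) yields one interval of k
    bases at the window start, so re-counting the intervals recovers the
    track.
    """
    grid = track.grid
    lengths = grid.window_lengths
    out = []
    for w, k in enumerate(track.counts):
        if k > lengths[w]:
            raise ValueError(f"window {w}: count {k} exceeds window length")
        if k > 0:
            start = w * grid.window_size
            out.append((grid.chrom, start, start + int(k)))
    return out


def generate_experimental(
    features: FeatureTrack,
    cento_ref: CentoTrack,
    cento_qry: CentoTrack,
    scenario: SyntheticScenario,
) -> RecombinationTrack:
    """Observed recombination: the true model's output plus truncated noise.

    The noiseless track is constructed as the exact pre-image of the model's
    final prediction under the evaluation smoothing, so at ``noise_sd=0`` the
    smoothed observation equals Id4 and the model scores r = 1, R² = 1.
    """
    truth = predict_track(features, cento_ref, cento_qry, scenario.true_params)
    base = np.concatenate([[0.0], truth.Id3[1:]]) * scenario.rate_scale
    rng = scenario.rng(2)
    if scenario.noise_sd > 0:
        base = base + rng.normal(0.0, scenario.noise_sd, size=len(base))
    rates = np.clip(base, 0.0, None)
    return RecombinationTrack(
        window_starts=features.grid.starts, rates=rates, chrom=features.grid.chrom
    )


def generate_bundle(scenario: SyntheticScenario) -> dict:
    """Everything the pipeline consumes, from one seed.

    Keys: ``features``, ``truth_counts``, ``coords_text``, ``snps_text``,
    ``qry_length``, ``cento_ref``, ``cento_qry``, ``experimental``, ``grid``.
    """
    features, truth = generate_feature_tracks(scenario)
    coords_text, snps_text, qry_length = emit_alignment_reports(features, scenario)
    cento_ref, cento_qry = emit_cento_tracks(scenario)
    experimental = generate_experimental(features, cento_ref, cento_qry, scenario)
    return {
        "features": features,
        "truth_counts": truth,
        "coords_text": coords_text,
        "snps_text": snps_text,
        "qry_length": qry_length,
        "cento_ref": cento_ref,
        "cento_qry": cento_qry,
        "experimental": experimental,
        "grid": scenario.grid,
    }
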