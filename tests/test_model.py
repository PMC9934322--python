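import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recland.features import CentoTrack, FeatureTrack, WindowGrid
from recland.model import (
    CASE_LABELS,
    CentromereEstimate,
    ModelParams,
    PredictionTrack,
    apply_cases,
    apply_centromere_correction,
    case_incidence,
    centromere_weights,
    clip_negative,
    detect_centromere,
    predict_track,
    smooth_prediction,
)
from recland.presets import PRESET_NAMES, load_preset

from tests.helpers import literal_case_rules, smoothing_closed_form


def make_features(id0, V=None, A=None, I=None):
    id0 = np.asarray(id0, dtype=float)
    n = len(id0)
    zeros = np.zeros(n)
    grid = WindowGrid(chrom_length=n * 100_000, window_size=100_000)
    return FeatureTrack(
        V=zeros if V is None else V,
        I=zeros if I is None else I,
        A=zeros if A is None else A,
        Id0=id0,
        grid=grid,
    )


class TestModelParams:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(p1=1.2)
        with pytest.raises(ValueError):
            ModelParams(alpha=1.0)

    def test_json_round_trip_exact(self):
        p = load_preset("chr01")
        assert ModelParams.from_json(p.to_json()) == p

    def test_chr01_preset_values(self):
        p = load_preset("chr01")
        assert (p.p1, p.t1, p.t4) == (0.529, 0.970, 0.002)
        assert (p.p2, p.p3, p.t2, p.t3) == (1.000, 1.000, 0.900, 0.000)
        assert p.alpha == 0.1

    def test_all_presets_load_within_bounds(self):
        for name in PRESET_NAMES:
            p = load_preset(name)
            assert all(0 <= getattr(p, k) <= 1 for k in ModelParams.PARAM_NAMES)

    def test_vector_round_trip(self):
        p = load_preset("chr05")
        assert ModelParams.from_vector(p.as_vector()) == p


class TestApplyCases:
    def test_chr01_penalty_case(self):
        # low identity with substantial variants: case 1, Id1 = 0.90 - 0.529
        params = load_preset("chr01")
        ft = make_features([0.90], V=[0.003])
        id1, labels = apply_cases(ft, params)
        assert labels[0] == "case1"
        assert id1[0] == pytest.approx(0.371, abs=1e-12)

    def test_perfect_window_matches_no_case(self):
        params = ModelParams(t1=0.9, t2=0.9, t3=0.0, t4=0.5)
        ft = make_features([1.0])
        id1, labels = apply_cases(ft, params)
        assert labels[0] == "none"
        assert id1[0] == 1.0

    def test_threshold_equality_matches_no_case(self):
        # strict inequalities: V == t4 falls through every guard
        params = ModelParams(p1=0.5, p2=0.5, p3=0.5, t1=0.9, t2=0.9, t3=0.0, t4=0.1)
        ft = make_features([0.5], V=[0.1], A=[0.5])
        id1, labels = apply_cases(ft, params)
        assert labels[0] == "none"
        assert id1[0] == 0.5

    def test_guard_grid_matches_literal_rules(self):
        # exhaustive boundary grid around each threshold, first match wins
        params = ModelParams(p1=0.3, p2=0.2, p3=0.4, t1=0.7, t2=0.5, t3=0.2, t4=0.1)
        eps = 1e-9
        id0s = [0.0, params.t2 - eps, params.t2, params.t1 - eps, params.t1, 1.0]
        vs = [0.0, params.t4 - eps, params.t4, params.t4 + eps, 1.0]
        as_ = [0.0, params.t3 - eps, params.t3, params.t3 + eps, 1.0]
        combos = list(itertools.product(id0s, vs, as_))
        ft = make_features(
            [c[0] for c in combos], V=[c[1] for c in combos], A=[c[2] for c in combos]
        )
        id1, labels = apply_cases(ft, params)
        for k, (i0, v, a) in enumerate(combos):
            lab, val = literal_case_rules(i0, v, a, params)
            assert labels[k] == lab, (i0, v, a)
            assert id1[k] == pytest.approx(val, abs=1e-15)

    def test_labels_partition_windows(self, bundle_small):
        scenario, bundle = bundle_small
        _, labels = apply_cases(bundle["features"], scenario.true_params)
        assert set(labels) <= set(CASE_LABELS)
        assert len(labels) == bundle["grid"].n


class TestClipNegative:
    def test_zeroes_negatives_only(self):
        np.testing.assert_array_equal(clip_negative([-0.2, 0.0, 0.5]), [0.0, 0.0, 0.5])

    def test_identity_on_non_negative(self):
        x = np.array([0.1, 0.0, 2.0])
        np.testing.assert_array_equal(clip_negative(x), x)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-2, 2), min_size=1, max_size=50))
    def test_elementwise_max_with_zero(self, values):
        out = clip_negative(values)
        assert (out >= 0).all()
        np.testing.assert_array_equal(out, np.maximum(0, values))


def cento(counts, grid):
    return CentoTrack(counts=np.asarray(counts, dtype=np.int64), grid=grid)


class TestDetectCentromere:
    grid = WindowGrid(chrom_length=10_000_000, window_size=100_000)  # n=100

    def track(self, peaks):
        counts = np.zeros(self.grid.n, dtype=np.int64)
        for w, c in peaks:
            counts[w] = c
        return cento(counts, self.grid)

    def test_separate_peaks_bracket_interval(self):
        est = detect_centromere(
            self.track([(40, 100)]), self.track([(42, 80)]), self.grid
        )
        assert (est.c0, est.c1) == (40, 42)
        assert not est.telocentric

    def test_coincident_peaks_collapse(self):
        est = detect_centromere(
            self.track([(40, 10)]), self.track([(40, 99)]), self.grid
        )
        assert (est.c0, est.c1) == (40, 40)

    def test_tied_maxima_form_argmax_set(self):
        est = detect_centromere(
            self.track([(40, 7), (45, 7)]), self.track([(41, 3)]), self.grid
        )
        assert (est.c0, est.c1) == (40, 45)

    def test_telocentric_classification_at_quarter(self):
        est = detect_centromere(self.track([(20, 5)]), self.track([(25, 5)]), self.grid)
        assert est.telocentric  # c1 = 25 = n/4 counts as telocentric

    def test_all_zero_tracks_rejected(self):
        with pytest.raises(ValueError, match="no CentO signal"):
            detect_centromere(self.track([]), self.track([]), self.grid)

    def test_single_silent_track_is_ignored(self):
        est = detect_centromere(self.track([(60, 5)]), self.track([]), self.grid)
        assert (est.c0, est.c1) == (60, 60)


class TestCentromereWeights:
    grid = WindowGrid(chrom_length=40_000_000, window_size=100_000)  # n=400

    def test_metacentric_piecewise_values(self):
        est = CentromereEstimate(c0=100, c1=120, telocentric=False)
        w = centromere_weights(est, self.grid)
        assert w[50] == 1.0
        assert w[75] == pytest.approx(0.5)
        assert w[100] == 0.0
        assert w[110] == 0.0
        assert w[145] == pytest.approx(0.5)
        assert w[171] == 1.0

    def test_metacentric_shape_invariants(self):
        est = CentromereEstimate(c0=100, c1=120, telocentric=False)
        w = centromere_weights(est, self.grid)
        assert (w[100:121] == 0).all()
        assert (w[: 100 - 50 + 1] == 1).all()
        assert (w[120 + 50 :] == 1).all()
        ramp_left = w[51:100]
        assert np.allclose(np.diff(ramp_left), -1 / 50)

    def test_telocentric_binary_mask(self):
        est = CentromereEstimate(c0=25, c1=30, telocentric=True)
        w = centromere_weights(est, self.grid)
        assert (w[:30] == 0).all()
        assert (w[30:] == 1).all()
        assert set(np.unique(w)) <= {0.0, 1.0}

    def test_left_ramp_clamped_at_chromosome_start(self):
        est = CentromereEstimate(c0=20, c1=30, telocentric=False)
        w = centromere_weights(est, self.grid)
        assert w[0] == pytest.approx(max(0.0, 20 / 50))


class TestCentromereCorrection:
    grid = WindowGrid(chrom_length=40_000_000, window_size=100_000)

    def test_unit_input_returns_weight_vector(self):
        est = CentromereEstimate(c0=100, c1=120, telocentric=False)
        id3 = apply_centromere_correction(np.ones(self.grid.n), est, self.grid)
        np.testing.assert_array_equal(id3, centromere_weights(est, self.grid))

    def test_centromeric_interval_zeroed(self):
        est = CentromereEstimate(c0=100, c1=120, telocentric=False)
        rng = np.random.default_rng(0)
        id3 = apply_centromere_correction(rng.uniform(0, 2, self.grid.n), est, self.grid)
        assert (id3[100:121] == 0).all()

    def test_telocentric_short_arm_silenced(self):
        est = CentromereEstimate(c0=25, c1=30, telocentric=True)
        id2 = np.ones(self.grid.n)
        id3 = apply_centromere_correction(id2, est, self.grid)
        assert (id3[:30] == 0).all()
        assert (id3[30:] == 1).all()


class TestSmoothing:
    def test_first_window_forced_to_zero(self):
        np.testing.assert_array_equal(smooth_prediction([5.0, 0.0, 0.0], 0.1), [0, 0, 0])

    def test_recurrence_values(self):
        np.testing.assert_allclose(
            smooth_prediction([0.0, 1.0, 1.0], 0.1), [0.0, 0.1, 0.19], atol=1e-15
        )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0, 2), min_size=2, max_size=60),
        st.floats(0.01, 0.99),
    )
    def test_matches_closed_form(self, values, alpha):
        values = np.asarray(values)
        out = smooth_prediction(values, alpha)
        assert out[0] == 0.0
        np.testing.assert_allclose(out, smoothing_closed_form(values, alpha), atol=1e-12)


class TestPredictTrack:
    def test_identical_parents_give_smoothed_masked_constant(self):
        grid = WindowGrid(chrom_length=20_000_000, window_size=100_000)
        n = grid.n
        ft = FeatureTrack(V=np.zeros(n), I=np.zeros(n), A=np.zeros(n),
                          Id0=np.ones(n), grid=grid)
        counts = np.zeros(n, dtype=np.int64)
        counts[n // 2] = 100
        ct = CentoTrack(counts=counts, grid=grid)
        params = ModelParams(t1=0.5, t2=0.5, t3=0.5, t4=0.5)
        track = predict_track(ft, ct, ct, params)
        assert (track.case_label == "none").all()
        np.testing.assert_array_equal(track.Id1, np.ones(n))
        est = track.centromere
        expected = smooth_prediction(
            centromere_weights(est, grid), params.alpha
        )
        np.testing.assert_allclose(track.Id4, expected, atol=1e-15)

    def test_pipeline_is_deterministic(self, bundle_small):
        scenario, bundle = bundle_small
        args = (bundle["features"], bundle["cento_ref"], bundle["cento_qry"],
                scenario.true_params)
        t1, t2 = predict_track(*args), predict_track(*args)
        for name in ("Id1", "Id2", "Id3", "Id4"):
            np.testing.assert_array_equal(getattr(t1, name), getattr(t2, name))
        np.testing.assert_array_equal(t1.case_label, t2.case_label)

    def test_intermediates_satisfy_stage_invariants(self, bundle_small):
        scenario, bundle = bundle_small
        track = predict_track(bundle["features"], bundle["cento_ref"],
                              bundle["cento_qry"], scenario.true_params)
        np.testing.assert_array_equal(track.Id2, np.maximum(0, track.Id1))
        assert track.Id4[0] == 0.0
        assert (track.Id1 >= -1 - 1e-12).all() and (track.Id1 <= 2 + 1e-12).all()
        assert (track.Id3 >= 0).all()


class TestCaseIncidence:
    def test_fractions_from_labels(self):
        grid = WindowGrid(chrom_length=400_000, window_size=100_000)
        track = PredictionTrack(
            Id1=np.zeros(4), Id2=np.zeros(4), Id3=np.zeros(4), Id4=np.zeros(4),
            case_label=np.array(["case1", "case1", "none", "case2"], dtype=object),
            grid=grid,
        )
        inc = case_incidence(track)
        assert inc == {"case1": 0.5, "case2": 0.25, "case3": 0.0, "none": 0.25}
        assert sum(inc.values()) == pytest.approx(1.0)

    def test_all_none(self):
        grid = WindowGrid(chrom_length=200_000, window_size=100_000)
        track = PredictionTrack(
            Id1=np.zeros(2), Id2=np.zeros(2), Id3=np.zeros(2), Id4=np.zeros(2),
            case_label=np.array(["none", "none"], dtype=object), grid=grid,
        )
        assert case_incidence(track)["none"] == 1.0
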