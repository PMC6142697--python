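import numpy as np
import pytest

from briqa import (
    BinaryFeatureImage,
    Config,
    QualityReport,
    Slice,
    Weights,
    aggregate,
    lightness,
    luminance_contrast,
    score_slice,
    score_volume,
    texture,
    texture_contrast,
    total,
)
from oracles import brute_agreement_score, brute_edge_match_score


def _binary(bits, name, fg=None):
    kinds = {"FGMG": ("grayscale", "mu_d"), "FCMG": ("grayscale", "mu_c"),
             "FCMC": ("contrast", "mu_c"), "FGMC": ("contrast", "mu_d")}
    kind, moment = kinds[name]
    fg = np.ones(bits.shape, bool) if fg is None else fg
    return BinaryFeatureImage(bits & fg, name, kind, moment, fg)


@pytest.fixture
def toy_pair():
    rng = np.random.default_rng(23)
    a = rng.uniform(0, 1, (8, 8)) > 0.4
    b = rng.uniform(0, 1, (8, 8)) > 0.6
    return a, b


class TestEdgeMatchingScores:
    def test_empty_versus_nonempty_is_zero(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        b[2:5, 2:5] = True
        assert luminance_contrast(_binary(a, "FGMG"), _binary(b, "FCMG")) == 0.0

    def test_both_empty_is_zero_with_warning(self):
        z = np.zeros((8, 8), bool)
        with pytest.warns(UserWarning):
            assert texture(_binary(z, "FGMC"), _binary(z, "FCMC")) == 0.0

    def test_matches_brute_force_counting(self, toy_pair):
        a, b = toy_pair
        got = luminance_contrast(_binary(a, "FGMG"), _binary(b, "FCMG"))
        assert got == pytest.approx(brute_edge_match_score(a, b), abs=0)
        got2 = texture(_binary(a, "FGMC"), _binary(b, "FCMC"))
        assert got2 == pytest.approx(brute_edge_match_score(a, b), abs=0)

    def test_identical_pair_scores_one_under_edge_denominator(self, toy_pair):
        a, _ = toy_pair
        q = luminance_contrast(_binary(a, "FGMG"), _binary(a, "FCMG"),
                               edge_denominator=True)
        assert q == 1.0

    def test_source_kind_mismatch_raises(self, toy_pair):
        a, b = toy_pair
        with pytest.raises(ValueError):
            luminance_contrast(_binary(a, "FGMG"), _binary(b, "FCMC"))
        with pytest.raises(ValueError):
            texture(_binary(a, "FGMG"), _binary(b, "FCMG"))


class TestPixelwiseScores:
    def test_identical_images_score_one(self, toy_pair):
        a, _ = toy_pair
        assert texture_contrast(_binary(a, "FGMC"), _binary(a, "FCMC"), 64) == 1.0
        assert lightness(_binary(a, "FGMG"), _binary(a, "FCMG"), 64) == 1.0

    def test_exact_complements_score_zero(self, toy_pair):
        a, _ = toy_pair
        assert texture_contrast(_binary(a, "FGMC"), _binary(~a, "FCMC"), 64) == 0.0

    def test_matches_brute_force_agreement(self, toy_pair):
        a, b = toy_pair
        fg = np.ones((8, 8), bool)
        got = texture_contrast(_binary(a, "FGMC"), _binary(b, "FCMC"), 64)
        assert got == brute_agreement_score(a, b, fg)

    def test_empty_foreground_raises(self, toy_pair):
        a, b = toy_pair
        with pytest.raises(ValueError):
            lightness(_binary(a, "FGMG"), _binary(b, "FCMG"), 0)


class TestTotal:
    @pytest.mark.parametrize(
        "q,expected", [((1, 1, 1, 1), 1.0), ((0, 0, 0, 0), 0.0), ((0.5, 0.5, 0.5, 0.5), 0.5)]
    )
    def test_convex_combination(self, q, expected):
        assert total(*q) == pytest.approx(expected, abs=1e-12)

    def test_custom_weights_and_validation(self):
        assert total(1, 0, 0, 0, Weights(1, 0, 0, 0)) == 1.0
        with pytest.raises(ValueError):
            Weights(0.5, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            Weights(-0.1, 0.4, 0.4, 0.3)
        with pytest.raises(ValueError):
            total(1.5, 0, 0, 0)


class TestScoreSlice:
    def test_ideal_phantom_has_perfect_pixelwise_scores(self, ideal_phantom):
        slc, _, _ = ideal_phantom
        r = score_slice(slc)
        assert r.q3 == 1.0 and r.q4 == 1.0

    def test_deterministic_for_fixed_input(self, small_phantom):
        slc, _, _ = small_phantom
        a, b = score_slice(slc), score_slice(slc)
        assert a == b

    def test_total_is_the_weighted_sum(self, small_phantom):
        slc, _, _ = small_phantom
        r = score_slice(slc)
        assert r.Q == pytest.approx(
            0.1 * r.q1 + 0.1 * r.q2 + 0.7 * r.q3 + 0.1 * r.q4, abs=1e-12
        )

    def test_heavy_noise_lowers_the_total(self, small_phantom):
        from briqa import rician_noise

        slc, _, _ = small_phantom
        assert score_slice(rician_noise(slc, 15, seed=2)).Q < score_slice(slc).Q

    def test_window_override_changes_the_contrast_feature(self, small_phantom):
        slc, _, _ = small_phantom
        r3 = score_slice(slc, Config(window=3))
        r5 = score_slice(slc, Config(window=5))
        assert r3.window == 3 and r5.window == 5
        assert r3.mu_c != r5.mu_c


class TestVolume:
    def test_identical_slices_mean_equals_slice_score(self, small_phantom):
        slc, _, _ = small_phantom
        vol = score_volume([slc, slc, slc])
        assert vol.mean_Q == pytest.approx(vol.per_slice[0].Q, abs=1e-12)

    def test_means_equal_hand_averages(self, small_phantom):
        from briqa import generate, PhantomSpec

        slices = [generate(PhantomSpec(height=64, width=64, seed=s))[0] for s in (0, 1, 2)]
        vol = score_volume(slices)
        assert vol.mean_Q == pytest.approx(
            np.mean([r.Q for r in vol.per_slice]), abs=1e-12
        )
        assert vol.mean_q2 == pytest.approx(
            np.mean([r.q2 for r in vol.per_slice]), abs=1e-12
        )

    def test_sequence_tag_selects_cutoff(self, small_phantom):
        slc, _, _ = small_phantom
        t1 = Slice(slc.pixels, "T1")
        t2 = Slice(slc.pixels, "T2")
        assert score_volume([t1]).cutoff == 0.40
        assert score_volume([t2]).cutoff == 0.45

    def test_empty_volume_raises(self):
        with pytest.raises(ValueError):
            score_volume([])

    def test_pass_fail_flips_exactly_at_cutoff(self):
        def report(Q):
            return QualityReport(q1=Q, q2=Q, q3=Q, q4=Q, Q=Q)

        for cutoff in (0.40, 0.45):
            assert aggregate([report(cutoff)], cutoff).passes
            assert not aggregate([report(cutoff - 1e-9)], cutoff).passes
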