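"""Per-nucleus metrics: PCC oracle and invariances, spot detection, calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mintcoloc import (
    AnalysisConfig,
    ChannelImage,
    ParameterError,
    SimParams,
    Spot,
    UndefinedPCCError,
    analyze_nucleus,
    call_colocalization,
    detect_spots,
    pearson_cc,
    segment_nucleus,
    simulate_nucleus,
)
from mintcoloc.metrics import STATUS_SEGMENTATION_FAILED
from conftest import pcc_bruteforce


def _pair_on_mask(y_vals, c_vals):
    """Embed two 5-value samples in tiny images under a 5-pixel mask."""
    n = len(y_vals)
    y = np.zeros((2, n))
    c = np.zeros((2, n))
    mask = np.zeros((2, n), bool)
    y[0], c[0], mask[0] = y_vals, c_vals, True
    return ChannelImage(y, "YFP"), ChannelImage(c, "CFP"), mask


class TestPearsonCC:
    def test_self_correlation_is_one(self):
        y, c, m = _pair_on_mask([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert pearson_cc(y, c, m) == pytest.approx(1.0, abs=1e-15)

    def test_worked_five_pixel_example(self):
        # means 3, 3; cross-sum 8; each sum of squares 10 -> r = 8/10
        y, c, m = _pair_on_mask([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert pearson_cc(y, c, m) == pytest.approx(0.8, abs=1e-15)

    def test_perfect_anticorrelation(self):
        y, c, m = _pair_on_mask([1, 2, 3, 4, 5], [99, 98, 97, 96, 95])  # c = -y + 100
        assert pearson_cc(y, c, m) == pytest.approx(-1.0, abs=1e-15)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_and_scipy_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        y = ChannelImage(rng.uniform(0, 500, (20, 20)), "YFP")
        c = ChannelImage(rng.uniform(0, 500, (20, 20)), "CFP")
        mask = rng.random((20, 20)) < 0.25
        mask.flat[:3] = True  # ensure >= 3 pixels
        r = pearson_cc(y, c, mask)
        assert r == pytest.approx(pcc_bruteforce(y.pixels[mask], c.pixels[mask]),
                                  abs=1e-12)
        assert r == pytest.approx(
            sps.pearsonr(y.pixels[mask], c.pixels[mask]).statistic, abs=1e-12
        )

    @given(st.integers(0, 10_000), st.floats(0.1, 50.0), st.floats(0.0, 100.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounds_symmetry_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        y = ChannelImage(rng.uniform(1, 100, (8, 8)), "YFP")
        c = ChannelImage(rng.uniform(1, 100, (8, 8)), "CFP")
        mask = np.ones((8, 8), bool)
        r = pearson_cc(y, c, mask)
        assert -1.0 <= r <= 1.0
        assert pearson_cc(c, y, mask) == pytest.approx(r, abs=1e-12)
        y_aff = ChannelImage(a * y.pixels + b, "YFP")
        assert pearson_cc(y_aff, c, mask) == pytest.approx(r, abs=1e-9)

    def test_zero_variance_raises_undefined(self):
        y, c, m = _pair_on_mask([5, 5, 5, 5, 5], [1, 2, 3, 4, 5])
        with pytest.raises(UndefinedPCCError):
            pearson_cc(y, c, m)

    def test_small_mask_and_shape_mismatch_rejected(self):
        y, c, m = _pair_on_mask([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        with pytest.raises(ParameterError, match="3 pixels"):
            pearson_cc(y, c, np.zeros_like(m))
        with pytest.raises(ParameterError, match="shape"):
            pearson_cc(y, ChannelImage(np.ones((3, 3)), "CFP"), m)

    def test_in_mask_pcc_differs_from_whole_image(self):
        """Including extranuclear background pixels changes (inflates) the
        correlation — the analysis domain must be the nucleus mask."""
        pair, truth = simulate_nucleus(SimParams(seed=8, enrichment=0.0))
        in_mask = pearson_cc(pair.yfp, pair.cfp, truth.true_mask)
        whole = pearson_cc(pair.yfp, pair.cfp, np.ones(truth.true_mask.shape, bool))
        assert abs(whole - in_mask) > 0.05
        assert whole > in_mask  # shared nucleus footprint correlates channels


def _gaussian_spot_image(shape, center, sigma, amplitude=200.0, floor=10.0):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return ChannelImage(floor + amplitude * np.exp(-d2 / (2 * sigma**2)), "CFP")


class TestDetectSpots:
    full = np.ones((64, 64), bool)

    def test_single_spot_recovered_subpixel(self):
        img = _gaussian_spot_image((64, 64), (30.4, 27.8), sigma=2.0)
        spots = detect_spots(img, self.full)
        assert len(spots) == 1
        assert math.hypot(spots[0].centroid[0] - 30.4,
                          spots[0].centroid[1] - 27.8) < 0.5

    def test_flat_image_yields_no_spots(self):
        assert detect_spots(ChannelImage(np.full((64, 64), 7.0), "CFP"),
                            self.full) == []

    def test_two_spots_ten_px_apart(self):
        a = _gaussian_spot_image((64, 64), (30.0, 25.0), 2.0).pixels
        b = _gaussian_spot_image((64, 64), (30.0, 35.0), 2.0, floor=0.0).pixels
        spots = detect_spots(ChannelImage(a + b, "CFP"), self.full)
        assert len(spots) == 2
        found = sorted(s.centroid for s in spots)
        for got, want in zip(found, [(30.0, 25.0), (30.0, 35.0)]):
            assert math.hypot(got[0] - want[0], got[1] - want[1]) < 0.5

    def test_spots_outside_mask_ignored(self):
        img = _gaussian_spot_image((64, 64), (30.0, 30.0), 2.0)
        mask = np.zeros((64, 64), bool)
        mask[:10, :10] = True
        assert detect_spots(img, mask) == []

    def test_invalid_sigma_range_rejected(self):
        img = _gaussian_spot_image((64, 64), (30.0, 30.0), 2.0)
        with pytest.raises(ParameterError, match="sigma_range"):
            detect_spots(img, self.full, sigma_range=[])


def _spot(r, c, sigma=2.0, channel="CFP", response=1.0):
    return Spot((float(r), float(c)), sigma, 100.0, response, channel)


class TestCallColocalization:
    def test_coincident_spots_match_at_distance_zero(self):
        called, pairs = call_colocalization([_spot(10, 10, channel="YFP")],
                                            [_spot(10, 10)])
        assert called and len(pairs) == 1 and pairs[0][2] == 0.0

    def test_cfp_without_yfp_is_exclusion(self):
        called, pairs = call_colocalization([], [_spot(10, 10)])
        assert (called, pairs) == (False, [])

    def test_distance_beyond_threshold_not_matched(self):
        called, pairs = call_colocalization(
            [_spot(10, 12.5, channel="YFP")], [_spot(10, 10)], d_max_px=2.0
        )
        assert (called, pairs) == (False, [])

    def test_distance_exactly_at_threshold_matches(self):
        called, _ = call_colocalization(
            [_spot(10, 12.0, channel="YFP")], [_spot(10, 10)], d_max_px=2.0
        )
        assert called

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_d_max(self, seed):
        rng = np.random.default_rng(seed)
        yfp = [_spot(*rng.uniform(0, 30, 2), channel="YFP") for _ in range(4)]
        cfp = [_spot(*rng.uniform(0, 30, 2)) for _ in range(3)]
        called_small, _ = call_colocalization(yfp, cfp, d_max_px=1.5)
        called_large, _ = call_colocalization(yfp, cfp, d_max_px=6.0)
        assert called_large >= called_small

    def test_scale_match_factor_blocks_dissimilar_spots(self):
        yfp = [_spot(10, 10, sigma=8.0, channel="YFP")]
        cfp = [_spot(10, 10, sigma=2.0)]
        assert call_colocalization(yfp, cfp)[0]
        assert not call_colocalization(yfp, cfp, scale_match_factor=2.0)[0]


class TestAnalyzeNucleus:
    def test_enriched_nucleus_called_colocalized(self):
        pair, truth = simulate_nucleus(SimParams(seed=2, enrichment=4.0))
        rec = analyze_nucleus(pair)
        assert rec.status == "ok"
        assert rec.coloc_call
        assert rec.pcc is not None and rec.pcc > 0.2
        assert rec.n_mask_px == segment_nucleus(pair.yfp).area_px
        # matched pair sits at the true locus position
        cfp_spot = rec.matched_pairs[0][0]
        assert math.hypot(cfp_spot.centroid[0] - truth.spot_position[0],
                          cfp_spot.centroid[1] - truth.spot_position[1]) < 1.0

    def test_coloc_call_implies_matched_pairs(self):
        pair, _ = simulate_nucleus(SimParams(seed=2, enrichment=4.0))
        rec = analyze_nucleus(pair)
        assert rec.coloc_call == bool(rec.matched_pairs)

    def test_segmentation_failure_recorded_not_raised(self):
        flat = ChannelImage(np.full((64, 64), 10.0), "YFP")
        cfp = ChannelImage(np.full((64, 64), 10.0), "CFP")
        from mintcoloc import NucleusImagePair
        rec = analyze_nucleus(NucleusImagePair(flat, cfp, "n0"))
        assert rec.status == STATUS_SEGMENTATION_FAILED
        assert rec.pcc is None and not rec.coloc_call

    def test_wider_match_radius_never_loses_a_call(self):
        pair, _ = simulate_nucleus(SimParams(seed=13, enrichment=1.0))
        narrow = analyze_nucleus(pair, AnalysisConfig(d_max_px=1.0))
        wide = analyze_nucleus(pair, AnalysisConfig(d_max_px=4.0))
        assert wide.coloc_call >= narrow.coloc_call
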