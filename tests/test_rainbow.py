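"""Rainbow gap measurement, channel registration, gradients, polarity."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage

from pcpkit.config import InvalidParameterError, PipelineConfig, SimConfig
from pcpkit.rainbow import (GapProfile, classify_alignment,
                            expected_extended_length, measure_gap,
                            measure_gradients, polarity_from_gap,
                            register_channels, straighten_boundary)
from pcpkit.synthetic import RainbowTruth, simulate_rainbow

PSF_SIGMA = 250.0 / 2.3548  # 250 nm FWHM
PX = 80.0  # nm/px


def _rainbow(gap, seed, shape=(56, 96), snr=10.0, poly=None, chromatic=0.0):
    poly = poly if poly is not None else np.array(
        [[shape[0] / 2.0, 4.0], [shape[0] / 2.0, shape[1] - 4.0]])
    truth = RainbowTruth(gap=gap, polyline=poly, snr=snr,
                         chromatic_shift=chromatic)
    cfg = SimConfig(seed=seed, pixel_size=PX, psf_sigma=PSF_SIGMA,
                    image_shape=shape)
    img, _ = simulate_rainbow(truth, cfg)
    return img, poly


class TestStraighten:
    def test_axis_aligned_boundary_equals_crop(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 5, (2, 40, 60))
        poly = np.array([[20.0, 10.0], [20.0, 50.0]])
        st_b = straighten_boundary(img, poly, normal_halfwidth=5, step=1.0)
        # positions run along the boundary; offsets along the normal (-row)
        crop = img[:, 15:26, 10:51]
        # normal = (-1, 0) for a +col tangent: offset +k maps to row 20-k
        expected = crop[:, ::-1, :].transpose(0, 2, 1)
        assert np.allclose(st_b.data, expected, atol=1e-6)

    def test_arc_length_preserved_for_quarter_circle(self):
        theta = np.linspace(0, np.pi / 2, 200)
        poly = np.column_stack([60 + 50 * np.sin(theta),
                                60 - 50 * np.cos(theta)])
        img = np.zeros((2, 128, 128))
        st_b = straighten_boundary(img, poly, normal_halfwidth=3, step=1.0)
        measured = (st_b.data.shape[1] - 1) * 1.0
        true_len = np.pi / 2 * 50
        assert abs(measured - true_len) / true_len < 0.01

    def test_normals_leaving_image_trimmed(self):
        img = np.zeros((2, 30, 60))
        mid = np.array([[15.0, 5.0], [15.0, 55.0]])
        st_b = straighten_boundary(img, mid, normal_halfwidth=10, step=1.0)
        assert st_b.trimmed_positions == 0
        near_edge = np.array([[2.0, 5.0], [2.0, 55.0]])
        st_b2 = straighten_boundary(img, near_edge, normal_halfwidth=10,
                                    step=1.0)
        assert st_b2.trimmed_positions > 0
        assert st_b2.data.shape[1] == 0

    def test_short_polyline_rejected(self):
        with pytest.raises(InvalidParameterError):
            straighten_boundary(np.zeros((2, 10, 10)), np.array([[1.0, 1.0]]))


class TestMeasureGap:
    def test_identical_channels_give_zero_gap(self):
        img, poly = _rainbow(0.0, seed=1, snr=0.0)
        st_b = straighten_boundary(img, poly, normal_halfwidth=10)
        gap = measure_gap(st_b, PX, PSF_SIGMA)
        assert abs(gap.mean_gap) < 5.0

    @pytest.mark.parametrize("true_gap", [0.0, 50.0, 116.0, 200.0])
    def test_unbiased_across_gap_range(self, true_gap):
        """Injected gaps from 0 to 200 nm at SNR 10 recovered with < 10 nm
        bias (mean over 12 boundaries)."""
        means = []
        for seed in range(12):
            img, poly = _rainbow(true_gap, seed=100 + seed)
            st_b = straighten_boundary(img, poly, normal_halfwidth=10)
            gap = measure_gap(st_b, PX, PSF_SIGMA)
            means.append(gap.mean_gap)
        assert abs(np.nanmean(means) - true_gap) < 10.0

    def test_sd_grows_with_noise(self):
        sds = []
        for snr in (50.0, 10.0, 5.0):
            img, poly = _rainbow(116.0, seed=7, snr=snr)
            st_b = straighten_boundary(img, poly, normal_halfwidth=10)
            sds.append(measure_gap(st_b, PX, PSF_SIGMA).sd_gap)
        assert sds[0] < sds[1] < sds[2]

    def test_curvature_invariance(self):
        """A radius-20 px arc changes the mean gap by < 10 nm vs straight."""
        t = np.linspace(-0.9, 0.9, 60)
        poly_curved = np.column_stack([28 + 20 * (1 - np.cos(t)),
                                       48 + 20 * np.sin(t)])
        img_c, _ = _rainbow(116.0, seed=3, shape=(72, 96), poly=poly_curved)
        st_c = straighten_boundary(img_c, poly_curved, normal_halfwidth=10)
        gap_c = measure_gap(st_c, PX, PSF_SIGMA)
        img_s, poly_s = _rainbow(116.0, seed=3, shape=(72, 96))
        st_s = straighten_boundary(img_s, poly_s, normal_halfwidth=10)
        gap_s = measure_gap(st_s, PX, PSF_SIGMA)
        assert abs(abs(gap_c.mean_gap) - abs(gap_s.mean_gap)) < 10.0

    def test_all_positions_failing_flagged(self):
        img = np.random.default_rng(0).normal(0, 1, (2, 30, 40))
        st_b = straighten_boundary(img, np.array([[15.0, 5.0], [15.0, 35.0]]),
                                   normal_halfwidth=8)
        gap = measure_gap(st_b, PX, PSF_SIGMA)
        assert gap.n_valid < 3
        assert np.isnan(gap.mean_gap) or gap.n_valid < 5


class TestRegisterChannels:
    @staticmethod
    def _beads(seed=0, shift=(0.0, 0.0), n=9):
        rng = np.random.default_rng(seed)
        green = np.zeros((128, 128))
        for r, c in rng.uniform(12, 116, (n, 2)):
            green[int(r), int(c)] = 1000.0
        green = ndimage.gaussian_filter(green, 2.0)
        red = ndimage.shift(green, shift, order=1)
        return green, red

    def test_identical_channels_zero_offset(self):
        g, r = self._beads()
        off, _, _ = register_channels(g, g, PX)
        assert np.abs(off).max() < 0.05

    def test_injected_shift_recovered(self):
        g, r = self._beads(shift=(0.7, 0.0))
        off, off_nm, apply = register_channels(g, r, PX)
        assert abs(off[0] - 0.7) < 0.1
        assert abs(off[1]) < 0.1
        corrected = apply(r)
        off2, _, _ = register_channels(g, corrected, PX)
        assert np.abs(off2).max() < 0.1

    def test_chromatic_shift_removed_gap_retained(self):
        """A 50 nm chromatic confound plus a 116 nm true gap: applying the
        bead-derived correction restores the true gap."""
        img, poly = _rainbow(116.0, seed=5, chromatic=50.0, snr=20.0)
        st_raw = straighten_boundary(img, poly, normal_halfwidth=10)
        raw = measure_gap(st_raw, PX, PSF_SIGMA).mean_gap
        assert raw == pytest.approx(166.0, abs=12.0)
        # beads see the same chromatic shift: red displaced along -row
        # (the normal direction for a +col boundary is (-1, 0))
        g, r = self._beads(seed=2, shift=(-50.0 / PX, 0.0))
        _, _, apply = register_channels(g, r, PX)
        corrected = np.stack([img[0], apply(img[1])])
        st_c = straighten_boundary(corrected, poly, normal_halfwidth=10)
        fixed = measure_gap(st_c, PX, PSF_SIGMA).mean_gap
        assert fixed == pytest.approx(116.0, abs=10.0)

    def test_too_few_beads_rejected(self):
        g, r = self._beads(n=2)
        with pytest.raises(InvalidParameterError):
            register_channels(g, r, PX)


class TestExtendedLength:
    @pytest.mark.parametrize("repeats,expected", [(34, 153.0), (27, 121.5),
                                                  (0, 0.0)])
    def test_cadherin_chain_lengths(self, repeats, expected):
        assert expected_extended_length(repeats) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(InvalidParameterError):
            expected_extended_length(-1)


class TestGradients:
    @staticmethod
    def _two_cell_image(left_fat=200.0, right_fat=100.0, left_ds=100.0,
                        right_ds=200.0, noise=0.0, seed=0):
        img = np.zeros((2, 100, 100))
        img[0, :, :50] = left_fat
        img[0, :, 50:] = right_fat
        img[1, :, :50] = left_ds
        img[1, :, 50:] = right_ds
        if noise:
            img += np.random.default_rng(seed).normal(0, noise, img.shape)
        masks = (np.zeros((100, 100), bool), np.zeros((100, 100), bool))
        masks[0][:, :50] = True
        masks[1][:, 50:] = True
        poly = np.array([[10.0, 50.0], [90.0, 50.0]])
        return img, poly, masks

    def test_equal_cells_zero_gradient(self):
        img, poly, masks = self._two_cell_image(150.0, 150.0, 80.0, 80.0,
                                                noise=2.0)
        cfg = PipelineConfig(pixel_size=400.0)
        rec = measure_gradients(img, poly, masks, config=cfg,
                                pixel_size=400.0)
        assert rec.g_fat == 0 and rec.g_ds == 0

    def test_sign_points_to_brighter_cell(self):
        img, poly, masks = self._two_cell_image(noise=2.0)
        cfg = PipelineConfig(pixel_size=400.0)
        rec = measure_gradients(img, poly, masks, config=cfg,
                                pixel_size=400.0)
        # A -> B normal points from the first mask to the second
        assert rec.g_fat == -1  # Fat brighter on side A
        assert rec.g_ds == 1
        ratio = rec.cyto_fat[0] / rec.cyto_fat[1]
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_bright_vesicle_excluded(self):
        """One 10x-cytoplasm vesicle inside a measurement box changes the
        estimate by < 2%."""
        img, poly, masks = self._two_cell_image(noise=2.0)
        cfg = PipelineConfig(pixel_size=400.0)
        clean = measure_gradients(img, poly, masks, config=cfg,
                                  pixel_size=400.0)
        img2 = img.copy()
        img2[0, 48:50, 40:42] = 2000.0  # vesicle in cell A's box
        with_v = measure_gradients(img2, poly, masks, config=cfg,
                                   pixel_size=400.0)
        assert abs(with_v.cyto_fat[0] / clean.cyto_fat[0] - 1) < 0.02

    def test_nucleus_pixels_excluded(self):
        img, poly, masks = self._two_cell_image()
        nuc = np.zeros((100, 100), bool)
        nuc[46:50, 39:43] = True  # partially overlaps cell A's box
        img[0][nuc] = 0.0  # nucleus is dark in the membrane channel
        cfg = PipelineConfig(pixel_size=400.0)
        rec = measure_gradients(img, poly, masks, nuclei_mask=nuc, config=cfg,
                                pixel_size=400.0)
        rec_no = measure_gradients(img, poly, masks, config=cfg,
                                   pixel_size=400.0)
        # with the mask, the dark nucleus no longer dilutes the estimate
        assert rec.cyto_fat[0] > rec_no.cyto_fat[0]


class TestAlignment:
    RULE = {"p": (-1, 0, 1), "g": (-1, 0, 1)}

    @staticmethod
    def _oracle(p, g_fat, g_ds):
        """Independent truth-table enumeration of the alignment rule."""
        if p == 0:
            return "NP"
        ds_ok = g_ds != 0 and p == g_ds
        fat_ok = g_fat != 0 and p == -g_fat
        if ds_ok and fat_ok:
            return "both"
        if fat_ok:
            return "Fat"
        if ds_ok:
            return "Ds"
        return "NP"

    def test_matches_exhaustive_truth_table(self):
        for p, gf, gd in itertools.product((-1, 0, 1), repeat=3):
            assert classify_alignment(p, gf, gd) == self._oracle(p, gf, gd)

    def test_opposed_gradients_consistent_polarity_is_both(self):
        assert classify_alignment(1, -1, 1) == "both"
        assert classify_alignment(-1, 1, -1) == "both"

    def test_aligned_gradients_split_by_dominance(self):
        assert classify_alignment(1, 1, 1) == "Ds"
        assert classify_alignment(-1, 1, 1) == "Fat"

    @given(st.sampled_from((-1, 0, 1)), st.sampled_from((-1, 0, 1)),
           st.sampled_from((-1, 0, 1)))
    def test_ab_relabeling_invariance(self, p, g_fat, g_ds):
        """Flipping the A/B frame negates every sign but leaves the
        category unchanged."""
        assert classify_alignment(p, g_fat, g_ds) == \
            classify_alignment(-p, -g_fat, -g_ds)

    def test_invalid_sign_rejected(self):
        with pytest.raises(InvalidParameterError):
            classify_alignment(2, 0, 0)


class TestPolarityFromGap:
    @staticmethod
    def _gap_profile(mean, n_valid=20):
        gaps = np.full(n_valid, mean)
        return GapProfile(gaps, gaps, gaps, mean, 5.0, abs(mean), 5.0,
                          n_positions=n_valid, n_valid=n_valid)

    def test_small_gap_is_nonpolarized(self):
        rec = polarity_from_gap(0, self._gap_profile(12.0), 1, 1)
        assert rec.p == 0 and rec.category == "NP"

    def test_clear_gap_sets_sign(self):
        assert polarity_from_gap(0, self._gap_profile(80.0), -1, 1).p == 1
        assert polarity_from_gap(0, self._gap_profile(-80.0), 1, -1).p == -1

    def test_too_few_positions_is_nonpolarized(self):
        rec = polarity_from_gap(0, self._gap_profile(80.0, n_valid=3), -1, 1)
        assert rec.p == 0
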