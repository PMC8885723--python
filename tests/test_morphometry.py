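"""Morphometry pipeline: Wiener preprocessing, four-class segmentation,
selection rules, and the AxDiam/AxDens/ELD summaries."""

import numpy as np
import pytest
from skimage.draw import disk as sk_disk

from tadmri import (
    MicroscopyPhantomSpec,
    compute_morphometry,
    eld,
    extract_axons,
    make_microscopy_phantom,
    preprocess_image,
    segment_tissue,
)

PX = 0.05  # um/px used in the small synthetic tests


class TestPreprocess:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 7.0)
        out = preprocess_image(img, window_um=0.2, pixel_size_um=0.033)
        assert np.allclose(out, 7.0)

    def test_window_under_three_pixels_rejected(self):
        with pytest.raises(ValueError, match="3 pixels"):
            preprocess_image(np.zeros((16, 16)), window_um=0.05,
                             pixel_size_um=0.05)

    def test_mean_preserved(self, rng):
        img = rng.normal(100.0, 20.0, (64, 64))
        out = preprocess_image(img, window_um=0.2, pixel_size_um=0.033)
        assert out.mean() == pytest.approx(img.mean(), rel=1e-3)

    def test_matches_local_statistics_oracle(self, rng):
        """Brute-force windowed mean/variance shrinkage reproduces the
        filter output away from the borders."""
        img = rng.normal(50.0, 10.0, (20, 20))
        win = 3
        out = preprocess_image(img, window_um=3 * PX, pixel_size_um=PX)
        # oracle: local mean/var with uniform window, global noise = mean var
        from scipy.ndimage import uniform_filter

        lm = uniform_filter(img, win)
        lv = uniform_filter(img**2, win) - lm**2
        noise = lv.mean()
        expected = lm + (np.maximum(lv - noise, 0)
                         / np.maximum(lv, noise)) * (img - lm)
        inner = (slice(2, -2), slice(2, -2))
        assert np.allclose(out[inner], expected[inner], rtol=1e-7)


class TestSegmentation:
    def test_exact_four_levels_segmented_pixel_perfect(self):
        img, truth, info = make_microscopy_phantom(MicroscopyPhantomSpec(
            field_size_um=10.0, pixel_size_um=PX, diameter_mean_um=1.0,
            diameter_sd_um=0.1, n_axons=15, seed=3))
        seg = segment_tissue(img, thresholds=(75, 145, 210))
        lvl = MicroscopyPhantomSpec().intensity_levels
        for cls, val in (("myel", lvl["myelin"]), ("ics", lvl["ics"]),
                         ("ecs", lvl["ecs"]), ("other", lvl["other"])):
            assert np.array_equal(seg.masks[cls], img == val)

    def test_fractions_sum_to_one_any_input(self, rng):
        img = rng.integers(0, 255, (40, 40))
        seg = segment_tissue(img, thresholds=(60, 120, 200))
        assert sum(seg.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_known_myelin_fraction_recovered(self):
        img, truth, info = make_microscopy_phantom(MicroscopyPhantomSpec(
            field_size_um=14.0, pixel_size_um=PX, diameter_mean_um=1.2,
            diameter_sd_um=0.15, n_axons=30, seed=11, debris_count=3))
        seg = segment_tissue(img, thresholds="auto")
        assert seg.fractions["myel"] == pytest.approx(
            info["fractions"]["myelin"], abs=0.01)

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            segment_tissue(np.zeros((4, 4)), thresholds=(100, 50, 150))

    def test_empty_class_allowed(self):
        seg = segment_tissue(np.full((8, 8), 250.0), thresholds=(50, 100, 150))
        assert seg.fractions["myel"] == 0.0
        assert seg.fractions["other"] == 1.0


def _disk_mask(radius_px, pad=6):
    n = 2 * int(radius_px) + 2 * pad
    m = np.zeros((n, n), bool)
    rr, cc = sk_disk((n / 2 - 0.5, n / 2 - 0.5), radius_px)
    m[rr, cc] = True
    return m


class TestSelectionRules:
    def test_digitized_disk_kept(self):
        m = _disk_mask(15)
        table, _ = extract_axons(m, np.full(m.shape, 100.0), PX)
        assert len(table) == 1
        assert table.iloc[0]["kept"]
        assert table.iloc[0]["shape_ratio"] == pytest.approx(
            2 * np.sqrt(np.pi), rel=0.03)

    @pytest.mark.parametrize("radius", [5, 15, 50])
    def test_disk_shape_ratio_converges_to_isoperimetric_bound(self, radius):
        m = _disk_mask(radius)
        table, _ = extract_axons(m, np.full(m.shape, 100.0), PX, min_area_px=1)
        ratio = table.iloc[0]["shape_ratio"]
        tol = {5: 0.05, 15: 0.02, 50: 0.005}[radius]
        assert ratio == pytest.approx(2 * np.sqrt(np.pi), rel=tol)

    def test_ten_to_one_bar_rejected_by_shape(self):
        m = np.zeros((30, 130), bool)
        m[10:20, 10:110]= True
        table, _ = extract_axons(m, np.full(m.shape, 100.0), PX)
        assert not table.iloc[0]["kept"]
        assert table.iloc[0]["rejection_reason"] == "shape"

    def test_mottled_object_rejected_by_uniformity(self, rng):
        m = _disk_mask(12)
        intensity = np.full(m.shape, 100.0)
        intensity[m] = rng.normal(100.0, 80.0, m.sum())
        table, _ = extract_axons(m, intensity, PX)
        assert table.iloc[0]["rejection_reason"] == "uniformity"

    def test_speckle_rejected_by_area(self):
        m = np.zeros((20, 20), bool)
        m[9:11, 9:11] = True  # 4 px < 10 px default
        table, _ = extract_axons(m, np.full(m.shape, 100.0), PX)
        assert table.iloc[0]["rejection_reason"] == "area"

    def test_constant_intensity_object_kept(self):
        m = _disk_mask(10)
        table, _ = extract_axons(m, np.full(m.shape, 55.0), PX)
        assert table.iloc[0]["uniformity_ratio"] == 0.0
        assert table.iloc[0]["kept"]

    def test_empty_mask_gives_empty_table(self):
        table, labels = extract_axons(np.zeros((10, 10), bool),
                                      np.zeros((10, 10)), PX)
        assert len(table) == 0

    def test_rules_are_conjunctive(self, rng):
        """An object failing two rules is rejected regardless of order;
        bookkeeping reports a deterministic first reason."""
        m = np.zeros((30, 130), bool)
        m[12:18, 10:110] = True
        intensity = np.full(m.shape, 100.0)
        intensity[m] = rng.normal(100.0, 90.0, m.sum())
        table, _ = extract_axons(m, intensity, PX)
        assert not table.iloc[0]["kept"]
        assert table.iloc[0]["rejection_reason"] in ("shape", "uniformity")


class TestMorphometrySummaries:
    def test_axdens_defining_ratio(self):
        """f_axon = 0.30 at AxDiam 1.0 um gives 0.30/(pi*0.25) per um^2
        = 3.82e5 per mm^2."""
        import pandas as pd

        n = 100
        side_um = 10.0
        area_px = int(round(0.30 * (side_um / PX) ** 2 / n))
        table = pd.DataFrame(dict(
            id=np.arange(1, n + 1),
            area_um2=np.full(n, 0.30 * side_um**2 / n),
            equivalent_diameter_um=np.full(n, 1.0),
            kept=np.full(n, True),
            rejection_reason=np.full(n, "none"),
        ))
        roi = np.ones((int(side_um / PX), int(side_um / PX)), bool)
        labels = np.zeros(roi.shape, int)
        res = compute_morphometry(table, labels, roi, PX,
                                  dilation_radius_um=2.0)
        assert res.ax_diam_um == 1.0
        assert res.sd_ax_diam_um == 0.0
        assert res.f_axon_area == pytest.approx(0.30, rel=1e-6)
        assert res.ax_dens_per_mm2 == pytest.approx(0.30 / (np.pi * 0.25) * 1e6,
                                                    rel=1e-6)

    def test_zero_kept_axons_yields_nan_not_error(self):
        import pandas as pd

        table = pd.DataFrame(columns=["id", "area_um2",
                                      "equivalent_diameter_um", "kept",
                                      "rejection_reason"])
        res = compute_morphometry(table, np.zeros((5, 5), int),
                                  np.ones((5, 5), bool), PX)
        assert res.n_kept == 0
        assert np.isnan(res.ax_diam_um)

    def test_recovery_on_synthetic_micrograph(self):
        """AxDiam within one pixel and AxDens within 5% on a seeded
        phantom (generator ground truth)."""
        spec = MicroscopyPhantomSpec(field_size_um=20.0, pixel_size_um=PX,
                                     diameter_mean_um=1.2, diameter_sd_um=0.2,
                                     n_axons=50, seed=21)
        img, truth, info = make_microscopy_phantom(spec)
        seg = segment_tissue(img, thresholds=(75, 145, 210))
        table, labels = extract_axons(seg.masks["ics"], img, PX)
        roi = np.ones(img.shape, bool)
        res = compute_morphometry(table, labels, roi, PX)
        assert res.n_kept == 50
        assert res.ax_diam_um == pytest.approx(truth["diameter_um"].mean(),
                                               abs=PX)
        true_dens = len(truth) / (info["field_area_mm2"])
        assert res.ax_dens_per_mm2 == pytest.approx(true_dens, rel=0.05)


class TestEld:
    def _morpho(self, layout, seed=31):
        spec = MicroscopyPhantomSpec(field_size_um=20.0, pixel_size_um=PX,
                                     diameter_mean_um=1.0, diameter_sd_um=0.1,
                                     n_axons=40, seed=seed,
                                     free_area_layout=layout)
        img, truth, info = make_microscopy_phantom(spec)
        seg = segment_tissue(img, thresholds=(75, 145, 210))
        table, labels = extract_axons(seg.masks["ics"], img, PX)
        return table, labels, np.ones(img.shape, bool)

    def test_clustered_free_space_raises_eld(self):
        td, ld, roi = self._morpho("dispersed")
        tc, lc, _ = self._morpho("clustered")
        eld_d = eld(td, ld, roi, PX)
        eld_c = eld(tc, lc, roi, PX)
        assert eld_c > eld_d

    def test_two_isolated_axons_exceed_global_density(self):
        m = np.zeros((200, 200), bool)
        rr, cc = sk_disk((20, 20), 8)
        m[rr, cc] = True
        rr, cc = sk_disk((180, 180), 8)
        m[rr, cc] = True
        table, labels = extract_axons(m, np.full(m.shape, 100.0), PX)
        roi = np.ones(m.shape, bool)
        val = eld(table, labels, roi, PX, dilation_radius_um=0.2)
        global_density = 2 / (roi.sum() * PX**2)
        assert val > 10 * global_density

    def test_needs_two_axons(self):
        m = _disk_mask(10)
        table, labels = extract_axons(m, np.full(m.shape, 80.0), PX)
        with pytest.raises(ValueError, match="two"):
            eld(table, labels, np.ones(m.shape, bool), PX)
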