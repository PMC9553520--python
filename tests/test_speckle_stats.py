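import numpy as np
import pytest
from scipy.integrate import quad

from conftest import rayleigh_sample
from helpers import grid_search_sse, rayleigh_pdf_reference

from octspeckle import (
    DegenerateHistogramError,
    IntensityHistogram,
    Region,
    RegionSpeckleModel,
    ROISpec,
    feature_map,
    fit_rayleigh,
    fit_sample,
    generate_region_volume,
    make_histogram,
    pool_roi,
    r_squared,
    rayleigh_pdf,
)


class TestRayleighPDF:
    def test_zero_at_and_below_shift(self):
        assert rayleigh_pdf(-0.2, 1.0, 1.0, -0.2) == 0.0
        assert rayleigh_pdf(-5.0, 1.0, 1.0, -0.2) == 0.0

    def test_mode_value_closed_form(self):
        # at x = c + b the density of the unit-amplitude curve is e^{-1/2}/b
        assert rayleigh_pdf(1.0, 1.0, 1.0, 0.0) == pytest.approx(np.exp(-0.5))

    def test_matches_reference_transcription(self, rng):
        x = rng.uniform(-2, 6, size=200)
        assert np.allclose(
            rayleigh_pdf(x, 1.7, 0.8, -0.3), rayleigh_pdf_reference(x, 1.7, 0.8, -0.3)
        )

    @pytest.mark.parametrize("b", [0.1, 1.0, 10.0])
    def test_unit_amplitude_integrates_to_one(self, b):
        c = -0.2
        val, err = quad(lambda x: rayleigh_pdf(x, 1.0, b, c), c, c + 20 * b)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_nonpositive_scale_raises(self):
        with pytest.raises(ValueError):
            rayleigh_pdf(1.0, 1.0, 0.0, 0.0)


class TestPooling:
    def test_roi_pixel_counts(self, small_phantom):
        vol, _ = small_phantom
        assert pool_roi(vol, ROISpec((0, 0, 0), (6, 6, 10))).size == 6 * 6 * 10 * vol.n_repeat
        assert pool_roi(vol, ROISpec((0, 0, 0), (1, 1, 1), (0, 1))).size == 1
        assert pool_roi(vol, ROISpec((0, 0, 0), (6, 6, 10), (0, 2))).size == 720

    def test_out_of_bounds_roi_raises(self, small_phantom):
        vol, _ = small_phantom
        with pytest.raises(IndexError):
            pool_roi(vol, ROISpec((58, 0, 0), (6, 6, 10)))
        with pytest.raises(IndexError):
            pool_roi(vol, ROISpec((0, 0, 0), (6, 6, 10), (0, 99)))

    def test_pooled_values_are_the_voxels(self):
        model = RegionSpeckleModel(region=Region.AIR, base_scale=1.0)
        vol = generate_region_volume(model, (3, 3, 3, 2), seed=1)
        got = pool_roi(vol, ROISpec((1, 1, 1), (2, 2, 2)))
        expected = vol.intensity[1:3, 1:3, 1:3, :].ravel()
        assert np.array_equal(np.sort(got), np.sort(expected.astype(np.float64)))


class TestHistogram:
    def test_density_normalization(self, rng):
        hist = make_histogram(rayleigh_sample(rng, 8640), n_bins=64)
        assert np.sum(hist.density * np.diff(hist.bin_edges)) == pytest.approx(1.0, abs=1e-9)

    def test_equal_mass_two_bins(self):
        hist = make_histogram([0.0, 1.0, 2.0, 3.0], n_bins=4)
        # four points, four equal-width bins over [0, 3]: one point per bin
        widths = np.diff(hist.bin_edges)
        assert np.allclose(hist.density * widths * 4, 1.0)

    def test_mode_bin_near_c_plus_b(self, rng):
        # the Rayleigh mode sits at x = c + b; locate it with the histogram
        # argmax (n large enough that bin noise cannot displace the peak)
        b, c = 1.0, -0.2
        hist = make_histogram(rayleigh_sample(rng, 200_000, b=b, c=c), n_bins=64)
        mode_center = hist.bin_centers[np.argmax(hist.density)]
        assert abs(mode_center - (c + b)) < hist.bin_width

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DegenerateHistogramError):
            make_histogram(np.full(100, 3.0))
        with pytest.raises(ValueError):
            make_histogram([], n_bins=8)
        with pytest.raises(ValueError):
            make_histogram([1.0, 2.0], n_bins=2)


def _exact_model_histogram(a, b, c, lo, hi, n_bins=64):
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return IntensityHistogram(
        bin_edges=edges,
        density=rayleigh_pdf(centers, a, b, c),
        n_pixels=8640,
        raw_min=lo,
        raw_max=hi,
    )


class TestFit:
    def test_noiseless_self_consistency(self):
        a, b, c = 1.2, 0.8, -0.2
        hist = _exact_model_histogram(a, b, c, lo=-0.19, hi=3.5)
        fit = fit_rayleigh(hist)
        assert fit.converged
        assert fit.a == pytest.approx(a, abs=1e-6)
        assert fit.b == pytest.approx(b, abs=1e-6)
        assert fit.c == pytest.approx(c, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_generating_parameter_recovery(self):
        b, c = 0.5, -0.2
        ok_b, ok_r2 = 0, 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            fit = fit_sample(rayleigh_sample(rng, 8640, b=b, c=c), n_bins=64)
            ok_b += abs(fit.b - b) / b < 0.03
            ok_r2 += fit.r_squared > 0.98
        assert ok_b >= 45
        assert ok_r2 >= 45

    def test_shift_equivariance(self, rng):
        sample = rayleigh_sample(rng, 8640, b=0.7, c=-0.1)
        delta = 3.25
        f0 = fit_sample(sample)
        f1 = fit_sample(sample + delta)
        assert f1.c == pytest.approx(f0.c + delta, abs=1e-6)
        assert f1.a == pytest.approx(f0.a, rel=1e-6)
        assert f1.b == pytest.approx(f0.b, rel=1e-6)
        assert f1.r_squared == pytest.approx(f0.r_squared, abs=1e-9)

    def test_scale_equivariance(self, rng):
        sample = rayleigh_sample(rng, 8640, b=0.7, c=-0.1)
        s = 2.5
        f0 = fit_sample(sample)
        f1 = fit_sample(s * sample)
        assert f1.b == pytest.approx(s * f0.b, rel=1e-6)
        assert f1.c == pytest.approx(s * f0.c, rel=1e-5, abs=1e-6)
        assert f1.r_squared == pytest.approx(f0.r_squared, abs=1e-9)

    def test_optimizer_never_loses_to_grid_search(self):
        """Brute-force oracle: exhaustive SSE over a grid bracketing the
        optimizer's solution never undercuts the optimizer."""
        for seed in range(20):
            rng = np.random.default_rng(seed + 200)
            b = rng.uniform(0.3, 3.0)
            c = rng.uniform(-1.0, 1.0)
            purity = rng.uniform(0.5, 1.0)
            n = 4000
            x = rayleigh_sample(rng, n, b=b, c=c)
            contaminate = rng.random(n) > purity
            x = np.where(contaminate, c + 1.8 * (x - c), x)
            hist = make_histogram(x, n_bins=48)
            fit = fit_rayleigh(hist)
            grid_sse = grid_search_sse(
                hist.bin_centers,
                hist.density,
                a_grid=np.linspace(0.7 * fit.a, 1.3 * fit.a, 40),
                b_grid=np.linspace(0.7 * fit.b, 1.3 * fit.b, 40),
                c_grid=np.linspace(
                    fit.c - 0.3 * fit.b, min(fit.c + 0.3 * fit.b, hist.raw_min), 40
                ),
            )
            assert fit.sse <= grid_sse + 1e-8

    def test_too_few_occupied_bins_raises(self):
        hist = make_histogram([0.0, 0.0, 0.0, 1.0] * 10, n_bins=8)
        with pytest.raises(DegenerateHistogramError):
            fit_rayleigh(hist)


class TestRSquared:
    def test_matches_manual_formula_and_fit_field(self, rng):
        hist = make_histogram(rayleigh_sample(rng, 8640), n_bins=64)
        fit = fit_rayleigh(hist)
        model = rayleigh_pdf(hist.bin_centers, fit.a, fit.b, fit.c)
        manual = 1.0 - np.sum((hist.density - model) ** 2) / np.sum(
            (hist.density - hist.density.mean()) ** 2
        )
        assert r_squared(hist, fit) == pytest.approx(manual, abs=1e-12)
        assert r_squared(hist, fit) == pytest.approx(fit.r_squared, abs=1e-9)

    def test_perfect_model_scores_one(self):
        hist = _exact_model_histogram(1.0, 1.0, 0.0, lo=0.01, hi=5.0)
        fit = fit_rayleigh(hist)
        assert r_squared(hist, fit) == pytest.approx(1.0, abs=1e-9)

    def test_flat_histogram_raises(self):
        hist = IntensityHistogram(
            bin_edges=np.linspace(0, 1, 9),
            density=np.ones(8),
            n_pixels=8,
            raw_min=0.0,
            raw_max=1.0,
        )
        from octspeckle import RayleighFit

        fit = RayleighFit(1, 1, 0, 0, 0, True, 8, 8)
        with pytest.raises(DegenerateHistogramError):
            r_squared(hist, fit)


class TestFeatureMap:
    def test_stride_equal_to_extent_gives_single_center(self):
        model = RegionSpeckleModel(region=Region.NOISE, base_scale=1.0)
        vol = generate_region_volume(model, (6, 6, 10, 24), seed=0)
        maps = feature_map(vol, window=(6, 6, 10), stride=(6, 6, 10))
        assert maps.mask.sum() == 1
        assert maps.mask[3, 3, 5]
        assert np.isfinite(maps.r_squared[3, 3, 5])

    def test_single_region_maps_are_near_constant(self):
        model = RegionSpeckleModel(region=Region.NOISE, base_scale=1.0, shift=-0.2)
        vol = generate_region_volume(model, (14, 14, 20, 24), seed=1)
        maps = feature_map(vol, window=(6, 6, 10), stride=(2, 2, 2))
        a_vals = maps.a_coeff[maps.mask]
        assert a_vals.size > 20
        assert np.std(a_vals) / np.mean(a_vals) < 0.2

    def test_window_larger_than_volume_raises(self):
        model = RegionSpeckleModel(region=Region.NOISE, base_scale=1.0)
        vol = generate_region_volume(model, (4, 4, 4, 2), seed=0)
        with pytest.raises(ValueError):
            feature_map(vol, window=(6, 6, 10))

    def test_r2_threshold_separates_noise_from_intralipid(self, paper_config):
        """Half noise / half Intralipid volume: thresholding the R^2 map at
        0.95 labels >= 90% of evaluated windows correctly."""
        noise = paper_config.region_models[Region.NOISE]
        il = paper_config.region_models[Region.INTRALIPID]
        top = generate_region_volume(noise, (18, 12, 12, 24), seed=2)
        bottom = generate_region_volume(il, (18, 12, 12, 24), seed=3)
        intensity = np.concatenate([top.intensity, bottom.intensity], axis=0)
        from octspeckle import OCTVolume

        vol = OCTVolume(intensity=intensity, voxel_pitch=top.voxel_pitch)
        maps = feature_map(vol, window=(6, 6, 10), stride=(2, 2, 2))
        cz, cx, cy = np.nonzero(maps.mask)
        predicted_noise = maps.r_squared[cz, cx, cy] > 0.95
        truly_noise = cz < 18
        assert np.mean(predicted_noise == truly_noise) >= 0.90
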