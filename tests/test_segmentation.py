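"""Background separation: fused index map, Otsu, bimodality, repeats."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from lymphspec.hypercube import Hypercube
from lymphspec.indices import index_image
from lymphspec.roi import central_roi_mask
from lymphspec.segmentation import (
    BodyMask,
    body_mask,
    fused_index_image,
    is_bimodal,
    otsu_threshold,
    select_best_repeat,
)
from lymphspec.synthetic import (
    SceneGeometry,
    background_spectral_model,
    body_spectral_model,
    simulate_hypercube,
    spectrum_values,
)


def brute_force_otsu(values, bins=256, value_range=(0.0, 2.0)):
    """Independent maximizer of between-class variance over histogram cuts.

    Evaluates every candidate cut directly from the raw values; ties
    (cuts through empty valleys) resolve to the plateau midpoint, as any
    of them separates the classes identically.
    """
    values = np.asarray(values, dtype=float).ravel()
    edges = np.histogram_bin_edges(values, bins=bins, range=value_range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # quantize to bin centers exactly like a histogram-based method
    which = np.clip(np.digitize(values, edges[1:-1]), 0, bins - 1)
    quantized = centers[which]
    best_val, best_cuts = -np.inf, []
    for cut in range(bins - 1):
        thr = edges[cut + 1]
        left = quantized[quantized < thr - 1e-12]
        right = quantized[quantized >= thr - 1e-12]
        if len(left) == 0 or len(right) == 0:
            continue
        w0, w1 = len(left), len(right)
        var = w0 * w1 * (left.mean() - right.mean()) ** 2
        # exact ties arise only from cuts through empty bins (identical
        # class partitions), so exact comparison is the right tie rule
        if var > best_val:
            best_val, best_cuts = var, [cut]
        elif var == best_val:
            best_cuts.append(cut)
    mid = int(round(np.mean(best_cuts)))
    return float(edges[mid + 1])


class TestOtsu:
    def test_separable_classes(self):
        thr = otsu_threshold(np.array([0.0, 0.0, 0.0, 2.0, 2.0, 2.0]))
        assert 0.0 < thr < 2.0

    def test_bimodal_mixture_threshold_in_valley(self, rng):
        values = np.concatenate(
            [rng.normal(0.4, 0.1, 500), rng.normal(1.6, 0.1, 500)]
        ).clip(0, 2)
        assert 0.8 < otsu_threshold(values) < 1.2

    def test_matches_brute_force_on_random_draws(self, rng):
        values = rng.uniform(0, 2, size=1000)
        assert otsu_threshold(values) == pytest.approx(brute_force_otsu(values))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full(50, 1.0))


class TestBimodality:
    def test_single_gaussian_is_unimodal(self, rng):
        assert not is_bimodal(rng.normal(1.0, 0.15, 2000).clip(0, 2))

    def test_separated_mixture_is_bimodal(self, rng):
        values = np.concatenate([rng.normal(0.4, 0.1, 1000), rng.normal(1.6, 0.1, 1000)])
        assert is_bimodal(values.clip(0, 2))

    def test_single_crossover_in_separation_sweep(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0.0, 0.1, 1500)
        flags = []
        for sep in np.linspace(1.2, 0.0, 13):
            values = np.concatenate([base + 0.4, base[:750] + 0.4 + sep])
            flags.append(is_bimodal(values))
        # bimodal at wide separation, unimodal at none, single flip
        assert flags[0] and not flags[-1]
        assert sum(1 for a, b in zip(flags, flags[1:]) if a != b) == 1

    def test_tiny_or_constant_input_is_false(self):
        assert not is_bimodal(np.array([1.0] * 50))
        assert not is_bimodal(np.array([0.1, 1.9]))


class TestFusedIndexImage:
    def test_spatially_constant_body_cube_gives_two(self, grid, body_spectrum):
        cube = Hypercube(
            np.broadcast_to(body_spectrum.values, (16, 16, 100)).astype(np.float32),
            grid,
        )
        fused = fused_index_image(cube)
        assert np.allclose(fused, 2.0)

    def test_bounded_by_two_on_random_scene(self, grid, rng):
        data = (rng.random((12, 12, 100)) * 0.5 + 0.05).astype(np.float32)
        fused = fused_index_image(Hypercube(data, grid))
        assert fused.min() >= 0.0 and fused.max() <= 2.0 + 1e-9

    def test_composition_of_documented_steps(self, noiseless_scene):
        cube, _ = noiseless_scene
        expected = np.zeros(cube.spatial_shape)
        for name in ("TWI", "STO2"):
            img = np.nan_to_num(index_image(cube, name, scaled=True), nan=0.0)
            img = gaussian_filter(img, sigma=1.0, truncate=2.0)
            expected += img / img.max()
        np.testing.assert_allclose(fused_index_image(cube), expected, rtol=1e-12)


class TestBodyMask:
    def test_noiseless_scene_recovered(self, noiseless_scene):
        cube, truth = noiseless_scene
        bm = body_mask(cube)
        assert bm.method == "otsu"
        recall = (bm.mask & truth).sum() / truth.sum()
        precision = (bm.mask & truth).sum() / bm.mask.sum()
        assert recall >= 0.99 and precision >= 0.99

    def test_intensity_rescaling_invariance(self, noiseless_scene):
        cube, _ = noiseless_scene
        bright = Hypercube(cube.data * 2.5, cube.grid)
        np.testing.assert_array_equal(body_mask(bright).mask, body_mask(cube).mask)

    def test_no_body_frame_takes_fixed_path(self, grid):
        rng = np.random.default_rng(3)
        cube, _ = simulate_hypercube(
            SceneGeometry(shape=(32, 32), axes=(1e-6, 1e-6)),
            body_spectral_model(),
            background_spectral_model(noise_sd=0.002),
            rng,
            grid,
        )
        bm = body_mask(cube)
        assert bm.method == "fixed" and bm.threshold == 1.0

    def test_full_frame_body_takes_fixed_path(self, grid):
        rng = np.random.default_rng(4)
        cube, truth = simulate_hypercube(
            SceneGeometry(shape=(32, 32), axes=(200.0, 200.0)),
            body_spectral_model(),
            background_spectral_model(),
            rng,
            grid,
        )
        assert truth.all()
        bm = body_mask(cube)  # must not error; histogram is unimodal
        assert bm.method == "fixed"

    def test_degrades_gracefully_with_noise(self, grid):
        ious = []
        for noise in (0.0, 0.01, 0.05):
            rng = np.random.default_rng(11)
            cube, truth = simulate_hypercube(
                SceneGeometry(shape=(48, 64)),
                body_spectral_model(noise_sd=noise),
                background_spectral_model(noise_sd=noise),
                rng,
                grid,
            )
            bm = body_mask(cube)
            ious.append((bm.mask & truth).sum() / (bm.mask | truth).sum())
        assert ious[0] >= 0.99
        assert ious[0] >= ious[1] >= ious[2] - 0.02  # monotone within jitter

    def test_otsu_iff_bimodal(self, noiseless_scene):
        cube, _ = noiseless_scene
        bm = body_mask(cube)
        assert bm.method == ("otsu" if is_bimodal(fused_index_image(cube)) else "fixed")


class TestRepeatSelection:
    def _mask(self, coverage, region):
        m = np.zeros(region.shape, dtype=bool)
        idx = np.flatnonzero(region)
        m.flat[idx[: int(round(coverage * idx.size))]] = True
        return BodyMask(mask=m, threshold=1.0, method="fixed")

    def test_picks_maximal_coverage(self):
        region = central_roi_mask((48, 64), 10)
        masks = [self._mask(c, region) for c in (0.20, 0.90, 0.50)]
        assert select_best_repeat(masks, region) == 1

    def test_tie_breaks_to_first(self):
        region = central_roi_mask((48, 64), 10)
        masks = [self._mask(0.5, region) for _ in range(3)]
        assert select_best_repeat(masks, region) == 0

    def test_jittered_triplicates_pick_best_centered(self, grid):
        rng = np.random.default_rng(5)
        region = central_roi_mask((48, 64), 10)
        cubes, truths = [], []
        for offset in (18.0, 0.0, 9.0):  # repeat 1 is perfectly centered
            cube, truth = simulate_hypercube(
                SceneGeometry(shape=(48, 64), center=(23.5 + offset, 31.5)),
                body_spectral_model(),
                background_spectral_model(),
                rng,
                grid,
            )
            cubes.append(cube)
            truths.append(truth)
        masks = [body_mask(c, central_region=region) for c in cubes]
        best = select_best_repeat(masks, region)
        true_cov = [t[region].mean() for t in truths]
        assert best == int(np.argmax(true_cov)) == 1

    def test_shape_mismatch_rejected(self):
        region = central_roi_mask((48, 64), 10)
        good = self._mask(0.5, region)
        bad = BodyMask(mask=np.zeros((10, 10), dtype=bool), threshold=1.0, method="fixed")
        with pytest.raises(ValueError):
            select_best_repeat([good, bad, good], region)
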