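import numpy as np
import pytest

from junctension import (
    ANTERIOR,
    EXCLUDED,
    POSTERIOR,
    DiscAnnotation,
    DiscImage,
    HeatMap,
    JunctionMask,
    average_discs,
    block_quantify,
    build_mask,
    normalize,
    pa_ratio,
    split_compartments,
)
from junctension.synthetic import SynthDiscParams, generate_disc


def _image(arr, pixel_size_um=1.0):
    return DiscImage(channels={"ecad": arr}, pixel_size_um=pixel_size_um,
                     roles={"ecad": "reference"})


def _full_mask(shape):
    return JunctionMask(np.ones(shape, bool), "fixed", 0.0)


def oracle_block_means(arr, mask, center, block_px):
    """Naive per-pixel double loop over the floored block lattice."""
    h, w = arr.shape

    def edges(c, size):
        ks = range(-int(np.floor(c / block_px)) - 1,
                   int(np.floor((size - c) / block_px)) + 2)
        e = sorted({int(np.floor(c + k * block_px)) for k in ks
                    if 0 <= np.floor(c + k * block_px) <= size})
        return e

    re_, ce_ = edges(center[0], h), edges(center[1], w)
    sums = np.zeros((len(re_) - 1, len(ce_) - 1))
    counts = np.zeros_like(sums, dtype=int)
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            bi = bj = None
            for b in range(len(re_) - 1):
                if re_[b] <= i < re_[b + 1]:
                    bi = b
            for b in range(len(ce_) - 1):
                if ce_[b] <= j < ce_[b + 1]:
                    bj = b
            if bi is None or bj is None:
                continue
            sums[bi, bj] += arr[i, j]
            counts[bi, bj] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


class TestBlockQuantify:
    def test_uniform_channel(self):
        img = _image(np.full((12, 12), 3.7))
        ann = DiscAnnotation(center_px=(6, 6), block_size_um=3.0)
        hm = block_quantify(img, _full_mask((12, 12)), ann, "ecad")
        np.testing.assert_allclose(hm.values, 3.7)

    def test_hand_written_6x6(self):
        arr = np.arange(36, dtype=float).reshape(6, 6)
        img = _image(arr)
        ann = DiscAnnotation(center_px=(3, 3), block_size_um=3.0)
        hm = block_quantify(img, _full_mask((6, 6)), ann, "ecad")
        # explicit per-pixel loop over the four 3x3 blocks
        expected = np.array([
            [arr[0:3, 0:3].mean(), arr[0:3, 3:6].mean()],
            [arr[3:6, 0:3].mean(), arr[3:6, 3:6].mean()],
        ])
        np.testing.assert_allclose(hm.values, expected)
        assert hm.center_index == (0, 0)
        np.testing.assert_array_equal(hm.counts, 9)

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.random((64, 64)) * 100
        mask = rng.random((64, 64)) < 0.4
        center = tuple(rng.integers(10, 54, size=2))
        block_px = float(rng.choice([3.0, 4.5, 6.0]))
        img = _image(arr)
        hm = block_quantify(img, JunctionMask(mask, "fixed", 0.0),
                            DiscAnnotation(center_px=center, block_size_um=block_px),
                            "ecad")
        means, counts = oracle_block_means(arr, mask, center, block_px)
        np.testing.assert_allclose(hm.values, means, atol=1e-12, equal_nan=True)
        np.testing.assert_array_equal(hm.counts, counts)

    def test_empty_blocks_missing_not_zero(self):
        mask = np.zeros((12, 12), bool)
        mask[:6, :6] = True
        img = _image(np.full((12, 12), 5.0))
        ann = DiscAnnotation(center_px=(6, 6), block_size_um=3.0)
        hm = block_quantify(img, JunctionMask(mask, "fixed", 0.0), ann, "ecad")
        assert np.isnan(hm.values[hm.counts == 0]).all()
        assert (hm.counts == 0).any()

    def test_physical_block_size_conversion(self):
        # 3 um blocks at 0.5 um/px -> 6 px blocks
        img = _image(np.zeros((24, 24)) + 1.0, pixel_size_um=0.5)
        ann = DiscAnnotation(center_px=(12, 12), block_size_um=3.0)
        hm = block_quantify(img, _full_mask((24, 24)), ann, "ecad")
        assert hm.shape == (4, 4)
        np.testing.assert_array_equal(hm.counts, 36)

    def test_partial_edge_blocks_dropped(self):
        img = _image(np.ones((10, 10)))
        ann = DiscAnnotation(center_px=(5, 5), block_size_um=3.0)
        hm = block_quantify(img, _full_mask((10, 10)), ann, "ecad")
        # edges at 2,5,8 -> 2 full blocks per axis; 0..2 and 8..10 dropped? no:
        # floor(5+k*3) in [0,10] -> 2,5,8 plus k=-2 gives -1 (out), k=+2 gives 11 (out)
        assert hm.shape == (2, 2)
        np.testing.assert_array_equal(hm.counts, 9)

    def test_block_smaller_than_pixel_errors(self):
        img = _image(np.ones((10, 10)), pixel_size_um=2.0)
        ann = DiscAnnotation(center_px=(5, 5), block_size_um=1.0)
        with pytest.raises(ValueError, match="smaller than one pixel"):
            block_quantify(img, _full_mask((10, 10)), ann, "ecad")

    def test_center_outside_errors(self):
        img = _image(np.ones((10, 10)))
        ann = DiscAnnotation(center_px=(50, 5), block_size_um=3.0)
        with pytest.raises(ValueError, match="outside image"):
            block_quantify(img, _full_mask((10, 10)), ann, "ecad")


def _toy_map(values, counts=None, **kw):
    values = np.asarray(values, dtype=float)
    if counts is None:
        counts = np.where(np.isnan(values), 0, 1)
    kw.setdefault("center_index", (0, 0))
    kw.setdefault("block_size_um", 3.0)
    return HeatMap(values=values, counts=counts, **kw)


class TestNormalize:
    def test_signal_equals_reference(self):
        sig = _toy_map([[2.0, 4.0], [6.0, 8.0]])
        out = normalize(sig, sig, mode="ratio_to_reference")
        np.testing.assert_allclose(out.values, 1.0)

    def test_hand_computed_two_step(self):
        sig = _toy_map([[2.0, 4.0], [6.0, 8.0]])
        ref = _toy_map([[1.0, 1.0], [1.0, 1.0]])
        out = normalize(sig, ref, mode="ratio_to_reference")
        # arithmetic oracle: sig/mean(sig)=v/5; ref/mean(ref)=1
        np.testing.assert_allclose(out.values, np.array([[0.4, 0.8], [1.2, 1.6]]))

    def test_self_mean_unit_mean(self, rng):
        vals = rng.random((5, 5)) + 0.5
        vals[0, 0] = np.nan
        sig = _toy_map(vals)
        out = normalize(sig, sig, mode="self_mean")
        assert np.nanmean(out.values) == pytest.approx(1.0, abs=1e-10)

    def test_scale_invariance(self, rng):
        vals = rng.random((4, 4)) + 0.5
        ref_vals = rng.random((4, 4)) + 0.5
        out1 = normalize(_toy_map(vals), _toy_map(ref_vals))
        out2 = normalize(_toy_map(vals * 7.3), _toy_map(ref_vals))
        np.testing.assert_allclose(out1.values, out2.values, atol=1e-12)

    def test_zero_reference_block_dropped(self):
        sig = _toy_map([[2.0, 4.0], [6.0, 8.0]])
        ref = _toy_map([[1.0, 0.0], [1.0, 1.0]])
        out = normalize(sig, ref)
        assert np.isnan(out.values[0, 1])
        assert np.isfinite(out.values[1, 1])

    def test_missing_propagates(self):
        sig = _toy_map([[np.nan, 4.0], [6.0, 8.0]])
        ref = _toy_map([[1.0, 1.0], [1.0, 1.0]])
        out = normalize(sig, ref)
        assert np.isnan(out.values[0, 0])

    def test_grid_mismatch_errors(self):
        a = _toy_map(np.ones((2, 2)))
        b = _toy_map(np.ones((3, 3)))
        with pytest.raises(ValueError, match="grid"):
            normalize(a, b)


class TestAverageDiscs:
    def test_three_identical_maps(self, rng):
        vals = rng.random((4, 4))
        maps = [_toy_map(vals.copy()) for _ in range(3)]
        out = average_discs(maps, min_count=3)
        np.testing.assert_allclose(out.values, vals)
        np.testing.assert_array_equal(out.counts, 3)

    def test_single_map_identity(self, rng):
        vals = rng.random((4, 5))
        vals[1, 2] = np.nan
        hm = _toy_map(vals, center_index=(2, 2))
        out = average_discs([hm], min_count=1)
        np.testing.assert_allclose(out.values, vals, equal_nan=True)
        assert out.center_index == (2, 2)

    def test_staggered_extents_min_count(self):
        # manual alignment oracle: big map 3x3 center (1,1); small 2x2 center (0,0)
        big = _toy_map(np.full((3, 3), 2.0), center_index=(1, 1))
        small = _toy_map(np.full((2, 2), 4.0), center_index=(0, 0))
        out = average_discs([big, small], min_count=2)
        assert out.shape == (3, 3)
        assert out.center_index == (1, 1)
        # overlap: small occupies rows 1-2, cols 1-2 of the big frame
        expected = np.full((3, 3), np.nan)
        expected[1:, 1:] = 3.0
        np.testing.assert_allclose(out.values, expected, equal_nan=True)
        np.testing.assert_array_equal(out.counts[1:, 1:], 2)
        assert (out.counts[0, :] == 0).all()

    def test_min_count_blocks_below_threshold_missing(self):
        maps = [
            _toy_map(np.full((2, 2), 1.0), center_index=(0, 0)),
            _toy_map(np.full((2, 2), 2.0), center_index=(0, 0)),
            _toy_map(np.full((3, 3), 3.0), center_index=(1, 1)),
        ]
        out = average_discs(maps, min_count=3)
        assert (out.counts[out.counts > 0] >= 3).all()
        assert np.isnan(out.values[out.counts < 3]).all()

    def test_empty_list_errors(self):
        with pytest.raises(ValueError, match="no heat maps"):
            average_discs([], min_count=3)

    def test_inconsistent_normalization_errors(self):
        a = _toy_map(np.ones((2, 2)), normalization="self_mean")
        b = _toy_map(np.ones((2, 2)), normalization="ratio_to_reference")
        with pytest.raises(ValueError, match="normalization"):
            average_discs([a, b])


class TestSplitCompartments:
    def test_four_column_enumeration(self):
        hm = _toy_map(np.ones((1, 4)), center_index=(0, 1))
        ann = DiscAnnotation(center_px=(5, 5), posterior_side="right")
        split = split_compartments(hm, ann)
        # enumerate blocks: col 0 anterior, col 1 excluded, cols 2-3 posterior
        np.testing.assert_array_equal(
            split.labels[0], [ANTERIOR, EXCLUDED, POSTERIOR, POSTERIOR]
        )

    @pytest.mark.parametrize("side,axis", [("left", 1), ("up", 0)])
    def test_mirrored_sides(self, side, axis):
        hm = _toy_map(np.ones((4, 4)), center_index=(1, 1))
        ann = DiscAnnotation(center_px=(5, 5), posterior_side=side)
        split = split_compartments(hm, ann)
        if axis == 1:
            assert (split.labels[:, 0] == POSTERIOR).all()
            assert (split.labels[:, 2:] == ANTERIOR).all()
        else:
            assert (split.labels[0, :] == POSTERIOR).all()
            assert (split.labels[2:, :] == ANTERIOR).all()

    def test_marker_matches_geometric(self, noiseless_disc, noiseless_annotation,
                                      noiseless_mask):
        hm = block_quantify(noiseless_disc.image, noiseless_mask,
                            noiseless_annotation, "signal")
        geo = split_compartments(hm, noiseless_annotation)
        mark = split_compartments(hm, noiseless_annotation,
                                  compartment_map=noiseless_disc.compartment_map,
                                  mask=noiseless_mask)
        np.testing.assert_array_equal(geo.labels, mark.labels)

    def test_all_posterior_marker_degenerate(self, noiseless_disc,
                                             noiseless_annotation, noiseless_mask):
        hm = block_quantify(noiseless_disc.image, noiseless_mask,
                            noiseless_annotation, "signal")
        split = split_compartments(hm, noiseless_annotation,
                                   compartment_map=np.ones(noiseless_disc.image.shape),
                                   mask=noiseless_mask)
        with pytest.raises(ValueError):
            pa_ratio(hm, split)


class TestPARatio:
    def test_symmetric_map(self):
        hm = _toy_map(np.ones((3, 5)), center_index=(1, 2))
        ann = DiscAnnotation(center_px=(5, 5), posterior_side="right")
        ratio = pa_ratio(hm, split_compartments(hm, ann))
        assert ratio.value == pytest.approx(1.0)

    def test_noiseless_disc_recovers_multiplier(self, noiseless_disc,
                                                noiseless_annotation, noiseless_mask):
        img = noiseless_disc.image
        hs = block_quantify(img, noiseless_mask, noiseless_annotation, "signal")
        hr = block_quantify(img, noiseless_mask, noiseless_annotation, "ecad")
        hm = normalize(hs, hr, mode="ratio_to_reference")
        split = split_compartments(hm, noiseless_annotation)
        ratio = pa_ratio(hm, split)
        assert ratio.value == pytest.approx(1.5, abs=1e-6)

    def test_noisy_cohort_within_band(self):
        ratios = []
        for seed in range(6):
            params = SynthDiscParams(posterior_multiplier=1.5, noise_sd_frac=0.1,
                                     seed=100 + seed)
            disc = generate_disc(params)
            ann = DiscAnnotation(center_px=disc.center_px,
                                 posterior_side=disc.posterior_axis)
            mask = build_mask(disc.image)
            hs = block_quantify(disc.image, mask, ann, "signal")
            hr = block_quantify(disc.image, mask, ann, "ecad")
            hm = normalize(hs, hr)
            ratios.append(pa_ratio(hm, split_compartments(hm, ann)).value)
        assert 1.4 <= np.mean(ratios) <= 1.6

    def test_empty_compartment_errors(self):
        vals = np.ones((1, 4))
        vals[0, 2:] = np.nan
        hm = _toy_map(vals, center_index=(0, 1))
        ann = DiscAnnotation(center_px=(5, 5), posterior_side="right")
        with pytest.raises(ValueError, match="no non-missing"):
            pa_ratio(hm, split_compartments(hm, ann))


class TestParameterRecovery:
    """Seeded cohorts recover the posterior multiplier within 7%."""

    @pytest.mark.parametrize("multiplier", [0.8, 1.0, 1.25, 1.5])
    def test_multiplier_recovery(self, multiplier):
        cohort_means = []
        for cohort in range(5):
            ratios = []
            for d in range(6):
                params = SynthDiscParams(
                    posterior_multiplier=multiplier, noise_sd_frac=0.1,
                    seed=1000 * cohort + 17 * d + int(multiplier * 100),
                    image_size_px=(120, 120), n_cells=30,
                )
                disc = generate_disc(params)
                ann = DiscAnnotation(center_px=disc.center_px,
                                     posterior_side=disc.posterior_axis)
                mask = build_mask(disc.image)
                hm = normalize(
                    block_quantify(disc.image, mask, ann, "signal"),
                    block_quantify(disc.image, mask, ann, "ecad"),
                )
                ratios.append(pa_ratio(hm, split_compartments(hm, ann)).value)
            cohort_means.append(np.mean(ratios))
        assert abs(np.mean(cohort_means) - multiplier) / multiplier < 0.07
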