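import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glomquant.errors import (
    DegenerateHistogramError,
    EmptyRegionError,
    UndefinedIndexError,
    ZeroReferenceVolumeError,
)
from glomquant.quant import (
    QuantConfig,
    call_phenotype,
    gaussian_blur,
    mean_density,
    mistargeting_ratio,
    otsu_threshold,
    preference_index,
    quantify_sample,
    segment_targeting,
)
from glomquant.synthetic import SimTruth, simulate_sample
from glomquant.types import GlomerulusAtlas, MistargetRecord, TargetingMask, VoxelStack


def brute_force_otsu(data, nbins=256):
    """Independent oracle: exhaustive scan of every histogram split."""
    lo, hi = float(data.min()), float(data.max())
    counts, edges = np.histogram(data.ravel(), bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    n = counts.sum()
    best_t, best_var = None, -1.0
    for t in range(nbins):
        w0 = counts[: t + 1].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: t + 1] * centers[: t + 1]).sum() / w0
        mu1 = (counts[t + 1 :] * centers[t + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:  # strict: keeps the lowest qualifying threshold
            best_var, best_t = var, t
    return centers[best_t]


class TestGaussianBlur:
    def test_constant_stack_unchanged(self):
        stack = VoxelStack(np.full((4, 16, 16), 3.7))
        out = gaussian_blur(stack, radius=1.0)
        np.testing.assert_allclose(out.data, 3.7, rtol=1e-9)

    def test_impulse_matches_direct_kernel_convolution(self):
        # oracle: explicit normalized 2D Gaussian kernel with the same support
        from glomquant.quant import GAUSSIAN_TRUNCATE

        sigma = 1.0
        stack = np.zeros((3, 33, 33))
        stack[1, 16, 16] = 1.0
        out = gaussian_blur(VoxelStack(stack), radius=sigma).data

        r = int(GAUSSIAN_TRUNCATE * sigma + 0.5)
        ax = np.arange(-r, r + 1)
        k1 = np.exp(-(ax**2) / (2 * sigma**2))
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        expected = np.zeros((33, 33))
        expected[16 - r : 16 + r + 1, 16 - r : 16 + r + 1] = kernel
        np.testing.assert_allclose(out[1], expected, atol=1e-9)
        assert out[1].sum() == pytest.approx(1.0, abs=1e-6)
        assert out[0].sum() == 0.0  # per-slice: no z mixing

    def test_semigroup_property(self, rng):
        # discrete sampled kernels compose exactly only in the continuum
        # limit; at sigma=1 the aliasing floor is ~3e-5 relative, gone by
        # sigma=1.5, so the tight bound is asserted there
        stack = VoxelStack(rng.random((2, 60, 60)) * 100)
        interior = (slice(None), slice(20, 40), slice(20, 40))

        twice = gaussian_blur(gaussian_blur(stack, 1.5), 1.5)
        once = gaussian_blur(stack, 1.5 * np.sqrt(2.0))
        np.testing.assert_allclose(twice.data[interior], once.data[interior], atol=1e-6)

        twice1 = gaussian_blur(gaussian_blur(stack, 1.0), 1.0)
        once1 = gaussian_blur(stack, np.sqrt(2.0))
        np.testing.assert_allclose(
            twice1.data[interior], once1.data[interior], rtol=5e-4, atol=5e-3
        )

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            gaussian_blur(VoxelStack(np.ones((2, 4, 4))), 0.0)


class TestOtsuThreshold:
    def test_two_level_stack(self):
        data = np.concatenate([np.full(100, 10.0), np.full(100, 200.0)])
        stack = VoxelStack(data.reshape(2, 10, 10))
        thr = otsu_threshold(stack)
        assert 10 < thr < 200
        fg = stack.data > thr
        assert fg.sum() == 100
        assert np.all(stack.data[fg] == 200.0)

    def test_constant_stack_raises(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(VoxelStack(np.full((2, 4, 4), 9.0)))

    def test_matches_brute_force_on_random_stacks(self):
        # >= 50 random 8-bit stacks against the exhaustive oracle
        rng = np.random.default_rng(1234)
        for _ in range(50):
            data = rng.integers(0, 256, size=(4, 16, 16)).astype(np.float64)
            if data.min() == data.max():
                continue
            stack = VoxelStack(data)
            assert otsu_threshold(stack) == pytest.approx(brute_force_otsu(data))

    def test_matches_brute_force_bimodal(self):
        rng = np.random.default_rng(99)
        data = np.concatenate(
            [rng.normal(40, 8, 2000), rng.normal(180, 15, 1000)]
        ).clip(0, 255)
        stack = VoxelStack(data.reshape(3, 25, 40))
        assert otsu_threshold(stack) == pytest.approx(brute_force_otsu(data))


class TestSegmentTargeting:
    def test_noiseless_sample_mask_recovers_planted_foreground(self, small_spec):
        # blur erodes at most a one-voxel boundary shell; the interior and
        # all background voxels must be classified exactly
        from scipy import ndimage as ndi

        truth = SimTruth(seed=3, mistarget_fraction={"VA1v": 0.2})
        channels, atlas, _ = simulate_sample(small_spec, truth)
        planted = channels["label"].data > 0
        mask = segment_targeting(channels["label"]).mask
        assert not (mask & ~planted).any()  # nothing added outside the truth
        interior = ndi.binary_erosion(planted)
        assert mask[interior].all()  # interior fully recovered
        mismatch = planted & ~mask
        assert mismatch.sum() <= 0.01 * planted.sum()  # only stray edge voxels

    def test_all_zero_stack_raises(self):
        with pytest.raises(DegenerateHistogramError):
            segment_targeting(VoxelStack(np.zeros((2, 8, 8))))

    def test_constant_offset_shift_invariance(self, rng):
        data = rng.integers(0, 200, size=(3, 20, 20)).astype(np.float64)
        m1 = segment_targeting(VoxelStack(data))
        m2 = segment_targeting(VoxelStack(data + 37.0))
        np.testing.assert_array_equal(m1.mask, m2.mask)

    def test_mask_monotone_under_foreground_boost(self, small_spec):
        truth = SimTruth(seed=8, mistarget_fraction={"VA1v": 0.1})
        channels, _, _ = simulate_sample(small_spec, truth)
        base = channels["label"].data
        mask_lo = segment_targeting(VoxelStack(base)).mask
        boosted = np.where(base > 0, base * 1.5, base)
        mask_hi = segment_targeting(VoxelStack(boosted)).mask
        assert np.all(mask_hi[mask_lo])  # no voxel drops out

    def test_threshold_recorded(self):
        data = np.concatenate([np.zeros(500), np.full(500, 100.0)]).reshape(4, 10, 25)
        mask = segment_targeting(VoxelStack(data), radius=1.0)
        assert mask.blur_radius == 1.0
        assert 0 < mask.threshold_used < 100


class TestMeanDensity:
    def _atlas(self):
        labels = np.zeros((1, 2, 3), dtype=np.int32)
        labels[0, 0, :3] = 1
        return GlomerulusAtlas(labels=labels, name_table={1: "VA1d"})

    def test_hand_arithmetic(self):
        stack = VoxelStack(np.array([[[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]]]))
        assert mean_density(stack, self._atlas(), "VA1d") == pytest.approx(2.0)

    def test_constant_region(self):
        stack = VoxelStack(np.full((1, 2, 3), 5.5))
        assert mean_density(stack, self._atlas(), "VA1d") == pytest.approx(5.5)

    def test_unknown_name_raises(self):
        stack = VoxelStack(np.zeros((1, 2, 3)))
        with pytest.raises(KeyError):
            mean_density(stack, self._atlas(), "nope")

    def test_empty_region_raises(self):
        labels = np.zeros((1, 2, 3), dtype=np.int32)
        atlas = GlomerulusAtlas(labels=labels, name_table={1: "VA1d"})
        with pytest.raises(EmptyRegionError):
            mean_density(VoxelStack(np.zeros((1, 2, 3))), atlas, "VA1d")


class TestPreferenceIndex:
    def test_symmetry_zero(self):
        assert preference_index(4.2, 4.2) == 0.0

    def test_boundaries(self):
        assert preference_index(3.0, 0.0) == 1.0
        assert preference_index(0.0, 3.0) == -1.0

    def test_hand_arithmetic(self):
        assert preference_index(3.0, 1.0) == pytest.approx(0.5)

    def test_undefined(self):
        with pytest.raises(UndefinedIndexError):
            preference_index(0.0, 0.0)

    @given(
        a=st.floats(min_value=0, max_value=1e6),
        b=st.floats(min_value=0, max_value=1e6),
    )
    def test_antisymmetry(self, a, b):
        if a + b == 0:
            return
        assert preference_index(a, b) == pytest.approx(-preference_index(b, a))

    @given(
        a=st.floats(min_value=1e-3, max_value=1e3),
        b=st.floats(min_value=1e-3, max_value=1e3),
        k=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance(self, a, b, k):
        assert preference_index(k * a, k * b) == pytest.approx(
            preference_index(a, b), abs=1e-9
        )

    @given(
        a=st.floats(min_value=0, max_value=1e6),
        b=st.floats(min_value=0, max_value=1e6),
    )
    def test_bounded(self, a, b):
        if a + b == 0:
            return
        assert -1.0 <= preference_index(a, b) <= 1.0


class TestMistargetingRatio:
    def _toy(self):
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[0, 0, :4] = 1  # reference strip
        labels[1, 0, :4] = 2  # off-target strip
        atlas = GlomerulusAtlas(labels=labels, name_table={1: "VA1d", 2: "VA1v"})
        return atlas

    def test_direct_voxel_count(self):
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels.ravel()[:60] = 1
        labels.ravel()[60:72] = 2
        atlas = GlomerulusAtlas(labels=labels, name_table={1: "VA1d", 2: "VA1v"})
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask.ravel()[:72] = True  # all 60 reference + all 12 off-target voxels
        tm = TargetingMask(mask=mask, threshold_used=0.0, blur_radius=1.0)
        rec = mistargeting_ratio(tm, atlas, "VA1d", ["VA1v"])
        assert rec.volumes == {"VA1d": 60, "VA1v": 12}
        assert rec.ratios["VA1v"] == pytest.approx(0.2)

    def test_no_off_target_gives_zero_ratios(self):
        atlas = self._toy()
        mask = atlas.labels == 1
        tm = TargetingMask(mask=mask, threshold_used=0.0, blur_radius=1.0)
        rec = mistargeting_ratio(tm, atlas, "VA1d", ["VA1v"])
        assert rec.ratios == {"VA1v": 0.0}

    def test_zero_reference_raises(self):
        atlas = self._toy()
        mask = np.zeros(atlas.shape, dtype=bool)
        tm = TargetingMask(mask=mask, threshold_used=0.0, blur_radius=1.0)
        with pytest.raises(ZeroReferenceVolumeError):
            mistargeting_ratio(tm, atlas, "VA1d", ["VA1v"])


class TestCallPhenotype:
    def _record(self, v_target):
        return MistargetRecord(
            volumes={"VA1d": 100, "VA1v": v_target},
            reference="VA1d",
            ratios={"VA1v": v_target / 100},
        )

    def test_zero_evidence_negative(self):
        assert not call_phenotype(self._record(0), "VA1v", 10).positive

    def test_boundary_is_positive(self):
        assert call_phenotype(self._record(10), "VA1v", 10).positive

    def test_unknown_target_raises(self):
        with pytest.raises(KeyError):
            call_phenotype(self._record(0), "DA1", 10)


class TestQuantifySample:
    def test_noiseless_pi_composition(self, small_spec):
        truth = SimTruth(
            seed=1,
            mistarget_fraction={"VA1v": 0.0},
            protein_mean={"VA1d": 3.0, "VA1v": 1.0},
        )
        channels, atlas, _ = simulate_sample(small_spec, truth)
        rec = quantify_sample(channels, atlas, QuantConfig(), "s")
        assert rec.preference_index == pytest.approx(0.5)

    def test_m_zero_negative_phenotype(self, small_spec, noiseless_truth):
        truth = SimTruth(
            seed=1, mistarget_fraction={"VA1v": 0.0},
            protein_mean={"VA1d": 150.0, "VA1v": 50.0},
        )
        channels, atlas, _ = simulate_sample(small_spec, truth)
        rec = quantify_sample(channels, atlas, QuantConfig(), "s")
        assert not rec.phenotype.positive
        assert rec.mistarget.ratios == {"VA1v": 0.0}

    def test_determinism(self, small_spec, noiseless_truth):
        channels, atlas, _ = simulate_sample(small_spec, noiseless_truth)
        r1 = quantify_sample(channels, atlas, QuantConfig(), "s")
        r2 = quantify_sample(channels, atlas, QuantConfig(), "s")
        assert r1.to_dict() == r2.to_dict()

    def test_shape_mismatch_annotated_with_sample_id(self, small_spec, noiseless_truth):
        channels, atlas, _ = simulate_sample(small_spec, noiseless_truth)
        bad = dict(channels)
        bad["label"] = VoxelStack(np.zeros((2, 4, 4)))
        with pytest.raises(ValueError, match="badsample"):
            quantify_sample(bad, atlas, QuantConfig(), "badsample")


class TestParameterRecovery:
    @pytest.mark.parametrize("r", [1.0, 2.0, 3.0])
    def test_pi_recovery(self, medium_spec, r):
        target = (r - 1) / (r + 1)
        for seed in range(5):
            truth = SimTruth(
                seed=seed,
                mistarget_fraction={"VA1v": 0.1},
                protein_mean={"VA1d": 50.0 * r, "VA1v": 50.0},
                gaussian_sd=5.0,
                psf_sigma=0.5,
            )
            channels, atlas, _ = simulate_sample(medium_spec, truth)
            rec = quantify_sample(channels, atlas, QuantConfig(), "s")
            assert rec.preference_index == pytest.approx(target, abs=0.05)

    @pytest.mark.parametrize("m", [0.05, 0.1, 0.2])
    def test_mistarget_recovery(self, m):
        # boundary-erosion bias shrinks with region size: use the full-size
        # default atlas, where recovery is well inside the 15% band
        from glomquant.synthetic import default_atlas_spec

        spec = default_atlas_spec()
        for seed in range(5):
            truth = SimTruth(
                seed=seed,
                mistarget_fraction={"VA1v": m},
                protein_mean={"VA1d": 100.0, "VA1v": 100.0},
                gaussian_sd=10.0,
                psf_sigma=0.5,
            )
            channels, atlas, manifest = simulate_sample(spec, truth)
            rec = quantify_sample(channels, atlas, QuantConfig(), "s")
            planted = manifest.planted_proportions["VA1v"]
            assert rec.mistarget.ratios["VA1v"] == pytest.approx(planted, rel=0.15)
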