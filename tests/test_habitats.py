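import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _helpers import two_means_oracle
from habitatmri.habitats import (
    build_habitat_map,
    composition,
    compute_cohort_habitats,
    decode_habitat,
    dichotomize,
    encode_habitat,
    linearize,
    pooled_threshold,
    scale_to_reference,
    subvolume_fractions,
)
from habitatmri.types import HabitatMap, SegmentationMap, VolumeGrid


def _toy_patient(ref_values, tumor_values):
    """Segmentation with a GM/WM reference block and a necrosis tumor block."""
    shape = (8, 8, 8)
    labels = np.zeros(shape, dtype=np.int16)
    values = np.zeros(shape)
    ref_values = np.asarray(ref_values, dtype=float)
    tumor_values = np.asarray(tumor_values, dtype=float)
    flat_labels = labels.ravel()
    flat_values = values.ravel()
    flat_labels[: ref_values.size // 2] = 2
    flat_labels[ref_values.size // 2: ref_values.size] = 3
    flat_values[: ref_values.size] = ref_values
    start = ref_values.size
    flat_labels[start: start + tumor_values.size] = 4
    flat_values[start: start + tumor_values.size] = tumor_values
    return (
        VolumeGrid(values=flat_values.reshape(shape)),
        SegmentationMap(labels=flat_labels.reshape(shape)),
    )


class TestScaleToReference:
    def test_z_score_arithmetic(self):
        ref = np.tile([90.0, 110.0], 60)  # mean 100, population sd 10
        vol, seg = _toy_patient(ref, [120.0, 100.0, 80.0])
        np.testing.assert_allclose(scale_to_reference(vol, seg), [2.0, 0.0, -2.0])

    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
    @settings(max_examples=25, deadline=None)
    def test_affine_intensity_invariance(self, a, b):
        rng = np.random.default_rng(0)
        vol, seg = _toy_patient(rng.normal(100, 10, 120), rng.normal(150, 30, 40))
        z = scale_to_reference(vol, seg)
        vol2 = VolumeGrid(values=a * vol.values + b, affine=vol.affine)
        np.testing.assert_allclose(scale_to_reference(vol2, seg), z, atol=1e-8)

    def test_constant_reference_is_degenerate(self):
        vol, seg = _toy_patient(np.full(120, 100.0), [120.0, 90.0])
        with pytest.raises(ValueError, match="degenerate reference"):
            scale_to_reference(vol, seg)

    def test_small_reference_region_rejected(self):
        vol, seg = _toy_patient([90.0, 110.0] * 10, [120.0])
        with pytest.raises(ValueError, match="reference tissue too small"):
            scale_to_reference(vol, seg)


class TestLinearize:
    def test_simple_vector(self):
        np.testing.assert_allclose(linearize(np.array([2.0, 4.0, 6.0])), [0, 0.5, 1])

    def test_constant_vector_maps_to_half_with_warning(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            out = linearize(np.full(5, 3.3))
        np.testing.assert_array_equal(out, np.full(5, 0.5))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            linearize(np.array([]))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rank_preservation(self, seed):
        v = np.random.default_rng(seed).normal(size=50)
        out = linearize(v)
        np.testing.assert_array_equal(np.argsort(out, kind="stable"),
                                      np.argsort(v, kind="stable"))
        assert out.min() == 0.0 and out.max() == 1.0


class TestPooledThreshold:
    def test_symmetric_binary_sample(self):
        t = pooled_threshold(np.array([0, 0, 0, 1, 1, 1], dtype=float))
        assert (t.center_low, t.center_high, t.threshold) == (0.0, 1.0, 0.5)

    def test_four_point_case_matches_breakpoint_enumeration(self):
        t = pooled_threshold(np.array([0.0, 0.1, 0.9, 1.0]))
        np.testing.assert_allclose(
            [t.center_low, t.center_high, t.threshold], [0.05, 0.95, 0.5]
        )

    def test_two_gaussians_threshold_between_means(self):
        rng = np.random.default_rng(3)
        lo = rng.normal(0.2, 0.05, 400)
        hi = rng.normal(0.8, 0.05, 300)
        t = pooled_threshold(np.concatenate([lo, hi]))
        assert lo.mean() < t.threshold < hi.mean()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_sse_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, rng.integers(10, 500))
        low, high, thr = two_means_oracle(x)
        t = pooled_threshold(x)
        np.testing.assert_allclose([t.center_low, t.center_high, t.threshold],
                                   [low, high, thr], atol=1e-12)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            pooled_threshold(np.full(10, 0.4))


class TestDichotomizeAndEncoding:
    def test_tie_at_threshold_goes_low(self):
        bits = dichotomize(np.array([0.5, 0.5 + 1e-12, 0.0]), 0.5)
        np.testing.assert_array_equal(bits, [0, 1, 0])

    def test_encode_decode_is_bijection(self):
        seen = {encode_habitat(*decode_habitat(h)) for h in range(16)}
        assert seen == set(range(16))

    def test_invalid_bits_rejected(self):
        with pytest.raises(ValueError):
            encode_habitat(0, 2, 0, 0)


class TestHabitatMapAndComposition:
    def test_single_voxel_map(self):
        idx = (np.array([1]), np.array([2]), np.array([3]))
        bits = {"FLAIR": np.array([0]), "T1": np.array([0]),
                "T1c": np.array([1]), "T2": np.array([1])}
        hmap = build_habitat_map(bits, idx, (4, 4, 4))
        assert hmap.labels[1, 2, 3] == 3
        assert (hmap.labels == -1).sum() == 63

    def test_empty_tumor_mask_rejected(self):
        idx = (np.array([], int),) * 3
        bits = {s: np.array([], int) for s in ("FLAIR", "T1", "T1c", "T2")}
        with pytest.raises(ValueError, match="empty tumor"):
            build_habitat_map(bits, idx, (4, 4, 4))

    def test_composition_counts(self):
        grid = np.full((2, 2, 1), -1, dtype=np.int16)
        grid.ravel()[:] = [2, 2, 7, 10]
        comp = composition(HabitatMap(labels=grid))
        expected = np.zeros(16)
        expected[[2, 7, 10]] = [0.5, 0.25, 0.25]
        np.testing.assert_allclose(comp.proportions, expected)
        assert comp.n_voxels == 4

    def test_composition_sums_to_one(self):
        rng = np.random.default_rng(1)
        grid = rng.integers(0, 16, size=(20, 20, 10)).astype(np.int16)
        comp = composition(HabitatMap(labels=grid))
        assert abs(comp.proportions.sum() - 1.0) <= 1e-12

    def test_uniform_labels_within_binomial_bound(self):
        n = 16000
        rng = np.random.default_rng(5)
        grid = rng.integers(0, 16, size=(40, 40, 10)).astype(np.int16)
        comp = composition(HabitatMap(labels=grid))
        p = 1.0 / 16
        bound = 4 * np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(comp.proportions - p) < bound)

    def test_subvolume_fractions_match_hand_tally(self):
        labels = np.zeros((4, 4, 1), dtype=np.int16)
        labels.ravel()[:8] = [4, 4, 4, 5, 5, 6, 7, 7]
        frac = subvolume_fractions(SegmentationMap(labels=labels))
        np.testing.assert_allclose(frac, [3 / 8, 2 / 8, 1 / 8, 2 / 8])
        labels2 = np.where(labels > 0, 4, 0).astype(np.int16)
        np.testing.assert_allclose(
            subvolume_fractions(SegmentationMap(labels=labels2)), [1, 0, 0, 0]
        )


class TestCohortPipeline:
    def test_planted_sectors_recovered_voxelwise_at_large_separation(self):
        from habitatmri.simulate import SimulationConfig, generate_patient_images
        from habitatmri.io import PatientImages

        config = SimulationConfig(
            n_patients=4, shape=(32, 32, 24), tumor_radius_range=(5.0, 8.0),
            separation=5.0, seed=99,
        )
        patients, truth_maps = {}, {}
        for i in range(config.n_patients):
            s = generate_patient_images(config, [config.seed, 0, i], f"P{i}")
            patients[s.patient_id] = PatientImages(
                volumes=s.volumes, segmentation=s.segmentation
            )
            truth_maps[s.patient_id] = s.true_habitat_map
        result = compute_cohort_habitats(patients)
        for pid, hmap in result.maps.items():
            mask = hmap.tumor_mask
            mismatch = np.mean(hmap.labels[mask] != truth_maps[pid][mask])
            assert mismatch <= 0.002

    def test_pipeline_invariant_under_affine_intensity_rescale(self, small_bundle):
        from habitatmri.io import PatientImages

        bundle, _ = small_bundle
        base = compute_cohort_habitats(bundle.patients)
        rescaled = {}
        for pid, pat in bundle.patients.items():
            vols = {
                seq: VolumeGrid(values=3.7 * v.values + 42.0, affine=v.affine)
                for seq, v in pat.volumes.items()
            }
            rescaled[pid] = PatientImages(volumes=vols, segmentation=pat.segmentation)
        again = compute_cohort_habitats(rescaled)
        for pid in bundle.patients:
            np.testing.assert_array_equal(
                base.maps[pid].labels, again.maps[pid].labels
            )
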