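import numpy as np
import pytest
from scipy import ndimage

from atquant.segmentation import STRUCTURE_26
from atquant.stack_io import VoxelGeometry
from atquant.synthetic import (GroundTruthManifest, SimulationConfig, add_noise,
                               apply_section_jitter, simulate_roi)

from conftest import make_stack


def quiet_config(**kw):
    """Noise-free, jitter-free, speck-free baseline config."""
    base = dict(field_size=(96, 96), n_sections=16, seed=1,
                background=0.0, gradient_amplitude=0.0, gaussian_noise_sd=0.0,
                poisson_noise=False, speck_rate=0.0, jitter_max_px=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="pairing_fraction"):
            SimulationConfig(pairing_fraction=1.2)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            SimulationConfig(density_per_um3={"SYP": -1.0})

    def test_puncta_thinner_than_two_sections_rejected(self):
        with pytest.raises(ValueError, match="span 2 sections"):
            SimulationConfig(radius_mean_um=0.05)

    def test_field_too_small_for_puncta(self):
        cfg = quiet_config(field_size=(3, 3), exact_count={"SYP": 1},
                           density_per_um3={"SYP": 0, "PSD95": 0, "OC": 0})
        with pytest.raises(ValueError, match="too small"):
            simulate_roi(cfg)

    def test_dict_round_trip(self):
        cfg = SimulationConfig(seed=9, field_size=(64, 64))
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg


class TestSimulateRoi:
    def test_zero_density_noise_off_gives_blank_stacks(self):
        cfg = quiet_config(density_per_um3={"SYP": 0, "PSD95": 0, "OC": 0})
        roi, man = simulate_roi(cfg)
        for ch, stack in roi.channels.items():
            assert stack.voxels.sum() == 0.0
            assert man.puncta[ch] == []
        assert man.pairs == []

    def test_same_seed_identical_voxels_and_manifest(self):
        cfg = SimulationConfig(field_size=(64, 64), n_sections=16, seed=42)
        roi1, man1 = simulate_roi(cfg)
        roi2, man2 = simulate_roi(cfg)
        for ch in roi1.channels:
            np.testing.assert_array_equal(roi1.channels[ch].voxels, roi2.channels[ch].voxels)
        assert [p.centroid_um for p in man1.puncta["SYP"]] == \
               [p.centroid_um for p in man2.puncta["SYP"]]
        assert man1.jitter_px == man2.jitter_px

    def test_exact_count_blob_hand_count(self):
        """Manifest count equals an independent blob count of the render."""
        cfg = quiet_config(field_size=(220, 220),
                           exact_count={"SYP": 50, "PSD95": 0, "OC": 0},
                           density_per_um3={"SYP": 0, "PSD95": 0, "OC": 0},
                           min_separation_um=1.0, amplitude_sd=0.0)
        roi, man = simulate_roi(cfg)
        assert len(man.puncta["SYP"]) == 50
        labels, n = ndimage.label(roi.channels["SYP"].voxels > 200.0, structure=STRUCTURE_26)
        assert n == 50

    def test_truth_burden_matches_recount_from_render(self):
        """Manifest burden equals voxels >= half-max recounted on the render."""
        cfg = quiet_config(exact_count={"SYP": 10, "PSD95": 0, "OC": 0},
                           density_per_um3={"SYP": 0, "PSD95": 0, "OC": 0},
                           min_separation_um=1.5, amplitude_sd=0.0)
        roi, man = simulate_roi(cfg)
        img = roi.channels["SYP"].voxels
        recount = 100.0 * np.count_nonzero(img >= 200.0 - 1e-9) / img.size
        assert man.burden_pct["SYP"] == pytest.approx(recount, abs=1e-12)
        # and the per-punctum volumes sum to the union volume (no overlap here)
        vox_vol = cfg.geometry.voxel_volume_um3
        total = sum(p.volume_um3 for p in man.puncta["SYP"])
        assert total == pytest.approx(man.burden_pct["SYP"] / 100.0 * img.size * vox_vol)

    def test_pairs_reference_existing_puncta_within_offset(self):
        cfg = SimulationConfig(seed=7, field_size=(128, 128), n_sections=16)
        _, man = simulate_roi(cfg)
        pre = {p.punctum_id: np.array(p.centroid_um) for p in man.puncta["SYP"]}
        post = {p.punctum_id: np.array(p.centroid_um) for p in man.puncta["PSD95"]}
        assert man.pairs, "default config should construct pairs"
        for i, j, d in man.pairs:
            assert i in pre and j in post
            dist = np.linalg.norm(pre[i] - post[j])
            assert dist == pytest.approx(d, abs=1e-9)
            assert dist <= cfg.pairing_offset_max_um + 1e-9

    def test_pairing_fraction_within_binomial_error(self):
        hits = trials = 0
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, field_size=(128, 128), n_sections=16)
            _, man = simulate_roi(cfg)
            hits += len(man.pairs)
            trials += len(man.puncta["SYP"])
        p_hat = hits / trials
        se = np.sqrt(0.3 * 0.7 / trials)
        assert abs(p_hat - 0.3) < 4 * se

    def test_specks_span_exactly_one_section(self):
        cfg = quiet_config(density_per_um3={"SYP": 0, "PSD95": 0, "OC": 0},
                           speck_rate=0.5)
        roi, man = simulate_roi(cfg)
        assert man.speck_count["SYP"] > 0
        labels, n = ndimage.label(roi.channels["SYP"].voxels > 200.0, structure=STRUCTURE_26)
        for obj in ndimage.find_objects(labels):
            assert obj[0].stop - obj[0].start == 1

    def test_manifest_json_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=3, field_size=(64, 64), n_sections=16)
        _, man = simulate_roi(cfg)
        man.to_json(tmp_path / "gt.json")
        loaded = GroundTruthManifest.from_json(tmp_path / "gt.json")
        assert loaded.pairs == [tuple(p) for p in man.pairs]
        assert loaded.burden_pct == pytest.approx(man.burden_pct)
        assert [p.centroid_um for p in loaded.puncta["OC"]] == \
               [p.centroid_um for p in man.puncta["OC"]]


class TestJitter:
    def test_zero_vectors_identity(self):
        cfg = quiet_config(exact_count={"SYP": 5, "PSD95": 0, "OC": 0},
                           density_per_um3={"SYP": 0, "PSD95": 0, "OC": 0})
        roi, _ = simulate_roi(cfg)
        out = apply_section_jitter(roi, [(0, 0)] * 16)
        np.testing.assert_array_equal(out.channels["SYP"].voxels, roi.channels["SYP"].voxels)

    def test_integer_shift_equals_roll_in_interior(self, rng):
        img = rng.random((16, 30, 30)) * 100
        roi_stack = make_stack(img)
        from atquant.stack_io import RegionOfInterest
        roi = RegionOfInterest("c", "control", 0, {"SYP": roi_stack})
        vectors = [(0, 0)] * 16
        vectors[4] = (3, -2)
        out = apply_section_jitter(roi, vectors)
        rolled = np.roll(np.roll(img[4], 3, axis=0), -2, axis=1)
        np.testing.assert_allclose(out.channels["SYP"].voxels[4][4:-4, 4:-4],
                                   rolled[4:-4, 4:-4])

    def test_wrong_vector_count_rejected(self):
        cfg = quiet_config(density_per_um3={"SYP": 0, "PSD95": 0, "OC": 0})
        roi, _ = simulate_roi(cfg)
        with pytest.raises(ValueError, match="jitter vectors"):
            apply_section_jitter(roi, [(1, 1)] * 5)

    def test_jitter_shared_across_channels(self):
        cfg = SimulationConfig(seed=12, field_size=(64, 64), n_sections=16)
        _, man = simulate_roi(cfg)
        assert len(man.jitter_px) == 16
        assert man.jitter_px[16 // 2] == (0.0, 0.0)  # reference section fixed


class TestAddNoise:
    def test_all_noise_off_is_identity(self, rng):
        cfg = quiet_config()
        stack = make_stack(rng.random((16, 20, 20)) * 50)
        out = add_noise(stack, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(out.voxels, stack.voxels)

    def test_blank_field_mean_matches_background(self):
        cfg = SimulationConfig(field_size=(256, 256), n_sections=16, seed=0,
                               background=50.0, gradient_amplitude=0.0,
                               gaussian_noise_sd=5.0, poisson_noise=False)
        blank = make_stack(np.zeros((16, 256, 256)))
        out = add_noise(blank, cfg, np.random.default_rng(1))
        n = out.voxels.size
        assert n >= 1_000_000
        # quantization to integer ADU preserves the mean to < 3 standard errors
        assert abs(out.voxels.mean() - 50.0) < max(3 * 5.0 / np.sqrt(n), 0.05)

    def test_same_rng_seed_same_noise(self):
        cfg = SimulationConfig(field_size=(32, 32), n_sections=16, seed=0)
        blank = make_stack(np.zeros((16, 32, 32)))
        a = add_noise(blank, cfg, np.random.default_rng(7))
        b = add_noise(blank, cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_output_non_negative(self):
        cfg = SimulationConfig(field_size=(32, 32), n_sections=16,
                               background=1.0, gaussian_noise_sd=10.0)
        blank = make_stack(np.zeros((16, 32, 32)))
        out = add_noise(blank, cfg, np.random.default_rng(2))
        assert out.voxels.min() >= 0.0
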