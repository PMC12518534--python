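"""Synthetic phantom generator: determinism, recoverability, splits,
and joint augmentation."""

import json

import numpy as np
import pytest

from dcfnet.config import ConfigError
from dcfnet.metrics import dsc_metric
from dcfnet.phantom import (PhantomSpec, apply_transform, augment,
                            generate_phantom, generate_split,
                            identity_transform, load_split)


class TestGeneratePhantom:
    def test_same_spec_and_index_reproduce_identical_bytes(self):
        spec = PhantomSpec(regime="multi_organ", img_size=64, seed=3)
        a_img, a_mask = generate_phantom(spec, 5)
        b_img, b_mask = generate_phantom(spec, 5)
        assert a_img.tobytes() == b_img.tobytes()
        assert a_mask.tobytes() == b_mask.tobytes()

    def test_different_indices_differ(self):
        spec = PhantomSpec(regime="lesion", img_size=48, seed=0)
        a, _ = generate_phantom(spec, 0)
        b, _ = generate_phantom(spec, 1)
        assert not np.array_equal(a, b)

    def test_noiseless_full_contrast_classes_recoverable_by_thresholding(self):
        spec = PhantomSpec(regime="multi_organ", img_size=96, contrast=1.0,
                           noise_sd=0.0, boundary_softness=0.0, seed=2)
        img, mask = generate_phantom(spec, 0)
        recovered = np.round(img * (spec.num_classes - 1)).astype(int)
        np.testing.assert_array_equal(recovered, mask)

    def test_multi_organ_label_census(self):
        spec = PhantomSpec(regime="multi_organ", img_size=96, seed=9)
        counts = []
        for i in range(50):
            _, mask = generate_phantom(spec, i)
            labels = set(np.unique(mask))
            assert labels <= set(range(9))
            counts.append(len(labels - {0}))
        assert np.mean(counts) >= 5.0

    @pytest.mark.parametrize("regime,nc", [("multi_organ", 9), ("cardiac", 4),
                                           ("lesion", 2)])
    def test_regime_class_counts_and_value_ranges(self, regime, nc):
        spec = PhantomSpec(regime=regime, img_size=64, seed=1)
        img, mask = generate_phantom(spec, 0)
        assert spec.num_classes == nc
        assert img.min() >= 0.0 and img.max() <= 1.0
        assert mask.min() >= 0 and mask.max() < nc

    def test_cardiac_topology(self):
        # LV blood pool pixels must be adjacent to myocardium, not background
        from scipy import ndimage
        spec = PhantomSpec(regime="cardiac", img_size=96, seed=4)
        _, mask = generate_phantom(spec, 0)
        lv = mask == 3
        if lv.any():
            ring = ndimage.binary_dilation(lv) & ~lv
            assert (mask[ring] == 2).all()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigError):
            generate_phantom(PhantomSpec(contrast=0.0), 0)
        with pytest.raises(ConfigError):
            generate_phantom(PhantomSpec(regime="xray"), 0)


class TestSplits:
    def test_fraction_arithmetic_and_disjointness(self, tmp_path):
        spec = PhantomSpec(regime="lesion", img_size=32, n_images=20, seed=0)
        manifest = generate_split(spec, (0.7, 0.1, 0.2), tmp_path / "d")
        idx = manifest["indices"]
        assert [len(idx[s]) for s in ("train", "val", "test")] == [14, 2, 4]
        all_idx = idx["train"] + idx["val"] + idx["test"]
        assert len(set(all_idx)) == len(all_idx) == 20

    def test_rerun_reproduces_manifest_and_images(self, tmp_path):
        spec = PhantomSpec(regime="lesion", img_size=32, n_images=6, seed=1)
        m1 = generate_split(spec, (0.5, 0.5, 0.0), tmp_path / "a")
        m2 = generate_split(spec, (0.5, 0.5, 0.0), tmp_path / "b")
        assert m1["indices"] == m2["indices"]
        ia, _ = load_split(tmp_path / "a", "train")
        ib, _ = load_split(tmp_path / "b", "train")
        np.testing.assert_array_equal(ia, ib)

    def test_bad_fractions_rejected(self, tmp_path):
        spec = PhantomSpec(regime="lesion", img_size=32, n_images=4)
        with pytest.raises(ConfigError):
            generate_split(spec, (0.5, 0.2, 0.2), tmp_path / "x")

    def test_manifest_written_with_spec(self, tmp_path):
        spec = PhantomSpec(regime="cardiac", img_size=32, n_images=4, seed=7)
        generate_split(spec, (1.0, 0.0, 0.0), tmp_path / "d")
        manifest = json.loads((tmp_path / "d" / "manifest.json").read_text())
        assert manifest["spec"]["seed"] == 7
        assert manifest["num_classes"] == 4


class TestAugment:
    def test_identity_transform_is_bit_exact(self):
        spec = PhantomSpec(regime="lesion", img_size=32, seed=0)
        img, mask = generate_phantom(spec, 0)
        img2, mask2 = apply_transform(img, mask, identity_transform())
        assert img2.tobytes() == img.tobytes()
        assert mask2.tobytes() == mask.tobytes()

    def test_label_histogram_unchanged_by_flips_and_quarter_turns(self):
        spec = PhantomSpec(regime="multi_organ", img_size=64, seed=5)
        _, mask = generate_phantom(spec, 0)
        img = np.zeros_like(mask, dtype=float)
        t = {"flip_h": True, "flip_v": True, "rot90": 3, "angle": 0.0}
        _, mask2 = apply_transform(img, mask, t)
        np.testing.assert_array_equal(np.bincount(mask.ravel(), minlength=9),
                                      np.bincount(mask2.ravel(), minlength=9))

    def test_small_angle_rotation_preserves_label_values(self):
        spec = PhantomSpec(regime="cardiac", img_size=48, seed=2)
        img, mask = generate_phantom(spec, 0)
        _, mask2 = apply_transform(img, mask, {"flip_h": False, "flip_v": False,
                                               "rot90": 0, "angle": 13.0})
        assert set(np.unique(mask2)) <= set(np.unique(mask))

    def test_dice_invariant_under_joint_transform(self, rng):
        spec = PhantomSpec(regime="lesion", img_size=32, seed=3)
        _, P = generate_phantom(spec, 0)
        _, L = generate_phantom(spec, 1)
        for seed in range(5):
            t = {"flip_h": bool(seed % 2), "flip_v": bool(seed // 2 % 2),
                 "rot90": seed % 4, "angle": 0.0}
            _, Pt = apply_transform(P.astype(float), P, t)
            _, Lt = apply_transform(L.astype(float), L, t)
            assert dsc_metric(Pt, Lt, cls=1) == dsc_metric(P, L, cls=1)

    def test_nifti_volume_roundtrip(self, tmp_path):
        import nibabel as nib
        from dcfnet.phantom import save_nifti_volume
        spec = PhantomSpec(regime="cardiac", img_size=32, seed=0)
        pairs = [generate_phantom(spec, i) for i in range(3)]
        imgs = np.stack([p[0] for p in pairs])
        masks = np.stack([p[1] for p in pairs])
        save_nifti_volume(imgs, masks, tmp_path / "case0")
        vol = np.asarray(nib.load(tmp_path / "case0_mask.nii.gz").dataobj)
        assert vol.shape == (32, 32, 3)
        np.testing.assert_array_equal(np.moveaxis(vol, -1, 0), masks)

    def test_seeded_augment_is_deterministic(self):
        spec = PhantomSpec(regime="lesion", img_size=32, seed=0)
        img, mask = generate_phantom(spec, 0)
        a = augment(img, mask, 42)
        b = augment(img, mask, 42)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
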