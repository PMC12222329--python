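"""Data pipeline: loading, augmentation, SMOTE, folds and phantoms."""

import numpy as np
import pytest
from PIL import Image

from hybridsnn.data import (
    AugmentConfig,
    Dataset,
    ImageSample,
    PhantomParams,
    augment,
    load_image_dir,
    save_dataset,
    smote_oversample,
    stratified_kfold,
    synth_phantoms,
)

SEED = 7


class TestLoadImageDir:
    def make_tree(self, tmp_path, counts=(5, 5, 5), size=32):
        rng = np.random.default_rng(0)
        for name, n in zip(("AD", "CI", "CN"), counts):
            sub = tmp_path / name
            sub.mkdir()
            for i in range(n):
                arr = rng.integers(0, 256, (size, size), dtype=np.uint8)
                Image.fromarray(arr).save(sub / f"{i}.png")
        return tmp_path

    def test_counts_and_normalisation(self, tmp_path):
        root = self.make_tree(tmp_path)
        ds = load_image_dir(root)
        assert len(ds) == 15
        assert ds.class_counts == {"AD": 5, "CI": 5, "CN": 5}
        assert ds.images.shape == (15, 128, 128, 3)
        assert 0.0 <= ds.images.min() and ds.images.max() <= 1.0

    def test_8bit_white_maps_to_one(self, tmp_path):
        sub = tmp_path / "CN"
        sub.mkdir()
        Image.fromarray(np.full((128, 128), 255, dtype=np.uint8)).save(
            sub / "white.png"
        )
        ds = load_image_dir(tmp_path)
        assert ds.images.max() == pytest.approx(1.0)

    def test_empty_class_warns_but_loads(self, tmp_path, caplog):
        root = self.make_tree(tmp_path, counts=(2, 2, 0))
        (root / "CN").mkdir(exist_ok=True)
        with caplog.at_level("WARNING"):
            ds = load_image_dir(root)
        assert ds.class_counts["CN"] == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_unknown_class_directory_rejected(self, tmp_path):
        (tmp_path / "UNKNOWN").mkdir()
        with pytest.raises(ValueError, match="unknown class"):
            load_image_dir(tmp_path)

    def test_mci_alias_maps_to_ci(self, tmp_path):
        sub = tmp_path / "MCI"
        sub.mkdir()
        Image.fromarray(np.zeros((16, 16), dtype=np.uint8)).save(
            sub / "a.png"
        )
        ds = load_image_dir(tmp_path)
        assert ds.class_counts == {"AD": 0, "CI": 1, "CN": 0}

    def test_nifti_middle_slice_extracted(self, tmp_path):
        nib = pytest.importorskip("nibabel")
        vol = np.zeros((32, 32, 9), dtype=np.float32)
        vol[:, :, 4] = np.linspace(0, 1, 32)[:, None]  # middle slice marked
        sub = tmp_path / "AD"
        sub.mkdir()
        nib.save(nib.Nifti1Image(vol, np.eye(4)), sub / "scan.nii.gz")
        ds = load_image_dir(tmp_path)
        assert len(ds) == 1
        # only the marked middle slice is non-zero; neighbours would load flat
        assert ds.images[0].max() == pytest.approx(1.0, abs=0.05)

    def test_dataset_roundtrip_via_png(self, tmp_path):
        phantoms = synth_phantoms(PhantomParams(seed=SEED), n_per_class=2)
        out = save_dataset(phantoms, tmp_path / "out")
        assert (out / "manifest.tsv").exists()
        reloaded = load_image_dir(out)
        assert reloaded.class_counts == phantoms.class_counts
        # 8-bit quantisation is the only loss
        np.testing.assert_allclose(
            sorted(reloaded.images.mean(axis=(1, 2, 3))),
            sorted(phantoms.images.mean(axis=(1, 2, 3))), atol=1 / 255,
        )


class TestAugment:
    def sample(self):
        rng = np.random.default_rng(3)
        return ImageSample(rng.random((64, 64, 3)), 1, "s0")

    def test_identity_parameters_leave_image_unchanged(self):
        cfg = AugmentConfig(zoom_range=(1, 1), brightness_range=(1, 1),
                            hflip_prob=0.0)
        out = augment(self.sample(), cfg, seed=0)
        np.testing.assert_array_equal(out.pixels, self.sample().pixels)
        assert out.label == 1

    def test_flip_is_involution(self):
        cfg = AugmentConfig(zoom_range=(1, 1), brightness_range=(1, 1),
                            hflip_prob=1.0)
        once = augment(self.sample(), cfg, seed=0)
        twice = augment(once, cfg, seed=1)
        np.testing.assert_array_equal(twice.pixels, self.sample().pixels)

    def test_brightness_clips_to_unit_interval(self):
        sample = ImageSample(np.full((8, 8, 3), 0.8), 0, "s")
        cfg = AugmentConfig(zoom_range=(1, 1), brightness_range=(2, 2),
                            hflip_prob=0.0)
        out = augment(sample, cfg, seed=0)
        np.testing.assert_array_equal(out.pixels, 1.0)

    def test_seed_determinism(self):
        cfg = AugmentConfig()
        a = augment(self.sample(), cfg, seed=11)
        b = augment(self.sample(), cfg, seed=11)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_zoom_keeps_shape_and_range(self):
        for z in (0.8, 1.25):
            cfg = AugmentConfig(zoom_range=(z, z), brightness_range=(1, 1),
                                hflip_prob=0.0)
            out = augment(self.sample(), cfg, seed=0)
            assert out.pixels.shape == (64, 64, 3)
            assert out.pixels.min() >= 0 and out.pixels.max() <= 1


class TestSmote:
    def imbalanced(self, counts=(10, 5, 5), size=8):
        rng = np.random.default_rng(5)
        images, labels, ids = [], [], []
        for cls, n in enumerate(counts):
            for i in range(n):
                images.append(rng.random((size, size, 3)))
                labels.append(cls)
                ids.append(f"c{cls}:{i}")
        return Dataset(np.stack(images).astype(np.float32),
                       np.array(labels), ids)

    def test_balanced_input_unchanged(self):
        ds = self.imbalanced(counts=(4, 4, 4))
        out = smote_oversample(ds, k_neighbors=3, seed=0)
        assert out.class_counts == ds.class_counts
        assert len(out) == len(ds)

    def test_minorities_raised_to_majority(self):
        out = smote_oversample(self.imbalanced(), k_neighbors=3, seed=0)
        assert out.class_counts == {"AD": 10, "CI": 10, "CN": 10}
        assert len(out) == 30

    def test_synthetics_are_convex_combinations_of_parents(self):
        ds = self.imbalanced()
        out = smote_oversample(ds, k_neighbors=3, seed=0)
        originals = {sid: img for sid, img in zip(ds.source_ids, ds.images)}
        checked = 0
        for sample in out.samples():
            if not sample.source_id.startswith("smote:"):
                continue
            p1, p2 = sample.source_id[len("smote:"):].split("+")
            a = originals[p1].ravel()
            b = originals[p2].ravel()
            x = sample.pixels.ravel()
            # x = a + u (b - a): recover u from the largest-gap pixel
            gaps = b - a
            j = np.argmax(np.abs(gaps))
            u = (x[j] - a[j]) / gaps[j]
            assert -1e-5 <= u <= 1 + 1e-5
            np.testing.assert_allclose(x, a + u * gaps, atol=1e-5)
            # parents share the synthetic sample's class
            assert p1.split(":")[0] == p2.split(":")[0]
            checked += 1
        assert checked == 10

    def test_too_small_class_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            smote_oversample(self.imbalanced(counts=(10, 3, 10)),
                             k_neighbors=5)


class TestStratifiedKFold:
    def test_partition_arithmetic(self):
        ds = synth_phantoms(PhantomParams(image_size=16, seed=SEED),
                            n_per_class=10)
        folds = stratified_kfold(ds, k=5, seed=0)
        for fold in range(5):
            train, val = folds.split(fold)
            assert len(val) == 6 and len(train) == 24
            assert np.intersect1d(train, val).size == 0

    def test_seed_determinism(self):
        ds = synth_phantoms(PhantomParams(image_size=16, seed=SEED),
                            n_per_class=10)
        a = stratified_kfold(ds, k=5, seed=3)
        b = stratified_kfold(ds, k=5, seed=3)
        np.testing.assert_array_equal(a.fold_index, b.fold_index)

    def test_per_fold_class_counts_near_proportional(self):
        # 34/33/33 split over 5 folds: each fold within 1 of n_c / k
        rng = np.random.default_rng(1)
        labels = np.array([0] * 34 + [1] * 33 + [2] * 33)
        images = rng.random((100, 8, 8, 3)).astype(np.float32)
        ds = Dataset(images, labels, [f"s{i}" for i in range(100)])
        folds = stratified_kfold(ds, k=5, seed=0)
        for fold in range(5):
            _, val = folds.split(fold)
            assert len(val) == 20
            for cls, n_cls in ((0, 34), (1, 33), (2, 33)):
                got = int((labels[val] == cls).sum())
                assert abs(got - n_cls / 5) <= 1

    def test_small_class_rejected(self):
        ds = synth_phantoms(PhantomParams(image_size=16, seed=SEED),
                            n_per_class=3)
        with pytest.raises(ValueError, match="folds"):
            stratified_kfold(ds, k=5)


class TestPhantoms:
    def test_balanced_counts(self):
        ds = synth_phantoms(PhantomParams(image_size=32, seed=SEED),
                            n_per_class=7)
        assert len(ds) == 21
        assert ds.class_counts == {"AD": 7, "CI": 7, "CN": 7}

    def test_seed_determinism(self):
        p = PhantomParams(image_size=32, seed=SEED)
        a = synth_phantoms(p, n_per_class=4)
        b = synth_phantoms(p, n_per_class=4)
        np.testing.assert_array_equal(a.images, b.images)

    def test_pixels_stay_in_unit_interval(self):
        ds = synth_phantoms(PhantomParams(image_size=32, pixel_noise_sd=0.3,
                                          seed=SEED), n_per_class=5)
        assert ds.images.min() >= 0 and ds.images.max() <= 1

    def test_ventricle_area_ordering_without_noise(self):
        """AD phantoms have visibly larger dark ventricles than CN."""
        ds = synth_phantoms(PhantomParams(pixel_noise_sd=0.0, seed=SEED),
                            n_per_class=20)
        dark = (ds.images[..., 0] < 0.2).mean(axis=(1, 2))
        ad = dark[ds.labels == 0].mean()
        cn = dark[ds.labels == 2].mean()
        assert ad > cn

    def test_threshold_classifier_separates_noiseless_phantoms(self):
        """Mean central intensity alone classifies noiseless phantoms well —
        the end-to-end training task is winnable by construction."""
        ds = synth_phantoms(PhantomParams(pixel_noise_sd=0.0, seed=SEED),
                            n_per_class=30)
        n = ds.images.shape[1]
        yy, xx = np.mgrid[0:n, 0:n]
        mask = (yy - n / 2) ** 2 + (xx - n / 2) ** 2 <= (0.16 * n) ** 2
        central = ds.images[:, :, :, 0][:, mask].mean(axis=1)
        # choose the two cut points from class means (ordered AD < CI < CN)
        means = [central[ds.labels == c].mean() for c in range(3)]
        cuts = [(means[0] + means[1]) / 2, (means[1] + means[2]) / 2]
        pred = np.digitize(central, cuts)
        assert (pred == ds.labels).mean() > 0.8

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            PhantomParams(ventricle_radius={"AD": 5.0, "CI": 7.0, "CN": 9.0})
        with pytest.raises(ValueError):
            synth_phantoms(PhantomParams(), n_per_class=0)
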