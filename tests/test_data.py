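"""Dataset scanning, balancing, augmentation, phantoms and splitting."""

import numpy as np
import pytest

from neurostage.data import (
    AugmentationConfig,
    BalancePlan,
    DatasetManifest,
    PhantomConfig,
    augment_to_target,
    derive_seed,
    generate_phantom_dataset,
    load_image,
    phantom_image,
    save_image,
    scan_dataset,
    select_utilized,
    stratified_split,
)
from neurostage.exceptions import DataError, ParameterError


@pytest.fixture
def image_tree(tmp_path, rng):
    for label in ("AD", "CN"):
        d = tmp_path / label
        d.mkdir()
        for i in range(3):
            save_image(rng.uniform(size=(8, 8)), d / f"img{i}.png")
    return tmp_path


class TestScan:
    def test_counts_and_order(self, image_tree):
        manifest = scan_dataset(image_tree)
        assert manifest.classes == ["AD", "CN"]
        assert manifest.counts == {"AD": 3, "CN": 3}

    def test_non_image_files_skipped(self, image_tree, caplog):
        (image_tree / "AD" / "notes.txt").write_text("not an image")
        with caplog.at_level("WARNING"):
            manifest = scan_dataset(image_tree)
        assert manifest.counts["AD"] == 3
        assert any("notes.txt" in rec.message for rec in caplog.records)

    def test_rescan_is_identical(self, image_tree):
        a, b = scan_dataset(image_tree), scan_dataset(image_tree)
        assert a.files == b.files

    def test_empty_class_rejected(self, image_tree):
        (image_tree / "EMCI").mkdir()
        with pytest.raises(DataError, match="EMCI"):
            scan_dataset(image_tree)


def _dummy_manifest(counts: dict) -> DatasetManifest:
    from pathlib import Path

    return DatasetManifest(
        classes=list(counts),
        files={
            label: [Path(f"{label}/img{i:05d}.png") for i in range(n)]
            for label, n in counts.items()
        },
    )


class TestSelection:
    def test_large_class_capped(self):
        manifest = _dummy_manifest({"AD": 8346, "EMCI": 480})
        out = select_utilized(manifest, BalancePlan(per_class_cap=500, seed=1))
        assert out.counts == {"AD": 500, "EMCI": 480}

    def test_selection_has_no_duplicates(self):
        manifest = _dummy_manifest({"AD": 1000})
        out = select_utilized(manifest, BalancePlan(per_class_cap=500, seed=2))
        assert len(set(out.files["AD"])) == 500
        assert set(out.files["AD"]) <= set(manifest.files["AD"])

    def test_seeded_determinism(self):
        manifest = _dummy_manifest({"AD": 1000})
        a = select_utilized(manifest, BalancePlan(per_class_cap=100, seed=3))
        b = select_utilized(manifest, BalancePlan(per_class_cap=100, seed=3))
        assert a.files == b.files

    def test_zero_cap_rejected(self):
        with pytest.raises(ParameterError):
            BalancePlan(per_class_cap=0)


class TestAugmentation:
    @pytest.fixture
    def sources(self, tmp_path, rng):
        src = tmp_path / "src"
        src.mkdir()
        paths = []
        for i in range(12):
            p = src / f"s{i}.png"
            save_image(rng.uniform(size=(16, 16)), p)
            paths.append(p)
        return paths

    def test_expansion_to_target(self, sources, tmp_path):
        out = augment_to_target(sources, 36, AugmentationConfig(seed=0), tmp_path / "aug")
        assert len(out) == 36
        assert out[:12] == sources  # originals retained untouched

    def test_target_equal_to_count_is_noop(self, sources, tmp_path):
        assert augment_to_target(sources, 12, AugmentationConfig(seed=0)) == sources

    def test_filenames_encode_source_and_op(self, sources, tmp_path):
        out = augment_to_target(sources, 20, AugmentationConfig(seed=0), tmp_path / "aug")
        for p in out[12:]:
            assert "__aug" in p.name
            assert any(p.name.startswith(s.stem) for s in sources)

    def test_augmented_pixels_differ_from_source(self, sources, tmp_path):
        out = augment_to_target(sources, 24, AugmentationConfig(seed=0), tmp_path / "aug")
        by_stem = {p.stem: p for p in sources}
        for p in out[12:]:
            src_stem = p.name.split("__aug")[0]
            assert not np.array_equal(load_image(p), load_image(by_stem[src_stem]))

    def test_seeded_rerun_identical(self, sources, tmp_path):
        a = augment_to_target(sources, 30, AugmentationConfig(seed=4), tmp_path / "a")
        b = augment_to_target(sources, 30, AugmentationConfig(seed=4), tmp_path / "b")
        assert [p.name for p in a] == [p.name for p in b]
        for pa, pb in zip(a[12:], b[12:]):
            assert np.array_equal(load_image(pa), load_image(pb))

    def test_empty_source_rejected(self, tmp_path):
        with pytest.raises(DataError):
            augment_to_target([], 10, AugmentationConfig(), tmp_path)

    def test_target_below_count_rejected(self, sources):
        with pytest.raises(ParameterError):
            augment_to_target(sources, 5, AugmentationConfig())


class TestPhantoms:
    def test_manifest_counts(self, small_phantom_tree):
        _, cfg, manifest = small_phantom_tree
        assert manifest.total == 60
        assert all(c == 12 for c in manifest.counts.values())
        assert manifest.classes == ["CN", "EMCI", "MCI", "LMCI", "AD"]

    def test_two_seeds_differ_pixelwise(self, tmp_path):
        cfg_a = PhantomConfig(n_classes=2, per_class=2, image_size=(32, 32), seed=1)
        cfg_b = PhantomConfig(n_classes=2, per_class=2, image_size=(32, 32), seed=2)
        ma = generate_phantom_dataset(cfg_a, tmp_path / "a")
        mb = generate_phantom_dataset(cfg_b, tmp_path / "b")
        assert ma.counts == mb.counts
        pa = load_image(ma.files["grade0"][0])
        pb = load_image(mb.files["grade0"][0])
        assert not np.array_equal(pa, pb)

    def test_noise_ablation_keeps_geometry_jitter(self):
        cfg = PhantomConfig(n_classes=2, per_class=2, image_size=(32, 32),
                            noise_sd=0.0, seed=3)
        rng = np.random.default_rng(0)
        a = phantom_image(0, cfg, rng)
        b = phantom_image(0, cfg, rng)
        assert not np.array_equal(a, b)  # jitter still varies within class

    def test_classes_linearly_separable_in_summary_features(self, small_phantom_tree):
        from scipy.ndimage import binary_fill_holes

        _, cfg, manifest = small_phantom_tree
        intensity, vent_area = {}, {}
        for label in manifest.classes:
            ints, areas = [], []
            for p in manifest.files[label]:
                img = load_image(p)
                interior = binary_fill_holes(img > 0.2)
                ints.append(img[interior].mean())
                areas.append(((img < 0.15) & interior).sum())
            intensity[label] = (min(ints), max(ints))
            vent_area[label] = (min(areas), max(areas))
        # per-class intensity intervals are disjoint and monotone decreasing
        # with grade, which implies linear separability of the 2-feature summary
        for worse, better in zip(manifest.classes[1:], manifest.classes[:-1]):
            assert intensity[worse][1] < intensity[better][0]
            assert np.mean(vent_area[worse]) > np.mean(vent_area[better])


class TestSplit:
    def test_per_class_proportions(self, small_phantom_tree):
        _, _, manifest = small_phantom_tree
        train, test = stratified_split(manifest, (0.75, 0.25), seed=1)
        for label in manifest.classes:
            assert len(train.files[label]) == 9
            assert len(test.files[label]) == 3
            assert set(train.files[label]).isdisjoint(test.files[label])

    def test_seeded_determinism(self, small_phantom_tree):
        _, _, manifest = small_phantom_tree
        a = stratified_split(manifest, (0.8, 0.2), seed=5)
        b = stratified_split(manifest, (0.8, 0.2), seed=5)
        assert a[0].files == b[0].files and a[1].files == b[1].files

    def test_degenerate_fractions_rejected(self, small_phantom_tree):
        _, _, manifest = small_phantom_tree
        with pytest.raises(ParameterError):
            stratified_split(manifest, (1.0, 0.0), seed=0)

    def test_tiny_class_rejected(self):
        manifest = _dummy_manifest({"AD": 1, "CN": 5})
        with pytest.raises(DataError):
            stratified_split(manifest, (0.8, 0.2), seed=0)


def test_manifest_csv_roundtrip(tmp_path, small_phantom_tree):
    _, _, manifest = small_phantom_tree
    manifest.to_csv(tmp_path / "m.csv")
    loaded = DatasetManifest.from_csv(tmp_path / "m.csv")
    assert loaded.classes == manifest.classes
    assert loaded.counts == manifest.counts


def test_derive_seed_stable_and_bounded():
    assert derive_seed(1, "split") == derive_seed(1, "split")
    assert derive_seed(1, "split") != derive_seed(1, "balance")
    assert 0 <= derive_seed(2**40, "x") < 2**31
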