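import numpy as np
import pandas as pd
import pytest

from hchsnet.augment import (
    AugmentationPolicy,
    apply_transform,
    augment_to_target,
    check_no_leakage,
    stratified_patient_split,
)

# original class counts of the six-class clinical dataset
CLASS_COUNTS = {"ACK": 730, "BCC": 845, "MEL": 52, "NEV": 244, "SCC": 192, "SEK": 235}


def _index_from_counts(counts):
    rows = []
    for label, n in counts.items():
        for i in range(n):
            rows.append(
                dict(image_id=f"{label}_{i:04d}", patient_id=f"p_{label}_{i // 2}",
                     label=label, origin="original", parent_image_id=None)
            )
    return pd.DataFrame(rows)


class TestStratifiedPatientSplit:
    def test_exact_divisibility_gives_two_test_patients(self):
        idx = pd.DataFrame(
            [dict(image_id=f"i{p}", patient_id=f"p{p}", label="A",
                  origin="original", parent_image_id=None) for p in range(10)]
        )
        split = stratified_patient_split(idx, test_fraction=0.2, seed=0)
        assert len(split.test_ids) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_patient_sets_disjoint(self, toy_manifest, seed):
        split = stratified_patient_split(toy_manifest, seed=seed)
        train_p = set(toy_manifest[toy_manifest.image_id.isin(split.train_ids)].patient_id)
        test_p = set(toy_manifest[toy_manifest.image_id.isin(split.test_ids)].patient_id)
        assert not train_p & test_p

    def test_multi_image_patients_stay_on_one_side(self, toy_manifest):
        # 5 patients x 3 images: exhaustively scan every patient
        split = stratified_patient_split(toy_manifest, seed=3)
        side = {i: "train" for i in split.train_ids}
        side.update({i: "test" for i in split.test_ids})
        for _, group in toy_manifest.groupby("patient_id"):
            assert len({side[i] for i in group.image_id}) == 1

    def test_single_patient_class_goes_to_train_with_warning(self, caplog):
        idx = pd.DataFrame(
            [dict(image_id=f"a{i}", patient_id=f"pa{i}", label="A",
                  origin="original", parent_image_id=None) for i in range(8)]
            + [dict(image_id="b0", patient_id="pb0", label="B",
                    origin="original", parent_image_id=None)]
        )
        with caplog.at_level("WARNING"):
            split = stratified_patient_split(idx, seed=0)
        assert "b0" in split.train_ids

    def test_class_proportions_near_target(self):
        idx = _index_from_counts(CLASS_COUNTS)
        split = stratified_patient_split(idx, test_fraction=0.2, seed=0)
        test = idx[idx.image_id.isin(set(split.test_ids))]
        for label, n in CLASS_COUNTS.items():
            frac = (test.label == label).sum() / n
            assert abs(frac - 0.2) < 0.05

    def test_augmented_records_rejected(self, toy_manifest):
        bad = toy_manifest.copy()
        bad.loc[0, "origin"] = "augmented"
        with pytest.raises(ValueError):
            stratified_patient_split(bad)


class TestAugmentToTarget:
    def test_clinical_class_counts_balance_to_fifteen_thousand(self):
        idx = _index_from_counts(CLASS_COUNTS)
        out = augment_to_target(idx, images=None, target_per_class=2500, seed=42)
        counts = out.label.value_counts()
        assert (counts == 2500).all()
        assert len(out) == 15_000

    def test_class_already_at_target_gets_no_replicas(self):
        idx = _index_from_counts({"A": 10, "B": 4})
        out = augment_to_target(idx, images=None, target_per_class=10, seed=0)
        assert (out[out.label == "A"].origin == "original").all()
        assert (out[out.label == "B"].origin == "augmented").sum() == 6

    def test_replicas_cycle_parents_uniformly(self):
        idx = _index_from_counts({"A": 4})
        out = augment_to_target(idx, images=None, target_per_class=14, seed=0)
        aug = out[out.origin == "augmented"]
        per_parent = aug.parent_image_id.value_counts()
        assert per_parent.max() - per_parent.min() <= 1

    def test_same_seed_regenerates_identical_images(self, rng):
        idx = _index_from_counts({"A": 3})
        imgs = {f"A_{i:04d}": rng.integers(0, 256, (32, 32, 3)).astype(float)
                for i in range(3)}
        a, b = dict(imgs), dict(imgs)
        augment_to_target(idx, images=a, target_per_class=9, seed=11)
        augment_to_target(idx, images=b, target_per_class=9, seed=11)
        assert set(a) == set(b)
        for k in a:
            assert np.array_equal(a[k], b[k])

    def test_different_seed_changes_images(self, rng):
        idx = _index_from_counts({"A": 3})
        a = {f"A_{i:04d}": rng.integers(0, 256, (32, 32, 3)).astype(float)
             for i in range(3)}
        b = dict(a)
        augment_to_target(idx, images=a, target_per_class=6, seed=1)
        augment_to_target(idx, images=b, target_per_class=6, seed=2)
        changed = [k for k in a if k not in b or not np.array_equal(a[k], b[k])]
        assert changed

    def test_empty_class_raises_naming_it(self):
        idx = _index_from_counts({"A": 3})
        idx.loc[:, "origin"] = "augmented"
        with pytest.raises(ValueError, match="A"):
            augment_to_target(idx, images=None, target_per_class=5)


class TestApplyTransform:
    def _identity_policy(self):
        return AugmentationPolicy(
            hflip_p=0.0, vflip_p=0.0, rotation_deg=(0.0, 0.0),
            brightness_range=(1.0, 1.0), affine_p=0.0,
        )

    def test_degenerate_policy_is_identity(self, rng):
        img = rng.integers(0, 256, (32, 32, 3)).astype(float)
        out = apply_transform(img, self._identity_policy(), np.random.default_rng(0))
        assert np.allclose(out, img)

    def test_horizontal_flip_is_an_involution(self, rng):
        img = rng.integers(0, 256, (16, 16, 3)).astype(float)
        pol = self._identity_policy()
        pol.hflip_p = 1.0
        once = apply_transform(img, pol, np.random.default_rng(0))
        twice = apply_transform(once, pol, np.random.default_rng(0))
        assert np.allclose(twice, img)

    def test_brightness_is_multiplicative_and_clamped(self):
        pol = self._identity_policy()
        pol.brightness_range = (1.2, 1.2)
        img = np.full((8, 8, 3), 100.0)
        out = apply_transform(img, pol, np.random.default_rng(0))
        assert np.allclose(out, 120.0)
        bright = np.full((8, 8, 3), 240.0)
        assert apply_transform(bright, pol, np.random.default_rng(0)).max() <= 255.0

    def test_output_shape_preserved_under_full_policy(self, rng):
        img = rng.integers(0, 256, (224, 224, 3)).astype(float)
        out = apply_transform(img, AugmentationPolicy(), np.random.default_rng(5))
        assert out.shape == (224, 224, 3)
        assert out.min() >= 0 and out.max() <= 255

    def test_invalid_policy_rejected(self):
        with pytest.raises(ValueError):
            AugmentationPolicy(hflip_p=1.5)
        with pytest.raises(ValueError):
            AugmentationPolicy(brightness_range=(1.2, 0.8))


class TestLeakageScan:
    def test_clean_pipeline_passes_scan(self, toy_manifest):
        split = stratified_patient_split(toy_manifest, seed=1)
        train = toy_manifest[toy_manifest.image_id.isin(set(split.train_ids))]
        out = augment_to_target(train.reset_index(drop=True), images=None,
                                target_per_class=6, seed=1)
        full = pd.concat(
            [out, toy_manifest[toy_manifest.image_id.isin(set(split.test_ids))]],
            ignore_index=True,
        )
        check_no_leakage(full, split)

    def test_scan_catches_augmented_record_in_test(self, toy_manifest):
        split = stratified_patient_split(toy_manifest, seed=1)
        bad = toy_manifest.copy()
        victim = split.test_ids[0]
        bad.loc[bad.image_id == victim, "origin"] = "augmented"
        with pytest.raises(AssertionError):
            check_no_leakage(bad, split)
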