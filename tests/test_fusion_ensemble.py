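import numpy as np
import pandas as pd
import pytest

from hchsnet.ensemble import (
    BoosterConfig,
    LesionEnsembleModel,
    LesionEnsembleResults,
    default_configs,
    run_ablation,
)
from hchsnet.features import FEATURE_BLOCKS, feature_names, fuse


class TestFuse:
    def test_full_fusion_is_128_dimensional(self):
        out = fuse(np.zeros(96), np.zeros(13), np.zeros(7), np.zeros(12))
        assert out.shape == (128,)

    def test_visual_only_is_116_dimensional(self):
        assert fuse(np.ones(96), np.ones(13), np.ones(7)).shape == (116,)

    def test_zero_blocks_give_zero_vector(self):
        assert np.all(fuse(np.zeros(96), np.zeros(13), np.zeros(7), np.zeros(12)) == 0)

    def test_wrong_block_length_names_the_block(self):
        with pytest.raises(ValueError, match="texture"):
            fuse(np.zeros(96), np.zeros(12), np.zeros(7), np.zeros(12))

    def test_block_boundaries(self):
        color = np.full(96, 1.0)
        tex = np.full(13, 2.0)
        shp = np.full(7, 3.0)
        meta = np.full(12, 4.0)
        out = fuse(color, tex, shp, meta)
        assert np.all(out[:96] == 1) and np.all(out[96:109] == 2)
        assert np.all(out[109:116] == 3) and np.all(out[116:] == 4)

    def test_feature_name_blocks_align(self):
        names = feature_names("chsm")
        assert len(names) == len(FEATURE_BLOCKS) == 128
        assert names[0].startswith("color")
        assert names[96].startswith("haralick")
        assert names[109].startswith("hu")
        assert names[116].startswith("meta")


def _gaussian_classes(rng, n_per_class, n_classes=6, n_features=20, sep=8.0):
    X, y = [], []
    for k in range(n_classes):
        mu = np.zeros(n_features)
        mu[k % n_features] = sep
        X.append(rng.normal(mu, 1.0, size=(n_per_class, n_features)))
        y += [f"C{k}"] * n_per_class
    return np.vstack(X), np.array(y)


@pytest.fixture(scope="module")
def fitted_six_class():
    rng = np.random.default_rng(0)
    X, y = _gaussian_classes(rng, 60)
    Xte, yte = _gaussian_classes(np.random.default_rng(1), 20)
    model = LesionEnsembleModel(X, y, configs=default_configs(seed=0, iterations=60))
    return model, model.fit(), Xte, yte


class TestTrainEnsemble:
    def test_linearly_separable_two_class_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(-5, 1, (100, 4)), rng.normal(5, 1, (100, 4))])
        y = np.array(["neg"] * 100 + ["pos"] * 100)
        res = LesionEnsembleModel(
            X, y, configs=default_configs(seed=0, iterations=50)
        ).fit()
        assert (res.predict(X) == y).all()

    def test_well_separated_six_class_holdout_accuracy(self, fitted_six_class):
        _, res, Xte, yte = fitted_six_class
        acc = (res.predict(Xte) == yte).mean()
        assert acc >= 0.95

    def test_refit_with_same_seeds_is_deterministic(self, fitted_six_class):
        model, res, Xte, _ = fitted_six_class
        res2 = LesionEnsembleModel(
            model.X, model.y, configs=default_configs(seed=0, iterations=60)
        ).fit()
        assert np.array_equal(res.predict_proba(Xte), res2.predict_proba(Xte))

    def test_single_class_input_rejected(self):
        with pytest.raises(ValueError):
            LesionEnsembleModel(np.zeros((5, 3)), ["A"] * 5)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BoosterConfig(family="random-forest")
        with pytest.raises(ValueError):
            BoosterConfig(iterations=0)


class TestPrediction:
    def test_ensemble_probability_is_member_mean(self, fitted_six_class):
        _, res, Xte, _ = fitted_six_class
        members = res.member_proba(Xte[:5])
        assert np.allclose(res.predict_proba(Xte[:5]), np.mean(members, axis=0))

    def test_probabilities_lie_on_simplex(self, fitted_six_class):
        _, res, Xte, _ = fitted_six_class
        p = res.predict_proba(Xte)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_prediction_equals_per_row(self, fitted_six_class):
        _, res, Xte, _ = fitted_six_class
        batch = res.predict(Xte[:8])
        single = np.concatenate([res.predict(row) for row in Xte[:8]])
        assert np.array_equal(batch, single)

    def test_schema_mismatch_raises(self, fitted_six_class):
        _, res, _, _ = fitted_six_class
        with pytest.raises(ValueError):
            res.predict(np.zeros((2, 7)))
        bad = pd.DataFrame(np.zeros((2, 20)), columns=[f"z{i}" for i in range(20)])
        with pytest.raises(ValueError):
            res.predict_proba(bad)

    def test_argmax_and_tie_break_to_lowest_index(self):
        # three identical distributions average to themselves; ties break low
        probs = np.array([[0.5, 0.3, 0.2], [0.4, 0.4, 0.2]])
        best = probs.argmax(axis=1)
        assert best.tolist() == [0, 0]

    def test_hard_vote_majority(self):
        rng = np.random.default_rng(3)
        X, y = _gaussian_classes(rng, 40, n_classes=3)
        res = LesionEnsembleModel(
            X, y, vote="hard", configs=default_configs(seed=0, iterations=40)
        ).fit()
        assert (res.predict(X) == y).mean() > 0.99


class TestRoundTrip:
    def test_save_load_preserves_predictions_exactly(self, fitted_six_class, tmp_path):
        _, res, Xte, _ = fitted_six_class
        before = res.predict_proba(Xte)
        res.save(tmp_path / "bundle")
        loaded = LesionEnsembleResults.load(tmp_path / "bundle")
        after = loaded.predict_proba(Xte)
        assert np.allclose(before, after, atol=1e-12)
        assert np.array_equal(res.predict(Xte), loaded.predict(Xte))
        assert loaded.label_order == res.label_order


class TestFeatureImportance:
    def test_single_informative_feature_ranks_first(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(300, 10))
        y = np.where(X[:, 0] > 0, "pos", "neg")
        res = LesionEnsembleModel(
            X, y, configs=default_configs(seed=0, iterations=40)
        ).fit()
        imp = res.feature_importance()
        assert imp.iloc[0]["feature"] == "x0"
        assert (imp.importance >= 0).all()

    def test_ranking_deterministic_under_fixed_seed(self, fitted_six_class):
        _, res, _, _ = fitted_six_class
        a = res.feature_importance()
        b = res.feature_importance()
        assert a.feature.tolist() == b.feature.tolist()


class TestSoftVotingSanity:
    def test_ensemble_tracks_best_member_on_average(self):
        # soft voting should not trail the weakest member by more than a
        # small margin, averaged over seeds
        gaps = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X, y = _gaussian_classes(rng, 30, n_classes=4, sep=2.0)
            Xte, yte = _gaussian_classes(np.random.default_rng(200 + seed), 30,
                                         n_classes=4, sep=2.0)
            res = LesionEnsembleModel(
                X, y, configs=default_configs(seed=seed, iterations=30)
            ).fit()
            member_acc = [
                np.mean(np.array([res.label_order[k] for k in p.argmax(axis=1)]) == yte)
                for p in res.member_proba(Xte)
            ]
            ens_acc = (res.predict(Xte) == yte).mean()
            gaps.append(ens_acc - min(member_acc))
        assert np.mean(gaps) >= -0.02


class TestAblationHarness:
    def test_all_block_subsets_train_and_report(self):
        rng = np.random.default_rng(5)
        cols = feature_names("chsm")
        n = 40
        X = pd.DataFrame(rng.normal(size=(n * 2, 128)), columns=cols)
        # make one color column and one metadata column informative
        y = np.array(["A"] * n + ["B"] * n)
        X.loc[:, "colorH_00"] += (y == "A") * 3.0
        X.loc[:, "meta_age_z"] += (y == "B") * 3.0
        table = run_ablation(X.iloc[::2], y[::2], X.iloc[1::2], y[1::2],
                             seed=0, iterations=20)
        assert set(table.blocks) == {"s", "h", "hs", "c", "cs", "ch", "chs", "chsm"}
        assert table.n_features.tolist() == [7, 13, 20, 96, 103, 109, 116, 128]
        assert {"accuracy", "macro_f1", "kappa", "mcc"} <= set(table.columns)
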