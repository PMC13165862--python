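"""Trial-grouped splitting, randomized search, and per-target ensembles."""

import numpy as np
import pytest

from cutkin.features import FEATURE_NAMES, FeatureMatrix
from cutkin.modeling import (
    DEFAULT_HYPERPARAMETERS,
    Dataset,
    HyperparamSpace,
    _cv_mean_r2,
    _cv_scores_shared,
    feature_importances,
    group_split,
    predict_waveforms,
    random_search,
    train_target_model,
)
from cutkin.preprocess import MOMENT_NAMES, TARGET_NAMES, KineticTargets
from cutkin.validation import r_squared


def make_synthetic_dataset(n_trials, rng, target_fn=None, noise=0.0):
    """Trials with smooth random feature curves; target defaults to a smooth
    function of two features (acc_ap, acc_v)."""
    trials = []
    phase = np.linspace(0, 1, 101)
    for i in range(n_trials):
        values = np.empty((101, 12))
        for j in range(12):
            a, b, ph = rng.uniform(0.5, 2.0), rng.uniform(1, 3), rng.uniform(0, 2 * np.pi)
            values[:, j] = a * np.sin(2 * np.pi * b * phase + ph)
        fm = FeatureMatrix(values=values, participant_id=f"P{i // 5:02d}", trial_id=f"T{i % 5}")
        if target_fn is None:
            y = 0.8 * fm.column("acc_ap") + 0.3 * fm.column("acc_v") ** 2
        else:
            y = target_fn(fm)
        y = y + rng.normal(0, noise, 101)
        kt = KineticTargets(
            vgrf_bw=y,
            moments=np.tile(y[:, None], (1, 6)),
            participant_id=fm.participant_id,
            trial_id=fm.trial_id,
        )
        trials.append((fm, kt))
    return Dataset(trials)


class TestGroupSplit:
    def test_sixtyfive_trials_split_13_52(self):
        rng = np.random.default_rng(0)
        ds = make_synthetic_dataset(65, rng)
        train, test = group_split(ds, 0.2, seed=1)
        assert len(test) == 13 and len(train) == 52
        assert not set(train.groups) & set(test.groups)

    def test_zero_fraction_rejected(self):
        ds = make_synthetic_dataset(10, np.random.default_rng(0))
        with pytest.raises(ValueError, match="non-empty"):
            group_split(ds, 0.0, seed=0)

    def test_single_trial_rejected(self):
        ds = make_synthetic_dataset(1, np.random.default_rng(0))
        with pytest.raises(ValueError, match="at least 2"):
            group_split(ds, 0.2, seed=0)

    def test_seed_determinism(self):
        ds = make_synthetic_dataset(20, np.random.default_rng(0))
        a1 = group_split(ds, 0.2, seed=5)[1].groups
        a2 = group_split(ds, 0.2, seed=5)[1].groups
        b = group_split(ds, 0.2, seed=6)[1].groups
        assert a1 == a2
        assert set(a1) != set(b)  # different seeds shuffle differently here

    def test_no_overlap_across_many_seeds(self):
        ds = make_synthetic_dataset(30, np.random.default_rng(1))
        for seed in range(20):
            train, test = group_split(ds, 0.2, seed=seed)
            assert not set(train.groups) & set(test.groups)


class TestHyperparamSpace:
    def test_counts(self):
        space = HyperparamSpace()
        assert space.n_combinations == 450
        assert len(space.combinations()) == 450

    def test_published_vgrf_configuration_validates(self):
        HyperparamSpace().validate(DEFAULT_HYPERPARAMETERS["vgrf"])

    def test_out_of_space_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            HyperparamSpace().validate(
                dict(n_estimators=123, max_depth=10, min_samples_split=2,
                     min_samples_leaf=2, max_features="log2")
            )


class TestRandomSearch:
    def test_single_point_space_returned_directly(self):
        ds = make_synthetic_dataset(6, np.random.default_rng(2))
        space = HyperparamSpace(
            n_estimators=(50,), max_depth=(5,), min_samples_split=(2,),
            min_samples_leaf=(1,), max_features=("sqrt",),
        )
        best = random_search(ds, space, "vgrf", n_iter=1, seed=0)
        assert best == space.combinations()[0]

    def test_n_iter_capped_with_warning(self):
        ds = make_synthetic_dataset(6, np.random.default_rng(2))
        space = HyperparamSpace(
            n_estimators=(20, 30), max_depth=(3,), min_samples_split=(2,),
            min_samples_leaf=(1,), max_features=("sqrt",),
        )
        with pytest.warns(UserWarning, match="capped"):
            best, results = random_search(
                ds, space, "vgrf", n_iter=99, seed=0, return_results=True
            )
        assert len(results) == 2

    def test_shared_prefix_scoring_equals_independent_fits(self):
        """The forest-sharing optimization is bit-identical to per-combo fits."""
        ds = make_synthetic_dataset(5, np.random.default_rng(3), noise=0.3)
        X, y, groups = ds.pooled("vgrf")
        combos = [
            dict(n_estimators=n, max_depth=d, min_samples_split=2,
                 min_samples_leaf=1, max_features="log2")
            for n in (20, 60) for d in (4, 8)
        ]
        shared = _cv_scores_shared(X, y, groups, combos, 5, seed=9, grouped=True)
        direct = [_cv_mean_r2(X, y, groups, c, 5, seed=9, grouped=True) for c in combos]
        assert np.array_equal(shared, np.array(direct))

    def test_small_space_matches_sklearn_grid_search(self):
        """Exhaustive draw equals GridSearchCV on the same folds and seeds."""
        from sklearn.ensemble import RandomForestRegressor
        from sklearn.model_selection import GridSearchCV, GroupKFold

        ds = make_synthetic_dataset(6, np.random.default_rng(4), noise=0.3)
        space = HyperparamSpace(
            n_estimators=(20, 40), max_depth=(3, 6), min_samples_split=(2,),
            min_samples_leaf=(1, 2), max_features=("log2",),
        )
        best = random_search(ds, space, "vgrf", n_iter=space.n_combinations, seed=7)
        X, y, groups = ds.pooled("vgrf")
        gs = GridSearchCV(
            RandomForestRegressor(random_state=7, n_jobs=1),
            {k: list(getattr(space, k)) for k in space.param_names},
            cv=GroupKFold(n_splits=5), scoring="r2",
        )
        gs.fit(X, y, groups=groups)
        # equivalence on the attained score (ties may reorder the argmax)
        our_score = _cv_mean_r2(X, y, groups, best, 5, seed=7, grouped=True)
        assert our_score == pytest.approx(gs.best_score_, abs=1e-12)


class TestTrainPredictImportances:
    def test_function_of_two_features_recovered(self):
        """Noise-free smooth target of 2 features -> held-out R2 > 0.95."""
        ds = make_synthetic_dataset(40, np.random.default_rng(5))
        train, test = group_split(ds, 0.2, seed=0)
        # all features considered at every split: isolates the recovery
        # question from split-candidate randomness
        params = dict(n_estimators=200, max_depth=15, min_samples_split=2,
                      min_samples_leaf=1, max_features=1.0)
        model = train_target_model(train, "vgrf", params, seed=0)
        preds = predict_waveforms(model, test)
        actual = np.concatenate([kt.vgrf_bw for _, kt in test.trials])
        predicted = np.concatenate([preds[fm.key] for fm, _ in test.trials])
        assert r_squared(actual, predicted) > 0.95

    def test_unknown_target_lists_valid_names(self):
        ds = make_synthetic_dataset(4, np.random.default_rng(6))
        with pytest.raises(KeyError, match="vgrf"):
            train_target_model(ds, "hip_sagittal", DEFAULT_HYPERPARAMETERS["vgrf"])

    def test_determinism_under_fixed_seed(self):
        ds = make_synthetic_dataset(10, np.random.default_rng(7), noise=0.2)
        params = DEFAULT_HYPERPARAMETERS["vgrf"]
        m1 = train_target_model(ds, "vgrf", params, seed=3)
        m2 = train_target_model(ds, "vgrf", params, seed=3)
        preds1 = predict_waveforms(m1, ds)
        preds2 = predict_waveforms(m2, ds)
        for k in preds1:
            assert np.array_equal(preds1[k], preds2[k])

    def test_prediction_contract(self):
        ds = make_synthetic_dataset(8, np.random.default_rng(8))
        model = train_target_model(ds, "vgrf", DEFAULT_HYPERPARAMETERS["vgrf"])
        preds = predict_waveforms(model, ds)
        assert all(v.shape == (101,) for v in preds.values())
        empty = Dataset([])
        assert predict_waveforms(model, empty) == {}

    def test_single_informative_feature_dominates_importances(self):
        rng = np.random.default_rng(9)
        ds = make_synthetic_dataset(
            30, rng, target_fn=lambda fm: 2.0 * fm.column("acc_ap"), noise=0.01
        )
        model = train_target_model(
            ds, "vgrf",
            dict(n_estimators=100, max_depth=10, min_samples_split=2,
                 min_samples_leaf=1, max_features="sqrt"),
            seed=0,
        )
        ranked = feature_importances(model)
        assert ranked[0][0] == "acc_ap"
        assert ranked[0][1] > 50.0
        assert sum(p for _, p in ranked) == pytest.approx(100.0, abs=1e-6)

    def test_pure_noise_target_importances_spread(self):
        rng = np.random.default_rng(10)
        ds = make_synthetic_dataset(
            30, rng, target_fn=lambda fm: np.zeros(101), noise=1.0
        )
        model = train_target_model(
            ds, "vgrf",
            dict(n_estimators=100, max_depth=10, min_samples_split=2,
                 min_samples_leaf=1, max_features="sqrt"),
            seed=0,
        )
        assert feature_importances(model)[0][1] < 25.0

    def test_model_persistence_round_trip(self, tmp_path):
        from cutkin.modeling import load_model, save_model

        ds = make_synthetic_dataset(6, np.random.default_rng(11), noise=0.2)
        model = train_target_model(ds, "ankle_sagittal", DEFAULT_HYPERPARAMETERS["ankle_sagittal"], seed=1)
        save_model(model, tmp_path)
        back = load_model(tmp_path, "ankle_sagittal")
        assert back.hyperparameters == model.hyperparameters
        assert np.allclose(back.importances, model.importances)
        preds_a = predict_waveforms(model, ds)
        preds_b = predict_waveforms(back, ds)
        for k in preds_a:
            assert np.array_equal(preds_a[k], preds_b[k])


def test_target_names_cover_all_moments():
    assert TARGET_NAMES == ("vgrf",) + MOMENT_NAMES
    assert len(TARGET_NAMES) == 7
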