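"""Trial-grouped splitting, randomized hyperparameter search, and per-target
random-forest waveform regression.

Each of the seven kinetic targets (vGRF + six joint moments) gets its own
bagged regression-tree ensemble.  Rows are individual normalized-time
samples (101 per trial, 12 features each); trials are the grouping unit
everywhere — the 80/20 split and the cross-validation folds never place rows
of one trial on both sides, preventing time-series leakage.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import GroupKFold, GroupShuffleSplit, KFold

from .features import FEATURE_NAMES, FeatureMatrix
from .preprocess import TARGET_NAMES, KineticTargets

logger = logging.getLogger(__name__)


@dataclass
class Dataset:
    """Aligned (FeatureMatrix, KineticTargets) pairs, one per trial."""

    trials: list[tuple[FeatureMatrix, KineticTargets]]

    def __post_init__(self) -> None:
        for fm, kt in self.trials:
            if (fm.participant_id, fm.trial_id) != (kt.participant_id, kt.trial_id):
                raise ValueError(
                    f"feature/target trial mismatch: {fm.key} vs {kt.key}"
                )

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def groups(self) -> list[str]:
        return [fm.key for fm, _ in self.trials]

    def pooled(self, target: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pool all trials into (X, y, row_groups) for one target."""
        if target not in TARGET_NAMES:
            raise KeyError(f"unknown target {target!r}; valid: {TARGET_NAMES}")
        X = np.vstack([fm.values for fm, _ in self.trials])
        y = np.concatenate([kt.waveform(target) for _, kt in self.trials])
        groups = np.repeat(self.groups, 101)
        return X, y, groups


@dataclass(frozen=True)
class HyperparamSpace:
    """The discrete random-forest search grid (450 combinations)."""

    n_estimators: tuple[int, ...] = (100, 150, 200, 250, 300)
    max_depth: tuple[int, ...] = (8, 10, 12, 15, 20)
    min_samples_split: tuple[int, ...] = (2, 5, 10)
    min_samples_leaf: tuple[int, ...] = (1, 2, 4)
    max_features: tuple[str, ...] = ("sqrt", "log2")

    @property
    def param_names(self) -> tuple[str, ...]:
        return (
            "n_estimators",
            "max_depth",
            "min_samples_split",
            "min_samples_leaf",
            "max_features",
        )

    def combinations(self) -> list[dict]:
        axes = [getattr(self, name) for name in self.param_names]
        return [
            dict(zip(self.param_names, combo))
            for combo in itertools.product(*axes)
        ]

    @property
    def n_combinations(self) -> int:
        return int(np.prod([len(getattr(self, n)) for n in self.param_names]))

    def validate(self, params: dict) -> None:
        for name in self.param_names:
            if name not in params:
                raise ValueError(f"missing hyperparameter {name!r}")
            if params[name] not in getattr(self, name):
                raise ValueError(
                    f"{name}={params[name]!r} outside the search space "
                    f"{getattr(self, name)}"
                )


#: per-target default hyperparameters (package defaults for the cutting task)
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "vgrf": dict(n_estimators=250, max_depth=10, min_samples_split=2,
                 min_samples_leaf=2, max_features="log2"),
    "ankle_sagittal": dict(n_estimators=100, max_depth=15, min_samples_split=10,
                           min_samples_leaf=1, max_features="log2"),
    "ankle_frontal": dict(n_estimators=100, max_depth=20, min_samples_split=10,
                          min_samples_leaf=4, max_features="log2"),
    "ankle_transverse": dict(n_estimators=200, max_depth=20, min_samples_split=10,
                             min_samples_leaf=4, max_features="log2"),
    "knee_sagittal": dict(n_estimators=200, max_depth=10, min_samples_split=5,
                          min_samples_leaf=2, max_features="log2"),
    "knee_frontal": dict(n_estimators=300, max_depth=15, min_samples_split=2,
                         min_samples_leaf=2, max_features="log2"),
    "knee_transverse": dict(n_estimators=100, max_depth=20, min_samples_split=10,
                            min_samples_leaf=2, max_features="log2"),
}


@dataclass
class TrainedModel:
    """A fitted per-target ensemble with its provenance."""

    target_name: str
    hyperparameters: dict
    ensemble: RandomForestRegressor
    importances: np.ndarray  # 12 weights summing to 1
    feature_names: tuple[str, ...] = FEATURE_NAMES
    seed: int = 0

    def manifest(self) -> dict:
        return {
            "target": self.target_name,
            "hyperparameters": self.hyperparameters,
            "seed": self.seed,
            "feature_schema": list(self.feature_names),
            "importances_pct": {
                name: round(float(w) * 100.0, 6)
                for name, w in zip(self.feature_names, self.importances)
            },
        }


def group_split(
    dataset: Dataset, test_fraction: float = 0.2, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Split whole trials into train/test with GroupShuffleSplit.

    The test side receives round(test_fraction * n_groups) whole trials; no
    trial contributes rows to both sides (asserted).
    """
    n_groups = len(dataset)
    if n_groups < 2:
        raise ValueError("need at least 2 trials to split")
    n_test = int(round(test_fraction * n_groups))
    if n_test < 1 or n_test >= n_groups:
        raise ValueError(
            f"test_fraction={test_fraction} yields {n_test} of {n_groups} "
            "test trials; both sides must be non-empty"
        )
    splitter = GroupShuffleSplit(n_splits=1, test_size=n_test, random_state=seed)
    idx = np.arange(n_groups)
    train_idx, test_idx = next(splitter.split(idx, groups=dataset.groups))
    train = Dataset([dataset.trials[i] for i in train_idx])
    test = Dataset([dataset.trials[i] for i in test_idx])
    overlap = set(train.groups) & set(test.groups)
    assert not overlap, f"leakage guard tripped: {overlap}"
    return train, test


def _make_forest(params: dict, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(random_state=seed, n_jobs=1, **params)


def _cv_splits(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, folds: int, grouped: bool
) -> list[tuple[np.ndarray, np.ndarray]]:
    if grouped:
        return list(GroupKFold(n_splits=folds).split(X, y, groups))
    return list(KFold(n_splits=folds).split(X, y))


_TREE_PARAM_NAMES = ("max_depth", "min_samples_split", "min_samples_leaf", "max_features")


def _cv_mean_r2(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    params: dict,
    folds: int,
    seed: int,
    grouped: bool,
) -> float:
    """Mean k-fold R² for one configuration (independent per-fold fits)."""
    scores = []
    for tr, te in _cv_splits(X, y, groups, folds, grouped):
        model = _make_forest(params, seed)
        model.fit(X[tr], y[tr])
        scores.append(r2_score(y[te], model.predict(X[te])))
    return float(np.mean(scores))


def _cv_scores_shared(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    combos: list[dict],
    folds: int,
    seed: int,
    grouped: bool,
) -> np.ndarray:
    """Mean k-fold R² for many configurations at once.

    Configurations sharing tree-shape parameters are scored from a single
    forest per fold: with a fixed random_state the first k trees of a larger
    forest are identical to a k-tree forest, so prefix averages of per-tree
    predictions reproduce the independent fits bit for bit (asserted in the
    test suite).  This makes exhaustive search over the n_estimators axis
    essentially free.
    """
    splits = _cv_splits(X, y, groups, folds, grouped)
    by_shape: dict[tuple, list[int]] = {}
    for i, c in enumerate(combos):
        by_shape.setdefault(tuple(c[k] for k in _TREE_PARAM_NAMES), []).append(i)
    scores = np.empty(len(combos))
    for shape, idxs in by_shape.items():
        ns = sorted({combos[i]["n_estimators"] for i in idxs})
        shape_params = dict(zip(_TREE_PARAM_NAMES, shape))
        fold_scores: dict[int, list[float]] = {n: [] for n in ns}
        for tr, te in splits:
            forest = RandomForestRegressor(
                n_estimators=max(ns), random_state=seed, n_jobs=1, **shape_params
            ).fit(X[tr], y[tr])
            # the low-level tree interface wants the same float32 view the
            # forest's own predict() would build
            X_te32 = np.ascontiguousarray(X[te], dtype=np.float32)
            cum = np.zeros(te.size)
            prefix_preds: dict[int, np.ndarray] = {}
            for j, tree in enumerate(forest.estimators_, start=1):
                cum += tree.tree_.predict(X_te32).ravel()
                if j in fold_scores:
                    prefix_preds[j] = cum / j
            for n in ns:
                fold_scores[n].append(r2_score(y[te], prefix_preds[n]))
        for i in idxs:
            scores[i] = np.mean(fold_scores[combos[i]["n_estimators"]])
    return scores


def random_search(
    train: Dataset,
    space: HyperparamSpace,
    target: str,
    n_iter: int = 50,
    folds: int = 5,
    seed: int = 0,
    grouped_cv: bool = True,
    return_results: bool = False,
):
    """Randomized hyperparameter search with k-fold CV on the training set.

    ``n_iter`` configurations are drawn uniformly without replacement from
    the discrete grid and scored by mean cross-validated R²; the argmax wins,
    ties broken by evaluation order.  CV folds are grouped by trial by
    default (set ``grouped_cv=False`` for plain shuffled folds).
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    combos = space.combinations()
    if n_iter > len(combos):
        warnings.warn(
            f"n_iter={n_iter} exceeds the {len(combos)} distinct "
            "combinations; capped at exhaustive search"
        )
        n_iter = len(combos)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))[:n_iter]
    drawn = [combos[int(i)] for i in order]
    if len(drawn) == 1:
        # single-point draw: nothing to compare, no CV needed
        if return_results:
            return dict(drawn[0]), [{**drawn[0], "mean_cv_r2": np.nan}]
        return dict(drawn[0])
    X, y, groups = train.pooled(target)
    scores = _cv_scores_shared(X, y, groups, drawn, folds, seed, grouped_cv)
    best = int(np.argmax(scores))  # argmax keeps the first-evaluated on ties
    results = [
        {**params, "mean_cv_r2": float(s)} for params, s in zip(drawn, scores)
    ]
    if return_results:
        return dict(drawn[best]), results
    return dict(drawn[best])


def train_target_model(
    train: Dataset, target: str, hyperparameters: dict, seed: int = 0
) -> TrainedModel:
    """Fit one random-forest ensemble for one kinetic target."""
    if target not in TARGET_NAMES:
        raise KeyError(f"unknown target {target!r}; valid: {TARGET_NAMES}")
    X, y, _ = train.pooled(target)
    model = _make_forest(hyperparameters, seed)
    model.fit(X, y)
    importances = model.feature_importances_
    total = importances.sum()
    if total <= 0:
        logger.warning(
            "target %r carried no impurity reduction (constant target?); "
            "importances flagged zero-information", target
        )
        importances = np.full(len(FEATURE_NAMES), 1.0 / len(FEATURE_NAMES))
    else:
        importances = importances / total
    return TrainedModel(
        target_name=target,
        hyperparameters=dict(hyperparameters),
        ensemble=model,
        importances=importances,
        seed=seed,
    )


def predict_waveforms(
    model: TrainedModel, test: Dataset
) -> dict[str, np.ndarray]:
    """Per-trial 101-point predicted waveforms, keyed by trial id."""
    out: dict[str, np.ndarray] = {}
    for fm, _ in test.trials:
        if tuple(fm.feature_names) != tuple(model.feature_names):
            missing = set(model.feature_names) - set(fm.feature_names)
            extra = set(fm.feature_names) - set(model.feature_names)
            raise ValueError(
                f"feature schema mismatch: missing={sorted(missing)} "
                f"extra={sorted(extra)}"
            )
        out[fm.key] = model.ensemble.predict(fm.values)
    return out


def feature_importances(model: TrainedModel) -> list[tuple[str, float]]:
    """MDI importances as percentages summing to 100, ranked descending."""
    pct = model.importances * 100.0
    order = np.argsort(pct)[::-1]
    return [(model.feature_names[i], float(pct[i])) for i in order]


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.ensemble, directory / f"{model.target_name}.joblib")
    manifest_path = directory / f"{model.target_name}.json"
    manifest_path.write_text(json.dumps(model.manifest(), indent=2))
    return manifest_path


def load_model(directory: str | Path, target: str) -> TrainedModel:
    directory = Path(directory)
    manifest = json.loads((directory / f"{target}.json").read_text())
    ensemble = joblib.load(directory / f"{target}.joblib")
    imp = np.array(
        [manifest["importances_pct"][n] for n in manifest["feature_schema"]]
    ) / 100.0
    return TrainedModel(
        target_name=manifest["target"],
        hyperparameters=manifest["hyperparameters"],
        ensemble=ensemble,
        importances=imp,
        feature_names=tuple(manifest["feature_schema"]),
        seed=manifest["seed"],
    )
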