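"""Supervised localization of virtual fish from simulated channel potentials.

A tree-ensemble regressor (25 trees, multi-output) maps the 7 channel
potentials to (x, y, sin, cos, length); its held-out coefficient of
determination and the spatial (Euclidean) error between true and predicted
position are the figures of merit used to rank electrode configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import ParameterSampler, cross_val_score, train_test_split
from sklearn.neural_network import MLPRegressor
from sklearn.utils.validation import check_is_fitted

from .field import LabeledFieldDataset, sample_fish, sample_placements
from .geometry import standard_setup

__all__ = [
    "DipoleLocalizer",
    "EvalReport",
    "train_localizer",
    "score_r2",
    "spatial_error",
    "compare_configurations",
    "DEFAULT_TUNING_GRID",
]

# hyperparameter grid sampled by the (budgeted) randomized search
DEFAULT_TUNING_GRID = {
    "max_depth": [None, 10, 20, 30],
    "min_samples_leaf": [1, 2, 4],
    "max_features": [1.0, 0.8, 0.6, 0.4],
    "bootstrap": [True, False],
}


class DipoleLocalizer(BaseEstimator, RegressorMixin):
    """Multi-output regressor from channel potentials to fish placement.

    Parameters
    ----------
    algorithm : {"tree_ensemble", "mlp_baseline"}
        Tree ensemble (random forest, default) or the single-hidden-layer
        perceptron baseline.
    n_trees : int
        Number of trees in the ensemble (default 25).
    tune_budget : int
        Number of hyperparameter candidates evaluated by cross-validated
        randomized search on the training data (default 25; 0 disables
        tuning).
    hidden_size : int
        Hidden-layer width for the MLP baseline (50, 100 or 200).
    max_iter : int
        Iteration cap for the MLP baseline.
    cv : int
        Cross-validation folds used during tuning.
    random_state : int
        Seed for the split-free parts: bootstrap, search sampling.
    """

    def __init__(self, algorithm="tree_ensemble", n_trees=25, tune_budget=25,
                 hidden_size=100, max_iter=10_000, cv=3, random_state=0):
        self.algorithm = algorithm
        self.n_trees = n_trees
        self.tune_budget = tune_budget
        self.hidden_size = hidden_size
        self.max_iter = max_iter
        self.cv = cv
        self.random_state = random_state

    def _base_model(self, **params):
        if self.algorithm == "tree_ensemble":
            return RandomForestRegressor(
                n_estimators=self.n_trees, random_state=self.random_state,
                **params)
        if self.algorithm == "mlp_baseline":
            return MLPRegressor(
                hidden_layer_sizes=(self.hidden_size,),
                max_iter=self.max_iter, random_state=self.random_state)
        raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, n_channels), y (n, n_targets)")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        self.n_candidates_ = 0
        best_params = {}
        if self.algorithm == "tree_ensemble" and self.tune_budget > 0:
            sampler = ParameterSampler(
                DEFAULT_TUNING_GRID, n_iter=self.tune_budget,
                random_state=self.random_state)
            best_score = -np.inf
            for params in sampler:
                self.n_candidates_ += 1
                score = cross_val_score(
                    self._base_model(**params), X, y, cv=self.cv).mean()
                if score > best_score:
                    best_score, best_params = score, params
        self.best_params_ = best_params
        self.model_ = self._base_model(**best_params).fit(X, y)
        self.n_features_in_ = X.shape[1]
        self.n_targets_ = y.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))

    def score(self, X, y):
        """Aggregate coefficient of determination 1 - u/v.

        u sums squared residuals over all samples and targets, v the squared
        deviations of the true values from their per-target means.
        """
        return score_r2(self, LabeledFieldDataset(
            np.asarray(X, float), np.asarray(y, float), seed=-1))


@dataclass
class EvalReport:
    """Held-out evaluation of a localizer."""

    r2_per_target: dict
    spatial_errors: np.ndarray
    median_error: float
    error_map: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def quartiles(self) -> tuple:
        return tuple(np.percentile(self.spatial_errors, [25, 75]))

    def to_json_dict(self) -> dict:
        return {
            "r2_per_target": {k: float(v) for k, v in self.r2_per_target.items()},
            "median_error_cm": float(self.median_error),
            "q1_cm": float(self.quartiles[0]),
            "q3_cm": float(self.quartiles[1]),
            "n": int(len(self.spatial_errors)),
        }


def train_localizer(data: LabeledFieldDataset, model: DipoleLocalizer | None = None,
                    train_fraction: float = 0.75, tune_budget: int = 25,
                    seed: int = 0):
    """Split, tune and fit a localizer; returns (model, test dataset).

    The split is seeded and disjoint; hyperparameter search (at most
    ``tune_budget`` candidates) uses cross-validation on the training split
    only.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    if len(data) < 4:
        raise ValueError("dataset too small to split")
    if model is None:
        model = DipoleLocalizer(tune_budget=tune_budget, random_state=seed)
    X_tr, X_te, y_tr, y_te = train_test_split(
        data.features, data.targets, train_size=train_fraction,
        random_state=seed, shuffle=True)
    model.fit(X_tr, y_tr)
    test = LabeledFieldDataset(X_te, y_te, seed=data.seed)
    return model, test


def score_r2(model, test: LabeledFieldDataset) -> float:
    """Coefficient of determination 1 - u/v on a held-out set.

    u = sum((true - predicted)^2), v = sum((true - mean(true))^2), both summed
    over every sample and target column.
    """
    if len(test) == 0:
        raise ValueError("empty test set")
    y = test.targets
    pred = model.predict(test.features)
    v = float(np.sum((y - y.mean(axis=0)) ** 2))
    if v == 0.0:
        raise ValueError("zero-variance targets: score undefined")
    u = float(np.sum((y - pred) ** 2))
    return 1.0 - u / v


def spatial_error(model, test: LabeledFieldDataset, map_threshold: float = 3.0,
                  cell_cm: float = 2.0, target_names=("x", "y", "sin", "cos",
                                                      "length")) -> EvalReport:
    """Per-sample Euclidean position error and a coarse map of bad cells.

    The error map bins the tank into ``cell_cm`` squares and keeps cells whose
    mean error exceeds ``map_threshold`` (default 3 cm).
    """
    y = test.targets
    pred = model.predict(test.features)
    errors = np.hypot(y[:, 0] - pred[:, 0], y[:, 1] - pred[:, 1])
    r2pt = {}
    for j, name in enumerate(target_names[: y.shape[1]]):
        v = float(np.sum((y[:, j] - y[:, j].mean()) ** 2))
        u = float(np.sum((y[:, j] - pred[:, j]) ** 2))
        r2pt[name] = 1.0 - u / v if v > 0 else np.nan
    ix = np.floor(y[:, 0] / cell_cm).astype(int)
    iy = np.floor(y[:, 1] / cell_cm).astype(int)
    df = pd.DataFrame({"ix": ix, "iy": iy, "error": errors})
    cells = df.groupby(["ix", "iy"], as_index=False)["error"].mean()
    bad = cells[cells["error"] > map_threshold].reset_index(drop=True)
    bad["x_cm"] = (bad["ix"] + 0.5) * cell_cm
    bad["y_cm"] = (bad["iy"] + 0.5) * cell_cm
    return EvalReport(
        r2_per_target=r2pt,
        spatial_errors=errors,
        median_error=float(np.median(errors)),
        error_map=bad,
    )


def compare_configurations(config_ids, n: int = 2500, seed: int = 0,
                           tune_budget: int = 0,
                           tank=None) -> pd.DataFrame:
    """Rank electrode configurations by held-out median spatial error.

    The identical random placement sample (positions, orientations, lengths)
    is reused for every configuration; only the electrode wiring changes.
    Returns one row per configuration, ranked ascending by median error.
    """
    config_ids = list(config_ids)
    if len(config_ids) < 2:
        raise ValueError("need at least 2 configurations to compare")
    base_tank, _ = standard_setup(config_ids[0], tank)
    fish = sample_fish(n, base_tank, seed=seed)
    rows = []
    for cid in config_ids:
        c_tank, config = standard_setup(cid, tank)
        data = sample_placements(n, c_tank, config, seed=seed, fish=fish)
        model, test = train_localizer(
            data, DipoleLocalizer(tune_budget=tune_budget, random_state=seed),
            seed=seed)
        report = spatial_error(model, test)
        q1, q3 = report.quartiles
        rows.append({
            "config_id": cid,
            "r2": score_r2(model, test),
            "median_error_cm": report.median_error,
            "q1_cm": q1,
            "q3_cm": q3,
        })
    table = pd.DataFrame(rows).sort_values(
        "median_error_cm", kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
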