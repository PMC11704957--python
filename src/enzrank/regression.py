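"""Few-shot fitness regression on pooled embeddings.

Three classical regressor families — k-nearest neighbors, support vector
regression (RBF kernel) and random forests — are tuned by exhaustive grid
search with seeded k-fold cross-validation scored on R^2, then refit on the
full training set. Evaluation reports both Spearman rank correlation (the
ranking statistic the workflow cares about) and R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

from .seqio import FitnessDataset

__all__ = [
    "RegressorSpec",
    "TrainedRanker",
    "EvaluationReport",
    "default_grid",
    "split_dataset",
    "grid_search_train",
    "predict",
    "spearman_rho",
    "coefficient_of_determination",
    "evaluate_model",
    "save_model",
    "load_model",
]

_FAMILIES = ("knn", "svr", "rfr")
_PERSIST_VERSION = 1


def default_grid(family: str) -> dict[str, list]:
    """Small exhaustive hyperparameter grids, reproducible at desk scale.

    The SVR gamma grid is expressed as multipliers of the scale heuristic
    ``1 / (n_features * Var(X))`` and resolved against the data at fit time.
    """
    if family == "knn":
        return {"n_neighbors": [1, 3, 5, 7, 11, 15], "metric": ["euclidean", "cosine"]}
    if family == "svr":
        return {"C": [0.1, 1.0, 10.0, 100.0], "gamma_scale": [0.1, 1.0, 10.0],
                "epsilon": [0.01, 0.1]}
    if family == "rfr":
        return {"n_estimators": [200, 500], "max_features": ["sqrt", 1 / 3],
                "min_samples_leaf": [1, 3]}
    raise ValueError(f"unknown regressor family {family!r}")


@dataclass
class RegressorSpec:
    """Which family to fit, over which grid, with which CV layout."""

    family: str
    grid: dict[str, list] | None = None
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}, got {self.family!r}")
        if self.grid is None:
            self.grid = default_grid(self.family)
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class TrainedRanker:
    """A fitted regressor plus the metadata needed to reuse it faithfully."""

    family: str
    chosen_hyperparameters: dict
    layer: int
    model: object
    train_ids: list[str]
    transform: str = "identity"
    seed: int = 0
    dim: int = 0
    cv_results: dict = field(default_factory=dict)


@dataclass(frozen=True)
class EvaluationReport:
    """Test-set performance: Spearman rho and coefficient of determination."""

    spearman_rho: float
    r_squared: float
    n_test: int
    split_seed: int = 0


def _as_matrix(X) -> np.ndarray:
    X = X.X if hasattr(X, "X") else X
    return np.asarray(X, dtype=float)


def split_dataset(
    dataset: FitnessDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[FitnessDataset, FitnessDataset]:
    """Seeded random train/test split (default 80/20).

    Train size is ``round(n * train_fraction)`` (half-up); the split is a
    disjoint, exhaustive partition and the same seed reproduces it exactly.
    """
    n = len(dataset)
    if n < 5:
        raise ValueError(f"need at least 5 examples to split, got {n}")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(np.floor(n * train_fraction + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return dataset.subset(sorted(perm[:n_train])), dataset.subset(sorted(perm[n_train:]))


def _build_estimator(family: str, params: Mapping, seed: int, X: np.ndarray):
    if family == "knn":
        return KNeighborsRegressor(**params)
    if family == "svr":
        params = dict(params)
        mult = params.pop("gamma_scale", None)
        if mult is not None:
            var = float(X.var())
            base = 1.0 / (X.shape[1] * var) if var > 0 else 1.0
            params["gamma"] = base * mult
        return SVR(kernel="rbf", **params)
    if family == "rfr":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    raise ValueError(f"unknown family {family!r}")


def grid_search_train(
    X,
    y: Sequence[float],
    spec: RegressorSpec,
    train_ids: Sequence[str] | None = None,
    layer: int = 0,
    transform: str = "identity",
) -> TrainedRanker:
    """Exhaustively tune one regressor family and refit on all the data.

    Every grid point is scored by mean out-of-fold R^2 on a fixed seeded
    k-fold partition; the best combination (ties broken by declaration order)
    is refit on the full ``(X, y)``. Deterministic given ``(X, y, spec)``.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of samples")
    n = X.shape[0]
    if n < spec.cv_folds:
        raise ValueError(f"{n} samples cannot fill {spec.cv_folds} CV folds")
    if n // spec.cv_folds < 2:
        raise ValueError("every CV fold needs at least 2 samples")

    if spec.family == "svr":
        # resolve the scale-heuristic gamma multipliers against this X
        var = float(X.var())
        base = 1.0 / (X.shape[1] * var) if var > 0 else 1.0
        grid = {
            ("gamma" if k == "gamma_scale" else k): (
                [base * m for m in v] if k == "gamma_scale" else list(v)
            )
            for k, v in spec.grid.items()
        }
        estimator = SVR(kernel="rbf")
    else:
        grid = {k: list(v) for k, v in spec.grid.items()}
        estimator = _build_estimator(spec.family, {}, spec.seed, X)

    cv = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(
        estimator, grid, scoring="r2", cv=cv, n_jobs=1, refit=True
    )
    if np.ptp(y) == 0:
        # degenerate constant target: R^2 undefined, fit the first grid point
        params = {k: v[0] for k, v in grid.items()}
        if spec.family == "svr":
            model = SVR(kernel="rbf", **params)
        else:
            model = _build_estimator(spec.family, params, spec.seed, X)
        model.fit(X, y)
        chosen, cv_results = params, {}
    else:
        search.fit(X, y)
        model = search.best_estimator_
        chosen = dict(search.best_params_)
        cv_results = {
            "mean_test_r2": search.cv_results_["mean_test_score"].tolist(),
            "params": [dict(p) for p in search.cv_results_["params"]],
            "best_index": int(search.best_index_),
        }
    return TrainedRanker(
        family=spec.family,
        chosen_hyperparameters=chosen,
        layer=layer,
        model=model,
        train_ids=list(train_ids) if train_ids is not None else [],
        transform=transform,
        seed=spec.seed,
        dim=X.shape[1],
        cv_results=cv_results,
    )


def predict(model: TrainedRanker, X) -> np.ndarray:
    """Predict (in transformed space), one finite value per row."""
    X = _as_matrix(X)
    if model.dim and X.shape[1] != model.dim:
        raise ValueError(
            f"feature dim {X.shape[1]} does not match training dim {model.dim}"
        )
    preds = np.asarray(model.model.predict(X), dtype=float)
    if not np.all(np.isfinite(preds)):
        raise ValueError("model produced non-finite predictions")
    return preds


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length 1-D arrays of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero rank variance")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def coefficient_of_determination(
    y_true: Sequence[float], y_pred: Sequence[float]
) -> float:
    """R^2 = 1 - SS_res / SS_tot about the mean of ``y_true``."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or len(y_true) < 2:
        raise ValueError("need two equal-length arrays of length >= 2")
    if np.ptp(y_true) == 0:
        raise ValueError("undefined R^2: zero variance in y_true")
    return float(r2_score(y_true, y_pred))


def evaluate_model(
    model: TrainedRanker, X_test, y_test: Sequence[float], split_seed: int = 0
) -> EvaluationReport:
    """Score a fitted ranker on a held-out partition."""
    preds = predict(model, X_test)
    return EvaluationReport(
        spearman_rho=spearman_rho(preds, y_test),
        r_squared=coefficient_of_determination(np.asarray(y_test, float), preds),
        n_test=len(preds),
        split_seed=split_seed,
    )


def save_model(model: TrainedRanker, path: str | Path) -> None:
    """Persist a trained ranker (versioned archive)."""
    joblib.dump({"version": _PERSIST_VERSION, "model": model}, path)


def load_model(path: str | Path) -> TrainedRanker:
    payload = joblib.load(path)
    if payload.get("version") != _PERSIST_VERSION:
        raise ValueError(
            f"incompatible model archive version {payload.get('version')!r}"
        )
    return payload["model"]
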