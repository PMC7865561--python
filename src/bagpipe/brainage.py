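"""Brain-age prediction: gradient-boosted tree regression of
chronological age on MRI-derived features, with repeated k-fold
cross-validation and nested grid search.

The learner is XGBoost with the study's settings (max depth 3, 180
estimators, learning rate 0.1) and no feature standardization — tree
ensembles are invariant to monotone transforms of single features.
Model validation follows the repeated scheme: k folds, ``reps``
independent shuffles, metrics (R², RMSE, MAE) recorded per held-out
fold and aggregated as mean ± SD over all k×reps fold records.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xgboost
from scipy import stats
from sklearn.model_selection import KFold
from xgboost import XGBRegressor

from .tables_io import FeatureTable

__all__ = [
    "Hyperparameters",
    "AgeModel",
    "CVResult",
    "CorrelationResult",
    "fit_age_model",
    "predict_age",
    "out_of_fold_predictions",
    "cross_validate",
    "nested_grid_search",
    "regression_metrics",
    "pearson_ci",
    "DEFAULT_GRID",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class Hyperparameters:
    max_depth: int = 3
    n_estimators: int = 180
    learning_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.max_depth <= 0 or self.n_estimators <= 0 or self.learning_rate <= 0:
            raise ValueError(f"hyperparameters must be positive: {self}")

    def to_dict(self) -> dict:
        return {
            "max_depth": self.max_depth,
            "n_estimators": self.n_estimators,
            "learning_rate": self.learning_rate,
        }


#: grid for nested search, centred on the study's chosen values
DEFAULT_GRID: dict[str, list] = {
    "max_depth": [2, 3, 4],
    "n_estimators": [90, 180, 360],
    "learning_rate": [0.05, 0.1, 0.2],
}


@dataclass
class AgeModel:
    """A fitted age-prediction model bound to its training feature names.

    Prediction requires the incoming table to carry exactly the training
    features (matched by name, order-insensitive)."""

    booster: XGBRegressor
    feature_names: list[str]
    hyper: Hyperparameters
    seed: int
    training_fingerprint: str

    def _align(self, features: FeatureTable) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in features.feature_names]
        if missing:
            raise ValueError(f"prediction table missing training features: {missing}")
        extra = [f for f in features.feature_names if f not in self.feature_names]
        if extra:
            raise ValueError(f"prediction table has unknown features: {extra}")
        order = [features.feature_names.index(f) for f in self.feature_names]
        return features.values[:, order]


def _fingerprint(values: np.ndarray, ages: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(values).tobytes())
    h.update(np.ascontiguousarray(ages).tobytes())
    return h.hexdigest()[:16]


def _make_regressor(hyper: Hyperparameters, seed: int) -> XGBRegressor:
    # hist + single thread keeps fits bit-reproducible for a given seed
    return XGBRegressor(
        max_depth=hyper.max_depth,
        n_estimators=hyper.n_estimators,
        learning_rate=hyper.learning_rate,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
    )


def fit_age_model(
    features: FeatureTable,
    ages: np.ndarray,
    hyper: Hyperparameters = Hyperparameters(),
    seed: int = 0,
) -> AgeModel:
    """Fit the boosted-tree age model; deterministic for a given seed."""
    ages = np.asarray(ages, dtype=float)
    if features.n_subjects < 2:
        raise ValueError("need at least 2 subjects to fit an age model")
    if len(ages) != features.n_subjects:
        raise ValueError(
            f"{len(ages)} ages for {features.n_subjects} subjects"
        )
    if not np.all(np.isfinite(ages)):
        raise ValueError("non-finite age values")
    reg = _make_regressor(hyper, seed)
    reg.fit(features.values, ages)
    return AgeModel(
        booster=reg,
        feature_names=list(features.feature_names),
        hyper=hyper,
        seed=seed,
        training_fingerprint=_fingerprint(features.values, ages),
    )


def predict_age(model: AgeModel, features: FeatureTable) -> np.ndarray:
    """Raw predicted ages, one per subject, in the input's subject order."""
    X = model._align(features)
    return model.booster.predict(X).astype(float)


@dataclass
class CVResult:
    """Per-fold metric records from repeated k-fold cross-validation."""

    k: int
    reps: int
    seed: int
    records: list[dict] = field(repr=False)  # rep, fold, r2, rmse, mae

    def __post_init__(self) -> None:
        if len(self.records) != self.k * self.reps:
            raise ValueError(
                f"{len(self.records)} fold records, expected {self.k * self.reps}"
            )

    def aggregate(self) -> dict[str, tuple[float, float]]:
        """Mean ± SD per metric over all k×reps fold records."""
        out = {}
        for metric in ("r2", "rmse", "mae"):
            vals = np.array([r[metric] for r in self.records])
            out[metric] = (float(vals.mean()), float(vals.std(ddof=1)))
        return out


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int
    level: float = 0.95


def regression_metrics(predicted: np.ndarray, ages: np.ndarray) -> tuple[float, float, float]:
    """(R², RMSE, MAE) of predictions against chronological age.

    R² = 1 − Σ(Y−Ω)² / Σ(Ω−mean Ω)²; undefined (error) for constant Ω.
    """
    y = np.asarray(predicted, dtype=float)
    omega = np.asarray(ages, dtype=float)
    if y.shape != omega.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("predictions and ages must be equal-length vectors (n >= 2)")
    sst = float(np.sum((omega - omega.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("R^2 undefined: chronological ages are constant")
    err = y - omega
    r2 = 1.0 - float(np.sum(err**2)) / sst
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    return r2, rmse, mae


def pearson_ci(
    predicted: np.ndarray, ages: np.ndarray, level: float = 0.95
) -> CorrelationResult:
    """Pearson r with a Fisher-z confidence interval (SE = 1/sqrt(n-3))."""
    y = np.asarray(predicted, dtype=float)
    omega = np.asarray(ages, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    r = float(stats.pearsonr(y, omega).statistic)
    if abs(r) >= 1.0 - 1e-15:
        return CorrelationResult(r=r, ci_low=r, ci_high=r, n=n, level=level)
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    return CorrelationResult(
        r=r,
        ci_low=math.tanh(z - zcrit * se),
        ci_high=math.tanh(z + zcrit * se),
        n=n,
        level=level,
    )


def _fold_splits(n: int, k: int, rep: int, seed: int):
    """Folds for repetition ``rep``: an independent shuffle seeded seed+rep."""
    return KFold(n_splits=k, shuffle=True, random_state=seed + rep).split(np.arange(n))


def cross_validate(
    features: FeatureTable,
    ages: np.ndarray,
    k: int = 5,
    reps: int = 100,
    hyper: Hyperparameters = Hyperparameters(),
    seed: int = 0,
) -> CVResult:
    """Repeated k-fold cross-validation of the age model.

    Metrics are computed on each held-out fold; repetition r reshuffles
    with ``seed + r`` so repetitions are independent yet reproducible.
    """
    ages = np.asarray(ages, dtype=float)
    n = features.n_subjects
    if k > n:
        raise ValueError(f"k={k} folds but only {n} subjects")
    records = []
    for rep in range(reps):
        for fold, (tr, te) in enumerate(_fold_splits(n, k, rep, seed)):
            reg = _make_regressor(hyper, seed)
            reg.fit(features.values[tr], ages[tr])
            pred = reg.predict(features.values[te]).astype(float)
            r2, rmse, mae = regression_metrics(pred, ages[te])
            records.append(
                {"rep": rep, "fold": fold, "r2": r2, "rmse": rmse, "mae": mae}
            )
    return CVResult(k=k, reps=reps, seed=seed, records=records)


def out_of_fold_predictions(
    features: FeatureTable,
    ages: np.ndarray,
    k: int = 5,
    hyper: Hyperparameters = Hyperparameters(),
    seed: int = 0,
) -> np.ndarray:
    """Pooled out-of-fold predictions from one seeded k-fold pass.

    These are the predictions used (by default) to fit the age-bias
    line: each subject is predicted by a model that never saw it, which
    avoids the optimistically steep slope of in-sample fits.
    """
    ages = np.asarray(ages, dtype=float)
    n = features.n_subjects
    oof = np.empty(n)
    for tr, te in _fold_splits(n, k, rep=0, seed=seed):
        reg = _make_regressor(hyper, seed)
        reg.fit(features.values[tr], ages[tr])
        oof[te] = reg.predict(features.values[te])
    return oof


def _grid_points(grid: dict[str, list]) -> list[Hyperparameters]:
    base = Hyperparameters().to_dict()
    keys = list(grid.keys())
    unknown = set(keys) - set(base)
    if unknown:
        raise ValueError(f"unknown grid dimensions: {sorted(unknown)}")
    points = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(base)
        params.update(dict(zip(keys, combo)))
        points.append(Hyperparameters(**params))
    return points


def nested_grid_search(
    features: FeatureTable,
    ages: np.ndarray,
    grid: dict[str, list] | None = None,
    outer_k: int = 5,
    inner_k: int = 5,
    seed: int = 0,
) -> tuple[Hyperparameters, CVResult]:
    """Nested cross-validation: per outer fold, an inner k-fold grid
    search picks the hyperparameters with the lowest mean inner-CV RMSE;
    outer-fold metrics are computed only on held-out data.

    Returns the hyperparameters chosen most often across outer folds
    (ties broken by grid order) and the outer-fold CVResult.  With a
    single-point grid the outer folds — and hence the CVResult — match a
    plain ``cross_validate`` run with the same seed and reps=1.
    """
    grid = DEFAULT_GRID if grid is None else grid
    candidates = _grid_points(grid)
    if not candidates:
        raise ValueError("empty hyperparameter grid")
    ages = np.asarray(ages, dtype=float)
    n = features.n_subjects
    records = []
    chosen: list[Hyperparameters] = []
    for fold, (tr, te) in enumerate(_fold_splits(n, outer_k, rep=0, seed=seed)):
        if len(candidates) == 1:
            best = candidates[0]
        else:
            best, best_rmse = None, np.inf
            for cand in candidates:
                rmses = []
                for itr, ite in _fold_splits(len(tr), inner_k, rep=0, seed=seed + 1000):
                    reg = _make_regressor(cand, seed)
                    reg.fit(features.values[tr[itr]], ages[tr[itr]])
                    pred = reg.predict(features.values[tr[ite]]).astype(float)
                    rmses.append(float(np.sqrt(np.mean((pred - ages[tr[ite]]) ** 2))))
                mean_rmse = float(np.mean(rmses))
                if mean_rmse < best_rmse:
                    best, best_rmse = cand, mean_rmse
        chosen.append(best)
        reg = _make_regressor(best, seed)
        reg.fit(features.values[tr], ages[tr])
        pred = reg.predict(features.values[te]).astype(float)
        r2, rmse, mae = regression_metrics(pred, ages[te])
        records.append({"rep": 0, "fold": fold, "r2": r2, "rmse": rmse, "mae": mae})
    counts = {c: chosen.count(c) for c in candidates if c in chosen}
    best_overall = max(counts, key=lambda c: counts[c])
    return best_overall, CVResult(k=outer_k, reps=1, seed=seed, records=records)


def save_model(model: AgeModel, directory: str | Path) -> None:
    """Persist as a directory: JSON manifest + xgboost's JSON model dump."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "feature_names": model.feature_names,
        "hyperparameters": model.hyper.to_dict(),
        "seed": model.seed,
        "training_fingerprint": model.training_fingerprint,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    model.booster.get_booster().save_model(directory / "model.json")


def load_model(directory: str | Path) -> AgeModel:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no model manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    hyper = Hyperparameters(**manifest["hyperparameters"])
    reg = _make_regressor(hyper, manifest["seed"])
    booster = xgboost.Booster()
    booster.load_model(str(directory / "model.json"))
    reg._Booster = booster  # rebind the fitted ensemble to the wrapper
    return AgeModel(
        booster=reg,
        feature_names=manifest["feature_names"],
        hyper=hyper,
        seed=manifest["seed"],
        training_fingerprint=manifest["training_fingerprint"],
    )
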