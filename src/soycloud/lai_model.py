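"""Trait-based LAI regression (SVM, random forest, gradient boosting).

A :class:`TraitTable` pairs each plot's six canopy traits with an observed
LAI.  The table is split at random into training and test sets (default
3:7), features are z-scored with training statistics only, and one of three
regressors maps traits to LAI.  Accuracy is reported as

* R^2 = 1 - SS_res / SS_tot  (0 by convention when the observations have
  zero variance),
* RMSE = sqrt(mean squared error),
* RRMSE = RMSE / mean(observed)  (undefined when the mean is ~ 0).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .traits import TraitVector

__all__ = [
    "TRAIT_COLUMNS",
    "MODELS",
    "FitReport",
    "make_trait_table",
    "split_table",
    "fit_lai",
    "evaluate_lai",
    "feature_correlations",
    "run_lai_study",
]

TRAIT_COLUMNS = list(TraitVector.FIELDS)
MODELS = ("svm", "rf", "xgboost")

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "svm": {"kernel": "rbf", "C": 10.0, "epsilon": 0.1},
    "rf": {"n_estimators": 500},
    "xgboost": {"n_estimators": 300, "max_depth": 4, "learning_rate": 0.1},
}


@dataclass
class FitReport:
    """Accuracy report of one fitted LAI model on a train/test split."""

    model: str
    train_ids: list
    test_ids: list
    r2_train: float
    r2_test: float
    rmse_train: float
    rmse_test: float
    rrmse_train: float | None
    rrmse_test: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def make_trait_table(
    plot_ids: Sequence, traits: Sequence[TraitVector], lai: Sequence[float]
) -> pd.DataFrame:
    """Assemble a TraitTable DataFrame (plot_id, six traits, lai)."""
    if not (len(plot_ids) == len(traits) == len(lai)):
        raise ValueError("plot_ids, traits and lai must have equal length")
    rows = {"plot_id": list(plot_ids)}
    mat = np.array([t.as_array() for t in traits])
    for j, col in enumerate(TRAIT_COLUMNS):
        rows[col] = mat[:, j]
    rows["lai"] = np.asarray(lai, dtype=np.float64)
    table = pd.DataFrame(rows)
    if table[TRAIT_COLUMNS + ["lai"]].isna().any().any():
        raise ValueError("trait table contains missing values")
    if (table["lai"] <= 0).any():
        raise ValueError("observed LAI must be positive")
    return table


def split_table(
    table: pd.DataFrame, train_frac: float = 0.3, rng_seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seed-deterministic random split into disjoint, exhaustive train/test.

    ``n_train = max(2, floor(n * train_frac))``; both sides must keep at
    least two rows.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0, 1)")
    n = len(table)
    n_train = max(2, int(np.floor(n * train_frac)))
    if n - n_train < 2:
        raise ValueError(f"too few rows ({n}) for a {train_frac:.0%} split")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    return table.iloc[np.sort(perm[:n_train])], table.iloc[np.sort(perm[n_train:])]


class _LaiPredictor:
    """Fitted scaler + regressor; maps a trait matrix to LAI."""

    def __init__(self, scaler: StandardScaler, model, name: str):
        self.scaler = scaler
        self.model = model
        self.name = name

    def predict(self, features: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            features = features[TRAIT_COLUMNS].to_numpy()
        return np.asarray(self.model.predict(self.scaler.transform(features)))


def fit_lai(
    train: pd.DataFrame,
    model: str = "svm",
    hyperparams: dict | None = None,
    rng_seed: int = 0,
) -> _LaiPredictor:
    """Fit one of the three regressors on a training TraitTable."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    if len(train) < 5:
        raise ValueError("need at least 5 training rows")
    params = dict(DEFAULT_HYPERPARAMS[model])
    if hyperparams:
        params.update(hyperparams)
    x = train[TRAIT_COLUMNS].to_numpy()
    y = train["lai"].to_numpy()
    if np.any(x.std(axis=0) < 1e-15):
        import warnings

        warnings.warn("constant feature column(s) in training data", stacklevel=2)
    scaler = StandardScaler()
    xs = scaler.fit_transform(x)  # zero-variance columns scale to zero
    if model == "svm":
        est = SVR(**params)
    elif model == "rf":
        est = RandomForestRegressor(random_state=rng_seed, **params)
    else:
        from xgboost import XGBRegressor

        est = XGBRegressor(random_state=rng_seed, verbosity=0, **params)
    est.fit(xs, y)
    return _LaiPredictor(scaler, est, model)


def evaluate_lai(
    pred: np.ndarray, obs: np.ndarray
) -> tuple[float, float, float | None]:
    """Return (R^2, RMSE, RRMSE) for predictions against observations."""
    pred = np.asarray(pred, dtype=np.float64)
    obs = np.asarray(obs, dtype=np.float64)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("pred and obs must be equal-length with >= 2 entries")
    resid = obs - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 0.0 if ss_tot < 1e-15 else float(1.0 - np.sum(resid**2) / ss_tot)
    mean_obs = float(obs.mean())
    rrmse = None if abs(mean_obs) < 1e-12 else rmse / mean_obs
    return r2, rmse, rrmse


def feature_correlations(table: pd.DataFrame) -> dict[str, float]:
    """Univariate Pearson correlation of each trait with observed LAI."""
    lai = table["lai"].to_numpy()
    out = {}
    for col in TRAIT_COLUMNS:
        x = table[col].to_numpy()
        if np.std(x) < 1e-15 or np.std(lai) < 1e-15:
            out[col] = float("nan")
        else:
            out[col] = float(np.corrcoef(x, lai)[0, 1])
    return out


def run_lai_study(
    table: pd.DataFrame,
    train_frac: float = 0.3,
    rng_seed: int = 0,
    models: Sequence[str] = MODELS,
    hyperparams: dict[str, dict] | None = None,
) -> dict[str, FitReport]:
    """Split once, then fit and evaluate every requested model on it."""
    train, test = split_table(table, train_frac, rng_seed)
    reports: dict[str, FitReport] = {}
    for model in models:
        hp = (hyperparams or {}).get(model)
        predictor = fit_lai(train, model, hp, rng_seed)
        r2_tr, rmse_tr, rrmse_tr = evaluate_lai(
            predictor.predict(train), train["lai"].to_numpy()
        )
        r2_te, rmse_te, rrmse_te = evaluate_lai(
            predictor.predict(test), test["lai"].to_numpy()
        )
        reports[model] = FitReport(
            model=model,
            train_ids=list(train["plot_id"]),
            test_ids=list(test["plot_id"]),
            r2_train=r2_tr,
            r2_test=r2_te,
            rmse_train=rmse_tr,
            rmse_test=rmse_te,
            rrmse_train=rrmse_tr,
            rrmse_test=rrmse_te,
        )
    return reports
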