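"""Hip ROM predictors: naive mean, simple/multiple linear regression,
random forest and recurrent networks, plus the 3-class ROM scheme.

The module follows the model/results idiom: a model object is built from
data, its ``fit()`` returns a results object carrying the estimates, their
uncertainties where defined, and a ``summary()``. The linear models are
ordinary least squares (backed by statsmodels); the random forest is backed
by scikit-learn; the recurrent predictors wrap :mod:`monohip.nn`.

Hip ROM classes: 1 = reduced (10-30 deg), 2 = average (30-45 deg),
3 = normal (>= 45 deg); values below 10 deg clamp to class 1 with a
warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.preprocessing import StandardScaler

from .nn import RecurrentNet, RNNSpec, build_rnn  # noqa: F401  (re-export)

DEFAULT_SEED = 17


# ---------------------------------------------------------------------------
# ROM classification scheme
# ---------------------------------------------------------------------------

@dataclass
class ClassScheme:
    """Half-open ROM bins: [10, 30) -> 1, [30, 45) -> 2, [45, inf) -> 3."""

    boundaries: tuple[float, ...] = (10.0, 30.0, 45.0)
    labels: dict[int, str] = field(default_factory=lambda: {
        1: "reduced", 2: "average", 3: "normal"})

    def __post_init__(self) -> None:
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")


def classify_rom(rom, scheme: ClassScheme | None = None):
    """Map hip ROM in degrees to class labels 1..3 (monotone, total)."""
    scheme = scheme or ClassScheme()
    arr = np.asarray(rom, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("rom must be finite")
    if np.any(arr < scheme.boundaries[0]):
        warnings.warn(
            f"ROM below {scheme.boundaries[0]} deg assigned to class 1",
            stacklevel=2)
    cls = np.digitize(arr, scheme.boundaries[1:]) + 1
    return int(cls) if np.isscalar(rom) else cls


# ---------------------------------------------------------------------------
# results objects
# ---------------------------------------------------------------------------

class ROMResults:
    """Base results: out-of-sample prediction plus a text summary."""

    model_name = "ROM predictor"

    def predict(self, X=None):
        raise NotImplementedError

    def predict_class(self, X=None, scheme: ClassScheme | None = None):
        """Classify the regression output through the ROM class scheme."""
        return classify_rom(self.predict(X), scheme)

    def summary(self) -> str:
        raise NotImplementedError


class NaiveResults(ROMResults):
    model_name = "naive (training mean)"

    def __init__(self, mean: float, n: int):
        self.mean_ = float(mean)
        self.nobs = int(n)

    def predict(self, X=None):
        if X is None:
            return self.mean_
        n = len(X) if hasattr(X, "__len__") else int(X)
        return np.full(n, self.mean_)

    def summary(self) -> str:
        return (f"{self.model_name}\n"
                f"  predicted value: {self.mean_:.3f} deg "
                f"(n = {self.nobs})")


class NaiveROM:
    """Constant predictor: the mean of the training hip ROM values."""

    def __init__(self, endog):
        y = np.asarray(endog, dtype=float)
        if y.size == 0:
            raise ValueError("training set must be non-empty")
        self.endog = y

    def fit(self) -> NaiveResults:
        return NaiveResults(self.endog.mean(), len(self.endog))


class LinearROMResults(ROMResults):
    """OLS results: intercept beta0 and one coefficient per feature."""

    def __init__(self, sm_results, feature_names: list[str]):
        self._res = sm_results
        self.feature_names = list(feature_names)
        self.nobs = int(sm_results.nobs)

    @property
    def beta0(self) -> float:
        return float(self._res.params[0])

    @property
    def betas(self) -> np.ndarray:
        return np.asarray(self._res.params[1:], dtype=float)

    @property
    def params(self) -> pd.Series:
        return pd.Series(np.asarray(self._res.params),
                         index=["intercept"] + self.feature_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.asarray(self._res.bse),
                         index=["intercept"] + self.feature_names)

    @property
    def rsquared(self) -> float:
        return float(self._res.rsquared)

    def predict(self, X=None):
        if X is None:
            return np.asarray(self._res.fittedvalues)
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.beta0 + X @ self.betas

    def summary(self) -> str:
        model = "SLR" if len(self.feature_names) == 1 else "MLR"
        lines = [f"{model}: hip_rom ~ " + " + ".join(self.feature_names),
                 f"  n = {self.nobs}, R^2 = {self.rsquared:.3f}"]
        for name, b, se in zip(self.params.index, self.params, self.bse):
            lines.append(f"  {name:>15s}  {b: 10.4f}  (se {se:.4f})")
        return "\n".join(lines)


class LinearROM:
    """OLS hip ROM regression  Y = b0 + b1 X1 + ... + bn Xn."""

    def __init__(self, endog, exog, feature_names: list[str] | None = None):
        y = np.asarray(endog, dtype=float)
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if feature_names is None:
            feature_names = [f"x{i + 1}" for i in range(X.shape[1])]
        if len(feature_names) != X.shape[1]:
            raise ValueError("feature_names must match the design columns")
        if len(y) != len(X):
            raise ValueError("endog and exog lengths differ")
        if len(y) <= X.shape[1]:
            raise ValueError("need more rows than features")
        # reject rank-deficient designs, naming the offending columns
        design = sm.add_constant(X, has_constant="add")
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            bad = [feature_names[j] for j in range(X.shape[1])
                   if np.std(X[:, j]) < 1e-12]
            if not bad:
                bad = _collinear_columns(X, feature_names)
            raise ValueError(
                f"rank-deficient design (rank {rank} < {design.shape[1]}); "
                f"offending columns: {bad or 'unresolved'}")
        self.endog, self.exog, self.feature_names = y, design, feature_names

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, features: list[str],
                       target: str = "hip_rom_ref") -> "LinearROM":
        return cls(df[target].to_numpy(float),
                   df[list(features)].to_numpy(float), list(features))

    def fit(self, cov_type: str = "nonrobust", **cov_kwds
            ) -> LinearROMResults:
        res = sm.OLS(self.endog, self.exog).fit(cov_type=cov_type,
                                                cov_kwds=cov_kwds or None)
        return LinearROMResults(res, self.feature_names)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(X)), others])
        resid = X[:, j] - A @ np.linalg.lstsq(A, X[:, j], rcond=None)[0]
        if np.std(resid) < 1e-10 * max(np.std(X[:, j]), 1.0):
            bad.append(names[j])
    return bad


def fit_slr(thigh_rom, hip_rom) -> LinearROMResults:
    """Simple linear regression of hip ROM on thigh ROM."""
    x = np.asarray(thigh_rom, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) < 1e-12:
        raise ValueError("thigh ROM predictor is constant")
    return LinearROM(hip_rom, x, ["thigh_rom"]).fit()


def fit_mlr(df: pd.DataFrame, features: list[str],
            target: str = "hip_rom_ref") -> LinearROMResults:
    """Multiple linear regression on the selected feature columns."""
    return LinearROM.from_dataframe(df, features, target).fit()


class ForestResults(ROMResults):
    model_name = "random forest"

    def __init__(self, estimator, task: str, feature_names):
        self._est = estimator
        self.task = task
        self.feature_names = feature_names

    def predict(self, X=None):
        if X is None:
            raise ValueError("the random forest needs inputs to predict")
        if isinstance(X, pd.DataFrame) and self.feature_names is not None:
            X = X[self.feature_names].to_numpy(float)
        return self._est.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        if self.task != "classification":
            raise ValueError("predict_proba requires a classification task")
        if isinstance(X, pd.DataFrame) and self.feature_names is not None:
            X = X[self.feature_names].to_numpy(float)
        return self._est.predict_proba(np.asarray(X, dtype=float))

    def summary(self) -> str:
        e = self._est
        return (f"{self.model_name} ({self.task})\n"
                f"  trees = {e.n_estimators}, "
                f"min leaf = {e.min_samples_leaf}, "
                f"seed = {e.random_state}")


class RandomForestROM:
    """Bootstrap-aggregated decision trees for ROM regression or
    classification, with the two canonical hyperparameters: number of trees
    and minimum leaf size."""

    def __init__(self, endog, exog, task: str = "regression",
                 n_trees: int = 100, min_leaf: int = 1,
                 seed: int = DEFAULT_SEED, bootstrap: bool = True,
                 feature_names: list[str] | None = None):
        if n_trees < 1 or min_leaf < 1:
            raise ValueError("n_trees and min_leaf must be >= 1")
        if task not in ("regression", "classification"):
            raise ValueError("task must be 'regression' or 'classification'")
        self.endog = np.asarray(endog)
        self.exog = np.asarray(exog, dtype=float)
        self.task = task
        self.n_trees, self.min_leaf, self.seed = n_trees, min_leaf, seed
        self.bootstrap = bootstrap
        self.feature_names = feature_names

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, features: list[str],
                       target: str = "hip_rom_ref", **kwargs
                       ) -> "RandomForestROM":
        return cls(df[target].to_numpy(), df[list(features)].to_numpy(float),
                   feature_names=list(features), **kwargs)

    def fit(self) -> ForestResults:
        cls = (RandomForestRegressor if self.task == "regression"
               else RandomForestClassifier)
        est = cls(n_estimators=self.n_trees,
                  min_samples_leaf=self.min_leaf,
                  bootstrap=self.bootstrap,
                  random_state=self.seed)
        est.fit(self.exog, self.endog)
        return ForestResults(est, self.task, self.feature_names)


class RecurrentResults(ROMResults):
    model_name = "recurrent network"

    def __init__(self, net: RecurrentNet):
        self.net = net
        self.history = net.history

    def predict(self, X=None):
        if X is None:
            raise ValueError("the recurrent model needs inputs to predict")
        return self.net.predict(X)

    def predict_proba(self, X):
        return self.net.predict_proba(X)

    def summary(self) -> str:
        s = self.net.spec
        last = self.history.loss[-1] if self.history.loss else float("nan")
        return (f"{self.model_name} ({s.cell}, {s.task})\n"
                f"  units = {s.units}, dropout = {s.dropout_rate}, "
                f"lr = {s.learning_rate}\n"
                f"  final training loss = {last:.4f} "
                f"({len(self.history.loss)} epochs)")


class RecurrentROM:
    """Sequence model over 100 x 7 gait-cycle tensors (sagittal thigh angle
    waveform, tri-axial acceleration, tri-axial angular velocity)."""

    def __init__(self, endog, exog, spec: RNNSpec | None = None,
                 seed: int = DEFAULT_SEED):
        self.spec = spec or RNNSpec()
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        self.seed = seed

    def fit(self, epochs: int = 30, batch_size: int = 32
            ) -> RecurrentResults:
        net = build_rnn(self.spec, seed=self.seed)
        y = self.endog
        if self.spec.task == "classification":
            y = y - 1  # labels 1..K -> 0..K-1
        net.fit(self.exog, y, epochs=epochs, batch_size=batch_size)
        return RecurrentResults(net)


# ---------------------------------------------------------------------------
# fold-wise training with standardization
# ---------------------------------------------------------------------------

class Standardizer:
    """Zero-mean unit-variance scaling fitted on training folds only.

    Handles 2-D feature matrices and 3-D cycle tensors (per-channel
    statistics for the latter)."""

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            self.mean_ = X.mean(axis=(0, 1))
            self.scale_ = X.std(axis=(0, 1))
        else:
            sc = StandardScaler().fit(X)
            self.mean_, self.scale_ = sc.mean_, sc.scale_
        self.scale_ = np.where(self.scale_ < 1e-12, 1.0, self.scale_)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


def train_predict(model_factory, X, y, groups, folds,
                  standardize: bool = True) -> np.ndarray:
    """Out-of-fold predictions under group-disjoint folds.

    `model_factory(X_train, y_train)` must return a fitted object with a
    ``predict`` method. The standardizer is fitted on each training fold
    only and applied to its test fold; predictions are returned in the
    original row order. Any group appearing on both sides of a fold raises.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.asarray(groups)
    oof = None
    for train_idx, test_idx in folds:
        leak = set(groups[train_idx]) & set(groups[test_idx])
        if leak:
            raise ValueError(f"group leakage across folds: {sorted(leak)}")
        Xtr, Xte = X[train_idx], X[test_idx]
        if standardize:
            sc = Standardizer().fit(Xtr)
            Xtr, Xte = sc.transform(Xtr), sc.transform(Xte)
        fitted = model_factory(Xtr, y[train_idx])
        pred = np.asarray(fitted.predict(Xte))
        if oof is None:
            oof = np.full(len(y), np.nan, dtype=pred.dtype
                          if pred.dtype.kind == "f" else float)
        oof[test_idx] = pred
    if oof is None:
        raise ValueError("no folds provided")
    return oof
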