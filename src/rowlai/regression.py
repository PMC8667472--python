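"""Predictive models mapping the eight canopy features to effective LAI.

Three model families are supported: bidirectional stepwise multiple
linear regression (SMLR), partial least squares regression (PLSR), and
support vector regression (SVR) with linear / polynomial / RBF / sigmoid
kernels. The train/test protocol follows the field design: genotype
varieties (not records) are split 75/25 so both replicates of a variety
always land on the same side, and hyperparameters are chosen by 10-fold
cross-validation on the training set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .features import MODEL_FEATURES

__all__ = [
    "Dataset",
    "ModelReport",
    "split_by_variety",
    "fit_smlr",
    "fit_plsr",
    "fit_svr",
    "fit_model",
    "evaluate",
    "r_squared",
    "SVR_GRIDS",
]

#: Documented SVR hyperparameter grids, searched exhaustively.
SVR_GRIDS: dict[str, dict[str, list]] = {
    "linear": {"C": [0.1, 1, 10, 100], "epsilon": [0.01, 0.1, 0.5]},
    "rbf": {
        "C": [0.1, 1, 10, 100],
        "gamma": ["scale", 0.01, 0.1, 1],
        "epsilon": [0.01, 0.1, 0.5],
    },
    "sigmoid": {
        "C": [0.1, 1, 10, 100],
        "gamma": ["scale", 0.01, 0.1, 1],
        "epsilon": [0.01, 0.1, 0.5],
    },
    "poly": {
        "C": [0.1, 1, 10, 100],
        "gamma": ["scale", 0.01, 0.1, 1],
        "epsilon": [0.01, 0.1, 0.5],
        "degree": [2, 3],
    },
}


@dataclass
class Dataset:
    """Feature matrix (records × 8, fixed column order), LAI_eff target,
    and the variety/replicate keys that drive the split protocol."""

    X: pd.DataFrame
    y: np.ndarray
    variety: np.ndarray
    replicate: np.ndarray
    region_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.variety = np.asarray(self.variety)
        self.replicate = np.asarray(self.replicate)
        if not (len(self.X) == self.y.size == self.variety.size == self.replicate.size):
            raise ValueError("X, y, variety, replicate must have equal length")
        if self.X.isna().any().any() or np.isnan(self.y).any():
            raise ValueError("dataset contains missing values; exclude flagged records first")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, index: np.ndarray) -> "Dataset":
        return Dataset(
            self.X.iloc[index].reset_index(drop=True),
            self.y[index],
            self.variety[index],
            self.replicate[index],
            None if self.region_id is None else self.region_id[index],
        )

    def drop_feature(self, name: str) -> "Dataset":
        return Dataset(
            self.X.drop(columns=[name]),
            self.y,
            self.variety,
            self.replicate,
            self.region_id,
        )

    @classmethod
    def from_features(
        cls, features: pd.DataFrame, reference: pd.DataFrame
    ) -> "Dataset":
        """Join a feature table to ground-reference LAI_eff on region_id,
        dropping records with any missing model feature."""
        merged = features.merge(reference[["region_id", "lai_eff"]], on="region_id")
        ok = merged[MODEL_FEATURES].notna().all(axis=1) & merged["lai_eff"].notna()
        merged = merged[ok].reset_index(drop=True)
        return cls(
            X=merged[MODEL_FEATURES].copy(),
            y=merged["lai_eff"].to_numpy(),
            variety=merged["genotype"].to_numpy(),
            replicate=merged["replicate"].to_numpy(),
            region_id=merged["region_id"].to_numpy(),
        )


@dataclass
class ModelReport:
    """A fitted model plus its evaluation metrics."""

    family: str
    selected_features: list[str] = field(default_factory=list)
    hyperparameters: dict = field(default_factory=dict)
    train_r2: float = np.nan
    cv_r2: float = np.nan
    test_r2: float = np.nan
    test_rmse: float = np.nan
    seed: int | None = None
    _predict: callable = field(default=None, repr=False, compare=False)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self._predict is None:
            raise ValueError("model has no attached predictor")
        return np.asarray(self._predict(X), dtype=float).ravel()

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "selected_features": self.selected_features,
            "hyperparameters": {k: str(v) for k, v in self.hyperparameters.items()},
            "train_r2": self.train_r2,
            "cv_r2": self.cv_r2,
            "test_r2": self.test_r2,
            "test_rmse": self.test_rmse,
            "seed": self.seed,
        }


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """1 − SS_res/SS_tot; a zero-variance truth yields 0 with a warning."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    if ss_tot == 0:
        warnings.warn("zero-variance target: R^2 reported as 0", stacklevel=2)
        return 0.0
    return float(1.0 - np.sum((y_true - y_pred) ** 2) / ss_tot)


def split_by_variety(
    ds: Dataset, train_fraction: float = 0.75, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Random variety-level 75/25 split.

    Varieties — not records — are partitioned, so both replicates of a
    genotype are always on the same side. Deterministic given the seed;
    round(train_fraction · V) varieties go to train.
    """
    varieties = np.unique(ds.variety)
    if varieties.size < 4:
        raise ValueError("need at least 4 distinct varieties to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(varieties)
    n_train = int(np.floor(train_fraction * varieties.size + 0.5))
    n_train = min(max(n_train, 1), varieties.size - 1)
    train_set = set(perm[:n_train])
    mask = np.fromiter((v in train_set for v in ds.variety), bool, ds.n)
    return ds.subset(np.flatnonzero(mask)), ds.subset(np.flatnonzero(~mask))


def _cv_splitter(n: int, seed: int | None, n_splits: int = 10) -> KFold:
    if n < 3:
        raise ValueError("cross-validation needs at least 3 records")
    return KFold(n_splits=min(n_splits, n), shuffle=True, random_state=seed)


def fit_smlr(train: Dataset, alpha: float = 0.05, **_: object) -> ModelReport:
    """Bidirectional stepwise OLS on the raw feature scale.

    Forward step: add the candidate with the smallest partial-F p-value
    if it is below alpha (for a single added coefficient the partial F
    equals the squared t, so the coefficient's p-value is used).
    Backward step: drop any retained predictor whose p-value rises to
    alpha or above. Iterates to a fixed point; if nothing is significant
    the intercept-only model is returned with a warning.
    """
    names = train.feature_names
    selected: list[str] = []

    def _perfect_fit() -> bool:
        # p-values on numerically-zero residuals are meaningless; stop
        # the search once the current model explains y to float precision
        if selected:
            pred = sm.OLS(train.y, sm.add_constant(train.X[selected])).fit().fittedvalues
        else:
            pred = np.full(train.n, train.y.mean())
        scale = max(float(np.abs(train.y).max()), 1.0)
        return float(np.sqrt(np.mean((train.y - pred) ** 2))) <= 1e-9 * scale

    changed = True
    guard = 0
    while changed and guard < 4 * len(names):
        guard += 1
        changed = False
        if _perfect_fit():
            break
        # forward
        best_p, best_name = np.inf, None
        for name in names:
            if name in selected:
                continue
            model = sm.OLS(train.y, sm.add_constant(train.X[selected + [name]])).fit()
            p = model.pvalues[name]
            if np.isfinite(p) and p < best_p:
                best_p, best_name = p, name
        if best_name is not None and best_p < alpha:
            selected.append(best_name)
            changed = True
        # backward
        while selected:
            model = sm.OLS(train.y, sm.add_constant(train.X[selected])).fit()
            pvals = model.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] >= alpha:
                selected.remove(worst)
                changed = True
            else:
                break
    if not selected:
        warnings.warn("no feature significant: intercept-only SMLR model", stacklevel=2)
        mean = float(train.y.mean())
        report = ModelReport(
            family="SMLR",
            selected_features=[],
            hyperparameters={"alpha": alpha, "coefficients": {"const": mean}},
            train_r2=0.0,
            _predict=lambda X, m=mean: np.full(len(X), m),
        )
        return report
    final = sm.OLS(train.y, sm.add_constant(train.X[selected])).fit()
    coefs = final.params.to_dict()

    def predict(X: pd.DataFrame, sel=tuple(selected), coefs=dict(coefs)) -> np.ndarray:
        out = np.full(len(X), coefs["const"], dtype=float)
        for name in sel:
            out += coefs[name] * X[name].to_numpy(dtype=float)
        return out

    return ModelReport(
        family="SMLR",
        selected_features=list(selected),
        hyperparameters={"alpha": alpha, "coefficients": coefs},
        train_r2=float(final.rsquared),
        _predict=predict,
    )


def fit_plsr(
    train: Dataset,
    max_components: int = 8,
    seed: int | None = 0,
    n_components: int | None = None,
    **_: object,
) -> ModelReport:
    """PLSR on standardized inputs; the component count maximizing 10-fold
    CV R² (pooled out-of-fold predictions) on the training set is
    retained, unless ``n_components`` pins it explicitly."""
    n_feat = len(train.feature_names)
    upper = min(max_components, n_feat, train.n - 1)
    X = train.X.to_numpy(dtype=float)
    best_score, best_k = np.nan, n_components
    if n_components is None:
        cv = _cv_splitter(train.n, seed)
        folds = list(cv.split(X))
        best_score, best_k = -np.inf, 1
        for k in range(1, upper + 1):
            preds = np.empty_like(train.y)
            for tr, te in folds:
                m = PLSRegression(n_components=k, scale=True)
                m.fit(X[tr], train.y[tr])
                preds[te] = m.predict(X[te]).ravel()
            score = r_squared(train.y, preds)
            if score > best_score + 1e-12:
                best_score, best_k = score, k
    model = PLSRegression(n_components=best_k, scale=True)
    model.fit(X, train.y)
    cols = list(train.feature_names)
    return ModelReport(
        family="PLSR",
        selected_features=cols,
        hyperparameters={"n_components": best_k},
        train_r2=r_squared(train.y, model.predict(X).ravel()),
        cv_r2=best_score,
        seed=seed,
        _predict=lambda Xn, m=model, c=cols: m.predict(Xn[c].to_numpy(dtype=float)).ravel(),
    )


def _grid_configs(kernel: str) -> list[dict]:
    grid = SVR_GRIDS[kernel]
    keys = list(grid)
    configs: list[dict] = [{}]
    for key in keys:
        configs = [{**c, key: v} for c in configs for v in grid[key]]
    return configs


def fit_svr(
    train: Dataset, kernel: str = "rbf", seed: int | None = 0, **_: object
) -> ModelReport:
    """SVR with z-scored inputs; hyperparameters by exhaustive grid search
    scored with 10-fold CV R² on the training set, refit on full train.

    The grid loop is written out by hand (fold-wise scaling + SVR fits)
    rather than delegated to a meta-estimator; this keeps the repeated
    leave-one-feature-out refits cheap. Ties break toward the earlier
    grid entry, so results are deterministic.
    """
    if kernel not in SVR_GRIDS:
        raise ValueError(f"unknown kernel {kernel!r}")
    X = train.X.to_numpy(dtype=float)
    y = train.y
    cv = _cv_splitter(train.n, seed)
    folds = []
    for tr, te in cv.split(X):
        if te.size < 1 or tr.size < 2:
            raise ValueError("cross-validation fold with < 2 records")
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        folds.append(((X[tr] - mu) / sd, y[tr], (X[te] - mu) / sd, te))
    configs = _grid_configs(kernel)
    best_score, best_cfg = -np.inf, configs[0]
    preds = np.empty_like(y)
    for cfg in configs:
        for Xtr, ytr, Xte, te in folds:
            svr = SVR(kernel=kernel, **cfg)
            svr.fit(Xtr, ytr)
            preds[te] = svr.predict(Xte)
        score = r_squared(y, preds)
        if score > best_score + 1e-12:
            best_score, best_cfg = score, cfg
    pipe = Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel=kernel, **best_cfg))])
    pipe.fit(X, y)
    cols = list(train.feature_names)
    return ModelReport(
        family=f"SVR-{kernel}",
        selected_features=cols,
        hyperparameters={"kernel": kernel, **best_cfg},
        train_r2=r_squared(y, pipe.predict(X)),
        cv_r2=best_score,
        seed=seed,
        _predict=lambda Xn, m=pipe, c=cols: m.predict(Xn[c].to_numpy(dtype=float)),
    )


_FAMILIES = {
    "smlr": fit_smlr,
    "plsr": fit_plsr,
    "svr-linear": lambda tr, **kw: fit_svr(tr, kernel="linear", **kw),
    "svr-rbf": lambda tr, **kw: fit_svr(tr, kernel="rbf", **kw),
    "svr-poly": lambda tr, **kw: fit_svr(tr, kernel="poly", **kw),
    "svr-sigmoid": lambda tr, **kw: fit_svr(tr, kernel="sigmoid", **kw),
}


def fit_model(train: Dataset, family: str, seed: int | None = 0) -> ModelReport:
    """Dispatch to a model family by name (smlr, plsr, svr-<kernel>)."""
    key = family.lower()
    if key not in _FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    return _FAMILIES[key](train, seed=seed)


def evaluate(report: ModelReport, test: Dataset) -> tuple[float, float]:
    """Held-out R² and RMSE; also recorded on the report."""
    pred = report.predict(test.X)
    r2 = r_squared(test.y, pred)
    rmse = float(np.sqrt(np.mean((test.y - pred) ** 2)))
    report.test_r2, report.test_rmse = r2, rmse
    return r2, rmse
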