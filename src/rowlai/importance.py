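"""Feature sensitivity analysis: correlation matrix and leave-one-out
feature weights.

The weight of a feature is 1 − R²_new / R²_orig, where R²_orig is the
held-out R² of the reference model fitted on all features and R²_new the
same protocol rerun without the feature. The split and the hyperparameter
search are pinned to one seed across all refits so the weights reflect
feature removal only. Weights can be negative (removal improved the fit);
that is reported as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regression import Dataset, evaluate, fit_model, split_by_variety

__all__ = [
    "FeatureWeights",
    "feature_weight",
    "correlation_matrix",
    "loo_feature_weights",
    "plot_correlation_heatmap",
]


@dataclass
class FeatureWeights:
    """Per-feature leave-one-out weights for one reference model."""

    model_family: str
    r2_original: float
    weights: dict[str, float] = field(default_factory=dict)
    r2_without: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def ranking(self) -> list[str]:
        """Features ordered from most to least important."""
        return sorted(self.weights, key=self.weights.get, reverse=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.weights),
                "weight": list(self.weights.values()),
                "r2_without": [self.r2_without[f] for f in self.weights],
            }
        )


def feature_weight(r2_new: float, r2_original: float) -> float:
    """1 − R²_new/R²_orig: the relative R² loss when a feature is dropped."""
    if r2_original <= 0:
        raise ValueError("baseline uninformative")
    return 1.0 - r2_new / r2_original


def correlation_matrix(
    ds: Dataset, include_target: bool = False, absolute: bool = True
) -> pd.DataFrame:
    """Absolute Pearson correlation among the features (optionally with
    the LAI target), on a 0–1 scale with a unit diagonal.

    A zero-variance column correlates 0 with everything (warning), but
    keeps its unit diagonal.
    """
    if ds.n < 3:
        raise ValueError("correlation matrix needs >= 3 records")
    frame = ds.X.copy()
    if include_target:
        frame["lai_eff"] = ds.y
    degenerate = frame.std(ddof=0) == 0
    if degenerate.any():
        warnings.warn(
            f"zero-variance column(s) {list(frame.columns[degenerate])}: correlation set to 0",
            stacklevel=2,
        )
    corr = frame.corr().fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr.abs() if absolute else corr


def loo_feature_weights(
    ds: Dataset,
    model: str = "svr-rbf",
    seed: int = 0,
    train_fraction: float = 0.75,
) -> FeatureWeights:
    """Leave-one-feature-out weights under the full fitting protocol.

    The variety-level split, CV folds and hyperparameter grid are reused
    (same seed) for the baseline and every reduced fit.
    """
    train, test = split_by_variety(ds, train_fraction=train_fraction, seed=seed)
    baseline = fit_model(train, model, seed=seed)
    r2_orig, _ = evaluate(baseline, test)
    if r2_orig <= 0:
        raise ValueError("baseline uninformative")
    out = FeatureWeights(model_family=baseline.family, r2_original=r2_orig, seed=seed)
    for name in ds.feature_names:
        reduced = fit_model(train.drop_feature(name), model, seed=seed)
        r2_new, _ = evaluate(reduced, test.drop_feature(name))
        out.r2_without[name] = r2_new
        # a reduced model worse than the test mean carries no explanatory
        # power left to lose: floor R²_new at 0 so weights stay <= 1
        out.weights[name] = feature_weight(max(r2_new, 0.0), r2_orig)
    return out


def plot_correlation_heatmap(corr: pd.DataFrame, path: str) -> None:
    """Save the correlation matrix as a heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.values, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(corr.columns)), corr.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(corr.index)), corr.index)
    for i in range(corr.shape[0]):
        for j in range(corr.shape[1]):
            ax.text(j, i, f"{corr.iat[i, j]:.2f}", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="|Pearson r|")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
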