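"""Feature sensitivity analysis for each panel.

Computes the absolute-Pearson feature correlation matrix and the
leave-one-feature-out weights (1 - R2_new/R2_orig) under the SVR-RBF
reference model with the split and grid search pinned to one seed, and
writes both as CSV (plus a heatmap PNG) under results/.

    python analysis/04_feature_importance.py --seed 2020
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from rowlai import Dataset, correlation_matrix, loo_feature_weights
from rowlai.importance import plot_correlation_heatmap

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2020)
    args = ap.parse_args()

    for name in ("sorghum", "maize"):
        feats_path = ROOT / "results" / f"features_{name}.csv"
        if not feats_path.exists():
            print(f"{name}: missing {feats_path}; run 02_extract_features.py first")
            continue
        ds = Dataset.from_features(
            pd.read_csv(feats_path), pd.read_csv(ROOT / "results" / f"truth_{name}.csv")
        )
        corr = correlation_matrix(ds, include_target=True)
        corr.to_csv(ROOT / "results" / f"correlations_{name}.csv")
        plot_correlation_heatmap(corr, ROOT / "results" / f"correlations_{name}.png")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = loo_feature_weights(ds, model="svr-rbf", seed=args.seed)
        w.to_frame().to_csv(ROOT / "results" / f"feature_weights_{name}.csv", index=False)
        print(
            f"{name}: baseline R2={w.r2_original:.3f}; "
            f"ranking: {', '.join(w.ranking())}"
        )


if __name__ == "__main__":
    main()
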