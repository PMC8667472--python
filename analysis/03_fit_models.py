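"""Fit and evaluate the three model families on each panel.

Joins the feature tables to the ground-truth effective LAI, splits at
the variety level (75% train / 25% test, replicates kept together), fits
SMLR, PLSR and SVR-RBF with 10-fold CV on the training side, and writes
model reports (JSON) and held-out predictions (CSV) under results/.

    python analysis/03_fit_models.py --seed 2020
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

from rowlai import Dataset, evaluate, fit_model, split_by_variety

ROOT = Path(__file__).resolve().parents[1]
FAMILIES = ("smlr", "plsr", "svr-rbf")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2020)
    args = ap.parse_args()

    for name in ("sorghum", "maize"):
        feats_path = ROOT / "results" / f"features_{name}.csv"
        truth_path = ROOT / "results" / f"truth_{name}.csv"
        if not feats_path.exists():
            print(f"{name}: missing {feats_path}; run 02_extract_features.py first")
            continue
        ds = Dataset.from_features(pd.read_csv(feats_path), pd.read_csv(truth_path))
        train, test = split_by_variety(ds, seed=args.seed)
        reports = {}
        preds = []
        for family in FAMILIES:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = fit_model(train, family, seed=args.seed)
                r2, rmse = evaluate(report, test)
            reports[family] = report.to_dict()
            preds.append(
                pd.DataFrame(
                    {
                        "region_id": test.region_id,
                        "family": family,
                        "y_true": test.y,
                        "y_pred": report.predict(test.X),
                    }
                )
            )
            extra = (
                f" selected={report.selected_features}" if family == "smlr" else ""
            )
            print(f"{name}/{family}: test R2={r2:.3f} RMSE={rmse:.3f}{extra}")
        (ROOT / "results" / f"models_{name}.json").write_text(
            json.dumps(reports, indent=1), encoding="utf-8"
        )
        pd.concat(preds).to_csv(ROOT / "results" / f"predictions_{name}.csv", index=False)


if __name__ == "__main__":
    main()
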