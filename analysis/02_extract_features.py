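"""Extract the eight canopy features for every region of each panel.

Reads the simulated studies written by 01_simulate_study.py (bare-earth
and canopy clouds, region polygons), builds the season-constant DTM,
normalizes heights with the 10 cm ground rule, and writes one feature
table per panel under results/.

    python analysis/02_extract_features.py
"""

from pathlib import Path

from rowlai import (
    extract_study_features,
    read_point_cloud,
    read_regions,
    records_to_frame,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    for name in ("sorghum", "maize"):
        study = ROOT / "scratch" / f"study_{name}"
        if not study.exists():
            print(f"{name}: no simulated study at {study}; run 01_simulate_study.py first")
            continue
        bare = read_point_cloud(study / "bare_earth.las")
        canopy = read_point_cloud(study / "canopy.las")
        regions = read_regions(study / "regions.geojson")
        records = extract_study_features(bare, canopy, regions)
        table = records_to_frame(records)
        out = ROOT / "results" / f"features_{name}.csv"
        table.to_csv(out, index=False)
        n_missing = int(table[["lpi"]].isna().sum().sum())
        print(
            f"{name}: {len(table)} regions featured "
            f"(LPI {table.lpi.min():.3f}-{table.lpi.max():.3f}, "
            f"{n_missing} missing) -> {out}"
        )


if __name__ == "__main__":
    main()
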