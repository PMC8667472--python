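"""Simulate the two field experiments the analysis runs on.

Generates a sorghum-style panel (80 varieties x 2 replicates = 160
two-row-block regions at ~200,000 plants/ha) and a maize-style panel
(44 x 2 = 88 regions at ~75,000 plants/ha), both with per-variety
effective LAI drawn uniformly from the observed field ranges and
Beer-Lambert canopy transmittance. Point clouds (large, binary) land
under scratch/; the truth tables under results/.

    python analysis/01_simulate_study.py --seed 2020
"""

import argparse
from pathlib import Path

from rowlai import generate_study, write_study

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2020)
    ap.add_argument("--pulse-density", type=float, default=500.0)
    args = ap.parse_args()

    panels = {
        "sorghum": dict(n_varieties=80, crop="sorghum", lai_eff_range=(0.5, 6.0)),
        "maize": dict(n_varieties=44, crop="maize", lai_eff_range=(0.5, 5.0)),
    }
    (ROOT / "results").mkdir(exist_ok=True)
    for name, kw in panels.items():
        bundle = generate_study(
            pulse_density=args.pulse_density, sigma_z=0.01, seed=args.seed, **kw
        )
        out = ROOT / "scratch" / f"study_{name}"
        write_study(bundle, out)
        bundle.truth.to_csv(ROOT / "results" / f"truth_{name}.csv", index=False)
        print(
            f"{name}: {len(bundle.regions)} regions, "
            f"{bundle.canopy.n:,} canopy points, "
            f"LAI_eff {bundle.truth.lai_eff.min():.2f}-{bundle.truth.lai_eff.max():.2f} "
            f"-> {out}"
        )


if __name__ == "__main__":
    main()
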