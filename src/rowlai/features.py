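"""Per-region canopy features from a height-normalized point cloud.

Eight features feed the predictive models: LPI, mean / standard deviation
/ skewness / 3rd-quartile of vegetation height, VCI, convex-hull volume,
and CAP. The coefficient of variation and the maximum height are computed
and reported alongside but are not model inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError

from .cap import CapConfig, cap_feature
from .pointcloud import PointCloud, RegionOfInterest
from .terrain import GROUND_THRESHOLD, HeightCloud

__all__ = [
    "FeatureConfig",
    "FeatureRecord",
    "lpi",
    "height_statistics",
    "vci",
    "hull_volume",
    "extract_features",
    "records_to_frame",
    "MODEL_FEATURES",
    "FEATURE_TABLE_COLUMNS",
]

#: Model-input feature columns, in the fixed order the regression stage uses.
MODEL_FEATURES = ["lpi", "h_mean", "h_std", "h_skew", "h_q3", "vci", "hull_volume", "cap"]

#: Full feature-table schema (one row per region per epoch).
FEATURE_TABLE_COLUMNS = [
    "region_id", "date", "das", "platform", "genotype", "replicate",
    "n_ground", "n_veg", "lpi", "h_mean", "h_std", "h_skew", "h_q3",
    "h_cv", "h_max", "vci", "hull_volume", "cap",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction knobs: VCI bin width (m), ground threshold (m),
    and the CAP parameters."""

    vci_bin_width: float = 0.10
    ground_threshold: float = GROUND_THRESHOLD
    cap: CapConfig = field(default_factory=CapConfig)


@dataclass
class FeatureRecord:
    """The per-region feature vector plus counts and region metadata.

    ``missing`` flags regions with too few vegetation points (< 3) to
    support the statistical features; such records are excluded from
    model fitting but keep their LPI and counts.
    """

    region_id: str
    n_ground: int = 0
    n_veg: int = 0
    lpi: float = np.nan
    h_mean: float = np.nan
    h_std: float = np.nan
    h_skew: float = np.nan
    h_q3: float = np.nan
    h_cv: float = np.nan
    h_max: float = np.nan
    vci: float = np.nan
    hull_volume: float = np.nan
    cap: float = np.nan
    genotype: str = ""
    replicate: int = 1
    date: str = ""
    das: int | None = None
    platform: str = ""
    missing: bool = False


def lpi(n_ground: int, n_vegetation: int) -> float:
    """Laser penetration index: ground points over total points."""
    total = n_ground + n_vegetation
    if total <= 0:
        raise ValueError("empty region")
    return n_ground / total


def height_statistics(veg_heights: Sequence[float]) -> tuple[float, float, float, float, float]:
    """(mean, std, skewness, q3, cv) of vegetation heights.

    Sample std (n−1), adjusted Fisher–Pearson skewness (0 for a constant
    sample, where it is undefined), linear-interpolation 75th percentile.
    """
    h = np.asarray(veg_heights, dtype=float)
    if h.size < 3:
        raise ValueError("height statistics need >= 3 vegetation points")
    mean = float(h.mean())
    std = float(h.std(ddof=1))
    if std == 0.0:
        skew = 0.0
    else:
        skew = float(stats.skew(h, bias=False))
    q3 = float(np.percentile(h, 75))  # linear interpolation (type 7)
    cv = std / mean if mean != 0 else np.nan
    return mean, std, skew, q3, cv


def vci(
    veg_heights: Sequence[float],
    bin_width: float = 0.10,
    ground_threshold: float = GROUND_THRESHOLD,
) -> float:
    """Vertical complexity index: normalized Shannon entropy of the
    vegetation height histogram.

    Bins of ``bin_width`` span [ground_threshold, max height]; with HB
    bins and proportional abundances p_i, VCI = −Σ p_i ln p_i / ln HB
    (0·ln 0 := 0), so 0 means all points in one bin and 1 a uniform
    spread over the bins.
    """
    h = np.asarray(veg_heights, dtype=float)
    if h.size == 0:
        raise ValueError("no vegetation points")
    span = h.max() - ground_threshold
    hb = int(np.ceil(round(span / bin_width, 9)))
    if hb < 2:
        raise ValueError("insufficient vertical extent for VCI")
    counts, _ = np.histogram(h, bins=hb, range=(ground_threshold, ground_threshold + hb * bin_width))
    p = counts[counts > 0] / h.size
    return float(-(p * np.log(p)).sum() / np.log(hb))


def hull_volume(veg_points: PointCloud | np.ndarray) -> float:
    """3D convex-hull volume (m³) of the vegetation points.

    Degenerate configurations (coplanar/collinear, or < 4 points) give 0
    with a warning rather than an error.
    """
    pts = veg_points.xyz() if isinstance(veg_points, PointCloud) else np.asarray(veg_points, float)
    pts = pts.reshape(-1, 3)
    if len(pts) < 4:
        warnings.warn("fewer than 4 points: hull volume set to 0", stacklevel=2)
        return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        warnings.warn("degenerate point configuration: hull volume set to 0", stacklevel=2)
        return 0.0


def extract_features(
    hc: HeightCloud,
    roi: RegionOfInterest,
    config: FeatureConfig = FeatureConfig(),
) -> FeatureRecord:
    """Compute the full feature record for one region.

    ``hc`` must already be clipped to the region. Regions with no points
    at all, or fewer than 3 vegetation points, are flagged missing; a
    bare field still reports LPI = 1 and its counts.
    """
    rec = FeatureRecord(
        region_id=roi.region_id,
        genotype=roi.genotype,
        replicate=roi.replicate,
        date=roi.date,
        das=roi.das,
        platform=roi.platform,
    )
    rec.n_ground = hc.n_ground
    rec.n_veg = hc.n_vegetation
    if rec.n_ground + rec.n_veg == 0:
        rec.missing = True
        return rec
    rec.lpi = lpi(rec.n_ground, rec.n_veg)
    veg = hc.vegetation_heights
    if veg.size < 3:
        rec.missing = True
        return rec
    rec.h_mean, rec.h_std, rec.h_skew, rec.h_q3, rec.h_cv = height_statistics(veg)
    rec.h_max = float(veg.max())
    try:
        rec.vci = vci(veg, config.vci_bin_width, hc.ground_threshold)
    except ValueError:
        rec.missing = True
    veg_cloud = hc.cloud.take(~hc.is_ground)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec.hull_volume = hull_volume(veg_cloud)
    rec.cap = float(cap_feature(hc, config.cap))
    return rec


def records_to_frame(records: Iterable[FeatureRecord], drop_missing: bool = False) -> pd.DataFrame:
    """Stack records into the canonical feature table."""
    rows = [asdict(r) for r in records]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=FEATURE_TABLE_COLUMNS)
    if drop_missing:
        df = df[~df["missing"]]
    return df[FEATURE_TABLE_COLUMNS].reset_index(drop=True)


def write_feature_table(records: Iterable[FeatureRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
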