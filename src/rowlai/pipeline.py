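"""End-to-end drivers: study → DTM → features → models → weights."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .features import FeatureConfig, FeatureRecord, extract_features, records_to_frame
from .importance import FeatureWeights, correlation_matrix, loo_feature_weights
from .pointcloud import PointCloud, RegionOfInterest, region_mask
from .regression import Dataset, ModelReport, evaluate, fit_model, split_by_variety
from .synthetic import StudyBundle
from .terrain import DEFAULT_CELL_SIZE, build_dtm, normalize_heights

__all__ = ["extract_study_features", "StudyAnalysis", "run_study_analysis"]


def extract_study_features(
    bare_earth: PointCloud,
    canopy: PointCloud,
    regions: list[RegionOfInterest],
    config: FeatureConfig = FeatureConfig(),
    cell_size: float = DEFAULT_CELL_SIZE,
) -> list[FeatureRecord]:
    """DTM from the bare-earth epoch, then per-region clipped features.

    The DTM is built once and reused for every region, mirroring a
    season-constant terrain model.
    """
    dtm = build_dtm(bare_earth, cell_size=cell_size)
    hc = normalize_heights(canopy, dtm, config.ground_threshold)
    records = []
    for roi in regions:
        sub = hc.take(region_mask(hc.cloud, roi))
        records.append(extract_features(sub, roi, config))
    return records


@dataclass
class StudyAnalysis:
    """Results of one full study run."""

    features: pd.DataFrame
    dataset: Dataset
    reports: dict[str, ModelReport] = field(default_factory=dict)
    weights: FeatureWeights | None = None
    correlations: pd.DataFrame | None = None


def run_study_analysis(
    bundle: StudyBundle,
    families: tuple[str, ...] = ("smlr", "plsr", "svr-rbf"),
    seed: int = 0,
    config: FeatureConfig = FeatureConfig(),
    with_weights: bool = False,
) -> StudyAnalysis:
    """Extract features from a study bundle, fit the model families on a
    variety-level 75/25 split, and (optionally) compute leave-one-out
    feature weights with the SVR-RBF reference model."""
    records = extract_study_features(bundle.bare_earth, bundle.canopy, bundle.regions, config)
    feats = records_to_frame(records)
    ds = Dataset.from_features(feats, bundle.truth)
    train, test = split_by_variety(ds, seed=seed)
    reports: dict[str, ModelReport] = {}
    for family in families:
        report = fit_model(train, family, seed=seed)
        evaluate(report, test)
        reports[family] = report
    analysis = StudyAnalysis(
        features=feats,
        dataset=ds,
        reports=reports,
        correlations=correlation_matrix(ds),
    )
    if with_weights:
        analysis.weights = loo_feature_weights(ds, model="svr-rbf", seed=seed)
    return analysis
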