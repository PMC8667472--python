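import numpy as np
import pytest
from shapely.geometry import Polygon

from rowlai import (
    RegionOfInterest,
    extract_features,
    height_statistics,
    hull_volume,
    lpi,
    records_to_frame,
    vci,
)
from rowlai.features import FeatureRecord, MODEL_FEATURES, FEATURE_TABLE_COLUMNS

from conftest import make_height_cloud


class TestLpi:
    @pytest.mark.parametrize(
        "ng,nv,expected", [(200, 800, 0.2), (0, 500, 0.0), (7, 0, 1.0), (1, 3, 0.25)]
    )
    def test_ratio(self, ng, nv, expected):
        assert lpi(ng, nv) == pytest.approx(expected, abs=1e-12)

    def test_empty_region_errors(self):
        with pytest.raises(ValueError, match="empty region"):
            lpi(0, 0)

    def test_permutation_invariant_through_counts(self):
        # LPI depends on the ground/vegetation counts only, so shuffling
        # the classified points cannot change it
        rng = np.random.default_rng(0)
        flags = rng.random(500) < 0.3
        assert lpi(int(flags.sum()), int((~flags).sum())) == lpi(
            int(flags[::-1].sum()), int((~flags[::-1]).sum())
        )


class TestHeightStatistics:
    def test_hand_computed_quartile(self):
        mean, std, skew, q3, cv = height_statistics([1.0, 2.0, 3.0, 4.0])
        assert mean == pytest.approx(2.5)
        assert q3 == pytest.approx(3.25)  # linear-interpolation percentile
        assert std == pytest.approx(np.sqrt(5.0 / 3.0))
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert cv == pytest.approx(std / 2.5)

    def test_degenerate_constant_sample(self):
        mean, std, skew, q3, _ = height_statistics([2.0, 2.0, 2.0, 2.0])
        assert (mean, std, skew, q3) == (2.0, 0.0, 0.0, 2.0)

    def test_symmetric_sample_zero_skewness(self):
        h = np.r_[1.0, 1.5, 2.0, 2.5, 3.0]
        assert height_statistics(h)[2] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            height_statistics([1.0, 2.0])

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        h = rng.uniform(0.5, 2.0, 50)
        m0, s0, sk0, q0, _ = height_statistics(h)
        m1, s1, sk1, q1, _ = height_statistics(h + 0.7)
        assert m1 == pytest.approx(m0 + 0.7)
        assert q1 == pytest.approx(q0 + 0.7)
        assert s1 == pytest.approx(s0)
        assert sk1 == pytest.approx(sk0)


class TestVci:
    def test_uniform_over_four_bins_is_one(self):
        h = np.repeat([0.15, 0.25, 0.35, 0.45], 25)
        assert vci(h, bin_width=0.10) == pytest.approx(1.0, abs=1e-12)

    def test_single_occupied_bin_is_zero(self):
        h = np.full(40, 0.45)  # top bin of four (span 0.1 -> 0.5)
        assert vci(h, bin_width=0.10) == pytest.approx(0.0, abs=1e-12)

    def test_two_of_four_bins_half_each(self):
        h = np.r_[np.full(50, 0.15), np.full(50, 0.45)]
        assert vci(h, bin_width=0.10) == pytest.approx(np.log(2) / np.log(4), abs=1e-12)

    def test_insufficient_extent_errors(self):
        with pytest.raises(ValueError, match="insufficient vertical extent"):
            vci(np.full(10, 0.15), bin_width=0.10)

    def test_invariant_to_uniform_duplication(self):
        rng = np.random.default_rng(7)
        h = rng.uniform(0.1, 2.0, 200)
        assert vci(np.repeat(h, 3)) == pytest.approx(vci(h), abs=1e-12)

    def test_bounded_unit_interval(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            h = rng.uniform(0.1, rng.uniform(0.4, 3.0), rng.integers(5, 200))
            if h.max() - 0.1 < 0.2:
                continue
            assert 0.0 <= vci(h) <= 1.0


class TestHullVolume:
    def test_unit_cube(self):
        corners = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], float)
        assert hull_volume(corners) == pytest.approx(1.0, abs=1e-12)

    def test_unit_right_tetrahedron(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        assert hull_volume(pts) == pytest.approx(1.0 / 6.0, abs=1e-12)

    def test_degenerate_coplanar_warns_zero(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.warns(UserWarning):
            assert hull_volume(pts) == 0.0

    def test_random_points_bounded_by_box(self):
        rng = np.random.default_rng(10)
        pts = rng.uniform(0, 1, (500, 3)) * np.array([2.0, 1.0, 3.0])
        vol = hull_volume(pts)
        assert 4.5 <= vol <= 6.0  # below the 2x1x3 box volume, approaching it


class TestExtractFeatures:
    def roi(self):
        return RegionOfInterest("r", Polygon([(0, 0), (2, 0), (2, 2), (0, 2)]))

    def test_closed_canopy_zero_lpi(self):
        rng = np.random.default_rng(1)
        hc = make_height_cloud(rng.uniform(0.5, 2.0, 400))
        rec = extract_features(hc, self.roi())
        assert rec.lpi == 0.0 and not rec.missing
        for name in MODEL_FEATURES:
            assert np.isfinite(getattr(rec, name))

    def test_bare_field_lpi_one_vegetation_missing(self):
        rng = np.random.default_rng(2)
        hc = make_height_cloud(rng.uniform(0.0, 0.05, 300))
        rec = extract_features(hc, self.roi())
        assert rec.lpi == 1.0
        assert rec.missing
        assert np.isnan(rec.h_mean)

    def test_two_layer_canopy_vci_hand_entropy(self):
        h = np.r_[np.full(100, 1.0), np.full(100, 2.0)]
        rec = extract_features(make_height_cloud(h), self.roi())
        hb = int(np.ceil((2.0 - 0.1) / 0.1))
        assert rec.vci == pytest.approx(np.log(2) / np.log(hb), abs=1e-12)

    def test_counts_partition(self):
        rng = np.random.default_rng(3)
        h = rng.uniform(0.0, 2.0, 500)
        rec = extract_features(make_height_cloud(h), self.roi())
        assert rec.n_ground + rec.n_veg == 500
        assert rec.lpi == pytest.approx(rec.n_ground / 500)

    def test_feature_table_schema(self):
        rng = np.random.default_rng(5)
        recs = [
            extract_features(make_height_cloud(rng.uniform(0.3, 2.0, 200), seed=i), self.roi())
            for i in range(3)
        ]
        recs.append(FeatureRecord(region_id="empty", missing=True))
        df = records_to_frame(recs)
        assert list(df.columns) == FEATURE_TABLE_COLUMNS
        assert len(df) == 4
        assert len(records_to_frame(recs, drop_missing=True)) == 3
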