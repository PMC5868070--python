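"""Morphometric features: moment ellipses, axis lengths, serialization."""

import math

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from leafdissect.features import (
    FeatureTable,
    LeafFeatures,
    LeafletFeatures,
    leaflet_shape_features,
    read_feature_table,
    whole_leaf_features,
    write_feature_table,
)
from leafdissect.pipeline import analyze_mask
from leafdissect.synthetic import SyntheticLeafSpec, generate_leaf


def moment_axes_oracle(mask: np.ndarray) -> tuple[float, float]:
    """Independent oracle: full axis lengths of the moment-equivalent
    ellipse via eigendecomposition of the pixel-coordinate covariance."""
    pts = np.argwhere(mask).astype(float)
    cov = np.cov(pts.T, bias=True)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    return 4.0 * math.sqrt(eig[0]), 4.0 * math.sqrt(eig[1])


class TestLeafletShape:
    def test_disk_is_nearly_circular(self):
        mask = np.zeros((60, 60), dtype=bool)
        rr, cc = draw_disk((30, 30), 20)
        mask[rr, cc] = True
        f = leaflet_shape_features(mask)
        assert f.eccentricity <= 0.05
        assert f.area == pytest.approx(math.pi * 400, rel=0.02)
        assert f.equivalent_diameter == pytest.approx(math.sqrt(4 * f.area / math.pi))

    def test_two_to_one_ellipse_eccentricity(self):
        mask = np.zeros((90, 140), dtype=bool)
        rr, cc = draw_ellipse(45, 70, 30, 60)
        mask[rr, cc] = True
        f = leaflet_shape_features(mask)
        assert abs(f.eccentricity - math.sqrt(3) / 2) <= 0.02

    def test_axes_match_covariance_eigendecomposition(self):
        """Moment-ellipse axes agree with an independent eigen-oracle."""
        rng = np.random.default_rng(5)
        mask = np.zeros((80, 80), dtype=bool)
        rr, cc = draw_ellipse(40, 40, 18, 30, rotation=0.6)
        mask[rr, cc] = True
        # roughen the boundary into an irregular blob
        noise = rng.random(mask.shape) < 0.02
        from scipy.ndimage import binary_dilation, binary_erosion

        blob = binary_dilation(binary_erosion(mask & ~noise, np.ones((2, 2))))
        f = leaflet_shape_features(blob)
        a, b = moment_axes_oracle(blob)
        assert f.major_axis == pytest.approx(a, abs=1e-9)
        assert f.minor_axis == pytest.approx(b, abs=1e-9)

    def test_eccentricity_in_unit_interval_and_monotone(self):
        eccs = []
        for major in (20, 30, 45, 60):
            mask = np.zeros((140, 140), dtype=bool)
            rr, cc = draw_ellipse(70, 70, 18, major)
            mask[rr, cc] = True
            e = leaflet_shape_features(mask).eccentricity
            assert 0 <= e < 1
            eccs.append(e)
        assert eccs == sorted(eccs)

    def test_single_pixel_reports_zero_eccentricity(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        f = leaflet_shape_features(mask)
        assert f.eccentricity == 0.0
        assert f.area == 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            leaflet_shape_features(np.zeros((4, 4), dtype=bool))

    @pytest.mark.parametrize("radius", [10, 25, 50])
    def test_perimeter_estimator_within_five_percent(self, radius):
        mask = np.zeros((2 * radius + 10,) * 2, dtype=bool)
        rr, cc = draw_disk((radius + 5, radius + 5), radius)
        mask[rr, cc] = True
        f = leaflet_shape_features(mask)
        assert f.perimeter == pytest.approx(2 * math.pi * radius, rel=0.05)


class TestWholeLeaf:
    def test_rectangle_area(self):
        mask = np.zeros((120, 70), dtype=bool)
        mask[10:110, 10:60] = True
        area, perim = whole_leaf_features(mask)
        assert area == 100 * 50

    def test_whole_area_equals_sum_of_partition_classes(self, two_pair_result):
        dis = two_pair_result.dissection
        total = two_pair_result.features.area
        parts = sum(
            dis.class_mask(name).sum() for name in set(dis.legend.values())
        )
        assert parts == total


class TestAxisFeatures:
    def test_petiolule_recovery_on_requested_length(self):
        spec = SyntheticLeafSpec(n_lateral_pairs=1, petiolule_lengths=30.0, seed=9)
        truth = generate_leaf(spec)
        res = analyze_mask(truth.mask)
        lateral = [f for f in res.features.leaflets if f.side in ("left", "right")]
        for f in lateral:
            assert abs(f.petiolule_length - 30.0) <= 3.0

    def test_straight_rachis_recovery_within_two_percent(self, two_pair_truth, two_pair_result):
        truth_len = two_pair_truth.unit_lengths["rachis"]
        assert two_pair_result.features.rachis_length == pytest.approx(
            truth_len, rel=0.02
        )

    def test_single_pair_has_no_inter_rachis(self):
        truth = generate_leaf(SyntheticLeafSpec(n_lateral_pairs=1, seed=2))
        res = analyze_mask(truth.mask)
        laterals = [f for f in res.features.leaflets if f.side in ("left", "right")]
        assert laterals and all(np.isnan(f.inter_rachis) for f in laterals)

    def test_inter_rachis_matches_generator_span(self, three_pair_truth, three_pair_result):
        spans = [
            three_pair_truth.unit_lengths[f"inter_rachis_{i}"] for i in range(2)
        ]
        measured = [
            f.inter_rachis
            for f in three_pair_result.features.leaflets
            if not np.isnan(f.inter_rachis)
        ]
        assert len(measured) == 4  # ranks 2 and 3, both sides
        for m in measured:
            assert min(abs(m - s) / s for s in spans) <= 0.1

    def test_length_features_scale_with_upsampling(self, two_pair_truth):
        """Integer upsampling of the mask scales skeleton lengths
        linearly (within rasterization tolerance)."""
        mask = two_pair_truth.mask
        big = np.kron(mask, np.ones((2, 2), dtype=bool))
        a = analyze_mask(mask)
        b = analyze_mask(big)
        assert b.features.rachis_length == pytest.approx(
            2 * a.features.rachis_length, rel=0.05
        )

    def test_mirror_preserves_sizes_and_swaps_sides(self, two_pair_truth):
        a = analyze_mask(two_pair_truth.mask)
        b = analyze_mask(two_pair_truth.mask[:, ::-1])
        key = lambda r: sorted(
            (f.rank, f.side, round(f.area)) for f in r.features.leaflets
        )
        swapped = [
            (rk, {"left": "right", "right": "left"}.get(sd, sd), ar)
            for rk, sd, ar in key(a)
        ]
        assert sorted(swapped) == key(b)


def _toy_table():
    table = FeatureTable()
    for leaf_id in ("leafA", "leafB"):
        lf = LeafFeatures(leaf_id=leaf_id, area=5000, perimeter=400,
                          rachis_length=150, petiole_length=40,
                          dpi=600, scale_factor=0.25)
        for rank, side in [(1, "left"), (1, "right"), (0, "terminal")]:
            lf.leaflets.append(
                LeafletFeatures(rank=rank, side=side, area=900, perimeter=120,
                                major_axis=44, minor_axis=26, eccentricity=0.8,
                                equivalent_diameter=33.8, petiolule_length=26)
            )
        lf.n_leaflets = 3
        table.append(lf)
    return table


class TestFeatureTable:
    def test_row_count_contract(self):
        df = _toy_table().to_frame()
        assert len(df) == 8  # 2 whole-leaf + 6 leaflet rows
        assert (df["unit"] == "leaf").sum() == 2

    def test_write_read_roundtrip(self, tmp_path):
        df = _toy_table().to_frame()
        path = tmp_path / "features.csv"
        write_feature_table(df, path)
        back = read_feature_table(path)
        assert list(back.columns) == list(df.columns)
        for col in df.columns:
            a, b = df[col], back[col]
            if a.dtype.kind == "f":
                assert np.allclose(a.fillna(-1), b.fillna(-1))
            else:
                assert a.fillna("").astype(str).tolist() == b.fillna("").astype(str).tolist()

    def test_missing_values_serialized_empty_not_zero(self, tmp_path):
        df = _toy_table().to_frame()
        path = tmp_path / "features.csv"
        write_feature_table(df, path)
        text = path.read_text()
        header = text.splitlines()[0].split(",")
        i = header.index("inter_rachis_px")
        leaflet_row = [l for l in text.splitlines()[1:] if ",leaflet," in l][0]
        assert leaflet_row.split(",")[i] == ""

    def test_mm_conversion_uses_effective_dpi(self):
        df = _toy_table().to_frame()
        row = df[df["unit"] == "leaf"].iloc[0]
        factor = 25.4 / (600 * 0.25)  # mm per pixel at effective dpi
        assert row["area_mm2"] == pytest.approx(5000 * factor**2)
        assert row["perimeter_mm"] == pytest.approx(400 * factor)

    def test_empty_table_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_feature_table(FeatureTable(), tmp_path / "x.csv")
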