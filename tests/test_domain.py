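"""Validity-domain geometry, CSR simulation and point/domain I/O."""

import json

import numpy as np
import pytest
from scipy.stats import chisquare

from lgclust import (
    PointPattern,
    SyntheticSpec,
    ValidityDomain,
    generate_csr,
    generate_fixture,
    read_domain,
    read_points,
    write_domain,
    write_points,
)


class TestContains:
    def test_interior_point(self, unit_square):
        assert unit_square.contains((0.5, 0.5))

    def test_point_in_hole_is_outside(self):
        dom = ValidityDomain.from_rings(
            [(0, 0), (1, 0), (1, 1), (0, 1)],
            [[(0.4, 0.4), (0.6, 0.4), (0.6, 0.6), (0.4, 0.6)]],
        )
        assert not dom.contains((0.5, 0.5))
        assert dom.contains((0.1, 0.1))

    def test_point_outside(self, unit_square):
        assert not unit_square.contains((2.0, 2.0))

    def test_boundary_counts_as_inside(self, unit_square):
        assert unit_square.contains((0.0, 0.5))
        assert unit_square.contains((1.0, 1.0))

    def test_nonfinite_coordinates_rejected(self, unit_square):
        with pytest.raises(ValueError):
            unit_square.contains((np.nan, 0.5))

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ValidityDomain.from_rings([(0, 0), (1, 1), (1, 0), (0, 1)])  # bow-tie


class TestCSR:
    def test_all_points_inside_and_count(self, unit_square):
        pat = generate_csr(unit_square, 1000, seed=1)
        assert pat.n == 1000
        assert unit_square.contains_many(pat.coords).all()

    def test_seeded_reproducibility(self, unit_square):
        a = generate_csr(unit_square, 500, seed=7)
        b = generate_csr(unit_square, 500, seed=7)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_rejection_acceptance_rate_matches_area_ratio(self, square_with_hole):
        # hole removes 20% of the bbox area, so a uniform bbox sample should
        # land inside the domain with probability ~0.8
        assert square_with_hole.area == pytest.approx(0.8, abs=1e-9)
        rng = np.random.default_rng(0)
        cand = rng.uniform(0, 1, size=(100000, 2))
        frac = square_with_hole.contains_many(cand).mean()
        assert frac == pytest.approx(0.8, abs=0.01)

    def test_density_uniform_over_partition(self, unit_square):
        # chi-square on a 4x4 partition of a convex domain must not reject
        pat = generate_csr(unit_square, 100000, seed=123)
        ij = np.minimum((pat.coords * 4).astype(int), 3)
        counts = np.bincount(ij[:, 0] * 4 + ij[:, 1], minlength=16)
        assert chisquare(counts).pvalue > 0.01

    def test_points_avoid_holes(self, square_with_hole):
        pat = generate_csr(square_with_hole, 5000, seed=2)
        assert square_with_hole.contains_many(pat.coords).all()


class TestFixtures:
    @pytest.mark.parametrize("kind", ["csr", "blobs", "thomas", "sierpinski", "line", "grid"])
    def test_deterministic_under_seed(self, kind):
        a = generate_fixture(SyntheticSpec(kind, 500, seed=9))
        b = generate_fixture(SyntheticSpec(kind, 500, seed=9))
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_blobs_equal_split_with_labels(self):
        pat = generate_fixture(SyntheticSpec("blobs", 3000, seed=0))
        assert pat.labels is not None
        np.testing.assert_array_equal(np.bincount(pat.labels), [1000, 1000, 1000])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown fixture kind"):
            SyntheticSpec("voronoi", 10)

    def test_grid_is_regular(self):
        pat = generate_fixture(SyntheticSpec("grid", 100))
        xs = np.unique(pat.coords[:, 0])
        assert np.allclose(np.diff(xs), xs[1] - xs[0])


class TestPatternValidation:
    def test_lonlat_units_rejected(self):
        with pytest.raises(ValueError, match="pre-project"):
            PointPattern(np.array([[7.44, 46.95]]), units="degrees")

    def test_point_outside_domain_rejected(self, unit_square):
        with pytest.raises(ValueError, match="outside"):
            PointPattern(np.array([[2.0, 2.0]]), domain=unit_square)

    def test_at_least_one_point(self):
        with pytest.raises(ValueError):
            PointPattern(np.empty((0, 2)))


class TestIO:
    def test_csv_roundtrip_full_precision(self, tmp_path):
        rng = np.random.default_rng(5)
        pat = PointPattern(rng.uniform(0, 1e6, size=(37, 2)))
        f = tmp_path / "pts.csv"
        write_points(pat, f)
        back = read_points(f)
        np.testing.assert_array_equal(back.coords, pat.coords)

    def test_csv_missing_columns(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="x"):
            read_points(f)

    def test_csv_nan_row_named(self, tmp_path):
        f = tmp_path / "nan.csv"
        f.write_text("x,y\n1,2\n,3\n4,5\n")
        with pytest.raises(ValueError, match=r"row\(s\) \[1\]"):
            read_points(f)

    def test_csv_empty_file(self, tmp_path):
        f = tmp_path / "empty.csv"
        f.write_text("x,y\n")
        with pytest.raises(ValueError, match="empty"):
            read_points(f)

    def test_geojson_roundtrip_with_hole(self, tmp_path, square_with_hole):
        f = tmp_path / "dom.geojson"
        write_domain(square_with_hole, f)
        back = read_domain(f)
        assert len(back.holes) == 1
        assert back.area == pytest.approx(square_with_hole.area)

    def test_geojson_feature_collection(self, tmp_path):
        gj = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]]],
                    },
                }
            ],
        }
        f = tmp_path / "fc.geojson"
        f.write_text(json.dumps(gj))
        assert read_domain(f).area == pytest.approx(1.0)

    def test_geojson_wrong_type(self, tmp_path):
        f = tmp_path / "pt.geojson"
        f.write_text(json.dumps({"type": "Point", "coordinates": [0, 0]}))
        with pytest.raises(ValueError, match="unsupported|not a polygon"):
            read_domain(f)
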