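"""Cell-shape statistics: worked examples, oracles and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petalmorph.geometry import (
    GeometryError,
    ImageSample,
    Polygon,
    clwr,
    estimate_cell_number,
    lobeyness,
    polygon_area,
    sample_cells,
    standardize_pamr,
)

UNIT_SQUARE = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], dtype=float)


def regular_polygon(n, r=1.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def star(n_points, r_out, r_in):
    th = np.linspace(0, 2 * np.pi, 2 * n_points, endpoint=False)
    r = np.where(np.arange(2 * n_points) % 2 == 0, r_out, r_in)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _raster_pixel_area(v, rows):
    """Even-odd scanline rasterization: number of pixel centers inside the
    polygon, counted row by row (vectorized over edges x rows)."""
    x0, y0 = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    y = rows[:, None]
    crosses = ((y0[None, :] <= y) & (y1[None, :] > y)) | ((y1[None, :] <= y) & (y0[None, :] > y))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (y - y0[None, :]) / (y1 - y0)[None, :]
    xc = np.where(crosses, x0[None, :] + t * (x1 - x0)[None, :], np.inf)
    xc.sort(axis=1)
    count = 0
    for row in xc:
        xs = row[np.isfinite(row)]
        for a, b in zip(xs[0::2], xs[1::2]):
            count += max(0, int(np.floor(b)) - int(np.floor(a)))
    return count


def raster_solidity(vertices, resolution=2000):
    """Independent rasterization estimate of solidity: pixel-center counts
    for the polygon and its convex hull on a ``resolution``^2 grid."""
    from scipy.spatial import ConvexHull

    v = np.asarray(vertices, dtype=float)
    lo = v.min(axis=0)
    span = (v.max(axis=0) - lo).max()
    px = (v - lo) / span * (resolution - 1)
    rows = np.arange(resolution) + 0.5
    a_poly = _raster_pixel_area(px, rows)
    hull = px[ConvexHull(px).vertices]
    a_hull = _raster_pixel_area(hull, rows)
    return a_poly / a_hull


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area(Polygon(UNIT_SQUARE)) == pytest.approx(1.0)

    def test_plus_shape_shoelace(self, plus_polygon):
        assert polygon_area(plus_polygon) == pytest.approx(5.0)

    def test_winding_invariance(self):
        assert polygon_area(Polygon(UNIT_SQUARE[::-1])) == pytest.approx(1.0)

    def test_rejects_degenerate(self):
        with pytest.raises(GeometryError):
            Polygon(np.array([(0, 0), (1, 1)]))
        with pytest.raises(GeometryError):
            polygon_area(Polygon(np.array([(0, 0), (1, 1), (2, 2)])))


class TestLobeyness:
    @pytest.mark.parametrize("n", [3, 4, 6, 12, 60])
    def test_convex_polygons_have_zero_lobeyness(self, n):
        s, cl = lobeyness(Polygon(regular_polygon(n)))
        assert cl == pytest.approx(0.0, abs=1e-9)
        assert s == pytest.approx(1.0, abs=1e-9)

    def test_plus_shape_exact(self, plus_polygon):
        # hull is the octagon cutting the four corners: area 9 - 4*(1/2) = 7
        s, cl = lobeyness(plus_polygon)
        assert s == pytest.approx(5 / 7, abs=1e-12)
        assert cl == pytest.approx(2 / 7, abs=1e-12)

    def test_four_pointed_star_vs_rasterization(self):
        v = star(4, 2.0, 1.0)
        s, _ = lobeyness(Polygon(v))
        assert s == pytest.approx(raster_solidity(v), abs=1e-3)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        angle=st.floats(0, 2 * np.pi),
        scale=st.floats(0.01, 100),
        dx=st.floats(-1e3, 1e3),
        dy=st.floats(-1e3, 1e3),
    )
    def test_similarity_invariance(self, angle, scale, dx, dy):
        """CL is invariant under rotation, uniform scaling and translation."""
        plus = np.array([
            (1, 0), (2, 0), (2, 1), (3, 1), (3, 2), (2, 2),
            (2, 3), (1, 3), (1, 2), (0, 2), (0, 1), (1, 1),
        ], dtype=float)
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        v = plus @ rot.T * scale + np.array([dx, dy])
        _, cl = lobeyness(Polygon(v))
        assert cl == pytest.approx(2 / 7, abs=1e-9)


class TestRasterizationOracleSuite:
    """Solidity agrees with the pixel-count oracle on a varied shape suite."""

    @pytest.mark.parametrize("i", range(25))
    def test_agreement(self, i):
        rng = np.random.default_rng(1000 + i)
        kind = i % 3
        if kind == 0:  # spiky star
            v = star(3 + i % 7, 2.0, rng.uniform(0.5, 1.5))
        elif kind == 1:  # perturbed regular polygon
            base = regular_polygon(8 + i)
            v = base * rng.uniform(0.7, 1.3, size=(len(base), 1))
        else:  # sinusoidal lobed cell
            th = np.linspace(0, 2 * np.pi, 72, endpoint=False)
            a, k = rng.uniform(0.1, 0.8), int(rng.integers(3, 8))
            r = 1 + a * np.sin(k * th)
            v = np.column_stack([r * np.cos(th), r * np.sin(th)])
        s, _ = lobeyness(Polygon(v))
        assert s == pytest.approx(raster_solidity(v), abs=1e-3)


class TestClwr:
    def test_rectangle_longitudinal_long_side(self):
        rect = np.array([(0, 0), (2, 0), (2, 4), (0, 4)], dtype=float)
        assert clwr(Polygon(rect, longitudinal_axis="y")) == pytest.approx(2.0)

    def test_rectangle_longitudinal_short_side(self):
        rect = np.array([(0, 0), (4, 0), (4, 2), (0, 2)], dtype=float)
        assert clwr(Polygon(rect, longitudinal_axis="y")) == pytest.approx(0.5)

    def test_rotated_square_extents_equal(self):
        c, s = np.cos(np.pi / 4), np.sin(np.pi / 4)
        rot = UNIT_SQUARE @ np.array([[c, -s], [s, c]]).T
        assert clwr(Polygon(rot)) == pytest.approx(1.0)

    def test_axis_aligned_equal_scaling_invariance(self, plus_polygon):
        base = clwr(plus_polygon)
        scaled = Polygon(plus_polygon.vertices * 3.7 + np.array([5.0, -2.0]))
        assert clwr(scaled) == pytest.approx(base, abs=1e-12)


class TestSampleCells:
    def _image(self, n):
        polys = [Polygon(UNIT_SQUARE + i) for i in range(n)]
        return ImageSample(area=100.0, cell_count=n, pamr=0.5, polygons=polys)

    def test_exact_count_returns_all(self):
        assert len(sample_cells(self._image(10), n=10, seed=0)) == 10

    def test_shortfall_returns_all_with_warning(self):
        with pytest.warns(UserWarning):
            got = sample_cells(self._image(7), n=10, seed=0)
        assert len(got) == 7

    def test_deterministic_under_seed(self):
        img = self._image(30)
        a = sample_cells(img, n=10, seed=42)
        b = sample_cells(img, n=10, seed=42)
        assert all(np.array_equal(x.vertices, y.vertices) for x, y in zip(a, b))

    def test_empty_image_errors(self):
        with pytest.raises(GeometryError):
            sample_cells(ImageSample(area=1.0, cell_count=0, pamr=0.0), n=10)


class TestStandardizePamr:
    @pytest.mark.parametrize("idx,k,orient,expected", [
        (1, 9, "basal_first", 0.0),
        (9, 9, "basal_first", 1.0),
        (1, 9, "apical_first", 1.0),
        (5, 9, "basal_first", 0.5),
        (2, 3, "apical_first", 0.5),
    ])
    def test_positions(self, idx, k, orient, expected):
        assert standardize_pamr(idx, k, orient) == pytest.approx(expected)

    def test_single_image_errors(self):
        with pytest.raises(ValueError):
            standardize_pamr(1, 1)


class TestEstimateCellNumber:
    def test_two_densities_worked_example(self):
        imgs = [ImageSample(area=100.0, cell_count=1, pamr=0.0),
                ImageSample(area=100.0, cell_count=2, pamr=1.0)]
        mean, se = estimate_cell_number(imgs, petal_area=1000.0)
        assert mean == pytest.approx(15.0)
        assert se == pytest.approx(5.0)  # sd(10, 20)/sqrt(2)

    def test_equal_densities_zero_se(self):
        imgs = [ImageSample(area=50.0, cell_count=5, pamr=p) for p in (0, 0.5, 1)]
        _, se = estimate_cell_number(imgs, petal_area=1234.0)
        assert se == pytest.approx(0.0)

    def test_against_bruteforce_arithmetic(self):
        rng = np.random.default_rng(3)
        imgs = [ImageSample(area=float(rng.uniform(50, 150)),
                            cell_count=int(rng.integers(10, 60)), pamr=p)
                for p in np.linspace(0, 1, 9)]
        petal = 54321.0
        mean, se = estimate_cell_number(imgs, petal)
        ests = [img.cell_count / img.area * petal for img in imgs]
        m = sum(ests) / len(ests)
        sd = (sum((e - m) ** 2 for e in ests) / (len(ests) - 1)) ** 0.5
        assert mean == pytest.approx(m, abs=1e-9)
        assert se == pytest.approx(sd / 3.0, abs=1e-9)

    def test_single_image_errors(self):
        with pytest.raises(ValueError):
            estimate_cell_number([ImageSample(area=1.0, cell_count=1, pamr=0.0)], 10.0)


class TestAgainstShapely:
    """Independent cross-check: area and solidity via shapely."""

    @pytest.mark.parametrize("i", range(8))
    def test_area_and_solidity(self, i):
        rng = np.random.default_rng(i)
        th = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        r = 1 + 0.6 * np.sin((3 + i) * th)
        v = np.column_stack([r * np.cos(th), r * np.sin(th)]) * rng.uniform(1, 10)
        from shapely.geometry import Polygon as SPoly

        sp = SPoly(v)
        assert polygon_area(Polygon(v)) == pytest.approx(sp.area, rel=1e-12)
        s, _ = lobeyness(Polygon(v))
        assert s == pytest.approx(sp.area / sp.convex_hull.area, rel=1e-12)
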