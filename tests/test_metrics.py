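"""Connectivity/cost metrics: closed-form silhouettes, hulls, balance curves."""

import numpy as np
import pandas as pd
import pytest

import arborfractal as af
from arborfractal.errors import DegenerateHullError, ParameterError
from arborfractal.metrics import (
    _silhouette_area,
    fibonacci_sphere,
)


def segment_arbor(a, b, radius):
    return af.Arbor(
        ids=np.array([1, 2]),
        positions=np.array([a, b], dtype=float),
        radii=np.array([radius, radius]),
        parents=np.array([-1, 1]),
        types=np.array([3, 3]),
    )


class TestProfileArea:
    def test_perpendicular_view_is_stadium(self):
        """L=20, r=1, expansion 2 viewed side-on: stadium of half-width 3."""
        area = _silhouette_area(
            np.array([[0.0, 0.0]]), np.array([[20.0, 0.0]]), np.array([3.0])
        )
        exact = 20 * 2 * 3 + np.pi * 3**2
        assert area == pytest.approx(exact, rel=2e-3)

    def test_axial_view_is_circle(self):
        area = _silhouette_area(
            np.array([[5.0, 5.0]]), np.array([[5.0, 5.0]]), np.array([3.0])
        )
        assert area == pytest.approx(np.pi * 9, rel=2e-3)

    def test_view_average_matches_cauchy_formula(self):
        """Mean projection area of a convex body is its surface area / 4;
        for the capsule of radius 3 around the segment: (2π·3·20 + 4π·9)/4."""
        arbor = segment_arbor([0, 0, 0], [20, 0, 0], 1.0)
        mean_area = af.profile_area(arbor, expansion=2.0, n_views=256)
        capsule_surface = 2 * np.pi * 3 * 20 + 4 * np.pi * 3**2
        assert mean_area == pytest.approx(capsule_surface / 4, rel=0.01)

    def test_monotone_in_expansion(self, stripped_natural):
        areas = [
            af.profile_area(stripped_natural, expansion=e, n_views=6)
            for e in (0.0, 1.0, 2.0, 4.0)
        ]
        assert np.all(np.diff(areas) > 0)

    def test_invalid_parameters(self, stripped_natural):
        with pytest.raises(ParameterError):
            af.profile_area(stripped_natural, n_views=0)
        with pytest.raises(ParameterError):
            af.profile_area(stripped_natural, expansion=-1.0)

    def test_fibonacci_sphere_is_unit_and_spread(self):
        dirs = fibonacci_sphere(100)
        assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0)
        # roughly isotropic: mean direction near zero
        assert np.linalg.norm(dirs.mean(axis=0)) < 0.05


class TestDendriteSurfaceArea:
    def test_single_cylinder_lateral_area(self):
        arbor = segment_arbor([0, 0, 0], [10, 0, 0], 1.0)
        assert af.dendrite_surface_area(arbor) == pytest.approx(
            2 * np.pi * 1 * 10, rel=0.01
        )

    def test_disjoint_cylinders_add(self):
        arbor = af.Arbor(
            ids=np.arange(1, 5),
            positions=np.array(
                [[0, 0, 0], [10, 0, 0], [0, 50, 0], [5, 50, 0]], dtype=float
            ),
            radii=np.array([1.0, 1.0, 0.5, 0.5]),
            parents=np.array([-1, 1, -1, 3]),
            types=np.full(4, 3),
        )
        expected = 2 * np.pi * 1 * 10 + 2 * np.pi * 0.5 * 5
        assert af.dendrite_surface_area(arbor) == pytest.approx(expected, rel=0.01)

    def test_interior_faces_removed(self):
        """A thin cylinder fully inside a fat collinear one contributes ~0."""
        arbor = af.Arbor(
            ids=np.array([1, 2, 3, 4]),
            positions=np.array(
                [[0, 0, 0], [10, 0, 0], [2, 0, 0], [8, 0, 0]], dtype=float
            ),
            radii=np.array([2.0, 2.0, 0.5, 0.5]),
            parents=np.array([-1, 1, -1, 3]),
            types=np.full(4, 3),
        )
        total = af.dendrite_surface_area(arbor)
        fat_only = 2 * np.pi * 2 * 10
        assert total == pytest.approx(fat_only, rel=0.02)


class TestDendriteVolume:
    def test_single_cylinder(self):
        arbor = segment_arbor([0, 0, 0], [10, 0, 0], 1.0)
        assert af.dendrite_volume(arbor) == pytest.approx(10 * np.pi)

    def test_split_segment_volume_unchanged(self):
        whole = segment_arbor([0, 0, 0], [10, 0, 0], 1.0)
        split = af.Arbor(
            ids=np.array([1, 2, 3]),
            positions=np.array([[0, 0, 0], [5, 0, 0], [10, 0, 0]], dtype=float),
            radii=np.ones(3),
            parents=np.array([-1, 1, 2]),
            types=np.full(3, 3),
        )
        assert af.dendrite_volume(split) == pytest.approx(
            af.dendrite_volume(whole)
        )

    def test_alpha_invariance(self, stripped_natural):
        """Distortion preserves lengths and radii, hence V_m exactly."""
        geom = af.decompose_to_angles(stripped_natural)
        base = af.dendrite_volume(stripped_natural)
        for alpha in (0.5, 2.0):
            assert af.dendrite_volume(
                af.apply_angle_multiplier(geom, alpha)
            ) == pytest.approx(base, rel=1e-9)


class TestBoundingHull:
    def test_unit_cube(self):
        corners = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
            dtype=float,
        )
        arbor = af.Arbor(
            ids=np.arange(1, 9), positions=corners, radii=np.full(8, 0.1),
            parents=np.full(8, -1), types=np.full(8, 3),
        )
        A_b, V_b = af.bounding_hull(arbor)
        assert A_b == pytest.approx(6.0)
        assert V_b == pytest.approx(1.0)

    def test_regular_tetrahedron(self):
        a = 2.0
        pts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) * (a / (2 * np.sqrt(2)))
        arbor = af.Arbor(
            ids=np.arange(1, 5), positions=pts, radii=np.full(4, 0.1),
            parents=np.full(4, -1), types=np.full(4, 3),
        )
        A_b, V_b = af.bounding_hull(arbor)
        assert A_b == pytest.approx(np.sqrt(3) * a**2)
        assert V_b == pytest.approx(a**3 / (6 * np.sqrt(2)))

    def test_coplanar_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        arbor = af.Arbor(
            ids=np.arange(1, 5), positions=pts, radii=np.full(4, 0.1),
            parents=np.full(4, -1), types=np.full(4, 3),
        )
        with pytest.raises(DegenerateHullError):
            af.bounding_hull(arbor)

    def test_rigid_motion_invariance(self, stripped_natural):
        A_b, V_b = af.bounding_hull(stripped_natural)
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = af.Arbor(
            ids=stripped_natural.ids,
            positions=stripped_natural.positions @ q + 17.0,
            radii=stripped_natural.radii,
            parents=stripped_natural.parents,
            types=stripped_natural.types,
        )
        A2, V2 = af.bounding_hull(moved)
        assert A2 == pytest.approx(A_b, rel=1e-6)
        assert V2 == pytest.approx(V_b, rel=1e-6)

    def test_hull_bounds_dendrite_volume(self, stripped_natural):
        m = af.compute_arbor_metrics(stripped_natural, n_views=4)
        assert 0 < m.V_m <= m.V_b
        assert m.P > 0 and m.A_s > 0 and m.A_b > 0
        assert np.isfinite([m.P, m.A_s, m.V_m, m.A_b, m.V_b]).all()


class TestBalanceCurves:
    def test_linear_metrics_constant_ratio(self):
        d = np.linspace(1.2, 1.6, 7)
        ensemble = pd.DataFrame(
            {"D_A": d, "P_norm": 2 * d, "A_s_norm": 4 * d, "V_m_norm": 8 * d}
        )
        curves = af.balance_curves(ensemble)
        assert np.allclose(curves.R_PA[~curves.singular_mask_PA], 0.5)
        assert np.allclose(curves.R_PV[~curves.singular_mask_PV], 0.25)

    def test_quadratic_numerator_changes_sign_at_vertex(self):
        d = np.linspace(1.0, 2.0, 9)
        vertex = 1.5
        ensemble = pd.DataFrame(
            {
                "D_A": d,
                "P_norm": (d - vertex) ** 2,
                "A_s_norm": 2 * d,
                "V_m_norm": 3 * d,
            }
        )
        curves = af.balance_curves(ensemble)
        grid = curves.D_A_grid
        r = curves.R_PA
        assert np.all(r[grid < vertex - 0.01] < 0)
        assert np.all(r[grid > vertex + 0.01] > 0)

    def test_singular_denominator_masked(self):
        d = np.linspace(1.0, 2.0, 9)
        ensemble = pd.DataFrame(
            {
                "D_A": d,
                "P_norm": 2 * d,
                "A_s_norm": (d - 1.5) ** 2,  # derivative crosses 0 at 1.5
                "V_m_norm": 3 * d,
            }
        )
        curves = af.balance_curves(ensemble)
        assert curves.singular_mask_PA.any()
        assert np.isnan(curves.R_PA[curves.singular_mask_PA]).all()

    def test_too_few_levels_rejected(self):
        ensemble = pd.DataFrame(
            {"D_A": [1.2, 1.3, 1.4], "P_norm": [1, 2, 3],
             "A_s_norm": [1, 2, 3], "V_m_norm": [1, 2, 3]}
        )
        with pytest.raises(ParameterError):
            af.balance_curves(ensemble)
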