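"""Surface area, local density, projections and alignment."""

import numpy as np
import pytest

import crossatlas as ca
from crossatlas.errors import IntegrityError
from crossatlas.geometry import triangles_from_edges

from conftest import icosphere, toy_atlas


def atlas_from_points(points, edges, egg_length=None):
    n = len(points)
    positions = np.asarray(points, dtype=float)[:, None, :]
    a = toy_atlas(n=n, genes=("g1",), T=1, edges=edges)
    a.positions = positions
    a.egg_length = egg_length or float(
        positions[:, 0, 0].max() - positions[:, 0, 0].min() or 1.0
    )
    return a


class TestSurfaceArea:
    def test_single_right_triangle(self):
        pts = [(0, 0, 0), (1, 0, 0), (0, 1, 0)]
        edges = [(0, 1), (0, 2), (1, 2)]
        atlas = atlas_from_points(pts, edges)
        assert ca.surface_area(atlas, 1) == pytest.approx(0.5)

    def test_degenerate_colinear_triangle_contributes_zero(self):
        pts = [(0, 0, 0), (1, 0, 0), (2, 0, 0)]
        edges = [(0, 1), (0, 2), (1, 2)]
        atlas = atlas_from_points(pts, edges)
        assert ca.surface_area(atlas, 1) == pytest.approx(0.0)

    def test_icosphere_matches_analytic_sphere(self):
        r = 180.0
        verts, edges = icosphere(subdivisions=3, radius=r)
        atlas = atlas_from_points(verts, edges)
        area = ca.surface_area(atlas, 1)
        assert abs(area - 4 * np.pi * r**2) / (4 * np.pi * r**2) < 0.01

    def test_rigid_motion_invariance(self):
        verts, edges = icosphere(subdivisions=2, radius=50.0)
        atlas = atlas_from_points(verts, edges)
        base = ca.surface_area(atlas, 1)
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        moved = atlas_from_points(verts @ rot.T + [5.0, -3.0, 11.0], edges)
        assert ca.surface_area(moved, 1) == pytest.approx(base, rel=1e-9)

    def test_non_triangular_faces_rejected(self):
        # a 4-cycle has no triangles at all
        pts = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)]
        edges = [(0, 1), (1, 2), (2, 3), (0, 3)]
        with pytest.raises(IntegrityError, match="triangul"):
            triangles_from_edges(np.array(edges), 4)


class TestLocalDensity:
    def test_isolated_nucleus_counts_itself(self):
        pts = [(0, 0, 0), (100, 0, 0), (200, 0, 0)]
        edges = [(0, 1), (0, 2), (1, 2)]
        atlas = atlas_from_points(pts, edges)
        dm = ca.local_density(atlas, 1, radius=15.0)
        np.testing.assert_allclose(dm.values, 1 / (np.pi * 15**2))

    def test_uniform_lattice_density(self):
        s = 3.0  # spacing µm, well below the 15 µm disk radius
        m = 24
        xs, ys = np.meshgrid(np.arange(m), np.arange(m))
        pts = np.column_stack([xs.ravel() * s, ys.ravel() * s, np.zeros(m * m)])
        atlas = toy_atlas(n=m * m, genes=("g1",), T=1, edges=[(0, 1)])
        atlas.positions = pts[:, None, :]
        dm = ca.local_density(atlas, 1, radius=15.0)
        lo, hi = 16.0, (m - 1) * s - 16.0
        interior = (
            (pts[:, 0] > lo) & (pts[:, 0] < hi)
            & (pts[:, 1] > lo) & (pts[:, 1] < hi)
        )
        assert abs(dm.values[interior].mean() - 1 / s**2) / (1 / s**2) < 0.10

    def test_density_times_disk_area_is_positive_integer(self, small_atlas):
        dm = ca.local_density(small_atlas, 3)
        counts = dm.values * np.pi * dm.radius**2
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)
        assert np.all(counts >= 1)

    def test_radius_doubling_on_homogeneous_field(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(0, 400, 4000),
                               rng.uniform(0, 400, 4000),
                               np.zeros(4000)])
        atlas = toy_atlas(n=4000, genes=("g1",), T=1, edges=[(0, 1)])
        atlas.positions = pts[:, None, :]
        d1 = ca.local_density(atlas, 1, radius=15.0).values
        d2 = ca.local_density(atlas, 1, radius=30.0).values
        interior = ((pts[:, 0] > 40) & (pts[:, 0] < 360)
                    & (pts[:, 1] > 40) & (pts[:, 1] < 360))
        assert d2[interior].mean() == pytest.approx(d1[interior].mean(), rel=0.05)


class TestProjection:
    def test_dorsal_midline_midpoint(self):
        pts = [(0, 1, 0), (50, 1, 0), (100, 1, 0), (50, -1, 0)]
        edges = [(0, 1), (1, 2), (1, 3), (0, 3), (2, 3)]
        atlas = atlas_from_points(pts, edges)
        pc = ca.cylindrical_projection(atlas, 1)
        assert pc.axial[1] == pytest.approx(0.5)
        assert pc.angle[1] == pytest.approx(0.0)   # dorsal (+y) is angle 0
        assert abs(pc.angle[3]) == pytest.approx(np.pi)  # ventral

    def test_ring_shares_axial_fraction(self):
        ang = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        ring = np.column_stack([np.full(12, 5.0), np.cos(ang), np.sin(ang)])
        pts = np.vstack([[0, 1, 0], ring, [10, 1, 0]])
        atlas = toy_atlas(n=14, genes=("g1",), T=1, edges=[(0, 1)])
        atlas.positions = pts[:, None, :]
        pc = ca.cylindrical_projection(atlas, 1)
        np.testing.assert_allclose(pc.axial[1:13], 0.5)

    def test_round_trip_on_ellipsoid(self, small_atlas):
        """The projection is invertible on the generated surface."""
        t = 1
        pc = ca.cylindrical_projection(small_atlas, t)
        p = small_atlas.positions[:, t - 1, :]
        x = p[:, 0]
        a = (x.max() - x.min()) / 2
        x0 = (x.max() + x.min()) / 2
        u = (pc.axial * 2 - 1)
        r = np.sqrt(np.clip(1 - u**2, 0, None))
        b = small_atlas.egg_length / 4
        recon = np.column_stack([
            x0 + a * u, b * r * np.cos(pc.angle), b * r * np.sin(pc.angle)
        ])
        err = np.linalg.norm(recon - p, axis=1)
        spacing = ca.mean_internuclear_spacing(small_atlas, t)
        assert err.max() < spacing

    def test_angle_range(self, small_atlas):
        pc = ca.cylindrical_projection(small_atlas, 2)
        assert pc.angle.min() >= -np.pi and pc.angle.max() < np.pi
        assert pc.axial.min() >= 0 and pc.axial.max() <= 1


class TestAlign:
    def test_self_alignment_identity(self, small_atlas):
        q, t = ca.align_atlases(small_atlas, small_atlas, 1)
        np.testing.assert_allclose(q, t)

    def test_unit_extent_and_centered(self, null_pair):
        a, b, _ = null_pair
        qa, qb = ca.align_atlases(a, b, 6)
        for p in (qa, qb):
            assert p[:, 0].max() - p[:, 0].min() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(p.mean(axis=0), 0.0, atol=1e-9)

    def test_translation_invariance(self, small_atlas):
        import copy
        shifted = copy.deepcopy(small_atlas)
        shifted.positions = shifted.positions + np.array([37.0, -12.0, 5.0])
        q1, t1 = ca.align_atlases(small_atlas, small_atlas, 3)
        q2, t2 = ca.align_atlases(small_atlas, shifted, 3)
        np.testing.assert_allclose(t1, t2, atol=1e-9)


class TestDensityGrid:
    def _maps(self, atlas, n=2, cohorts=(1, 2)):
        return [
            (ca.local_density(atlas, t), ca.cylindrical_projection(atlas, t))
            for t in cohorts[:n]
        ]

    def test_single_map_sd_zero(self, small_atlas):
        grid = ca.average_density_grid(self._maps(small_atlas, 1))
        np.testing.assert_array_equal(grid.sd, 0.0)
        assert grid.n == 1

    def test_identical_maps_sd_zero(self, small_atlas):
        m = self._maps(small_atlas, 1)
        grid = ca.average_density_grid(m + m)
        np.testing.assert_allclose(grid.sd, 0.0, atol=1e-15)

    def test_constant_density_conserved(self, small_atlas):
        dm = ca.local_density(small_atlas, 1)
        const = ca.DensityMap(values=np.full_like(dm.values, 0.007), cohort=1,
                              radius=dm.radius)
        pc = ca.cylindrical_projection(small_atlas, 1)
        grid = ca.average_density_grid([(const, pc)])
        np.testing.assert_allclose(grid.mean, 0.007)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ca.average_density_grid([])


class TestMorphologyScaling:
    def test_nuclei_count_vs_area_linear_common_slope(self):
        """Across generated embryos of both species, nuclei count scales
        linearly with measured surface area with a shared slope."""
        from crossatlas.synthetic import embryo_series

        slopes = []
        for li, base in enumerate((ca.SpeciesSpec.melanogaster,
                                   ca.SpeciesSpec.pseudoobscura)):
            spec = base(seed=40 + li)
            spec.n_nuclei //= 6  # smaller embryos, same statistical structure
            spec.egg_length /= np.sqrt(6)
            spec.transverse_radii = tuple(r / np.sqrt(6) for r in spec.transverse_radii)
            counts, areas = [], []
            for espec in embryo_series(spec, 5, size_cv=0.08):
                atlas = ca.generate_geometry(espec)
                counts.append(atlas.n_cells)
                areas.append(ca.surface_area(atlas, 1))
            slope, _ = np.polyfit(areas, counts, 1)
            resid = counts - np.polyval(np.polyfit(areas, counts, 1), areas)
            assert np.abs(resid).max() < 0.02 * np.mean(counts)  # linear fit
            slopes.append(slope)
        assert slopes[0] == pytest.approx(slopes[1], rel=0.10)
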