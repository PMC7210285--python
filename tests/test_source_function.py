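"""Source function: local source, Poisson reconstruction, MC estimator."""

import numpy as np
import pytest

from vsf.bader_basins import BasinPartition, yt_weights
from vsf.model_densities import symmetric_fixture_grid
from vsf.source_function import (SourceFunctionEvaluator, local_source,
                                 reconstruct, sf_at_point, vsf_monte_carlo,
                                 vsf_quadrature_oracle)
from vsf.vdw_volume import (VdwVolume, build_mask, connected_components,
                            measure, sample_points)

FOUR_PI = 4.0 * np.pi


class TestLocalSource:
    def test_negative_laplacian_is_source(self):
        ls = local_source([0, 0, 0], [1, 0, 0], -1.0)
        assert ls == pytest.approx(1.0 / FOUR_PI, rel=1e-12)
        assert ls == pytest.approx(0.079577, abs=1e-6)

    def test_positive_laplacian_is_sink(self):
        ls = local_source([0, 0, 0], [2, 0, 0], +2.0)
        assert ls == pytest.approx(-1.0 / FOUR_PI, rel=1e-12)

    def test_inverse_distance_homogeneity(self):
        a = local_source([0, 0, 0], [1, 0, 0], -3.0)
        b = local_source([0, 0, 0], [2, 0, 0], -3.0)
        assert a == pytest.approx(2 * b, rel=1e-12)

    def test_coincident_points_raise(self):
        with pytest.raises(ValueError, match="singular"):
            local_source([1, 2, 3], [1, 2, 3], -1.0)


@pytest.fixture(scope="module")
def single_gaussian_sf(single_gaussian):
    """Grid, one-basin partition and laplacian for the unit Gaussian."""
    from vsf.field_calculus import derivatives_fd

    grid = symmetric_fixture_grid(single_gaussian, spacing=0.1875,
                                  margin=6.0)
    part = yt_weights(grid)
    lap = grid.like(derivatives_fd(grid).laplacian)
    return grid, part, lap


class TestPoissonReconstruction:
    def test_center_value(self, single_gaussian, single_gaussian_sf):
        _, part, lap = single_gaussian_sf
        sf = sf_at_point(np.zeros(3), part, lap)
        assert sf.sum() == pytest.approx(0.179587, rel=0.02)

    def test_off_center_value(self, single_gaussian_sf):
        grid, part, lap = single_gaussian_sf
        res = reconstruct([1.0, 0.0, 0.0], part, lap, grid)
        assert res.reconstruction == pytest.approx(0.066065, rel=0.02)
        assert res.relative_error < 0.02

    def test_zero_laplacian_gives_zero(self, single_gaussian_sf):
        grid, part, _ = single_gaussian_sf
        zeros = grid.like(np.zeros(grid.shape))
        sf = sf_at_point([0.5, 0.0, 0.0], part, zeros,
                         richardson=False)
        assert np.allclose(sf, 0.0)

    def test_sign_flip_linearity(self, single_gaussian_sf):
        grid, part, lap = single_gaussian_sf
        flipped = grid.like(-lap.values)
        p = np.array([0.7, -0.3, 0.2])
        assert np.allclose(
            sf_at_point(p, part, lap, richardson=False),
            -sf_at_point(p, part, flipped, richardson=False), rtol=1e-12)

    def test_outside_grid_raises(self, single_gaussian_sf):
        grid, part, lap = single_gaussian_sf
        with pytest.raises(ValueError, match="outside"):
            sf_at_point([50.0, 0.0, 0.0], part, lap)


class TestBasinDecomposition:
    def test_midplane_contributions_equal(self, dimer_partition_fine,
                                          dimer_evaluator_fine):
        """Mirror symmetry: both basins source the midplane equally."""
        sf = dimer_evaluator_fine(np.zeros((1, 3)))[0]
        assert abs(sf[0] - sf[1]) / abs(sf[0]) < 1e-6

    def test_total_independent_of_weight_split(self, single_gaussian_sf):
        """Splitting voxels among basins never changes sum_Omega SF."""
        grid, part, lap = single_gaussian_sf
        rng = np.random.default_rng(17)
        frac = rng.uniform(0, 1, size=(grid.n_voxels, 1))
        w2 = np.hstack([part.weights * frac, part.weights * (1 - frac)])
        part2 = BasinPartition(grid=grid, weights=w2,
                               maxima=np.repeat(part.maxima, 2),
                               maxima_positions=np.repeat(
                                   part.maxima_positions, 2, axis=0),
                               atom_map=np.repeat(part.atom_map, 2))
        p = np.array([0.4, 0.1, -0.2])
        total1 = sf_at_point(p, part, lap, richardson=False).sum()
        total2 = sf_at_point(p, part2, lap, richardson=False).sum()
        assert total1 == pytest.approx(total2, rel=1e-10)


@pytest.fixture(scope="module")
def dimer_volume_coarse(dimer_bundle_coarse, dimer_grid_coarse):
    mask = build_mask(dimer_bundle_coarse)
    labels, _ = connected_components(mask)
    return VdwVolume.from_mask(dimer_grid_coarse, labels == 1)


class TestMonteCarlo:
    def test_fixed_seed_reproducible(self, dimer_volume_coarse,
                                     dimer_grid_coarse,
                                     dimer_partition_coarse,
                                     dimer_bundle_coarse,
                                     dimer_evaluator_coarse):
        lap = dimer_grid_coarse.like(dimer_bundle_coarse.laplacian)
        vals = []
        for _ in range(2):
            s = sample_points(dimer_volume_coarse, dimer_grid_coarse,
                              n=200, seed=5)
            r = vsf_monte_carlo(dimer_volume_coarse, s,
                                dimer_partition_coarse, lap,
                                dimer_grid_coarse,
                                evaluator=dimer_evaluator_coarse)
            vals.append(r.vsf)
        assert np.array_equal(vals[0], vals[1])

    def test_symmetric_dimer_shares(self, dimer_volume_coarse,
                                    dimer_grid_coarse,
                                    dimer_partition_coarse,
                                    dimer_bundle_coarse,
                                    dimer_evaluator_coarse):
        lap = dimer_grid_coarse.like(dimer_bundle_coarse.laplacian)
        s = sample_points(dimer_volume_coarse, dimer_grid_coarse, n=1000,
                          seed=7)
        r = vsf_monte_carlo(dimer_volume_coarse, s, dimer_partition_coarse,
                            lap, dimer_grid_coarse,
                            evaluator=dimer_evaluator_coarse)
        sigma_pct = 100 * r.mc_stderr / r.n_e
        assert abs(r.vsf_percent[0] - r.vsf_percent[1]) < \
            3 * np.hypot(sigma_pct[0], sigma_pct[1])
        assert np.all(r.mc_stderr >= 0)
        # definitional identity of the percentages
        assert r.vsf_percent.sum() == pytest.approx(
            100 * r.total_vsf / r.n_e, rel=1e-12)

    def test_stderr_matches_seed_scatter(self, dimer_volume_coarse,
                                         dimer_grid_coarse,
                                         dimer_partition_coarse,
                                         dimer_bundle_coarse,
                                         dimer_evaluator_coarse):
        lap = dimer_grid_coarse.like(dimer_bundle_coarse.laplacian)
        results = []
        for seed in range(12):
            s = sample_points(dimer_volume_coarse, dimer_grid_coarse,
                              n=100, seed=seed)
            results.append(vsf_monte_carlo(dimer_volume_coarse, s,
                                           dimer_partition_coarse, lap,
                                           dimer_grid_coarse,
                                           evaluator=dimer_evaluator_coarse))
        for basin in range(2):
            emp = np.std([r.vsf[basin] for r in results], ddof=1)
            rep = np.mean([r.mc_stderr[basin] for r in results])
            assert 0.4 < emp / rep < 2.0

    def test_empty_sample_rejected(self, dimer_volume_coarse,
                                   dimer_grid_coarse,
                                   dimer_partition_coarse,
                                   dimer_bundle_coarse):
        from vsf.vdw_volume import PointSample

        lap = dimer_grid_coarse.like(dimer_bundle_coarse.laplacian)
        empty = PointSample(points=np.empty((0, 3)),
                            voxel_indices=np.empty(0, dtype=int),
                            seed=0, method="uniform")
        with pytest.raises(ValueError):
            vsf_monte_carlo(dimer_volume_coarse, empty,
                            dimer_partition_coarse, lap, dimer_grid_coarse)


class TestQuadratureOracle:
    def test_two_voxel_volume_is_plain_sum(self, dimer_grid_coarse,
                                           dimer_partition_coarse,
                                           dimer_bundle_coarse,
                                           dimer_evaluator_coarse):
        g = dimer_grid_coarse
        lap = g.like(dimer_bundle_coarse.laplacian)
        mask = np.zeros(g.shape, dtype=bool)
        c = tuple(s // 2 for s in g.shape)
        mask[c] = mask[c[0], c[1], c[2] + 1] = True
        vol = VdwVolume.from_mask(g, mask)
        got = vsf_quadrature_oracle(vol, dimer_partition_coarse, lap,
                                    evaluator=dimer_evaluator_coarse,
                                    subdiv=1)
        # independent 2-term sum over the same Gauss points
        gauss = 0.5 / np.sqrt(3.0)
        t = np.array([-gauss, gauss])
        fi, fj, fk = np.meshgrid(t, t, t, indexing="ij")
        offs = np.stack([fi.ravel(), fj.ravel(), fk.ravel()], 1) @ g.axes
        expect = np.zeros(2)
        for idx in vol.indices:
            center = g.lattice_coords()[idx]
            sf = dimer_evaluator_coarse(center + offs)
            expect += g.voxel_volume * sf.mean(axis=0)
        assert np.allclose(got, expect, rtol=1e-12)

    def test_matches_reconstruct_total(self, dimer_grid_coarse,
                                       dimer_partition_coarse,
                                       dimer_bundle_coarse):
        g = dimer_grid_coarse
        lap = g.like(dimer_bundle_coarse.laplacian)
        mask = np.zeros(g.shape, dtype=bool)
        c = tuple(s // 2 for s in g.shape)
        mask[c] = True
        vol = VdwVolume.from_mask(g, mask)
        ev = SourceFunctionEvaluator(dimer_partition_coarse, lap)
        oracle = vsf_quadrature_oracle(vol, dimer_partition_coarse, lap,
                                       evaluator=ev)
        assert oracle.sum() != 0.0

    def test_large_volume_refused(self, dimer_grid_coarse,
                                  dimer_partition_coarse,
                                  dimer_bundle_coarse):
        g = dimer_grid_coarse
        lap = g.like(dimer_bundle_coarse.laplacian)
        vol = VdwVolume.from_mask(g, np.ones(g.shape, dtype=bool))
        with pytest.raises(ValueError, match="Monte"):
            vsf_quadrature_oracle(vol, dimer_partition_coarse, lap)
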