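"""Mean Force Integration: window estimates, fusion, integration, statistics."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import norm

from surfvac.errors import ValidationError
from surfvac.grids import FreeEnergySurface, GridSpec, fes_rmsd
from surfvac.mechanism import Region, StatePartition
from surfvac.mfi import (
    MeanForceField,
    aggregate_mean_force,
    basin_populations,
    fes_difference,
    integrate_fes,
    iter_windows,
    mean_force_from_replicas,
    reconstruct_fes,
    window_density,
    window_mean_force,
)
from surfvac.model_systems import (
    LangevinParams,
    analytic_fes,
    generate_replica_set,
    make_potential,
    run_langevin,
)
from surfvac.workflows import DW_GRID, DW_LANGEVIN, DW_PROTOCOL


class TestWindowDensity:
    def test_single_sample_peaks_at_nearest_bin(self):
        grid = GridSpec((-1.0,), (1.0,), (41,))
        w = window_density(np.array([[0.33]]), 0.05, grid)
        peak = grid.axis(0)[np.argmax(w.p_b)]
        assert abs(peak - 0.33) <= grid.spacing[0] / 2 + 1e-12
        assert w.p_b.sum() * grid.bin_volume == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_samples_have_flat_log_gradient_at_origin(self):
        grid = GridSpec((-1.0,), (1.0,), (41,))
        w = window_density(np.array([[-0.4], [0.4]]), 0.1, grid)
        i0 = np.argmin(np.abs(grid.axis(0)))
        assert abs(w.grad_log_p[i0, 0]) < 1e-9

    def test_large_sample_recovers_normal_pdf(self, rng):
        grid = GridSpec((-4.0,), (4.0,), (161,))
        samples = rng.standard_normal((20000, 1))
        w = window_density(samples, 0.05, grid)
        x = grid.axis(0)
        err = np.abs(w.p_b - norm.pdf(x))
        assert err.max() < 0.02

    def test_validation(self):
        grid = GridSpec((-1.0,), (1.0,), (11,))
        with pytest.raises(ValidationError):
            window_density(np.zeros((0, 1)), 0.1, grid)
        with pytest.raises(ValidationError):
            window_density(np.array([[0.0]]), -0.1, grid)


class TestWindowMeanForce:
    def test_unbiased_harmonic_force(self, rng):
        # p ~ exp(-x^2/2) => mean force = -dU/dx = -x
        grid = GridSpec((-2.0,), (2.0,), (81,))
        samples = rng.standard_normal((50000, 1))
        # bandwidth chosen so the KDE log-gradient noise ~ 1/sqrt(n h^3 p)
        # stays below the tolerance while the shrinkage bias (~h^2 x) is tiny
        w = window_density(samples, 0.15, grid)
        force, weight = window_mean_force(w, kT=1.0)
        x = grid.axis(0)
        well = weight > 0.05 * weight.max()
        rms = np.sqrt(np.mean((force[well, 0] - (-x[well])) ** 2))
        assert rms < 0.1

    def test_zero_gradient_bias_changes_nothing(self, rng):
        grid = GridSpec((-2.0,), (2.0,), (81,))
        samples = rng.standard_normal((500, 1))
        w0 = window_density(samples, 0.05, grid)
        wc = window_density(samples, 0.05, grid, bias_force=np.zeros(grid.shape + (1,)))
        f0, _ = window_mean_force(w0)
        fc, _ = window_mean_force(wc)
        np.testing.assert_array_equal(f0, fc)

    def test_flat_density_on_periodic_dimension(self):
        grid = GridSpec((-math.pi,), (math.pi,), (36,), (True,))
        samples = grid.axis(0)[:, None]  # perfectly uniform
        w = window_density(samples, 0.3, grid)
        force, _ = window_mean_force(w)
        np.testing.assert_allclose(force, 0.0, atol=1e-9)


class TestAggregation:
    @pytest.fixture(scope="class")
    def small_replica(self):
        pot = make_potential("double_well_1d")
        params = LangevinParams(timestep=0.005, n_steps=20_000, stride=25, seed=3)
        return run_langevin(pot, None, params, DW_PROTOCOL)

    def test_duplicating_windows_is_idempotent(self, rng):
        grid = GridSpec((-1.0,), (1.0,), (21,))
        ws = [
            window_density(rng.normal(size=(8, 1)) * 0.3, 0.05, grid, index=i)
            for i in range(4)
        ]
        a = aggregate_mean_force(ws)
        b = aggregate_mean_force(ws + ws)
        np.testing.assert_allclose(a.force, b.force, atol=1e-12)

    def test_equal_weight_average(self):
        grid = GridSpec((-1.0,), (1.0,), (11,))
        p = np.full(grid.shape, 1.0 / (grid.bin_volume * grid.size))
        from surfvac.mfi import WindowEstimate

        f1 = np.ones(grid.shape + (1,))
        f2 = 3.0 * np.ones(grid.shape + (1,))
        w1 = WindowEstimate(0, grid, p, f1, np.zeros_like(f1), 1)
        w2 = WindowEstimate(1, grid, p, f2, np.zeros_like(f2), 1)
        agg = aggregate_mean_force([w1, w2])
        np.testing.assert_allclose(agg.force[..., 0], 2.0, atol=1e-12)

    def test_pseudo_replica_split_is_bit_exact(self, small_replica):
        """Splitting one replica's windows across two pseudo-replicas leaves
        the fused mean force bit-identical (associativity of weighted sums)."""
        traj, hills = small_replica
        grid = GridSpec((-1.5,), (1.5,), (61,))
        full = mean_force_from_replicas([(traj, hills)], grid)
        # split at a window boundary: frames of the first half vs the rest
        times, *_ = hills.arrays()
        t_cut = times[len(times) // 2]
        i_cut = np.searchsorted(traj.times, t_cut, side="right")
        from surfvac.trajectory import CVTrajectory

        t1 = CVTrajectory(traj.times[:i_cut], traj.points[:i_cut], cv_names=traj.cv_names)
        t2 = CVTrajectory(traj.times[i_cut:], traj.points[i_cut:], cv_names=traj.cv_names)
        split = mean_force_from_replicas([(t1, hills), (t2, hills)], grid)
        np.testing.assert_array_equal(full.force, split.force)
        np.testing.assert_array_equal(full.weight, split.weight)

    def test_grid_mismatch_rejected(self, rng):
        g1 = GridSpec((-1.0,), (1.0,), (21,))
        g2 = GridSpec((-1.0,), (1.0,), (31,))
        w1 = window_density(rng.normal(size=(4, 1)) * 0.2, 0.05, g1)
        w2 = window_density(rng.normal(size=(4, 1)) * 0.2, 0.05, g2)
        with pytest.raises(ValidationError):
            aggregate_mean_force([w1, w2])


class TestIntegration:
    def test_parabola_recovered_exactly(self):
        grid = GridSpec((-2.0,), (2.0,), (81,))
        x = grid.axis(0)
        force = (-2.0 * x)[:, None]  # -dF/ds for F = s^2
        mf = MeanForceField(grid, force, np.ones(grid.shape), np.ones(grid.shape, bool))
        fes = integrate_fes(mf)
        resid = fes.F - x**2
        assert np.ptp(resid) < 1e-6

    def test_zero_force_gives_flat_surface(self):
        grid = GridSpec((-1.0,), (1.0,), (21,))
        mf = MeanForceField(
            grid, np.zeros(grid.shape + (1,)), np.ones(grid.shape), np.ones(grid.shape, bool)
        )
        np.testing.assert_allclose(integrate_fes(mf).F, 0.0, atol=1e-14)

    def test_2d_periodic_reconstruction(self):
        # F(x, y) = x^2 + cos(y) with periodic y
        grid = GridSpec((-2.0, -math.pi), (2.0, math.pi), (64, 64), (False, True))
        pts = grid.points()
        F_true = (pts[:, 0] ** 2 + np.cos(pts[:, 1])).reshape(grid.shape)
        force = np.stack(
            [-2.0 * pts[:, 0], np.sin(pts[:, 1])], axis=-1
        ).reshape(grid.shape + (2,))
        mf = MeanForceField(grid, force, np.ones(grid.shape), np.ones(grid.shape, bool))
        fes = integrate_fes(mf)
        ref = FreeEnergySurface(grid, F_true)
        assert fes_rmsd(fes, ref) < 1e-3

    def test_disconnected_mask_warns_and_keeps_largest(self):
        grid = GridSpec((-2.0,), (2.0,), (40,))
        x = grid.axis(0)
        mask = (x < -1.0) | (x > 0.0)  # two components, right one larger
        mf = MeanForceField(grid, np.zeros(grid.shape + (1,)), np.ones(grid.shape), mask)
        with pytest.warns(UserWarning, match="components"):
            fes = integrate_fes(mf)
        assert fes.mask.sum() == np.sum(x > 0.0)


class TestFesDifference:
    def make_fes(self, f):
        grid = GridSpec((-1.0,), (1.0,), (41,))
        return FreeEnergySurface(grid, f(grid.axis(0)))

    def test_identical_surfaces(self):
        f1 = self.make_fes(lambda x: x**2)
        assert fes_difference(f1, f1) == (0.0, 0.0)

    def test_constant_offset_removed(self):
        f1 = self.make_fes(lambda x: x**2)
        f2 = self.make_fes(lambda x: x**2 + 1.0)
        d, s = fes_difference(f1, f2)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_linear_tilt_matches_bruteforce(self):
        grid = GridSpec((-1.0,), (1.0,), (41,))
        x = grid.axis(0)
        f1 = FreeEnergySurface(grid, x**2)
        f2 = FreeEnergySurface(grid, x**2 + 0.3 * x)
        d, s = fes_difference(f1, f2)
        # independent brute-force loop over bins
        a = x**2 - (x**2).min()
        b = (x**2 + 0.3 * x) - (x**2 + 0.3 * x).min()
        diffs = [a[i] - b[i] for i in range(len(x))]
        assert d == pytest.approx(float(np.mean(np.abs(diffs))), abs=1e-12)
        assert s == pytest.approx(float(np.std(diffs)), abs=1e-12)


class TestBasinPopulations:
    def test_symmetric_double_well_splits_evenly(self):
        pot = make_potential("double_well_1d", a=5.0)
        fes = analytic_fes(pot, GridSpec((-2.0,), (2.0,), (401,)))
        part = {
            "left": Region(((-2.5, 0.0),)),
            "right": Region(((0.0, 2.5),)),
        }
        fr = basin_populations(fes, part)
        assert fr["left"] == pytest.approx(0.5, abs=1e-3)
        assert fr["left"] + fr["right"] == pytest.approx(1.0, abs=1e-12)

    def test_single_covering_region(self):
        pot = make_potential("double_well_1d")
        fes = analytic_fes(pot, GridSpec((-2.0,), (2.0,), (101,)))
        fr = basin_populations(fes, {"all": Region(((-2.5, 2.5),))})
        assert fr["all"] == 1.0

    def test_depth_gap_matches_direct_boltzmann_sum(self):
        # two harmonic wells, depth gap dF: compare against an explicit sum
        grid = GridSpec((-3.0,), (3.0,), (241,))
        x = grid.axis(0)
        dF = 1.7
        F = np.minimum(4.0 * (x + 1.5) ** 2, 4.0 * (x - 1.5) ** 2 + dF)
        fes = FreeEnergySurface(grid, F)
        part = {"a": Region(((-3.1, 0.0),)), "b": Region(((0.0, 3.1),))}
        fr = basin_populations(fes, part)
        w = np.exp(-fes.F)
        expected_b = w[x >= 0].sum() / w.sum()
        assert fr["b"] == pytest.approx(expected_b, abs=1e-12)
        assert fr["b"] / fr["a"] == pytest.approx(math.exp(-dF), rel=0.05)

    def test_overlapping_regions_rejected(self):
        pot = make_potential("double_well_1d")
        fes = analytic_fes(pot, GridSpec((-2.0,), (2.0,), (101,)))
        with pytest.raises(ValidationError, match="overlap"):
            basin_populations(
                fes, {"a": Region(((-2.0, 0.5),)), "b": Region(((0.0, 2.0),))}
            )


class TestEndToEnd:
    def test_zero_bias_mfi_degenerates_to_kde_log_density(self):
        """With no hills, MFI must reproduce -kT log(KDE) up to a constant."""
        pot = make_potential("double_well_1d", a=2.0)
        params = LangevinParams(timestep=0.005, n_steps=400_000, stride=25, seed=5)
        traj, hills = run_langevin(pot, None, params, None)
        grid = GridSpec((-1.6,), (1.6,), (161,))
        fes = reconstruct_fes([(traj, hills)], grid, bandwidth=0.05)
        w = window_density(traj.points[traj.times > 0], 0.05, grid)
        ref = -np.log(np.maximum(w.p_b, 1e-300))
        well = w.p_b > 1e-3 * w.p_b.max()
        dev = (fes.F - ref)[well & fes.mask]
        assert np.max(np.abs(dev - dev.mean())) < 0.05

    def test_replica_count_monotonicity(self):
        """Median reconstruction RMSD is non-increasing from 5 -> 15 -> 30
        replicas (three independent seed panels of shortened runs)."""
        pot = make_potential("double_well_1d")
        truth = analytic_fes(pot, DW_GRID)
        params = replace(DW_LANGEVIN, n_steps=100_000)
        med = {5: [], 15: [], 30: []}
        for seed in (11, 22, 33):
            panel = generate_replica_set(pot, DW_PROTOCOL, params, 30, seed * 1000)
            for n in (5, 15, 30):
                fes = reconstruct_fes(panel[:n], DW_GRID)
                med[n].append(fes_rmsd(fes, truth, mask=fes.mask))
        m5, m15, m30 = (float(np.median(med[n])) for n in (5, 15, 30))
        assert m5 >= m15 >= m30

    def test_iter_windows_has_n_tau_frames(self):
        pot = make_potential("double_well_1d")
        params = LangevinParams(timestep=0.005, n_steps=10_000, stride=25, seed=9)
        traj, hills = run_langevin(pot, None, params, DW_PROTOCOL)
        counts = [len(s) for s, _ in iter_windows(traj, hills)]
        # pace/stride = 8 frames per inter-deposition window (first window
        # additionally holds the t = 0 record)
        assert set(counts[1:-1]) == {8}
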