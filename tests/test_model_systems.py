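"""Model potentials, Langevin sampler and molecular fixtures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surfvac.cv import SwitchingSpec, compute_colvar_series
from surfvac.errors import ConfigurationError, SimulationError, ValidationError
from surfvac.grids import GridSpec
from surfvac.model_systems import (
    LangevinParams,
    analytic_fes,
    generate_replica_set,
    make_potential,
    run_langevin,
    synth_molecular_fixture,
    SCRIPTED_Z_TOTAL,
)
from surfvac.bias import BiasProtocol

PRESETS = ["double_well_1d", "three_basin_2d", "detachment_3d"]


class TestPotentials:
    def test_double_well_closed_form(self):
        pot = make_potential("double_well_1d", a=5.0)
        assert pot.energy([1.0]) == pytest.approx(0.0, abs=1e-14)
        assert pot.energy([-1.0]) == pytest.approx(0.0, abs=1e-14)
        assert pot.energy([0.0]) == pytest.approx(5.0)

    @pytest.mark.parametrize("name", PRESETS)
    def test_gradient_vanishes_at_minima(self, name):
        pot = make_potential(name)
        for label, x in pot.minima.items():
            g = pot.gradient(x)
            assert np.linalg.norm(g) < 1e-8, (label, g)

    def test_flipped_lies_above_crystalline(self):
        pot = make_potential("detachment_3d")
        dE = pot.energy(pot.minima["flipped"]) - pot.energy(pot.minima["crystalline"])
        assert dE > 0

    def test_unknown_preset_names_valid_ones(self):
        with pytest.raises(ConfigurationError, match="double_well_1d"):
            make_potential("nonexistent")

    def test_parameter_out_of_range(self):
        with pytest.raises(ValidationError, match="outside documented range"):
            make_potential("double_well_1d", a=-1.0)
        with pytest.raises(ValidationError, match="unknown parameter"):
            make_potential("double_well_1d", b=1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        name=st.sampled_from(PRESETS),
        u=st.lists(st.floats(0.05, 0.95), min_size=3, max_size=3),
    )
    def test_gradient_matches_finite_differences(self, name, u):
        pot = make_potential(name)
        lo, hi = pot.domain
        # keep clear of the quartic walls where the FD step is fine anyway
        x = np.array([lo[d] + u[d] * (hi[d] - lo[d]) for d in range(pot.ndim)])
        g = pot.gradient(x)
        h = 1e-6
        for d in range(pot.ndim):
            e = np.zeros(pot.ndim)
            e[d] = h
            fd = (pot.energy(x + e) - pot.energy(x - e)) / (2 * h)
            assert fd == pytest.approx(g[d], rel=1e-5, abs=1e-6)

    def test_periodic_dimension_exact(self):
        pot = make_potential("detachment_3d")
        rng = np.random.default_rng(5)
        pts = rng.uniform([0, 0, -math.pi], [7, 2.5, math.pi], size=(50, 3))
        shifted = pts.copy()
        shifted[:, 2] += 2 * math.pi
        np.testing.assert_allclose(pot.energy(pts), pot.energy(shifted), rtol=0, atol=1e-10)
        # continuity across the seam
        eps = 1e-8
        a = pot.energy([5.0, 0.3, math.pi - eps])
        b = pot.energy([5.0, 0.3, -math.pi + eps])
        assert abs(a - b) < 1e-6


class TestAnalyticFes:
    def test_double_well_barrier(self):
        pot = make_potential("double_well_1d", a=5.0)
        fes = analytic_fes(pot, GridSpec((-2.0,), (2.0,), (401,)))
        x = fes.grid.axis(0)
        i0 = np.argmin(np.abs(x))
        i1 = np.argmin(np.abs(x - 1.0))
        assert fes.F[i0] - fes.F[i1] == pytest.approx(5.0, abs=1e-12)
        assert fes.F.min() == 0.0

    def test_detachment_minimum_location(self):
        pot = make_potential("detachment_3d")
        grid = GridSpec(
            (-0.5, -0.5, -math.pi), (7.5, 2.8, math.pi), (21, 21, 21), (False, False, True)
        )
        fes = analytic_fes(pot, grid)
        idx = fes.argmin()
        loc = np.array([grid.axis(d)[idx[d]] for d in range(3)])
        cry = pot.minima["crystalline"]
        # same bin as the declared crystalline minimum (angle is periodic)
        spacing = np.array(grid.spacing)
        delta = np.abs(loc - cry)
        delta[2] = min(delta[2], 2 * math.pi - delta[2])
        assert np.all(delta <= spacing)

    def test_grid_outside_domain_rejected(self):
        pot = make_potential("double_well_1d")
        with pytest.raises(ValidationError):
            analytic_fes(pot, GridSpec((-5.0,), (5.0,), (101,)))


class TestLangevin:
    def test_zero_noise_limit_stays_at_minimum(self):
        # vanishing D and kT at fixed mobility D/kT = 1: no noise, no net force
        pot = make_potential("double_well_1d")
        params = LangevinParams(
            timestep=0.005, n_steps=10_000, stride=100, temperature=1e-30,
            diffusion=1e-30, seed=3,
        )
        traj, _ = run_langevin(pot, None, params, None, start=np.array([-1.0]))
        assert np.max(np.abs(traj.points + 1.0)) < 1e-9

    def test_fixed_seed_reproducible(self):
        pot = make_potential("double_well_1d")
        proto = BiasProtocol(widths=(0.1,), height0=1.0, bias_factor=10.0, pace=100)
        params = LangevinParams(timestep=0.005, n_steps=5000, stride=10, seed=42)
        t1, h1 = run_langevin(pot, None, params, proto)
        t2, h2 = run_langevin(pot, None, params, proto)
        np.testing.assert_array_equal(t1.points, t2.points)
        np.testing.assert_array_equal(h1.arrays()[3], h2.arrays()[3])

    def test_unbiased_double_well_symmetry(self):
        # long unbiased run at a low barrier: both wells equally occupied
        pot = make_potential("double_well_1d", a=2.0)
        params = LangevinParams(timestep=0.005, n_steps=2_000_000, stride=25, seed=11)
        traj, _ = run_langevin(pot, None, params, None)
        x = traj.points[:, 0]
        frac = np.mean(x > 0)
        # effective sample size from the number of well alternations
        signs = np.sign(x[np.abs(x) > 0.5])
        n_flips = np.sum(np.diff(signs) != 0)
        se = 0.5 / np.sqrt(max(n_flips, 1))
        assert abs(frac - 0.5) < 3 * se

    def test_detailed_balance_within_well(self):
        # conditional Boltzmann density inside the reactant well (5e6 steps).
        # Restricting to one well removes the slow well-exchange noise; the
        # fine timestep keeps the Euler-Maruyama stationary-density bias
        # (O(dt U'')) below the statistical resolution, and the stride spans
        # two intra-well relaxation times so samples are near-independent.
        pot = make_potential("double_well_1d", a=5.0)
        params = LangevinParams(timestep=5e-4, n_steps=5_000_000, stride=100, seed=7)
        traj, _ = run_langevin(pot, None, params, None, start=np.array([-1.0]))
        x = traj.points[:, 0]
        x = x[x < -0.3]
        edges = np.linspace(-1.6, -0.4, 31)
        counts, _ = np.histogram(x, bins=edges)
        centers = 0.5 * (edges[1:] + edges[:-1])
        p = np.exp(-pot.energy(centers[:, None]))
        p /= p.sum()
        n = counts.sum()
        expected = n * p
        se = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - expected) < 5 * np.maximum(se, 1.0))

    def test_periodic_coordinate_stays_wrapped(self):
        pot = make_potential("detachment_3d")
        params = LangevinParams(
            timestep=0.001, n_steps=50_000, stride=10, diffusion=(0.5, 0.5, 0.5), seed=1
        )
        traj, _ = run_langevin(pot, None, params, None)
        th = traj.points[:, 2]
        assert th.min() >= -math.pi and th.max() < math.pi

    def test_divergence_raises_with_advice(self):
        pot = make_potential("double_well_1d")
        params = LangevinParams(timestep=5.0, n_steps=10_000, stride=10, seed=0)
        with pytest.raises(SimulationError, match="smaller timestep"):
            run_langevin(pot, None, params, None, start=np.array([2.0]))


class TestReplicaSet:
    def test_replicas_distinct_and_seeded(self):
        pot = make_potential("double_well_1d")
        proto = BiasProtocol(widths=(0.1,), height0=1.0, bias_factor=10.0, pace=100)
        params = LangevinParams(timestep=0.005, n_steps=2000, stride=10, seed=999)
        reps = generate_replica_set(pot, proto, params, 5, base_seed=100)
        assert len(reps) == 5
        for (ta, _), (tb, _) in zip(reps, reps[1:]):
            assert not np.array_equal(ta.points, tb.points)
        for _, hills in reps:
            assert len(hills) > 0
        # replica 0 reproduces a direct run with seed base+0 bit-exactly
        from dataclasses import replace

        t0, _ = run_langevin(pot, None, replace(params, seed=100), proto)
        np.testing.assert_array_equal(reps[0][0].points, t0.points)

    def test_n_replicas_validation(self):
        pot = make_potential("double_well_1d")
        params = LangevinParams(timestep=0.005, n_steps=100, stride=10, seed=0)
        with pytest.raises(ValidationError):
            generate_replica_set(pot, None, params, 0, base_seed=1)


class TestMolecularFixtures:
    def test_uniform_gas_coordination_matches_quadrature(self):
        box = (5.0, 5.0, 5.0)
        n = 500  # density 4 nm^-3
        frames = synth_molecular_fixture(n, box, "uniform_gas", seed=8, n_frames=800)
        spec = SwitchingSpec()
        traj = compute_colvar_series(frames, spec)
        mean_cn = traj.points[:, 0].mean()
        # oracle: rho * integral of s(|r|) over the relative-offset cell
        from numpy.polynomial.legendre import leggauss

        t, w = leggauss(48)
        half = np.array(box) / 2.0
        xs = [half[d] * t for d in range(3)]
        ws = [half[d] * w for d in range(3)]
        X, Y, Z = np.meshgrid(xs[0], xs[1], xs[2], indexing="ij")
        r = np.sqrt(X**2 + Y**2 + Z**2)
        integ = np.einsum("i,j,k,ijk->", ws[0], ws[1], ws[2], spec.value(r))
        rho = n / np.prod(box)
        expected = rho * integ
        assert mean_cn == pytest.approx(expected, rel=0.02)

    def test_lattice_slab_is_crystalline(self):
        frames = synth_molecular_fixture(60, (4.0, 4.0, 5.0), "lattice_slab", seed=0)
        traj = compute_colvar_series(frames, SwitchingSpec())
        assert abs(abs(traj.points[0, 2]) - math.pi) < 1e-12
        assert np.ptp(traj.points[:, 0]) < 1e-9  # identical frames -> constant CN
        assert traj.points[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_scripted_detachment_schedule(self):
        frames = synth_molecular_fixture(60, (4.0, 4.0, 5.0), "scripted_detachment", seed=0)
        traj = compute_colvar_series(frames, SwitchingSpec())
        z = traj.points[:, 1]
        assert np.all(np.diff(z) >= -1e-12)
        assert z[-1] == pytest.approx(SCRIPTED_Z_TOTAL, abs=1e-12)

    def test_unknown_layout(self):
        with pytest.raises(ConfigurationError, match="lattice_slab"):
            synth_molecular_fixture(10, 4.0, "bogus", seed=0)
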