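import math

import numpy as np
import pandas as pd
import pytest

from fibergen.distributions import VPKernel, VPParams, lognormal_params_from_moments
from fibergen.network import FiberNetwork, NetworkSpec, build_network
from fibergen.relax import (
    MechanicsParams,
    NeighborList,
    ParticleSystem,
    angle_forces,
    bond_forces,
    contact_forces,
    drag_forces,
    particle_system_from_network,
    percent_fiber_overlap,
    relax,
    step_velocity_verlet,
    stiffness_from_elasticity,
)
from fibergen.tortuosity import FiberPath


def _chain_system(points, diameter=1.0, box=100.0, E=1.0, nu=0.3):
    """One-fiber particle system from explicit points."""
    spec = NetworkSpec(
        box_length=box, volume_fraction=0.01, diameter_mean=diameter,
        diameter_std=0.0, length_mean=10.0, length_std=0.0,
        orientation=VPParams((VPKernel([0, 0, 1], 0.0),)),
        tortuosity=lognormal_params_from_moments(1.0, 0.0),
    )
    path = FiberPath(np.asarray(points, dtype=float), diameter=diameter)
    net = FiberNetwork(fibers=[path], spec=spec,
                       prescribed=pd.DataFrame(), seeds=np.zeros((1, 3)))
    return particle_system_from_network(net, MechanicsParams(youngs=E, poisson=nu))


def _multi_system(paths, box=100.0, **mech):
    spec = NetworkSpec(
        box_length=box, volume_fraction=0.01, diameter_mean=1.0,
        diameter_std=0.0, length_mean=10.0, length_std=0.0,
        orientation=VPParams((VPKernel([0, 0, 1], 0.0),)),
        tortuosity=lognormal_params_from_moments(1.0, 0.0),
    )
    net = FiberNetwork(fibers=list(paths), spec=spec,
                       prescribed=pd.DataFrame(), seeds=np.zeros((len(paths), 3)))
    return net, particle_system_from_network(net, MechanicsParams(**mech))


class TestStiffness:
    def test_bond_stiffness_formula(self):
        kb, _, _ = stiffness_from_elasticity(1.0, 0.3, 1.0, R0=1.0)
        assert kb == pytest.approx(math.pi / 4)

    def test_angle_to_bond_ratio(self):
        kb, kt, _ = stiffness_from_elasticity(2.0, 0.3, 1.5, R0=0.7)
        assert kt / kb == pytest.approx(1.5**2 / 8.0)

    def test_standard_second_moment_halves_angle_stiffness(self):
        _, kt32, _ = stiffness_from_elasticity(1.0, 0.3, 1.0, R0=1.0)
        _, kt64, _ = stiffness_from_elasticity(1.0, 0.3, 1.0, R0=1.0,
                                               standard_second_moment=True)
        assert kt64 == pytest.approx(kt32 / 2)

    def test_contact_stiffness_monotone_in_modulus(self):
        _, _, k1 = stiffness_from_elasticity(1.0, 0.3, 1.0)
        _, _, k2 = stiffness_from_elasticity(5.0, 0.3, 1.0)
        assert 0 < k1 < k2


class TestBondForces:
    def test_equilibrium_zero(self):
        sys_ = _chain_system([[0, 0, 0], [0, 0, 0.5], [0, 0, 1.0]])
        f = bond_forces(sys_)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_stretched_magnitude_and_reaction(self):
        sys_ = _chain_system([[0, 0, 0], [0, 0, 1.0]])
        sys_.positions[1, 2] = 1.1  # stretch by 0.1 from R0=1
        f = bond_forces(sys_)
        kb = sys_.bond_k[0]
        assert np.linalg.norm(f[0]) == pytest.approx(2 * kb * 0.1)
        np.testing.assert_allclose(f[0], -f[1])
        assert f[1][2] < 0  # pulled back toward particle 0

    def test_coincident_particles_raise(self):
        sys_ = _chain_system([[0, 0, 0], [0, 0, 1.0]])
        sys_.positions[1] = sys_.positions[0]
        with pytest.raises(FloatingPointError):
            bond_forces(sys_)


class TestAngleForces:
    def test_rest_angle_zero_force(self):
        sys_ = _chain_system([[0, 0, 0], [1, 0, 0], [2, 0.3, 0]])
        f = angle_forces(sys_)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_trio_forces_sum_to_zero(self, rng):
        pts = rng.standard_normal((5, 3)).cumsum(axis=0) * 2
        sys_ = _chain_system(pts)
        sys_.positions += rng.standard_normal(sys_.positions.shape) * 0.2
        f = angle_forces(sys_)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-12)

    def test_restoring_direction(self):
        # open the angle beyond rest: force should close it back
        sys_ = _chain_system([[0, 0, 0], [1, 0, 0], [1, 1, 0]])  # rest 90 deg
        sys_.positions[2] = [1.5, 0.866, 0]  # opened toward straight
        f = angle_forces(sys_)
        # force on k should push it back toward decreasing theta
        assert np.linalg.norm(f[2]) > 0

    def test_equal_arm_torque_balance(self, rng):
        # with equal arm lengths the trio torque about the center vanishes
        for _ in range(5):
            a = rng.uniform(0.3, math.pi - 0.3)
            pts = [[math.cos(a), math.sin(a), 0], [0, 0, 0], [1, 0, 0]]
            sys_ = _chain_system(pts)
            sys_.ang_theta0[:] = a / 2  # force out of equilibrium
            f = angle_forces(sys_)
            torque = (np.cross(np.asarray(pts[0]), f[0])
                      + np.cross(np.asarray(pts[2]), f[2]))
            np.testing.assert_allclose(torque, 0.0, atol=1e-10)

    def test_collinear_regularization_finite(self):
        sys_ = _chain_system([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        sys_.ang_theta0[:] = math.pi / 2
        f = angle_forces(sys_)
        assert np.all(np.isfinite(f))
        assert np.linalg.norm(f) > 0


class TestContactForces:
    def _pair(self, dist):
        p1 = FiberPath([[0, 0, 0], [0, 0, 0.5], [0, 0, 1.0]], diameter=1.0)
        p2 = FiberPath([[dist, 0, 0], [dist, 0, 0.5], [dist, 0, 1.0]], diameter=1.0)
        return _multi_system([p1, p2])

    def test_zero_beyond_cutoff(self):
        _, sys_ = self._pair(1.2)  # Rc = 1.0
        f = contact_forces(sys_, NeighborList(sys_))
        np.testing.assert_allclose(f, 0.0)

    def test_maximum_at_half_cutoff(self):
        mags = []
        for d in (0.3, 0.5, 0.7):
            _, sys_ = self._pair(d)
            f = contact_forces(sys_, NeighborList(sys_))
            mags.append(np.linalg.norm(f[0]))
        assert mags[1] > mags[0] and mags[1] > mags[2]

    def test_soft_core_vanishes_at_zero_separation(self):
        # fibers extend in opposite z so only the first beads (nearly
        # coincident) are within the cutoff of each other
        p1 = FiberPath([[0, 0, 0], [0, 0, 1.0], [0, 0, 2.0]], diameter=1.0)
        p2 = FiberPath([[1e-9, 0, 0], [1e-9, 0, -1.0], [1e-9, 0, -2.0]], diameter=1.0)
        _, sys_ = _multi_system([p1, p2])
        f = contact_forces(sys_, NeighborList(sys_))
        assert np.linalg.norm(f[0]) < 1e-6

    def test_bonded_pairs_excluded(self):
        sys_ = _chain_system([[0, 0, 0], [0, 0, 0.2], [0, 0, 0.4]])  # overlapping beads
        f = contact_forces(sys_, NeighborList(sys_))
        np.testing.assert_allclose(f, 0.0)


class TestDrag:
    def test_zero_velocity(self):
        sys_ = _chain_system([[0, 0, 0], [0, 0, 1.0]])
        np.testing.assert_allclose(drag_forces(sys_, 1.0), 0.0)

    def test_linearity_in_viscosity(self):
        sys_ = _chain_system([[0, 0, 0], [0, 0, 1.0]])
        sys_.velocities[:] = [[1, 0, 0], [0, 2, 0]]
        f1 = drag_forces(sys_, 1.0)
        f2 = drag_forces(sys_, 2.0)
        np.testing.assert_allclose(f2, 2 * f1)
        np.testing.assert_allclose(f1[0], [-3 * math.pi, 0, 0])

    def test_free_particle_velocity_decay(self):
        """A dragged free particle decays exponentially at rate 3*pi*eta*d/m."""
        sys_ = _chain_system([[0, 0, 0], [0, 0, 5.0]])
        sys_.bonds_i = sys_.bonds_i[:0]
        sys_.bonds_j = sys_.bonds_j[:0]
        sys_.bond_r0 = sys_.bond_r0[:0]
        sys_.bond_k = sys_.bond_k[:0]
        sys_.fixed_mask[:] = False
        sys_.velocities[0] = [1.0, 0, 0]
        eta, dt, m = 0.5, 0.001, 1.0
        params = MechanicsParams(viscosity=eta, dt=dt, fixed_end_steps=0)
        nl = NeighborList(sys_)
        for i in range(1000):
            step_velocity_verlet(sys_, params, nl, dt, eta, step_index=i)
        rate = 3 * math.pi * eta * 1.0 / m
        expected = math.exp(-rate * 1000 * dt)
        assert sys_.velocities[0, 0] == pytest.approx(expected, rel=0.01)


class TestPFO:
    def test_no_overlap_zero(self):
        _, sys_ = _multi_system([
            FiberPath([[0, 0, 0], [0, 0, 1]], diameter=1.0),
            FiberPath([[5, 0, 0], [5, 0, 1]], diameter=1.0),
        ])
        assert percent_fiber_overlap(sys_) == 0.0

    def test_two_coincident_spheres_fifty_percent(self):
        _, sys_ = _multi_system([
            FiberPath([[0, 0, 0], [0, 0, 10]], diameter=1.0),
            FiberPath([[0, 0, 0], [0, 0, -10]], diameter=1.0),
        ])
        # first beads of the two fibers coincide; far ends are separate
        lens = 4 / 3 * math.pi * 0.5**3
        total = 4 * 4 / 3 * math.pi * 0.5**3
        assert percent_fiber_overlap(sys_) == pytest.approx(lens / total * 100)

    def test_lens_volume_matches_monte_carlo(self, rng):
        """Analytic sphere-sphere lens volumes agree with MC integration."""
        from fibergen.relax import _lens_volumes

        for _ in range(5):
            r1, r2 = rng.uniform(0.5, 2.0, 2)
            # partial-overlap regime (containment is covered analytically
            # by the coincident-spheres case)
            d = rng.uniform(abs(r1 - r2) * 1.05 + 0.05, (r1 + r2) * 0.95)
            analytic = _lens_volumes(np.array([d]), np.array([r1]), np.array([r2]))[0]
            # tight bounding box of the lens keeps the MC variance low
            c1 = (d**2 + r1**2 - r2**2) / (2 * d)
            a = math.sqrt(max(r1**2 - c1**2, 1e-12))
            n = 400_000
            lo = np.array([d - r2, -a, -a])
            hi = np.array([r1, a, a])
            pts = rng.uniform(lo, hi, size=(n, 3))
            in1 = (pts**2).sum(1) < r1**2
            c2 = pts - np.array([d, 0, 0])
            in2 = (c2**2).sum(1) < r2**2
            mc = np.mean(in1 & in2) * np.prod(hi - lo)
            assert analytic == pytest.approx(mc, rel=0.01)


class TestIntegrator:
    def test_free_particle_uniform_motion(self):
        sys_ = _chain_system([[0, 0, 0], [0, 0, 5.0]])
        sys_.bonds_i = sys_.bonds_i[:0]; sys_.bonds_j = sys_.bonds_j[:0]
        sys_.bond_r0 = sys_.bond_r0[:0]; sys_.bond_k = sys_.bond_k[:0]
        sys_.fixed_mask[:] = False
        sys_.velocities[0] = [0.5, 0, 0]
        params = MechanicsParams(viscosity=0.0, dt=0.01, fixed_end_steps=0)
        nl = NeighborList(sys_)
        for i in range(100):
            step_velocity_verlet(sys_, params, nl, 0.01, 0.0, step_index=i)
        np.testing.assert_allclose(sys_.positions[0], [0.5, 0, 0], atol=1e-12)

    def test_undamped_dimer_energy_conservation(self):
        """Velocity Verlet conserves a stretched dimer's energy to 0.1%
        over ten thousand steps."""
        sys_ = _chain_system([[0, 0, 0], [0, 0, 1.0]])
        sys_.fixed_mask[:] = False
        sys_.positions[1, 2] = 1.1
        kb = float(sys_.bond_k[0])
        dt = 0.02 * math.sqrt(1.0 / kb)
        params = MechanicsParams(viscosity=0.0, dt=dt, fixed_end_steps=0)
        nl = NeighborList(sys_)

        def energy():
            r = np.linalg.norm(sys_.positions[1] - sys_.positions[0])
            pot = kb * (r - sys_.bond_r0[0]) ** 2
            kin = 0.5 * np.sum(sys_.velocities**2)
            return pot + kin

        e0 = energy()
        drift = 0.0
        for i in range(10_000):
            step_velocity_verlet(sys_, params, nl, dt, 0.0, step_index=i)
            drift = max(drift, abs(energy() - e0))
        assert drift / e0 < 1e-3

    def test_damped_dimer_envelope(self):
        """The stretch amplitude decays like the analytic damped oscillator."""
        sys_ = _chain_system([[0, 0, 0], [0, 0, 1.0]])
        sys_.fixed_mask[:] = False
        sys_.positions[1, 2] = 1.05
        kb = float(sys_.bond_k[0])
        eta = 0.1
        c = 3 * math.pi * eta * 1.0
        dt = 0.01 * math.sqrt(1.0 / kb)
        params = MechanicsParams(viscosity=eta, dt=dt, fixed_end_steps=0)
        nl = NeighborList(sys_)
        n_steps = 20_000
        for i in range(n_steps):
            step_velocity_verlet(sys_, params, nl, dt, eta, step_index=i)
        # relative coordinate: mu s'' = -4 kb s - c s'  (mu = m/2)
        gamma = c / (2 * 0.5)
        t = n_steps * dt
        s = np.linalg.norm(sys_.positions[1] - sys_.positions[0]) - sys_.bond_r0[0]
        envelope = 0.05 * math.exp(-gamma / 2 * t)
        assert abs(s) <= envelope * 1.05

    def test_instability_reported(self):
        sys_ = _chain_system([[0, 0, 0], [0, 0, 1.0]])
        sys_.fixed_mask[:] = False
        sys_.positions[1, 2] = 2.0
        params = MechanicsParams(viscosity=0.0, dt=50.0, fixed_end_steps=0)
        nl = NeighborList(sys_)
        with pytest.raises(FloatingPointError):
            for i in range(100):
                step_velocity_verlet(sys_, params, nl, 50.0, 0.0, step_index=i)


class TestNewtonThirdLaw:
    def test_total_internal_force_vanishes(self, small_network):
        """Bond + angle + contact forces sum to zero over all particles."""
        from fibergen.relax import _conservative_forces

        params = MechanicsParams()
        sys_ = particle_system_from_network(small_network, params)
        nl = NeighborList(sys_)
        f = _conservative_forces(sys_, params, nl)
        scale = np.abs(f).max() or 1.0
        np.testing.assert_allclose(f.sum(axis=0) / scale, 0.0, atol=1e-10)


class TestRelax:
    def test_non_overlapping_input_unchanged(self):
        paths = [
            FiberPath([[0, 0, 0], [0, 0, 0.5], [0, 0, 1.0]], diameter=0.5),
            FiberPath([[3, 0, 0], [3, 0, 0.5], [3, 0, 1.0]], diameter=0.5),
        ]
        net, _ = _multi_system(paths, box=10.0)
        res = relax(net, MechanicsParams(max_steps=500, fixed_end_steps=100,
                                         pfo_every=50, stop_window=200))
        assert res.pfo_trace[:, 1].max() == 0.0
        assert res.change.means["length"] < 0.1
        assert res.change.means["tau"] < 0.1

    def test_two_crossing_fibers_separate(self):
        n = 21
        t = np.linspace(-5, 5, n)
        f1 = FiberPath(np.column_stack([t, np.zeros(n), np.zeros(n)]), diameter=1.0)
        f2 = FiberPath(np.column_stack([np.zeros(n), t, np.full(n, 0.2)]), diameter=1.0)
        net, _ = _multi_system([f1, f2], box=30.0)
        res = relax(net, MechanicsParams(max_steps=4000, fixed_end_steps=200,
                                         pfo_every=100, stop_window=1000))
        assert res.pfo_trace[0, 1] > 0
        assert res.pfo_trace[-1, 1] < 0.05 * res.pfo_trace[0, 1]

    def test_pfo_trend_decreasing(self, small_network):
        res = relax(small_network, MechanicsParams(
            max_steps=1500, fixed_end_steps=200, pfo_every=100, stop_window=600))
        pfo = res.pfo_trace[:, 1]
        assert pfo[-1] < pfo[0]
        # decreasing trend: every value beyond warmup below the initial
        assert np.all(pfo[3:] < pfo[0])

    def test_dissipation_bond_contact_system(self):
        """Kinetic + potential energy is non-increasing for a damped
        bond+contact system (no angle trios)."""
        f1 = FiberPath([[0, 0, 0], [0, 0, 1.0]], diameter=1.0)
        f2 = FiberPath([[0.6, 0, 0], [0.6, 0, 1.0]], diameter=1.0)
        net, sys_ = _multi_system([f1, f2], box=20.0)
        sys_.fixed_mask[:] = False
        params = MechanicsParams(viscosity=0.05, fixed_end_steps=0)
        nl = NeighborList(sys_)
        kb = sys_.bond_k
        dt = 0.02 * math.sqrt(1.0 / kb.max())

        def energy():
            d = sys_.positions[sys_.bonds_i] - sys_.positions[sys_.bonds_j]
            r = np.linalg.norm(d, axis=1)
            pot = float(np.sum(kb * (r - sys_.bond_r0) ** 2))
            i, j = nl.pairs_i, nl.pairs_j
            dd = sys_.minimum_image(sys_.positions[i] - sys_.positions[j])
            rr = np.linalg.norm(dd, axis=1)
            rc = sys_.radii[i] + sys_.radii[j]
            kc = 1.0 / 16.0 * 0.3 ** (1 / 3) * np.sqrt(0.5)
            hit = rr < rc
            pot += float(np.sum(kc * (1 + np.cos(math.pi * rr[hit] / rc[hit]))))
            kin = 0.5 * float(np.sum(sys_.velocities**2))
            return pot + kin

        energies = [energy()]
        for i in range(2000):
            step_velocity_verlet(sys_, params, nl, dt, 0.05, step_index=i)
            if (i + 1) % 100 == 0:
                energies.append(energy())
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-9)
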