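"""Damage dynamics: ionization channels, motion, escape and observables."""

import dataclasses

import numpy as np
import pytest

import xspidam as xd
from xspidam.constants import M_E
from xspidam.dynamics import (MECH_AUGER, MECH_IMPACT, MECH_PHOTO, PhysicsParams,
                              Snapshot, Trajectory, _isotropic_unit,
                              compute_observables, run_trajectory, step_auger,
                              step_collisional, step_motion, step_photoabsorption,
                              system_energy)
from xspidam.pulse import PulseProfile
from xspidam.sample import _new_config


def single_atom_state(tables, element="C", occupancy=None, charge=0):
    cfg = _new_config([element], [[0.0, 0.0, 0.0]], [0], 0.0, "test")
    state = Snapshot.from_configuration(cfg, tables)
    if occupancy is not None:
        state.occupancies[0] = occupancy
        state.charges[0] = charge
    return state


def zero_pulse(n_bins=963, dt=0.027):
    t = (np.arange(n_bins) - (n_bins - 1) / 2) * dt
    return PulseProfile(times=t, n0=np.zeros(n_bins), photon_energy_keV=4.96,
                        focus_fwhm_nm=(250, 160), fdhm_fs=9.0)


class TestPhotoabsorption:
    def test_zero_flux_leaves_state_unchanged(self, tables, rng):
        state = single_atom_state(tables)
        out = step_photoabsorption(state, 0.0, 0.027, tables, rng)
        assert out.charges.sum() == 0 and out.n_free == 0

    def test_absorption_probability_matches_poisson_oracle(self, tables):
        # one neutral C, sigma * phi chosen to give p = 1 - exp(-0.5)
        sigma = tables.photo_cross_section("C", [2, 2, 2, 0, 0, 0, 0], 4.96)
        flux = 0.5 / sigma  # photons/cm^2/fs with dt = 1 fs
        rng = np.random.default_rng(42)
        state = single_atom_state(tables)
        hits = sum(
            step_photoabsorption(state, flux, 1.0, tables, rng).n_free
            for _ in range(2000)
        )
        p_true = 1 - np.exp(-0.5)
        sigma_p = np.sqrt(p_true * (1 - p_true) / 2000)
        assert abs(hits / 2000 - p_true) < 3 * sigma_p

    def test_photoelectron_energy_and_bookkeeping(self, tables):
        rng = np.random.default_rng(0)
        state = single_atom_state(tables)
        out = state
        while out.n_free == 0:
            out = step_photoabsorption(state, 1e23, 1.0, tables, rng)
        assert out.charges[0] == 1
        assert out.occupancies[0].sum() == 5
        ke = 0.5 * M_E * np.sum(out.electron_velocities[0] ** 2)
        # K-shell dominates: KE = 4960 - 284.2 eV
        assert ke == pytest.approx(4960 - 284.2, rel=1e-6)
        assert out.holes[0, 0] == 1  # core hole registered with its Auger clock

    def test_emission_is_isotropic(self):
        dirs = _isotropic_unit(np.random.default_rng(7), 10_000)
        assert np.linalg.norm(dirs.mean(0)) < 0.05


class TestAuger:
    def kshell_hole_state(self, tables):
        state = single_atom_state(tables, "C", occupancy=[1, 2, 2, 0, 0, 0, 0],
                                  charge=1)
        state.holes[0, 0] = 1
        return state

    def test_no_core_holes_is_noop(self, tables, rng):
        state = single_atom_state(tables)
        out = step_auger(state, 26.0, tables, rng)
        assert out.charges[0] == 0 and out.n_free == 0

    def test_decay_fraction_matches_exponential_oracle(self, tables):
        # tau(C) = 6.6 fs, dt = 26 fs -> p = 1 - exp(-26/6.6)
        rng = np.random.default_rng(11)
        state = self.kshell_hole_state(tables)
        n = 1000
        decays = sum(step_auger(state, 26.0, tables, rng).n_free for _ in range(n))
        p_true = 1 - np.exp(-26.0 / tables.auger_lifetime("C"))
        sigma_p = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(decays / n - p_true) < 3 * sigma_p

    def test_decay_bookkeeping_and_kll_energy(self, tables):
        rng = np.random.default_rng(2)
        state = self.kshell_hole_state(tables)
        out = state
        while out.n_free == 0:
            out = step_auger(state, 26.0, tables, rng)
        # exactly one extra charge, one emitted electron, hole cleared
        assert out.charges[0] == 2 and out.n_free == 1
        assert out.holes[0].sum() == 0
        assert out.occupancies[0].tolist() == [2, 2, 0, 0, 0, 0, 0]
        ke = 0.5 * M_E * np.sum(out.electron_velocities[0] ** 2)
        assert ke == pytest.approx(284.2 - 2 * 11.26, rel=1e-6)

    def test_atom_without_two_outer_electrons_relaxes_radiatively(self, tables):
        state = single_atom_state(tables, "C", occupancy=[1, 0, 1, 0, 0, 0, 0],
                                  charge=4)
        state.holes[0, 0] = 1
        rng = np.random.default_rng(3)
        out = step_auger(state, 260.0, tables, rng)
        assert out.n_free == 0 and out.charges[0] == 4
        assert out.occupancies[0].tolist() == [2, 0, 0, 0, 0, 0, 0]


class TestCollisional:
    def test_no_free_electrons_is_noop(self, tables, rng):
        state = single_atom_state(tables)
        out = step_collisional(state, 0.027, tables, rng)
        assert np.array_equal(out.occupancies, state.occupancies)

    def test_event_rate_matches_kinetic_theory(self, tables):
        # one electron crossing a random uniform C gas: rate == n sigma v
        ke = 20.0
        v = np.sqrt(2 * ke / M_E)
        dt = 0.6
        half, n_atoms = 15.0, 324
        density = n_atoms / (2 * half) ** 3
        sigma_A2 = tables.beb_impact_cross_section("C", [2, 2, 2, 0, 0, 0, 0], ke) * 1e16
        p_true = 1 - np.exp(-density * sigma_A2 * v * dt)
        rng = np.random.default_rng(21)
        hits = 0
        trials = 4000
        for _ in range(trials):
            cfg = _new_config(["C"] * n_atoms, rng.uniform(-half, half, (n_atoms, 3)),
                              np.zeros(n_atoms), 0.0, "gas")
            state = Snapshot.from_configuration(cfg, tables)
            state.electron_positions = np.array([[-14.0, 0.0, 0.0]])
            state.electron_velocities = np.array([[v, 0.0, 0.0]])
            state.electron_origins = np.array([0], dtype=np.int8)
            out = step_collisional(state, dt, tables, rng)
            hits += int(out.event_counts[:, MECH_IMPACT].sum())
        rate = -np.log(1 - hits / trials) / dt
        rate_true = density * sigma_A2 * v
        assert abs(rate - rate_true) / rate_true < 0.05

    def test_event_energy_bookkeeping(self, tables):
        ke_in = 100.0
        v = np.sqrt(2 * ke_in / M_E)
        rng = np.random.default_rng(5)
        base = single_atom_state(tables)
        out = base
        while out.event_counts[:, MECH_IMPACT].sum() == 0:
            state = base.copy()
            state.electron_positions = np.array([[-3.0, 0.0, 0.0]])
            state.electron_velocities = np.array([[v, 0.0, 0.0]])
            state.electron_origins = np.array([0], dtype=np.int8)
            out = step_collisional(state, 0.5, tables, rng)
        ke_out = 0.5 * M_E * np.sum(out.electron_velocities**2)
        binding = 11.26  # least-bound C electron (2p)
        assert ke_out == pytest.approx(ke_in - binding, rel=1e-9)
        assert out.charges[0] == 1 and out.n_free == 2


class TestMotion:
    def test_neutral_configuration_is_inertial(self, tables, tiny_toy):
        state = Snapshot.from_configuration(tiny_toy, tables)
        out = step_motion(state, 0.027, tables)
        np.testing.assert_array_equal(out.positions, state.positions)

    def orbit_state(self, tables):
        state = single_atom_state(tables, "C", occupancy=[2, 2, 1, 0, 0, 0, 0],
                                  charge=1)
        state.electron_positions = np.array([[2.0, 0.0, 0.0]])
        # near-circular orbit speed for the softened potential at r = 2 A
        f = 14.399645 * 2.0 / (4.0 + 0.25) ** 1.5
        v = np.sqrt(f * 2.0 / M_E)
        state.electron_velocities = np.array([[0.0, v, 0.0]])
        state.electron_origins = np.array([0], dtype=np.int8)
        return state

    def test_electron_ion_pair_conserves_energy(self, tables):
        state = self.orbit_state(tables)
        e0 = system_energy(state, tables)
        for _ in range(1000):
            state = step_motion(state, 0.027, tables)
        assert state.n_free == 1  # still bound
        e1 = system_energy(state, tables)
        assert abs(e1 - e0) / abs(e0) < 1e-3

    def test_momentum_conservation(self, tables):
        from xspidam.constants import AMU

        state = self.orbit_state(tables)
        m_ion = tables.mass_amu[tables.index("C")] * AMU
        p0 = m_ion * state.velocities[0] + M_E * state.electron_velocities[0]
        scale = M_E * np.linalg.norm(state.electron_velocities[0])
        for _ in range(200):
            state = step_motion(state, 0.027, tables)
        p1 = m_ion * state.velocities[0] + M_E * state.electron_velocities[0]
        assert np.linalg.norm(p1 - p0) / scale < 1e-9


@pytest.fixture(scope="module")
def hydrated_run(tables):
    toy = xd.build_toy_protein(150, radius=11.5, seed=8, allocation="exact")
    wet = xd.add_water_shell(toy, 3.0, seed=9)
    pulse = xd.generate_sase_profile(seed=30)
    return xd.run_trajectory(wet, pulse, seed=31)


class TestRunTrajectory:
    def test_zero_photon_pulse_stays_pristine(self, tiny_toy):
        traj = run_trajectory(tiny_toy, zero_pulse(), seed=1)
        assert len(traj.snapshots) == 100
        for snap in traj.snapshots:
            assert snap.charges.sum() == 0 and snap.n_free == 0
            np.testing.assert_array_equal(snap.positions, snap.initial_positions)

    def test_charge_balance_exact_at_every_snapshot(self, hydrated_run):
        for snap in hydrated_run.snapshots:
            assert snap.charge_balance() == 0

    def test_event_counts_cumulative_and_first_snapshot_pristine(self, hydrated_run):
        first = hydrated_run.snapshots[0]
        assert first.charges.sum() == 0 and first.event_counts.sum() == 0
        prev = first.event_counts
        for snap in hydrated_run.snapshots[1:]:
            assert np.all(snap.event_counts >= prev)
            prev = snap.event_counts
        assert hydrated_run.final.event_counts.sum() > 0

    def test_energetic_electrons_predominantly_escape(self, hydrated_run):
        final = hydrated_run.final
        emitted = final.event_counts.sum()
        assert final.n_escaped > 0.5 * (final.n_free + final.n_escaped)
        assert emitted >= final.n_free + final.n_escaped  # rest recombined

    def test_charges_monotone_without_recombination(self):
        params = PhysicsParams(recombination=False)
        toy = xd.build_toy_protein(200, {"C": 1.0}, radius=13.0, seed=4)
        finals = []
        for s in range(5):
            pulse = xd.generate_sase_profile(seed=60 + s)
            traj = run_trajectory(toy, pulse, params, seed=s)
            prev = traj.snapshots[0].charges
            for snap in traj.snapshots[1:]:
                assert np.all(snap.charges >= prev)
                prev = snap.charges
            finals.append(traj.final.charges.mean())
        assert np.mean(finals) > 0

    def test_deterministic_per_seed(self, tiny_toy, default_pulse):
        a = run_trajectory(tiny_toy, default_pulse, seed=13)
        b = run_trajectory(tiny_toy, default_pulse, seed=13)
        np.testing.assert_array_equal(a.final.positions, b.final.positions)
        np.testing.assert_array_equal(a.final.event_counts, b.final.event_counts)

    def test_mismatched_pulse_grid_rejected(self, tiny_toy):
        with pytest.raises(ValueError, match="grid|timestep"):
            run_trajectory(tiny_toy, zero_pulse(n_bins=100), seed=0)


class TestObservables:
    def test_pristine_trajectory_gives_zero_observables(self, tiny_toy):
        traj = run_trajectory(tiny_toy, zero_pulse(), seed=2)
        obs = compute_observables([traj], "C", "protein")
        assert np.all(obs.mean_charge == 0) and np.all(obs.mean_displacement == 0)

    def test_hand_built_two_snapshot_average(self, tables):
        cfg = _new_config(["C", "C", "O"], np.zeros((3, 3)), [0, 0, 0], 0.0, "t")
        s0 = Snapshot.from_configuration(cfg, tables)
        s1 = s0.copy()
        s1.time = 1.0
        s1.charges = np.array([1, 3, 2])
        s1.positions = s0.positions + np.array([[3, 0, 0], [0, 4, 0], [0, 0, 0]])
        traj = Trajectory(snapshots=[s0, s1], pulse_id=0,
                          base_quaternion=np.array([1.0, 0, 0, 0]), seed=0,
                          timestep_fs=0.027, escape_radius_A=30.0)
        obs = compute_observables([traj], "C", "protein")
        np.testing.assert_allclose(obs.mean_charge, [0.0, 2.0])
        np.testing.assert_allclose(obs.mean_displacement, [0.0, 3.5])

    def test_absent_element_rejected(self, tiny_toy):
        traj = run_trajectory(tiny_toy, zero_pulse(), seed=2)
        with pytest.raises(ValueError, match="Fe|no"):
            compute_observables([traj], "Fe", "water")

    def test_core_shell_charge_structure_in_plasma_regime(self):
        """At strong ionization a quasi-neutral core and a positively charged
        expanding outer shell form (trapped electrons screen the interior)."""
        toy = xd.build_toy_protein(300, radius=14.5, seed=9, allocation="exact")
        wet = xd.add_water_shell(toy, 3.0, seed=10)
        trajs = [
            xd.run_trajectory(wet, xd.generate_sase_profile(n_photons=5e12, seed=40 + s),
                              seed=50 + s)
            for s in range(2)
        ]
        obs = compute_observables(trajs, "O", "all")
        prof = obs.radial_net_charge[-1]
        centers = 0.5 * (obs.radial_edges[1:] + obs.radial_edges[:-1])
        r_bound = wet.bounding_radius
        total_pos = np.mean([t.final.charges.sum() for t in trajs])
        core = prof[centers < r_bound / 2].sum()
        outer = prof[centers > 2 * r_bound / 3].sum()
        assert abs(core) < 0.10 * total_pos
        assert outer > 0.4 * total_pos
        assert prof.min() > -0.05 * total_pos


def test_water_shell_enhances_protein_ionization(tables):
    """Electrons released from the tamper layer penetrate the particle and
    enhance collisional ionization of its light elements."""
    toy = xd.build_toy_protein(400, radius=16.0, seed=3, allocation="exact")
    wet = xd.add_water_shell(toy, 4.0, seed=5)
    protein_c = toy.elements == "C"
    bare, hyd = [], []
    for s in range(8):
        pulse = xd.generate_sase_profile(seed=70 + s)
        bare.append(xd.run_trajectory(toy, pulse, seed=s).final.charges[protein_c].mean())
        hyd.append(
            xd.run_trajectory(wet, pulse, seed=s).final.charges[: len(toy.elements)][
                protein_c
            ].mean()
        )
    assert np.mean(hyd) > np.mean(bare)
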