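"""Detector geometry, structure factors and time-integrated patterns."""

import dataclasses

import numpy as np
import pytest

import xspidam as xd
from xspidam import quaternions as qu
from xspidam.constants import R_E2_CM2, wavelength_A
from xspidam.diffraction import (DEFAULT_COMPONENTS, build_detector,
                                 elastic_amplitude, inelastic_term,
                                 integrate_pattern, poisson_sample)
from xspidam.dynamics import Snapshot, run_trajectory
from xspidam.pulse import focus_area_cm2, rebin_nin
from xspidam.sample import _new_config


def snapshot_of(elements, positions, tables):
    cfg = _new_config(elements, positions, np.zeros(len(elements)), 0.0, "t")
    return Snapshot.from_configuration(cfg, tables)


class TestDetector:
    def test_edge_resolution_of_study_geometry(self, detector):
        # 81x81 pixels of 1200 um at 13 cm and 4.96 keV -> ~7 A at the edge
        assert detector.edge_resolution_A() == pytest.approx(7.1, abs=0.2)

    def test_q_magnitude_consistent_with_scattering_angle(self, detector):
        lam = wavelength_A(4.96)
        expected = 4 * np.pi / lam * np.sin(detector.theta / 2)
        np.testing.assert_allclose(detector.q_abs, expected, rtol=1e-9)

    def test_central_pixel(self, detector):
        c = detector.n_pix // 2
        assert detector.q_abs[c] == 0.0
        assert detector.thomson_cm2_sr[c] == pytest.approx(R_E2_CM2)
        assert detector.omega_sr[c] == pytest.approx(0.12**2 / 13.0**2)

    def test_solid_angle_matches_quadrature(self, detector):
        # numerically integrate the subtended solid angle over pixel areas
        pix, d = 0.12, 13.0
        for iy, ix in [(40, 40), (40, 0), (0, 0), (20, 65)]:
            x0 = (ix - 40) * pix - pix / 2
            y0 = (iy - 40) * pix - pix / 2
            xs = x0 + (np.arange(100) + 0.5) * pix / 100
            ys = y0 + (np.arange(100) + 0.5) * pix / 100
            X, Y = np.meshgrid(xs, ys)
            integrand = d / (X**2 + Y**2 + d**2) ** 1.5
            omega_quad = integrand.sum() * (pix / 100) ** 2
            got = detector.omega_sr[iy * 81 + ix]
            assert got == pytest.approx(omega_quad, rel=1e-3)

    def test_solid_angle_decreases_off_axis(self, detector):
        order = np.argsort(detector.theta)
        omega_sorted = detector.omega_sr[order]
        assert omega_sorted[0] == omega_sorted.max()
        assert omega_sorted[-1] == omega_sorted.min()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            build_detector(distance_cm=0.0)
        with pytest.raises(ValueError):
            build_detector(polarization="circular")


class TestElasticAmplitude:
    def test_single_neutral_atom_at_origin(self, tables, detector):
        snap = snapshot_of(["C"], [[0.0, 0.0, 0.0]], tables)
        F = elastic_amplitude(snap, detector, "all", tables)
        np.testing.assert_allclose(F.imag, 0.0, atol=1e-12)
        np.testing.assert_allclose(
            F.real, tables.elastic_form_factor("C", 6, detector.q_abs), rtol=1e-12
        )

    def test_two_atom_interference_closed_form(self, tables, detector):
        d = 3.0
        snap = snapshot_of(["O", "O"], [[d / 2, 0, 0], [-d / 2, 0, 0]], tables)
        F = elastic_amplitude(snap, detector, "all", tables)
        f = tables.elastic_form_factor("O", 8, detector.q_abs)
        expected = 4 * f**2 * np.cos(detector.qvec[:, 0] * d / 2) ** 2
        for p in np.linspace(0, detector.n_pix - 1, 10, dtype=int):
            assert np.abs(F[p]) ** 2 == pytest.approx(expected[p], abs=1e-9 * 64)

    def test_direct_sum_matches_brute_force_double_loop(self, tables, detector):
        rng = np.random.default_rng(17)
        els = rng.choice(["C", "N", "O", "S"], size=50)
        pos = rng.uniform(-15, 15, (50, 3))
        snap = snapshot_of(els, pos, tables)
        snap.occupancies[0, 2] -= 2  # include an ion
        snap.charges[0] = 2
        F = elastic_amplitude(snap, detector, "all", tables)
        brute = np.zeros(detector.n_pix, dtype=complex)
        for j in range(50):
            f = tables.elastic_form_factor(str(els[j]), int(snap.n_bound[j]),
                                           detector.q_abs)
            brute += f * np.exp(1j * detector.qvec @ pos[j])
        np.testing.assert_allclose(F, brute, rtol=0, atol=1e-10 * np.abs(brute).max())


class TestInelasticTerm:
    def test_zero_at_central_pixel_and_for_stripped_atoms(self, tables, detector):
        snap = snapshot_of(["C", "O"], [[0, 0, 0], [3, 0, 0]], tables)
        S = inelastic_term(snap, detector, "all", tables)
        assert S[detector.n_pix // 2] == 0.0
        snap.occupancies[:] = 0
        snap.charges[:] = [6, 8]
        assert np.all(inelastic_term(snap, detector, "all", tables) == 0.0)

    def test_additivity(self, tables, detector):
        one = snapshot_of(["C"], [[0, 0, 0]], tables)
        two = snapshot_of(["C", "C"], [[0, 0, 0], [4, 0, 0]], tables)
        np.testing.assert_allclose(
            inelastic_term(two, detector, "all", tables),
            2 * inelastic_term(one, detector, "all", tables),
            rtol=1e-12,
        )


class TestIntegratePattern:
    def test_single_bin_pristine_formula(self, tables, detector, tiny_toy):
        """One-term sum: n(q) = Omega dsigma_T n_in |F(q)|^2 exactly."""
        from helpers import static_trajectory, flat_pulse
        traj = static_trajectory(tiny_toy, tables)
        pulse = flat_pulse(n_photons=1e10)
        pat = integrate_pattern(traj, pulse, detector, delta_t=pulse.timestep_fs,
                                components={"protein_elastic"}, precision="double")
        F = elastic_amplitude(traj.snapshots[0], detector, "protein", tables)
        fluence = 1e10 / focus_area_cm2(pulse)  # incident photons per cm^2
        expected = (detector.omega_sr * detector.thomson_cm2_sr * fluence
                    * np.abs(F) ** 2)
        np.testing.assert_allclose(pat.counts, expected, rtol=1e-10)

    def test_full_integration_matches_direct_equation_oracle(
            self, tables, detector, tiny_toy, default_pulse):
        """Incremental integrator == brute-force per-snapshot evaluation of
        the time-integrated scattering model."""
        traj = run_trajectory(tiny_toy, default_pulse, seed=11)
        orient = xd.sample_orientations(1, 3)[0]
        pat = integrate_pattern(traj, default_pulse, detector,
                                final_orientation=orient, precision="double")
        rel = qu.multiply(orient, qu.conjugate(traj.base_quaternion))
        rot = qu.to_matrix(rel)
        snap0 = traj.snapshots[0]
        m = tables.mass_amu[snap0.elem_idx]
        com = (m[:, None] * snap0.initial_positions).sum(0) / m.sum()
        _, nin = rebin_nin(default_pulse, 0.27)
        centers = (np.arange(len(nin)) + 0.5) * (0.27 / default_pulse.timestep_fs)
        steps = np.array([s.step_index for s in traj.snapshots], float)
        assign = np.argmin(np.abs(centers[:, None] - steps[None, :]), axis=1)
        w = np.zeros(len(steps))
        np.add.at(w, assign, nin)
        counts = np.zeros(detector.n_pix)
        for wi, s in zip(w, traj.snapshots):
            if wi == 0:
                continue
            s2 = s.copy()
            s2.positions = (s.positions - com) @ rot.T + com
            F = elastic_amplitude(s2, detector, "protein", tables)
            S = inelastic_term(s2, detector, "all", tables)
            counts += wi * (np.abs(F) ** 2 + S + s.n_free)
        counts *= (detector.omega_sr * detector.thomson_cm2_sr
                   / focus_area_cm2(default_pulse))
        np.testing.assert_allclose(pat.counts, counts, rtol=1e-10)

    def test_pattern_linearity_in_photon_number(self, tables, detector, tiny_toy,
                                                default_pulse):
        traj = run_trajectory(tiny_toy, default_pulse, seed=4)
        double_pulse = dataclasses.replace(default_pulse, n0=2 * default_pulse.n0)
        a = integrate_pattern(traj, default_pulse, detector, precision="double")
        b = integrate_pattern(traj, double_pulse, detector, precision="double")
        np.testing.assert_allclose(b.counts, 2 * a.counts, rtol=1e-12)

    def test_component_sum_equals_all_when_one_elastic_subset(
            self, tables, detector, tiny_toy, default_pulse):
        traj = run_trajectory(tiny_toy, default_pulse, seed=4)
        full = integrate_pattern(traj, default_pulse, detector,
                                 components=DEFAULT_COMPONENTS, precision="double")
        parts = sum(
            integrate_pattern(traj, default_pulse, detector, components={c},
                              precision="double").counts
            for c in DEFAULT_COMPONENTS
        )
        np.testing.assert_allclose(full.counts, parts, rtol=1e-10)

    def test_unknown_component_rejected(self, tiny_toy, default_pulse, detector):
        traj = run_trajectory(tiny_toy, default_pulse, seed=4)
        with pytest.raises(ValueError, match="unknown"):
            integrate_pattern(traj, default_pulse, detector,
                              components={"fluorescence"})

    def test_friedel_symmetry_on_inner_detector(self, tables, detector):
        """|F|^2 of a centrosymmetrized object is Friedel-symmetric on the
        low-angle third of the detector (Ewald curvature is second order)."""
        rng = np.random.default_rng(3)
        pos = rng.uniform(-10, 10, (30, 3))
        pos = np.vstack([pos, -pos])
        snap = snapshot_of(["C"] * 60, pos, tables)
        inten = np.abs(elastic_amplitude(snap, detector, "all", tables)) ** 2
        img = detector.image(inten)
        mirrored = img[::-1, ::-1]
        # the residual is the Ewald-curvature phase q_z*z (first order at
        # speckle minima): graded tolerance, tighter where curvature vanishes
        sl = slice(27, 54)  # inner third around the beam center
        np.testing.assert_allclose(img[sl, sl], mirrored[sl, sl],
                                   atol=0.05 * img[sl, sl].max())
        ctr = slice(38, 43)
        np.testing.assert_allclose(img[ctr, ctr], mirrored[ctr, ctr],
                                   atol=0.01 * img[ctr, ctr].max())

    def test_central_pixel_counts_square_of_total_charge(self, tables, detector,
                                                         tiny_toy):
        from helpers import static_trajectory, flat_pulse
        traj = static_trajectory(tiny_toy, tables)
        pulse = flat_pulse(n_photons=1e11)
        pat = integrate_pattern(traj, pulse, detector,
                                components={"protein_elastic", "compton_bound",
                                            "free_electrons"}, precision="double")
        c = detector.n_pix // 2
        z_sum = sum(tables.z_of(e) for e in tiny_toy.elements)
        fluence = 1e11 / focus_area_cm2(pulse)
        expected = detector.omega_sr[c] * R_E2_CM2 * fluence * z_sum**2
        assert pat.counts[c] == pytest.approx(expected, rel=1e-10)


class TestPoissonSampling:
    def test_zero_pattern_stays_zero(self, detector):
        pat = xd.DiffractionPattern(counts=np.zeros(detector.n_pix),
                                    components=frozenset({"protein_elastic"}),
                                    orientation=np.array([1.0, 0, 0, 0]),
                                    detector_meta=detector.meta())
        out = poisson_sample(pat, seed=1)
        assert out.sampled and np.all(out.counts == 0)

    def test_sample_mean_and_determinism(self, detector):
        pat = xd.DiffractionPattern(counts=np.full(detector.n_pix, 100.0),
                                    components=frozenset({"protein_elastic"}),
                                    orientation=np.array([1.0, 0, 0, 0]),
                                    detector_meta=detector.meta())
        a = poisson_sample(pat, seed=2)
        b = poisson_sample(pat, seed=2)
        np.testing.assert_array_equal(a.counts, b.counts)
        sigma = np.sqrt(100.0 / detector.n_pix)
        assert abs(a.counts.mean() - 100.0) < 3 * sigma
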