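"""Shared construction helpers for the test suite."""

import numpy as np

from xspidam.dynamics import PhysicsParams, Snapshot, Trajectory
from xspidam.pulse import PulseProfile


def flat_pulse(n_photons=1e10, n_bins=10, dt=0.027):
    """Uniform pulse: all photons spread over a short flat window."""
    t = np.arange(n_bins) * dt
    return PulseProfile(times=t, n0=np.full(n_bins, n_photons / n_bins),
                        photon_energy_keV=4.96, focus_fwhm_nm=(250, 160),
                        fdhm_fs=9.0)


def static_trajectory(config, tables):
    """One-snapshot pristine trajectory (undamaged, static sample)."""
    snap = Snapshot.from_configuration(config, tables)
    snap.step_index = 0
    return Trajectory(snapshots=[snap], pulse_id=0,
                      base_quaternion=np.array([1.0, 0, 0, 0]), seed=0,
                      timestep_fs=0.027, escape_radius_A=0.0,
                      params=PhysicsParams())
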