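"""SASE-like temporal pulse profiles and fluence bookkeeping.

A partial-coherence surrogate replaces propagated FEL wavefronts: each
profile is a Gaussian envelope (set by the FDHM) multiplied by the squared
magnitude of low-pass-filtered complex Gaussian noise, which reproduces
the spiky sub-femtosecond intensity structure of SASE radiation with a
spike width of order the coherence time. The spatial profile is reduced
to a single fluence number at the sample (particle much smaller than the
focus); no transverse wavefront is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .constants import KEV_TO_J

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PulseProfile:
    """Photon-number time series n0(t).

    times: uniform grid in fs; n0: expected photons per time bin (>= 0);
    photon_energy keV; focus_fwhm (x, y) in nm; fdhm_fs is the nominal
    envelope duration used for intensity bookkeeping.
    """

    times: np.ndarray
    n0: np.ndarray
    photon_energy_keV: float
    focus_fwhm_nm: tuple
    fdhm_fs: float
    profile_id: int = 0

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        n0 = np.asarray(self.n0, dtype=float)
        if times.ndim != 1 or times.shape != n0.shape:
            raise ValueError("times and n0 must be matching 1-D arrays")
        dt = np.diff(times)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-9 * dt[0]):
            raise ValueError("times must be strictly increasing and uniform")
        if np.any(n0 < 0):
            raise ValueError("n0 must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "n0", n0)

    @property
    def timestep_fs(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_total(self) -> float:
        return float(self.n0.sum())

    def fdhm_measured(self) -> float:
        """Full duration at half maximum of this profile, in fs."""
        half = self.n0.max() / 2.0
        above = np.nonzero(self.n0 >= half)[0]
        return float(self.times[above[-1]] - self.times[above[0]]) + self.timestep_fs


def generate_sase_profile(
    photon_energy_keV: float = 4.96,
    fdhm_fs: float = 9.0,
    n_photons: float = 5e11,
    coherence_time_fs: float | None = 0.25,
    timestep_fs: float = 0.027,
    seed: int = 0,
    span_fs: float = 26.0,
    focus_fwhm_nm: tuple = (250.0, 160.0),
    profile_id: int = 0,
) -> PulseProfile:
    """Generate one surrogate SASE temporal profile.

    ``coherence_time_fs=None`` (or inf) returns the smooth envelope alone.
    Deterministic for a fixed seed.
    """
    for name, v in (("fdhm", fdhm_fs), ("timestep", timestep_fs), ("n_photons", n_photons)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    n_bins = int(round(span_fs / timestep_fs))
    times = (np.arange(n_bins) - (n_bins - 1) / 2.0) * timestep_fs
    sigma_t = fdhm_fs * _FWHM_TO_SIGMA
    envelope = np.exp(-0.5 * (times / sigma_t) ** 2)

    if coherence_time_fs is None or not np.isfinite(coherence_time_fs):
        intensity = envelope
    else:
        if coherence_time_fs <= 0:
            raise ValueError("coherence_time must be > 0")
        rng = np.random.default_rng(seed)
        noise = rng.normal(size=n_bins) + 1j * rng.normal(size=n_bins)
        sig_bins = coherence_time_fs * _FWHM_TO_SIGMA / timestep_fs
        field = gaussian_filter1d(noise.real, sig_bins, mode="wrap") + 1j * gaussian_filter1d(
            noise.imag, sig_bins, mode="wrap"
        )
        intensity = envelope * np.abs(field) ** 2
    n0 = intensity * (n_photons / intensity.sum())
    return PulseProfile(
        times=times,
        n0=n0,
        photon_energy_keV=photon_energy_keV,
        focus_fwhm_nm=tuple(focus_fwhm_nm),
        fdhm_fs=fdhm_fs,
        profile_id=profile_id,
    )


def align_time_zero(profiles) -> list:
    """Shift all profiles by a common time so the summed profile peaks at t=0."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    step = profiles[0].timestep_fs
    for p in profiles:
        if abs(p.timestep_fs - step) > 1e-12 or p.times.shape != profiles[0].times.shape:
            raise ValueError("profiles must share the time grid")
    total = np.sum([p.n0 for p in profiles], axis=0)
    t_peak = profiles[0].times[int(np.argmax(total))]
    return [replace(p, times=p.times - t_peak) for p in profiles]


def rebin_nin(profile: PulseProfile, delta_t: float):
    """Partition the time axis into half-open windows [t, t + delta_t).

    Returns (t_i, n_in) with exact photon conservation. delta_t must be an
    integer multiple of the grid step.
    """
    step = profile.timestep_fs
    k = delta_t / step
    if abs(k - round(k)) > 1e-6:
        raise ValueError(f"delta_t={delta_t} is not an integer multiple of the grid step {step}")
    k = int(round(k))
    n = len(profile.n0)
    n_bins = int(np.ceil(n / k))
    padded = np.zeros(n_bins * k)
    padded[:n] = profile.n0
    n_in = padded.reshape(n_bins, k).sum(1)
    t_i = profile.times[0] + np.arange(n_bins) * delta_t
    return t_i, n_in


def fluence_and_intensity(profile: PulseProfile):
    """(fluence J/cm^2, peak intensity W/cm^2) from photon count and focus.

    fluence = pulse energy / (FWHM_x * FWHM_y); intensity = fluence / FDHM.
    """
    fx, fy = profile.focus_fwhm_nm
    area_cm2 = (fx * 1e-7) * (fy * 1e-7)
    if area_cm2 <= 0:
        raise ValueError("focus area must be positive")
    energy_J = profile.n_total * profile.photon_energy_keV * KEV_TO_J
    fluence = energy_J / area_cm2
    intensity = fluence / (profile.fdhm_fs * 1e-15)
    return fluence, intensity


def focus_area_cm2(profile: PulseProfile) -> float:
    """Effective focus area FWHM_x * FWHM_y in cm^2."""
    fx, fy = profile.focus_fwhm_nm
    return (fx * 1e-7) * (fy * 1e-7)


def flux_density_per_bin(profile: PulseProfile) -> np.ndarray:
    """Incident photons per cm^2 in each time bin (for the damage model)."""
    return profile.n0 / focus_area_cm2(profile)
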