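"""Time-integrated 2D diffraction patterns from damage trajectories.

The expected photon count on a pixel with scattering vector q is

    n(q) = Omega * dsigma_T/dOmega * sum_i phi_in(t_i)
           [ |F(q, t_i)|^2 + S(q, t_i) + N_free(t_i) ]

where phi_in(t_i) is the incident photon fluence (photons/cm^2 at the
sample, i.e. window photons over the focus area) in the time window around
t_i, F is the coherent (elastic) structure factor of the selected bound
atoms, S the incoherent (Compton) scattering strength of the selected
bound atoms, and N_free the number of quasi-free electrons (flat
background at the Thomson cross section). Components are selected by
flags, so e.g. water elastic scattering is simply never summed rather
than computed and subtracted. No photon or detector noise is applied by
default; ``poisson_sample`` is available off-path.

Compton scattering is treated at the Thomson cross section and the
Compton wavelength shift is ignored, mirroring the time-integrated model
above.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import quaternions
from .atomic_data import ScatteringTables, default_tables
from .constants import R_E2_CM2, wavelength_A
from .pulse import PulseProfile, focus_area_cm2, rebin_nin
from .sample import PROTEIN, WATER

COMPONENTS = frozenset(
    {"protein_elastic", "water_elastic", "compton_bound", "free_electrons"}
)
DEFAULT_COMPONENTS = frozenset({"protein_elastic", "compton_bound", "free_electrons"})
ELASTIC_ONLY = frozenset({"protein_elastic"})


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat pixel-array detector normal to the beam, with per-pixel
    Ewald-sphere scattering vectors, solid angles and Thomson factors."""

    n_pixels: tuple
    pixel_size_um: float
    distance_cm: float
    photon_energy_keV: float
    polarization: str
    qvec: np.ndarray        # (P, 3) A^-1
    q_abs: np.ndarray       # (P,)
    theta: np.ndarray       # (P,) scattering angle, rad
    omega_sr: np.ndarray    # (P,) pixel solid angle
    thomson_cm2_sr: np.ndarray  # (P,) r_e^2 * P(theta, phi)

    @property
    def n_pix(self) -> int:
        return len(self.q_abs)

    @property
    def shape(self) -> tuple:
        return tuple(self.n_pixels)

    def image(self, flat: np.ndarray) -> np.ndarray:
        return np.asarray(flat).reshape(self.shape)

    def meta(self) -> tuple:
        return (self.n_pixels, self.pixel_size_um, self.distance_cm,
                self.photon_energy_keV, self.polarization)

    def edge_resolution_A(self) -> float:
        """Full-period resolution 2 pi / |q| at the edge-center pixel."""
        ny, nx = self.n_pixels
        idx = (ny // 2) * nx  # row center, first column
        return float(2.0 * np.pi / self.q_abs[idx])

    def corner_resolution_A(self) -> float:
        return float(2.0 * np.pi / self.q_abs.max())


def build_detector(
    n_pixels=(81, 81),
    pixel_size_um: float = 1200.0,
    distance_cm: float = 13.0,
    photon_energy_keV: float = 4.96,
    polarization: str = "horizontal",
) -> DetectorGeometry:
    """Construct the detector geometry.

    Odd pixel counts put the beam center on the central pixel. Per pixel:
    q = k_out - k_in with |k| = 2 pi / lambda; Omega = A cos^3(theta)/d^2;
    Thomson factor r_e^2 P with P = 1 - (sin(theta) cos(phi))^2 for
    horizontal polarization and (1 + cos^2(theta))/2 for "none".
    """
    ny, nx = n_pixels
    if min(ny, nx) < 1 or pixel_size_um <= 0 or distance_cm <= 0 or photon_energy_keV <= 0:
        raise ValueError("detector parameters must be positive")
    if polarization not in ("horizontal", "none"):
        raise ValueError(f"unknown polarization {polarization!r}")

    pix_cm = pixel_size_um * 1e-4
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    x = (ix.ravel() - cx) * pix_cm
    y = (iy.ravel() - cy) * pix_cm

    lam = wavelength_A(photon_energy_keV)
    k = 2.0 * np.pi / lam
    norm = np.sqrt(x**2 + y**2 + distance_cm**2)
    s_hat = np.stack([x / norm, y / norm, np.full_like(x, distance_cm) / norm], axis=1)
    qvec = k * (s_hat - np.array([0.0, 0.0, 1.0]))
    q_abs = np.linalg.norm(qvec, axis=1)
    theta = np.arccos(np.clip(distance_cm / norm, -1.0, 1.0))

    omega = (pix_cm**2) * np.cos(theta) ** 3 / distance_cm**2
    if polarization == "horizontal":
        phi = np.arctan2(y, x)
        pol = 1.0 - (np.sin(theta) * np.cos(phi)) ** 2
    else:
        pol = 0.5 * (1.0 + np.cos(theta) ** 2)
    return DetectorGeometry(
        n_pixels=tuple(n_pixels),
        pixel_size_um=float(pixel_size_um),
        distance_cm=float(distance_cm),
        photon_energy_keV=float(photon_energy_keV),
        polarization=polarization,
        qvec=qvec,
        q_abs=q_abs,
        theta=theta,
        omega_sr=omega,
        thomson_cm2_sr=R_E2_CM2 * pol,
    )


@dataclass(frozen=True)
class DiffractionPattern:
    """Per-pixel expected photon counts n(q) with provenance metadata."""

    counts: np.ndarray
    components: frozenset
    orientation: np.ndarray
    water_thickness: float = 0.0
    pulse_id: int = 0
    seed: int = 0
    sampled: bool = False
    detector_meta: tuple = None

    @property
    def n_pix(self) -> int:
        return len(self.counts)


def _subset_mask(labels, subset):
    if subset == "all":
        return np.ones(len(labels), bool)
    if subset == "protein":
        return labels == PROTEIN
    if subset == "water":
        return labels == WATER
    raise ValueError(f"unknown subset {subset!r}")


def _group_key(elem_idx, n_bound):
    return elem_idx * 64 + n_bound


def elastic_amplitude(snapshot, detector: DetectorGeometry, subset: str = "all",
                      tables: ScatteringTables | None = None) -> np.ndarray:
    """Coherent structure factor F(q) = sum_j f_j(q) exp(i q . r_j) by direct
    summation over the selected atoms (protein / water / all)."""
    tables = tables or default_tables()
    mask = _subset_mask(snapshot.labels, subset)
    pos = snapshot.positions[mask]
    key = _group_key(snapshot.elem_idx[mask], snapshot.n_bound[mask])
    F = np.zeros(detector.n_pix, dtype=complex)
    for k in np.unique(key):
        ei, nb = int(k) // 64, int(k) % 64
        f = tables.elastic_form_factor(tables.elements[ei], nb, detector.q_abs)
        ph = pos[key == k] @ detector.qvec.T
        F += f * (np.cos(ph).sum(0) + 1j * np.sin(ph).sum(0))
    return F


def inelastic_term(snapshot, detector: DetectorGeometry, subset: str = "all",
                   tables: ScatteringTables | None = None) -> np.ndarray:
    """Incoherent (Compton) structure factor S(q) = sum_j S_incoh,j(q):
    additive per atom, no interference."""
    tables = tables or default_tables()
    mask = _subset_mask(snapshot.labels, subset)
    key = _group_key(snapshot.elem_idx[mask], snapshot.n_bound[mask])
    uniq, counts = np.unique(key, return_counts=True)
    S = np.zeros(detector.n_pix)
    for k, c in zip(uniq, counts):
        ei, nb = int(k) // 64, int(k) % 64
        S += c * tables.incoherent_function(tables.elements[ei], nb, detector.q_abs)
    return S


class _ElasticAccumulator:
    """Incremental elastic intensity over snapshots of one trajectory.

    Neutral atoms feel no force in the damage model, so atoms that were
    never ionized sit exactly at their initial positions; the structure
    factor of snapshot t differs from the pristine one only through the
    "dirty" atoms (ionized and/or displaced). F_t = F_0 + sum_dirty
    [f_now e^{iq.r_now} - f_neutral e^{iq.r_0}], evaluated over the dirty
    set only, which makes the 100-snapshot time integration tractable.
    """

    def __init__(self, snap0, sel, rot, com, detector, tables, dtype):
        self.sel = sel
        self.rot = rot
        self.com = com
        self.det = detector
        self.tables = tables
        self.dtype = dtype
        self.ref_nbound = snap0.n_bound[sel]
        self.ref_pos = self._rotated(snap0.positions[sel])
        self.elem_idx = snap0.elem_idx[sel]
        self.F0 = self._sum(self.ref_pos, self.elem_idx, self.ref_nbound)
        self._ref_rows = {}

    def _rotated(self, pos):
        return (pos - self.com) @ self.rot.T + self.com

    def _sum(self, pos, elem_idx, nbound):
        det, tables = self.det, self.tables
        F = np.zeros(det.n_pix, dtype=complex)
        key = _group_key(elem_idx, nbound)
        for k in np.unique(key):
            ei, nb = int(k) // 64, int(k) % 64
            f = tables.elastic_form_factor(tables.elements[ei], nb, det.q_abs)
            ph = (pos[key == k] @ det.qvec.T).astype(self.dtype)
            F += f * (np.cos(ph).sum(0) + 1j * np.sin(ph).sum(0))
        return F

    def _ref_row(self, local_i):
        row = self._ref_rows.get(local_i)
        if row is None:
            ei, nb = self.elem_idx[local_i], self.ref_nbound[local_i]
            f = self.tables.elastic_form_factor(self.tables.elements[ei], nb,
                                                self.det.q_abs)
            ph = (self.ref_pos[local_i] @ self.det.qvec.T).astype(self.dtype)
            row = f * (np.cos(ph) + 1j * np.sin(ph))
            self._ref_rows[local_i] = row
        return row

    def intensity(self, snap) -> np.ndarray:
        pos = snap.positions[self.sel]
        nbound = snap.n_bound[self.sel]
        dirty = np.nonzero(
            (nbound != self.ref_nbound)
            | np.any(pos != self.ref_pos_unrotated(snap), axis=1)
        )[0]
        F = self.F0.copy()
        if len(dirty):
            F += self._sum(self._rotated(pos[dirty]), self.elem_idx[dirty], nbound[dirty])
            for i in dirty:
                F -= self._ref_row(int(i))
        return (F.real**2 + F.imag**2)

    def ref_pos_unrotated(self, snap):
        return snap.initial_positions[self.sel]


def integrate_pattern(
    trajectory,
    pulse: PulseProfile,
    detector: DetectorGeometry,
    delta_t: float = 0.27,
    components: frozenset = DEFAULT_COMPONENTS,
    final_orientation=None,
    tables: ScatteringTables | None = None,
    precision: str = "single",
) -> DiffractionPattern:
    """Time-integrated pattern from one trajectory (the bracketed sum above).

    The sample is rotated by final_orientation o base_quaternion^-1 so it
    reaches the requested final orientation; each pulse time window of
    width delta_t is associated with the nearest recorded snapshot and
    weighted with the incident photons n_in of that window.
    """
    components = frozenset(components)
    unknown = components - COMPONENTS
    if unknown:
        raise ValueError(f"unknown components {sorted(unknown)}")
    tables = tables or default_tables()
    if final_orientation is None:
        final_orientation = quaternions.IDENTITY
    dtype = {"single": np.float32, "double": np.float64}[precision]

    rel_q = quaternions.multiply(final_orientation,
                                 quaternions.conjugate(trajectory.base_quaternion))
    rot = quaternions.to_matrix(rel_q)
    snaps = trajectory.snapshots
    snap0 = snaps[0]
    masses = tables.mass_amu[snap0.elem_idx]
    com = (masses[:, None] * snap0.initial_positions).sum(0) / masses.sum()

    # photon weight per snapshot: nearest-snapshot association of delta_t bins
    t_bins, n_in = rebin_nin(pulse, delta_t)
    k = delta_t / pulse.timestep_fs
    bin_center_steps = (np.arange(len(n_in)) + 0.5) * k
    snap_steps = np.array([s.step_index for s in snaps], dtype=float)
    assign = np.argmin(np.abs(bin_center_steps[:, None] - snap_steps[None, :]), axis=1)
    weights = np.zeros(len(snaps))
    np.add.at(weights, assign, n_in)

    elastic_subsets = []
    if "protein_elastic" in components:
        elastic_subsets.append(PROTEIN)
    if "water_elastic" in components:
        elastic_subsets.append(WATER)
    sel = np.nonzero(np.isin(snap0.labels, elastic_subsets))[0]

    acc = None
    if len(sel):
        acc = _ElasticAccumulator(snap0, sel, rot, com, detector, tables, dtype)

    counts = np.zeros(detector.n_pix)
    for w, snap in zip(weights, snaps):
        if w == 0.0:
            continue
        term = np.zeros(detector.n_pix)
        if acc is not None:
            term += acc.intensity(snap)
        if "compton_bound" in components:
            term += inelastic_term(snap, detector, "all", tables)
        if "free_electrons" in components:
            term += float(snap.n_free)
        counts += w * term
    # photon weights enter as incident fluence (photons/cm^2) at the sample,
    # so Omega * dsigma_T/dOmega * fluence * [..] is an expected photon count
    counts *= detector.omega_sr * detector.thomson_cm2_sr / focus_area_cm2(pulse)
    return DiffractionPattern(
        counts=counts,
        components=components,
        orientation=np.asarray(final_orientation, dtype=float),
        water_thickness=float(getattr(snap0, "water_thickness", 0.0) or 0.0),
        pulse_id=trajectory.pulse_id,
        seed=trajectory.seed,
        detector_meta=detector.meta(),
    )


def poisson_sample(pattern: DiffractionPattern, seed: int = 0) -> DiffractionPattern:
    """Per-pixel Poisson photon sampling of an expected-count pattern."""
    if np.any(pattern.counts < 0):
        raise ValueError("pattern counts must be non-negative")
    rng = np.random.default_rng(seed)
    return replace(pattern, counts=rng.poisson(pattern.counts).astype(float),
                   sampled=True)
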