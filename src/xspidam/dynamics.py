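"""X-ray-driven ionization and real-space dynamics of the hydrated sample.

A reduced molecular-dynamics / Monte-Carlo scheme in the spirit of
XMDYN-class codes:

* photoabsorption: per atom, per timestep Bernoulli draw with rate
  sigma_ph * flux; the subshell is chosen proportionally to the partial
  cross sections and a photoelectron is launched isotropically with
  KE = photon energy - binding energy;
* Auger decay: registered core holes decay with an effective per-element
  lifetime; one outer electron fills the hole and a second is emitted
  (atoms without two outer electrons relax radiatively);
* collisional (impact) ionization: quasi-free electrons ionize atoms whose
  centers lie within a cylinder of radius r_c around the electron's path;
  the per-pair event probability sigma_BEB / (pi r_c^2) reproduces the
  kinetic-theory rate n sigma v;
* optional three-body recombination: an electron within the capture radius
  of an ion with negative pair energy is captured into the least-bound
  vacancy;
* motion: velocity-Verlet dynamics of ions and quasi-free electrons under
  pairwise softened Coulomb forces; neutral atoms feel no force. Electrons
  crossing the escape radius with positive total energy are removed and
  counted in the escape ledger.

Charge bookkeeping is exact at every step:
sum(ion charges) - n_active_electrons - n_escaped == 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import quaternions
from .atomic_data import N_SUBSHELLS, ScatteringTables, default_tables
from .constants import AMU, CM2_TO_A2, COULOMB_EV_AA, M_E, electron_speed
from .sample import AtomicConfiguration, rotate_configuration

MECHANISMS = ("photo", "auger", "impact")
MECH_PHOTO, MECH_AUGER, MECH_IMPACT = 0, 1, 2
ORIGIN_NAMES = {0: "photo", 1: "auger", 2: "impact"}

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _coulomb_kernel(pos, q, soft2):
    """Pairwise softened Coulomb forces (eV/A) and per-particle potential (eV).

    pot[i] = sum_j k q_i q_j / sqrt(r_ij^2 + a^2) -- the full interaction
    energy of particle i with everyone else (used for the escape test).
    """
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    pot = np.zeros(n)
    k = 14.399645
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz + soft2
            inv = 1.0 / np.sqrt(r2)
            c = k * q[i] * q[j]
            u = c * inv
            pot[i] += u
            pot[j] += u
            f = u / r2
            forces[i, 0] += f * dx
            forces[i, 1] += f * dy
            forces[i, 2] += f * dz
            forces[j, 0] -= f * dx
            forces[j, 1] -= f * dy
            forces[j, 2] -= f * dz
    return forces, pot


@dataclass
class QuasiFreeElectron:
    """View of one quasi-free electron."""

    position: np.ndarray
    velocity: np.ndarray
    origin: str
    escaped: bool = False


@dataclass
class PhysicsParams:
    """Tunable physics/integration parameters of the damage model."""

    timestep_fs: float = 0.027
    span_fs: float = 26.0
    n_snapshots: int = 100
    photon_energy_keV: float = 4.96
    softcore_A: float = 0.5
    escape_radius_factor: float = 3.0
    recombination: bool = True
    capture_radius_A: float = 1.0
    collision_cylinder_radius_A: float = 5.0
    secondary_energy_sharing: str = "mott"  # or "uniform"
    auger_branching: float = 1.0
    neighbor_refresh_steps: int = 20

    @property
    def n_steps(self) -> int:
        return int(round(self.span_fs / self.timestep_fs))


@dataclass
class Snapshot:
    """Full sample state at one instant (atoms + quasi-free electrons + ledger)."""

    time: float
    elements: np.ndarray
    labels: np.ndarray
    elem_idx: np.ndarray          # row index into the ScatteringTables arrays
    positions: np.ndarray
    initial_positions: np.ndarray
    velocities: np.ndarray
    charges: np.ndarray
    occupancies: np.ndarray
    holes: np.ndarray             # (N, n_subshells) pending core holes
    electron_positions: np.ndarray
    electron_velocities: np.ndarray
    electron_origins: np.ndarray
    n_escaped: int = 0
    event_counts: np.ndarray = None   # (n_table_elements, 3) cumulative
    recomb_counts: np.ndarray = None  # (n_table_elements,) cumulative
    step_index: int = 0

    @classmethod
    def from_configuration(cls, config: AtomicConfiguration,
                           tables: ScatteringTables | None = None) -> "Snapshot":
        tables = tables or default_tables()
        elem_idx = np.array([tables.index(el) for el in config.elements], dtype=np.int32)
        nel = len(tables.elements)
        return cls(
            time=0.0,
            elements=config.elements.copy(),
            labels=config.labels.copy(),
            elem_idx=elem_idx,
            positions=config.positions.copy(),
            initial_positions=config.initial_positions.copy(),
            velocities=config.velocities.copy(),
            charges=config.charges.astype(np.int32),
            occupancies=config.occupancies.astype(np.int8),
            holes=np.zeros((config.n_atoms, N_SUBSHELLS), dtype=np.int8),
            electron_positions=np.empty((0, 3)),
            electron_velocities=np.empty((0, 3)),
            electron_origins=np.empty(0, dtype=np.int8),
            event_counts=np.zeros((nel, 3), dtype=np.int64),
            recomb_counts=np.zeros(nel, dtype=np.int64),
        )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_free(self) -> int:
        return len(self.electron_positions)

    @property
    def n_bound(self) -> np.ndarray:
        return self.occupancies.sum(1)

    def free_electrons(self):
        return [
            QuasiFreeElectron(self.electron_positions[i].copy(),
                              self.electron_velocities[i].copy(),
                              ORIGIN_NAMES[int(self.electron_origins[i])])
            for i in range(self.n_free)
        ]

    def charge_balance(self) -> int:
        """sum(atom charges) - active electrons - escaped; 0 when consistent."""
        return int(self.charges.sum()) - self.n_free - self.n_escaped

    def copy(self) -> "Snapshot":
        return Snapshot(
            time=self.time,
            elements=self.elements,             # immutable statics shared
            labels=self.labels,
            elem_idx=self.elem_idx,
            positions=self.positions.copy(),
            initial_positions=self.initial_positions,
            velocities=self.velocities.copy(),
            charges=self.charges.copy(),
            occupancies=self.occupancies.copy(),
            holes=self.holes.copy(),
            electron_positions=self.electron_positions.copy(),
            electron_velocities=self.electron_velocities.copy(),
            electron_origins=self.electron_origins.copy(),
            n_escaped=self.n_escaped,
            event_counts=self.event_counts.copy(),
            recomb_counts=self.recomb_counts.copy(),
            step_index=self.step_index,
        )


def _isotropic_unit(rng, n=1):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _emit(state: Snapshot, position, ke_ev, origin_code, rng):
    direction = _isotropic_unit(rng)[0]
    vel = electron_speed(max(ke_ev, 0.0)) * direction
    state.electron_positions = np.vstack([state.electron_positions, position[None, :]])
    state.electron_velocities = np.vstack([state.electron_velocities, vel[None, :]])
    state.electron_origins = np.append(state.electron_origins, np.int8(origin_code))


def _least_bound_occupied(tables, ei, occ_row):
    """Index of the occupied subshell with the smallest binding energy."""
    binding = np.where(occ_row > 0, tables.binding_eV[ei], np.inf)
    j = int(np.argmin(binding))
    return j if occ_row[j] > 0 else -1


# ---------------------------------------------------------------------------
# step operators (in-place workers + copying public wrappers)
# ---------------------------------------------------------------------------

def _photo_inplace(state: Snapshot, phi_cm2, tables, rng, photon_energy_keV):
    """phi_cm2: incident photons per cm^2 during this step."""
    if phi_cm2 <= 0:
        return
    sig = tables.photo_sigma_matrix(photon_energy_keV)[state.elem_idx]  # (N, 7)
    sigma_atom = np.einsum("ij,ij->i", state.occupancies.astype(float), sig)
    p = -np.expm1(-phi_cm2 * sigma_atom)
    hits = np.nonzero(rng.random(state.n_atoms) < p)[0]
    e_ph_ev = photon_energy_keV * 1e3
    for a in hits:
        weights = state.occupancies[a] * sig[a]
        total = weights.sum()
        if total <= 0:
            continue
        sub = rng.choice(N_SUBSHELLS, p=weights / total)
        ei = state.elem_idx[a]
        binding = tables.binding_eV[ei, sub]
        state.occupancies[a, sub] -= 1
        state.charges[a] += 1
        state.event_counts[ei, MECH_PHOTO] += 1
        _emit(state, state.positions[a], e_ph_ev - binding, MECH_PHOTO, rng)
        # register a core hole when more loosely bound electrons remain
        outer = (state.occupancies[a] > 0) & (tables.binding_eV[ei] < binding)
        if outer.any():
            state.holes[a, sub] += 1


def _auger_inplace(state: Snapshot, dt, tables, rng, branching=1.0):
    hole_atoms = np.nonzero(state.holes.sum(1) > 0)[0]
    if len(hole_atoms) == 0:
        return
    tau = tables.auger_lifetime_fs[state.elem_idx[hole_atoms]]
    p = -np.expm1(-dt / tau)
    decays = hole_atoms[rng.random(len(hole_atoms)) < p]
    for a in decays:
        ei = state.elem_idx[a]
        sub = int(np.nonzero(state.holes[a] > 0)[0][0])  # deepest pending hole
        state.holes[a, sub] -= 1
        b_hole = tables.binding_eV[ei, sub]
        outer_mask = (state.occupancies[a] > 0) & (tables.binding_eV[ei] < b_hole)
        n_outer = int(state.occupancies[a, outer_mask].sum())
        if n_outer == 0:
            continue  # stranded hole: nothing can fill it
        # filler: least-bound occupied outer electron drops into the hole
        filler = _least_bound_occupied(tables, ei, np.where(outer_mask, state.occupancies[a], 0))
        state.occupancies[a, filler] -= 1
        state.occupancies[a, sub] += 1
        radiative = n_outer < 2 or rng.random() >= branching
        if radiative:
            continue
        outer_mask2 = (state.occupancies[a] > 0) & (tables.binding_eV[ei] < b_hole)
        emit_sub = _least_bound_occupied(tables, ei, np.where(outer_mask2, state.occupancies[a], 0))
        ke = b_hole - tables.binding_eV[ei, filler] - tables.binding_eV[ei, emit_sub]
        if emit_sub < 0 or ke <= 0:
            continue  # energetically closed: counts as radiative relaxation
        state.occupancies[a, emit_sub] -= 1
        state.charges[a] += 1
        state.event_counts[ei, MECH_AUGER] += 1
        _emit(state, state.positions[a], ke, MECH_AUGER, rng)


def _sample_secondary_energy(e_avail, binding, rng, mode):
    """Energy of the secondary electron, in [0, e_avail].

    "mott": asymmetric binary-encounter spectrum dsigma/dW ~ 1/(W + B)^2
    for the slower electron (W <= e_avail/2), sampled by inverse
    transform -- the physically standard shape, under which the fast
    primary keeps most of its energy. "uniform": flat split.
    """
    if mode == "uniform":
        return rng.random() * e_avail
    if mode == "mott":
        w_max = 0.5 * e_avail
        u = rng.random()
        inv = 1.0 / binding - u * (1.0 / binding - 1.0 / (w_max + binding))
        return 1.0 / inv - binding
    raise ValueError(f"unknown secondary_energy_sharing {mode!r}")


def _collisional_inplace(state: Snapshot, dt, tables, rng, r_cyl, tree=None,
                         sharing: str = "mott"):
    n_e = state.n_free
    if n_e == 0 or state.n_atoms == 0:
        return
    if tree is None:
        tree = cKDTree(state.positions)
    area = np.pi * r_cyl**2  # A^2
    for ie in range(n_e):
        v = state.electron_velocities[ie]
        speed = float(np.linalg.norm(v))
        if speed == 0.0:
            continue
        ke = 0.5 * M_E * speed**2
        seg = v * dt
        length = speed * dt
        mid = state.electron_positions[ie] + 0.5 * seg
        cand = np.asarray(tree.query_ball_point(mid, 0.5 * length + r_cyl), dtype=int)
        if cand.size == 0:
            continue
        rel = state.positions[cand] - state.electron_positions[ie]
        t_proj = rel @ (seg / length)
        perp2 = np.einsum("ij,ij->i", rel, rel) - t_proj**2
        inside = (t_proj >= 0.0) & (t_proj <= length) & (perp2 <= r_cyl**2)
        cand, t_proj = cand[inside], t_proj[inside]
        if cand.size == 0:
            continue
        sigma = tables.beb_sigma_atoms(ke, state.occupancies[cand], state.elem_idx[cand])
        p_pair = np.minimum(sigma * CM2_TO_A2 / area, 1.0)
        hit = rng.random(len(cand)) < p_pair
        if not hit.any():
            continue
        a = int(cand[hit][np.argmin(t_proj[hit])])  # first collision on the path
        ei = state.elem_idx[a]
        j = _least_bound_occupied(tables, ei, state.occupancies[a])
        binding = tables.binding_eV[ei, j]
        e_avail = ke - binding
        if j < 0 or e_avail <= 0:
            continue
        w_secondary = _sample_secondary_energy(e_avail, binding, rng, sharing)
        state.occupancies[a, j] -= 1
        state.charges[a] += 1
        state.event_counts[ei, MECH_IMPACT] += 1
        state.electron_velocities[ie] = (
            electron_speed(e_avail - w_secondary) * _isotropic_unit(rng)[0]
        )
        _emit(state, state.positions[a], w_secondary, MECH_IMPACT, rng)


def _recombine_inplace(state: Snapshot, tables, rng, capture_radius, softcore):
    if state.n_free == 0:
        return
    ions = np.nonzero(state.charges > 0)[0]
    if len(ions) == 0:
        return
    tree = cKDTree(state.positions[ions])
    d, nearest = tree.query(state.electron_positions)
    close = np.nonzero(d < capture_radius)[0]
    captured = []
    for ie in close:
        a = int(ions[nearest[ie]])
        if state.charges[a] <= 0:
            continue
        vrel = state.electron_velocities[ie] - state.velocities[a]
        ke = 0.5 * M_E * float(vrel @ vrel)
        pot = -COULOMB_EV_AA * state.charges[a] / np.sqrt(d[ie] ** 2 + softcore**2)
        if ke + pot >= 0:
            continue
        ei = state.elem_idx[a]
        vac = np.where(
            tables.ground_occ[ei] - state.occupancies[a] > 0, tables.binding_eV[ei], np.inf
        )
        j = int(np.argmin(vac))
        if not np.isfinite(vac[j]):
            continue
        state.occupancies[a, j] += 1
        state.charges[a] -= 1
        if state.holes[a, j] > 0:
            state.holes[a, j] -= 1
        state.recomb_counts[ei] += 1
        captured.append(ie)
    if captured:
        keep = np.setdiff1d(np.arange(state.n_free), np.array(captured))
        state.electron_positions = state.electron_positions[keep]
        state.electron_velocities = state.electron_velocities[keep]
        state.electron_origins = state.electron_origins[keep]


def _charged_system(state: Snapshot, tables):
    ions = np.nonzero(state.charges != 0)[0]
    n_e = state.n_free
    pos = np.vstack([state.positions[ions], state.electron_positions])
    q = np.concatenate([state.charges[ions].astype(float), -np.ones(n_e)])
    m_ion = tables.mass_amu[state.elem_idx[ions]] * AMU
    m = np.concatenate([m_ion, np.full(n_e, M_E)])
    return ions, pos, q, m


def _motion_inplace(state: Snapshot, dt, tables, params, com0, escape_radius):
    ions, pos, q, m = _charged_system(state, tables)
    soft2 = params.softcore_A**2
    n_i = len(ions)

    if len(q):
        f1, _ = _coulomb_kernel(pos, q, soft2)
        acc1 = f1 / m[:, None]
        state.velocities[ions] += 0.5 * dt * acc1[:n_i]
        if state.n_free:
            state.electron_velocities += 0.5 * dt * acc1[n_i:]

    # inertial drift of everything (neutral atoms keep zero velocity)
    state.positions += dt * state.velocities
    if state.n_free:
        state.electron_positions += dt * state.electron_velocities

    if len(q):
        pos2 = np.vstack([state.positions[ions], state.electron_positions])
        f2, pot = _coulomb_kernel(pos2, q, soft2)
        acc2 = f2 / m[:, None]
        state.velocities[ions] += 0.5 * dt * acc2[:n_i]
        if state.n_free:
            state.electron_velocities += 0.5 * dt * acc2[n_i:]
            # escape: beyond the boundary with positive total energy
            ke = 0.5 * M_E * np.einsum("ij,ij->i", state.electron_velocities,
                                       state.electron_velocities)
            r = np.linalg.norm(state.electron_positions - com0, axis=1)
            esc = (r > escape_radius) & (ke + pot[n_i:] > 0)
            if esc.any():
                state.n_escaped += int(esc.sum())
                keep = ~esc
                state.electron_positions = state.electron_positions[keep]
                state.electron_velocities = state.electron_velocities[keep]
                state.electron_origins = state.electron_origins[keep]


def _public(worker):
    """Wrap an in-place worker into a copying step operator."""

    def step(state: Snapshot, *args, **kwargs) -> Snapshot:
        out = state.copy()
        worker(out, *args, **kwargs)
        return out

    return step


def step_photoabsorption(state: Snapshot, flux_density, dt, tables, rng,
                         photon_energy_keV: float = 4.96) -> Snapshot:
    """One photoabsorption step; flux_density in photons/cm^2/fs."""
    out = state.copy()
    _photo_inplace(out, flux_density * dt, tables, rng, photon_energy_keV)
    return out


def step_auger(state: Snapshot, dt, tables, rng, branching: float = 1.0) -> Snapshot:
    out = state.copy()
    _auger_inplace(out, dt, tables, rng, branching)
    return out


def step_collisional(state: Snapshot, dt, tables, rng,
                     cylinder_radius: float = 5.0,
                     sharing: str = "mott") -> Snapshot:
    out = state.copy()
    _collisional_inplace(out, dt, tables, rng, cylinder_radius, sharing=sharing)
    return out


def step_motion(state: Snapshot, dt, tables=None,
                params: PhysicsParams | None = None) -> Snapshot:
    tables = tables or default_tables()
    params = params or PhysicsParams()
    out = state.copy()
    com0 = out.initial_positions.mean(0)
    r_bound = max(np.linalg.norm(out.initial_positions - com0, axis=1).max(), 1.0)
    _motion_inplace(out, dt, tables, params, com0, params.escape_radius_factor * r_bound)
    return out


def system_energy(state: Snapshot, tables=None, softcore: float = 0.5) -> float:
    """Total kinetic + softened-Coulomb potential energy (eV) of charged particles."""
    tables = tables or default_tables()
    ions, pos, q, m = _charged_system(state, tables)
    vel = np.vstack([state.velocities[ions], state.electron_velocities])
    ke = 0.5 * np.sum(m * np.einsum("ij,ij->i", vel, vel))
    if len(q):
        _, pot = _coulomb_kernel(pos, q, softcore**2)
        return float(ke + 0.5 * pot.sum())
    return float(ke)


# ---------------------------------------------------------------------------
# trajectory driver
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Ordered snapshots from one damage run."""

    snapshots: list
    pulse_id: int
    base_quaternion: np.ndarray
    seed: int
    timestep_fs: float
    escape_radius_A: float
    params: PhysicsParams = None

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    @property
    def n_free(self) -> np.ndarray:
        return np.array([s.n_free for s in self.snapshots])

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1]


def run_trajectory(
    sample: AtomicConfiguration,
    pulse,
    params: PhysicsParams | None = None,
    seed: int = 0,
    tables: ScatteringTables | None = None,
    base_quaternion=None,
    pulse_id: int | None = None,
) -> Trajectory:
    """Run one stochastic damage trajectory.

    Interleaves photoabsorption -> Auger -> collisional -> recombination
    (optional) -> motion each timestep and records ``params.n_snapshots``
    uniformly spaced snapshots; the first snapshot is the pristine sample.
    Deterministic for a fixed seed.
    """
    params = params or PhysicsParams()
    tables = tables or default_tables()
    rng = np.random.default_rng(seed)

    if base_quaternion is None:
        base_quaternion = quaternions.IDENTITY.copy()
    else:
        sample = rotate_configuration(sample, base_quaternion)

    n_steps = params.n_steps
    if len(pulse.n0) != n_steps:
        raise ValueError(
            f"pulse grid ({len(pulse.n0)} bins) does not match the "
            f"{n_steps}-step simulation span"
        )
    if abs(pulse.timestep_fs - params.timestep_fs) > 1e-9:
        raise ValueError("pulse timestep differs from the MD timestep")

    from .pulse import flux_density_per_bin

    phi = flux_density_per_bin(pulse)  # photons/cm^2 per bin
    dt = params.timestep_fs

    state = Snapshot.from_configuration(sample, tables)
    com0 = state.initial_positions.mean(0)
    r_bound = max(np.linalg.norm(state.initial_positions - com0, axis=1).max(), 1.0)
    escape_radius = params.escape_radius_factor * r_bound

    snap_steps = np.unique(np.round(np.linspace(0, n_steps, params.n_snapshots)).astype(int))
    snapset = set(snap_steps.tolist())

    snapshots = []

    def record(i):
        s = state.copy()
        s.time = i * dt
        s.step_index = i
        snapshots.append(s)

    tree = None
    tree_age = 10**9
    for i in range(n_steps):
        if i in snapset:
            record(i)
        _photo_inplace(state, phi[i], tables, rng, params.photon_energy_keV)
        _auger_inplace(state, dt, tables, rng, params.auger_branching)
        if state.n_free:
            if tree is None or tree_age >= params.neighbor_refresh_steps:
                tree = cKDTree(state.positions)
                tree_age = 0
            _collisional_inplace(state, dt, tables, rng,
                                 params.collision_cylinder_radius_A, tree,
                                 sharing=params.secondary_energy_sharing)
            tree_age += 1
        if params.recombination:
            _recombine_inplace(state, tables, rng, params.capture_radius_A,
                               params.softcore_A)
        _motion_inplace(state, dt, tables, params, com0, escape_radius)
    if n_steps in snapset:
        record(n_steps)

    return Trajectory(
        snapshots=snapshots,
        pulse_id=pulse_id if pulse_id is not None else pulse.profile_id,
        base_quaternion=np.asarray(base_quaternion, dtype=float),
        seed=seed,
        timestep_fs=dt,
        escape_radius_A=escape_radius,
        params=params,
    )


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

@dataclass
class Observables:
    times: np.ndarray
    mean_charge: np.ndarray
    mean_displacement: np.ndarray
    radial_edges: np.ndarray
    radial_net_charge: np.ndarray  # (n_snapshots, n_radial_bins)
    element: str
    label_filter: str
    n_trajectories: int


def compute_observables(trajectories, element: str, label_filter: str = "protein",
                        n_radial_bins: int = 12) -> Observables:
    """Trajectory-averaged transient charge and displacement of one element.

    Averages, per snapshot, over the atoms of ``element`` restricted by
    ``label_filter`` ("protein", "water" or "all") and over trajectories:
    (a) the ionic charge and (b) |position - initial position|. Also
    accumulates a radial net-charge profile (ion charge minus active
    electrons, binned on distance from the initial center) as the
    core-shell diagnostic.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("need at least one trajectory")
    from .sample import LABEL_NAMES

    first = trajectories[0].snapshots[0]
    if label_filter == "all":
        lmask = np.ones(first.n_atoms, bool)
    else:
        code = {v: k for k, v in LABEL_NAMES.items()}[label_filter]
        lmask = first.labels == code
    mask = lmask & (first.elements == element)
    if not mask.any():
        raise ValueError(f"no {element} atoms with label {label_filter!r}")

    n_snap = len(trajectories[0].snapshots)
    com0 = first.initial_positions.mean(0)
    r_max = np.linalg.norm(first.initial_positions - com0, axis=1).max() * 1.3 + 1e-9
    edges = np.linspace(0.0, r_max, n_radial_bins + 1)

    charge = np.zeros(n_snap)
    disp = np.zeros(n_snap)
    radial = np.zeros((n_snap, n_radial_bins))
    for traj in trajectories:
        if len(traj.snapshots) != n_snap:
            raise ValueError("trajectories have inconsistent snapshot counts")
        for k, snap in enumerate(traj.snapshots):
            charge[k] += snap.charges[mask].mean()
            disp[k] += np.linalg.norm(
                snap.positions[mask] - snap.initial_positions[mask], axis=1
            ).mean()
            r_atoms = np.linalg.norm(snap.positions - com0, axis=1)
            radial[k] += np.histogram(r_atoms, bins=edges, weights=snap.charges)[0]
            if snap.n_free:
                r_el = np.linalg.norm(snap.electron_positions - com0, axis=1)
                radial[k] -= np.histogram(r_el, bins=edges)[0]
    n_traj = len(trajectories)
    return Observables(
        times=trajectories[0].times,
        mean_charge=charge / n_traj,
        mean_displacement=disp / n_traj,
        radial_edges=edges,
        radial_net_charge=radial / n_traj,
        element=element,
        label_filter=label_filter,
        n_trajectories=n_traj,
    )


def impact_fraction(trajectories, elements=("S", "Fe")) -> float:
    """Pooled fraction (0-1) of ionization events on the given elements that
    are collisional (electron-impact), over a set of trajectories."""
    tables = default_tables()
    idx = [tables.index(el) for el in elements]
    total = np.zeros(3, dtype=np.int64)
    for traj in trajectories:
        total += traj.final.event_counts[idx].sum(0)
    n_all = total.sum()
    return float(total[MECH_IMPACT] / n_all) if n_all else 0.0
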