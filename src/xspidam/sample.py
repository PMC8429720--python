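"""Hydrated-sample construction.

Builds atomic configurations for the damage and diffraction stages: either
a real protein read from a PDB file, or a synthetic globular pseudo-protein
with a 2NIP-like element stoichiometry, optionally wrapped in a uniform
water shell of prescribed thickness.

Conventions: Cartesian coordinates in Angstrom, no periodic boundary.
Water-layer "thickness" is defined through the distance to the nearest
protein atom: water oxygens are placed where that distance lies in
(r_contact, r_contact + thickness], with r_contact = 2.8 A by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import quaternions
from .atomic_data import GROUND_OCC, N_SUBSHELLS, ScatteringTables, default_tables

PROTEIN, WATER = 0, 1
LABEL_NAMES = {PROTEIN: "protein", WATER: "water"}

# heavy-atom stoichiometry of the 2NIP nitrogenase iron protein
NIP2_HEAVY_COUNTS = {"C": 2712, "N": 735, "O": 859, "S": 46, "Fe": 4}
NIP2_COMPOSITION = {
    el: n / sum(NIP2_HEAVY_COUNTS.values()) for el, n in NIP2_HEAVY_COUNTS.items()
}

# rigid water geometry (TIP3P-like): O-H bond length and H-O-H angle
OH_BOND_A = 0.9572
HOH_ANGLE_DEG = 104.52
LIQUID_WATER_DENSITY = 0.0334  # molecules / A^3


class PDBParseError(ValueError):
    pass


@dataclass
class Atom:
    """Read-only view of a single atom in a configuration."""

    element: str
    position: np.ndarray
    initial_position: np.ndarray
    velocity: np.ndarray
    charge: int
    shell_occupancy: np.ndarray
    label: str


@dataclass
class AtomicConfiguration:
    """The sample at one instant: atoms with element, position, charge,
    subshell occupancies and a protein/water label.

    Atom order is stable; diffraction component selection indexes into it.
    """

    elements: np.ndarray          # (N,) unicode symbols
    positions: np.ndarray         # (N, 3) A
    initial_positions: np.ndarray  # (N, 3) A
    velocities: np.ndarray        # (N, 3) A/fs
    charges: np.ndarray           # (N,) int
    occupancies: np.ndarray       # (N, N_SUBSHELLS) int
    labels: np.ndarray            # (N,) int, PROTEIN or WATER
    water_thickness: float = 0.0
    provenance: str = ""

    def __post_init__(self):
        n = len(self.elements)
        for name in ("positions", "initial_positions", "velocities"):
            arr = np.asarray(getattr(self, name), dtype=float).reshape(n, 3)
            setattr(self, name, arr)
        self.charges = np.asarray(self.charges, dtype=np.int64).reshape(n)
        self.occupancies = np.asarray(self.occupancies, dtype=np.int64).reshape(n, N_SUBSHELLS)
        self.labels = np.asarray(self.labels, dtype=np.int8).reshape(n)

    # -- basic queries ----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_water_molecules(self) -> int:
        return int(np.sum((self.labels == WATER) & (self.elements == "O")))

    def element_counts(self, label: int | None = None) -> dict:
        mask = np.ones(self.n_atoms, bool) if label is None else self.labels == label
        els, counts = np.unique(self.elements[mask], return_counts=True)
        return dict(zip(els.tolist(), counts.tolist()))

    def masses(self, tables: ScatteringTables | None = None) -> np.ndarray:
        tables = tables or default_tables()
        idx = np.array([tables.index(el) for el in self.elements])
        return tables.mass_amu[idx]

    def center_of_mass(self) -> np.ndarray:
        m = self.masses()
        return (m[:, None] * self.positions).sum(0) / m.sum()

    @property
    def bounding_radius(self) -> float:
        if self.n_atoms == 0:
            return 0.0
        return float(np.linalg.norm(self.positions - self.center_of_mass(), axis=1).max())

    def atom(self, i: int) -> Atom:
        return Atom(
            element=str(self.elements[i]),
            position=self.positions[i].copy(),
            initial_position=self.initial_positions[i].copy(),
            velocity=self.velocities[i].copy(),
            charge=int(self.charges[i]),
            shell_occupancy=self.occupancies[i].copy(),
            label=LABEL_NAMES[int(self.labels[i])],
        )

    def copy(self) -> "AtomicConfiguration":
        return AtomicConfiguration(
            elements=self.elements.copy(),
            positions=self.positions.copy(),
            initial_positions=self.initial_positions.copy(),
            velocities=self.velocities.copy(),
            charges=self.charges.copy(),
            occupancies=self.occupancies.copy(),
            labels=self.labels.copy(),
            water_thickness=self.water_thickness,
            provenance=self.provenance,
        )

    def validate(self) -> None:
        """Check structural invariants (occupancy/charge sum, water geometry)."""
        tables = default_tables()
        z = np.array([tables.z_of(el) for el in self.elements])
        if not np.array_equal(self.occupancies.sum(1) + self.charges, z):
            raise ValueError("occupancy + charge does not equal Z for some atom")
        if (self.charges < 0).any():
            raise ValueError("negative ionic charge")
        wmask = self.labels == WATER
        if self.water_thickness == 0 and wmask.any():
            raise ValueError("water atoms present at water_thickness = 0")
        omask = wmask & (self.elements == "O")
        hmask = wmask & (self.elements == "H")
        if omask.any():
            tree = cKDTree(self.positions[hmask])
            n_close = tree.query_ball_point(self.positions[omask], r=1.2, return_length=True)
            if not np.all(n_close == 2):
                raise ValueError("water oxygen without exactly two H within 1.2 A")


def _new_config(elements, positions, labels, water_thickness, provenance) -> AtomicConfiguration:
    elements = np.asarray(elements, dtype="U2")
    positions = np.asarray(positions, dtype=float)
    occ = np.array([GROUND_OCC[el] for el in elements], dtype=np.int64).reshape(len(elements), N_SUBSHELLS)
    return AtomicConfiguration(
        elements=elements,
        positions=positions,
        initial_positions=positions.copy(),
        velocities=np.zeros_like(positions),
        charges=np.zeros(len(elements), dtype=np.int64),
        occupancies=occ,
        labels=np.asarray(labels, dtype=np.int8),
        water_thickness=water_thickness,
        provenance=provenance,
    )


# -- PDB input ------------------------------------------------------------

_WATER_RESIDUES = {"HOH", "WAT", "DOD", "H2O"}


def _prescan_pdb(path) -> None:
    """Line-by-line sanity scan so parse failures name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"line {lineno}: truncated {rec} record")
            try:
                for col in (slice(30, 38), slice(38, 46), slice(46, 54)):
                    float(line[col])
            except ValueError:
                raise PDBParseError(f"line {lineno}: unparseable coordinates in {rec} record")


def load_pdb(path, include_hydrogens: bool = True) -> AtomicConfiguration:
    """Read a PDB file into an AtomicConfiguration.

    All non-water atoms are labelled protein (HETATM groups such as FeS
    clusters included); water residues (HOH etc.) are dropped. Element
    symbols come from columns 77-78 with an atom-name fallback (gemmi's
    rule). Positions are in Angstrom.
    """
    import gemmi

    _prescan_pdb(path)
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc

    elements, positions = [], []
    model = structure[0]
    for chain in model:
        for residue in chain:
            if residue.name.strip() in _WATER_RESIDUES:
                continue
            for atom in residue:
                symbol = atom.element.name
                if symbol in ("X", ""):
                    raise PDBParseError(
                        f"unknown element symbol {atom.name!r} in residue {residue.name}"
                    )
                if symbol == "D":
                    symbol = "H"
                if symbol == "H" and not include_hydrogens:
                    continue
                elements.append(symbol)
                positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not elements:
        raise PDBParseError(f"no non-water ATOM/HETATM records in {path}")
    positions = np.asarray(positions)
    return _new_config(
        elements, positions, np.zeros(len(elements)), 0.0, f"pdb:{path}"
    )


# -- synthetic particle ---------------------------------------------------

def _allocate_counts(n_atoms, composition, rng, allocation):
    symbols = list(composition)
    fracs = np.array([composition[s] for s in symbols], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"composition fractions sum to {fracs.sum()}, not 1")
    if allocation == "multinomial":
        counts = rng.multinomial(n_atoms, fracs)
    elif allocation == "exact":
        # largest-remainder rounding: deterministic counts, rare species kept
        ideal = fracs * n_atoms
        counts = np.floor(ideal).astype(int)
        remainder = ideal - counts
        for i in np.argsort(-remainder)[: n_atoms - counts.sum()]:
            counts[i] += 1
    else:
        raise ValueError(f"unknown allocation {allocation!r}")
    return symbols, counts


def build_toy_protein(
    n_atoms: int,
    composition: dict | None = None,
    radius: float = 20.0,
    seed: int = 0,
    min_dist: float = 1.2,
    allocation: str = "multinomial",
) -> AtomicConfiguration:
    """Generate a compact globular pseudo-protein.

    Atoms are placed uniformly in a ball of the given radius subject to a
    hard minimum pair distance; elements are drawn from ``composition``
    (default: the 2NIP heavy-atom ratio C:N:O:S:Fe = 2712:735:859:46:4).
    ``allocation="exact"`` replaces the multinomial draw with
    largest-remainder rounding so that rare species (S, Fe) are always
    present at their expected count.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    composition = composition or NIP2_COMPOSITION
    rng = np.random.default_rng(seed)
    symbols, counts = _allocate_counts(n_atoms, composition, rng, allocation)

    accepted = np.empty((0, 3))
    attempts, max_attempts = 0, 200 * n_atoms + 10000
    while len(accepted) < n_atoms:
        batch = max(256, n_atoms - len(accepted))
        pts = rng.normal(size=(4 * batch, 3))
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= radius * rng.random(len(pts))[:, None] ** (1.0 / 3.0)
        attempts += len(pts)
        for p in pts:
            if len(accepted) >= n_atoms:
                break
            if len(accepted) == 0 or np.min(np.linalg.norm(accepted - p, axis=1)) >= min_dist:
                accepted = np.vstack([accepted, p])
        if attempts > max_attempts and len(accepted) < n_atoms:
            raise RuntimeError(
                f"could not place {n_atoms} atoms at min distance {min_dist} A "
                f"inside radius {radius} A; increase the radius"
            )
    elements = np.repeat(symbols, counts)
    elements = elements[rng.permutation(n_atoms)]
    positions = accepted - accepted.mean(0)
    return _new_config(
        elements, positions, np.zeros(n_atoms), 0.0,
        f"toy(n={n_atoms},r={radius},seed={seed},allocation={allocation})",
    )


# -- water shell ----------------------------------------------------------

def _water_h_offsets(rng, n):
    """Random-orientation rigid-geometry H offsets for n water molecules."""
    half = np.deg2rad(HOH_ANGLE_DEG / 2.0)
    template = OH_BOND_A * np.array(
        [[np.sin(half), 0.0, np.cos(half)], [-np.sin(half), 0.0, np.cos(half)]]
    )
    quats = quaternions.random_quaternions(n, rng)
    mats = np.stack([quaternions.to_matrix(q) for q in quats])
    return np.einsum("nij,kj->nki", mats, template)  # (n, 2, 3)


def add_water_shell(
    config: AtomicConfiguration,
    thickness: float,
    number_density: float = LIQUID_WATER_DENSITY,
    seed: int = 0,
    r_contact: float = 2.8,
    min_oo_dist: float = 2.6,
) -> AtomicConfiguration:
    """Wrap the sample in a uniform-density water shell.

    Oxygen sites are placed at ``number_density`` in the region where the
    distance to the nearest protein atom lies in (r_contact,
    r_contact + thickness], subject to a hard O-O core of 2.6 A; each O is
    dressed with two H at rigid TIP3P-like geometry in a random
    orientation. Protein atoms are untouched; thickness = 0 returns the
    input unchanged.
    """
    if thickness < 0:
        raise ValueError("water thickness must be >= 0")
    if number_density <= 0:
        raise ValueError("number density must be > 0")
    if thickness == 0:
        out = config.copy()
        out.water_thickness = 0.0
        return out

    rng = np.random.default_rng(seed)
    protein_pos = config.positions[config.labels == PROTEIN]
    tree = cKDTree(protein_pos)
    lo = protein_pos.min(0) - (r_contact + thickness)
    hi = protein_pos.max(0) + (r_contact + thickness)
    v_box = float(np.prod(hi - lo))

    # Monte-Carlo estimate of the shell volume, then greedy hard-core filling
    n_probe = 20000
    probes = rng.uniform(lo, hi, size=(n_probe, 3))
    d_probe, _ = tree.query(probes)
    frac = np.mean((d_probe > r_contact) & (d_probe <= r_contact + thickness))
    v_shell = v_box * frac
    target = int(round(number_density * v_shell))

    oxygens = np.empty((0, 3))
    attempts, max_attempts = 0, 400 * max(target, 1) + 20000
    while len(oxygens) < target and attempts < max_attempts:
        m = max(1024, 4 * (target - len(oxygens)))
        cand = rng.uniform(lo, hi, size=(m, 3))
        attempts += m
        d, _ = tree.query(cand)
        cand = cand[(d > r_contact) & (d <= r_contact + thickness)]
        for p in cand:
            if len(oxygens) >= target:
                break
            if len(oxygens) == 0 or np.min(np.linalg.norm(oxygens - p, axis=1)) >= min_oo_dist:
                oxygens = np.vstack([oxygens, p])

    n_w = len(oxygens)
    h_off = _water_h_offsets(rng, n_w) if n_w else np.empty((0, 2, 3))
    water_elements = np.tile(["O", "H", "H"], n_w)
    water_pos = np.empty((3 * n_w, 3))
    water_pos[0::3] = oxygens
    water_pos[1::3] = oxygens + h_off[:, 0]
    water_pos[2::3] = oxygens + h_off[:, 1]

    elements = np.concatenate([config.elements, water_elements])
    positions = np.vstack([config.positions, water_pos])
    labels = np.concatenate([config.labels, np.full(3 * n_w, WATER, dtype=np.int8)])
    out = _new_config(
        elements, positions, labels, float(thickness),
        config.provenance + f"+water(t={thickness},rho={number_density},seed={seed})",
    )
    # preserve any pre-existing protein state
    n0 = config.n_atoms
    out.velocities[:n0] = config.velocities
    out.charges[:n0] = config.charges
    out.occupancies[:n0] = config.occupancies
    out.initial_positions[:n0] = config.initial_positions
    return out


# -- rigid rotation -------------------------------------------------------

def rotate_configuration(config: AtomicConfiguration, quaternion) -> AtomicConfiguration:
    """Rigidly rotate all positions (and velocities) about the center of mass."""
    rot = quaternions.to_matrix(quaternion)
    out = config.copy()
    com = config.center_of_mass()
    out.positions = (config.positions - com) @ rot.T + com
    out.initial_positions = (config.initial_positions - com) @ rot.T + com
    out.velocities = config.velocities @ rot.T
    return out
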