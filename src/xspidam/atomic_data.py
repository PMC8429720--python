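"""Per-element, per-charge-state scattering and ionization data.

The shipped YAML (``data/atomic_data.yaml``) carries, for H, C, N, O, S and
Fe: Cromer-Mann elastic form-factor fits f0(s), tabulated incoherent
(Compton) scattering functions S_incoh(s), subshell binding energies,
subshell photoionization cross sections at the 5 keV reference energy,
mean subshell kinetic energies for the binary-encounter-Bethe (BEB)
electron-impact model, and effective core-hole (Auger) lifetimes.

Ions are handled with two reduced models:

* elastic: f_ion(q) = f0(q) - (Z - n_bound) * v(q), with v a normalized
  single-Gaussian valence profile per element (v(0) = 1), clipped at 0.
  This reproduces the leading damage effect - low-q suppression
  proportional to the number of lost electrons - and is exact at q = 0.
* inelastic: S_ion(q) = S_incoh(q) * n_bound / Z.

``s`` below is the crystallographic variable sin(theta')/lambda = q/(4 pi)
in 1/A; all public operations take the physicist's q = 4 pi s.
"""

from __future__ import annotations

import functools
from importlib import resources

import numpy as np
import yaml

# global subshell ordering used for every occupancy vector in the package
SUBSHELLS = ("1s", "2s", "2p", "3s", "3p", "3d", "4s")
N_SUBSHELLS = len(SUBSHELLS)

# ground-state occupancies over SUBSHELLS
GROUND_OCC = {
    "H": (1, 0, 0, 0, 0, 0, 0),
    "C": (2, 2, 2, 0, 0, 0, 0),
    "N": (2, 2, 3, 0, 0, 0, 0),
    "O": (2, 2, 4, 0, 0, 0, 0),
    "S": (2, 2, 6, 2, 4, 0, 0),
    "Fe": (2, 2, 6, 2, 6, 6, 2),
}

ELEMENTS = tuple(GROUND_OCC)

_FOUR_PI_A0_SQ_CM2 = 3.5189e-16  # 4 pi a0^2
_RYDBERG_EV = 13.6057


def _require_element(element: str, known) -> None:
    if element not in known:
        raise KeyError(f"element {element!r} not in shipped tables {sorted(known)}")


class ScatteringTables:
    """Scattering/ionization data service backed by the shipped YAML tables."""

    def __init__(self, raw: dict):
        self.source_note: str = raw["source_note"]
        self.energy_range_keV = tuple(raw["photon_energy_range_keV"])
        self.reference_energy_keV = float(raw["reference_energy_keV"])
        self.elements = tuple(raw["elements"])
        self._index = {el: i for i, el in enumerate(self.elements)}
        nel = len(self.elements)

        self.Z = np.zeros(nel, dtype=np.int64)
        self.mass_amu = np.zeros(nel)
        self.ground_occ = np.zeros((nel, N_SUBSHELLS), dtype=np.int64)
        self.binding_eV = np.full((nel, N_SUBSHELLS), np.inf)
        self.sigma_ref_per_electron = np.zeros((nel, N_SUBSHELLS))
        self.mean_KE_eV = np.zeros((nel, N_SUBSHELLS))
        self.auger_lifetime_fs = np.full(nel, np.inf)
        self._cm_a = np.zeros((nel, 4))
        self._cm_b = np.zeros((nel, 4))
        self._cm_c = np.zeros(nel)
        self._valence_b = np.zeros(nel)
        self._sincoh_s = {}
        self._sincoh_v = {}

        for el, d in raw["elements"].items():
            i = self._index[el]
            z = int(d["Z"])
            self.Z[i] = z
            self.mass_amu[i] = d["mass_amu"]
            self.ground_occ[i] = GROUND_OCC[el]
            a = np.asarray(d["cm_a"], dtype=float)
            c = float(d["cm_c"])
            # rescale so that f0(0) == Z exactly (fits are within 0.02 e)
            raw0 = a.sum() + c
            if abs(raw0 - z) > 0.02:
                raise ValueError(f"{el}: Cromer-Mann fit f0(0)={raw0} departs from Z={z}")
            scale = z / raw0
            self._cm_a[i] = a * scale
            self._cm_b[i] = d["cm_b"]
            self._cm_c[i] = c * scale
            self._valence_b[i] = d["valence_b"]
            self._sincoh_s[el] = np.asarray(d["sincoh_s"], dtype=float)
            self._sincoh_v[el] = np.asarray(d["sincoh_vals"], dtype=float)
            if d["auger_lifetime_fs"] is not None:
                self.auger_lifetime_fs[i] = float(d["auger_lifetime_fs"])
            for sub in d["subshells"]:
                j = SUBSHELLS.index(sub["label"])
                occ = GROUND_OCC[el][j]
                if occ == 0:
                    raise ValueError(f"{el}: data for unoccupied subshell {sub['label']}")
                self.binding_eV[i, j] = sub["binding_eV"]
                self.sigma_ref_per_electron[i, j] = sub["sigma_at_5keV_cm2"] / occ
                self.mean_KE_eV[i, j] = sub["mean_KE_eV"]

    # -- construction -----------------------------------------------------

    @classmethod
    @functools.lru_cache(maxsize=1)
    def default(cls) -> "ScatteringTables":
        path = resources.files("xspidam.data") / "atomic_data.yaml"
        with path.open() as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def from_yaml(cls, path) -> "ScatteringTables":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def index(self, element: str) -> int:
        _require_element(element, self._index)
        return self._index[element]

    def z_of(self, element: str) -> int:
        return int(self.Z[self.index(element)])

    # -- elastic ----------------------------------------------------------

    def neutral_form_factor(self, element: str, q):
        """Tabulated (rescaled) Cromer-Mann f0 at q (1/A) for the neutral atom."""
        i = self.index(element)
        s2 = (np.asarray(q, dtype=float) / (4.0 * np.pi)) ** 2
        f = self._cm_c[i] + np.sum(
            self._cm_a[i] * np.exp(-self._cm_b[i] * s2[..., None]), axis=-1
        )
        return f

    def elastic_form_factor(self, element: str, n_bound: int, q):
        """Elastic form factor (electrons) for an atom/ion with n_bound electrons."""
        i = self.index(element)
        z = self.Z[i]
        if not 0 <= n_bound <= z:
            raise ValueError(f"n_bound={n_bound} outside [0, {z}] for {element}")
        f = self.neutral_form_factor(element, q)
        if n_bound != z:
            s2 = (np.asarray(q, dtype=float) / (4.0 * np.pi)) ** 2
            f = f - (z - n_bound) * np.exp(-self._valence_b[i] * s2)
        return np.clip(f, 0.0, None)

    # -- inelastic --------------------------------------------------------

    def incoherent_function(self, element: str, n_bound: int, q):
        """Compton scattering strength S_incoh (electrons) for n_bound electrons."""
        i = self.index(element)
        z = self.Z[i]
        if not 0 <= n_bound <= z:
            raise ValueError(f"n_bound={n_bound} outside [0, {z}] for {element}")
        s = np.asarray(q, dtype=float) / (4.0 * np.pi)
        base = np.interp(s, self._sincoh_s[element], self._sincoh_v[element])
        return base * (n_bound / z)

    # -- photoionization --------------------------------------------------

    def _check_energy(self, photon_energy_keV: float) -> None:
        lo, hi = self.energy_range_keV
        if not lo <= photon_energy_keV <= hi:
            raise ValueError(
                f"photon energy {photon_energy_keV} keV outside shipped table "
                f"range [{lo}, {hi}] keV"
            )

    @functools.lru_cache(maxsize=8)
    def photo_sigma_matrix(self, photon_energy_keV: float) -> np.ndarray:
        """(n_elements, n_subshells) per-electron cross sections (cm^2).

        Subshells whose binding energy exceeds the photon energy contribute 0.
        Within the 4-6 keV window the photoelectric E^-3 scaling is applied
        around the 5 keV reference.
        """
        self._check_energy(photon_energy_keV)
        scale = (self.reference_energy_keV / photon_energy_keV) ** 3
        sig = self.sigma_ref_per_electron * scale
        sig = np.where(self.binding_eV < photon_energy_keV * 1e3, sig, 0.0)
        sig.flags.writeable = False
        return sig

    def photo_cross_section(self, element: str, shell_occupancy, photon_energy_keV: float) -> float:
        """Total photoionization cross section (cm^2) of one atom/ion."""
        i = self.index(element)
        occ = np.asarray(shell_occupancy, dtype=float)
        sig = self.photo_sigma_matrix(float(photon_energy_keV))
        return float(occ @ sig[i])

    # -- electron impact (BEB) --------------------------------------------

    def beb_sigma_matrix(self, electron_KE_eV: float) -> np.ndarray:
        """(n_elements, n_subshells) per-electron BEB cross sections (cm^2)."""
        T = float(electron_KE_eV)
        B = self.binding_eV
        with np.errstate(divide="ignore", invalid="ignore"):
            t = T / B
            u = self.mean_KE_eV / B
            s0 = _FOUR_PI_A0_SQ_CM2 * (_RYDBERG_EV / B) ** 2
            lnt = np.log(np.where(t > 1.0, t, 1.0))
            bracket = 0.5 * lnt * (1.0 - 1.0 / t**2) + 1.0 - 1.0 / t - lnt / (t + 1.0)
            sig = s0 / (t + u + 1.0) * bracket
        sig = np.where((t > 1.0) & np.isfinite(B), sig, 0.0)
        return np.clip(sig, 0.0, None)

    def beb_impact_cross_section(self, element: str, shell_occupancy, electron_KE_eV: float) -> float:
        """Total BEB electron-impact ionization cross section (cm^2).

        Exactly 0 when the electron energy is below the smallest occupied
        binding energy.
        """
        if electron_KE_eV < 0:
            raise ValueError("electron kinetic energy must be >= 0")
        i = self.index(element)
        occ = np.asarray(shell_occupancy, dtype=float)
        return float(occ @ self.beb_sigma_matrix(electron_KE_eV)[i])

    def beb_sigma_atoms(self, electron_KE_eV: float, occupancies: np.ndarray,
                        elem_idx: np.ndarray) -> np.ndarray:
        """Vectorized per-atom BEB cross sections for one electron energy."""
        sig = self.beb_sigma_matrix(electron_KE_eV)
        return np.einsum("ij,ij->i", occupancies.astype(float), sig[elem_idx])

    # -- bookkeeping ------------------------------------------------------

    def auger_lifetime(self, element: str) -> float:
        return float(self.auger_lifetime_fs[self.index(element)])

    def subshell_binding(self, element: str) -> np.ndarray:
        return self.binding_eV[self.index(element)].copy()


def default_tables() -> ScatteringTables:
    return ScatteringTables.default()
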