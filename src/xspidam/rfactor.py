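"""Resolution-dependent R-factor fidelity analysis.

The R factor between a damaged pattern and the ideal (undamaged,
water-free) reference, accumulated up to resolution D, is

    R(D) = sum_{q <= 2 pi / D} Omega(q) | sqrt(N(q)) / Sigma'
                                - sqrt(N_ideal(q)) / Sigma'_ideal |

with N(q) = n(q) / Omega(q) the counts per unit solid angle and Sigma'
the Omega-weighted sum of sqrt(N) over the same cumulative region. R is
the L1 distance of two unit-normalized non-negative distributions, hence
0 <= R <= 2, R = 0 for identical patterns, and R is invariant to scaling
either pattern by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atomic_data import ScatteringTables, default_tables
from .diffraction import (DetectorGeometry, DiffractionPattern, ELASTIC_ONLY,
                          integrate_pattern)
from .dynamics import PhysicsParams, Snapshot, Trajectory
from .sample import WATER, AtomicConfiguration


def default_resolution_grid(d_min: float = 5.0, d_max: float = 60.0,
                            n: int = 28) -> np.ndarray:
    """Resolution lengths D (A), log-spaced from d_min to d_max."""
    return np.geomspace(d_min, d_max, n)


@dataclass
class RFactorCurve:
    """Orientation-averaged R(D) for one water thickness / component set."""

    D_grid: np.ndarray
    mean_R: np.ndarray
    std_R: np.ndarray
    water_thickness: float
    n_patterns: int
    components: frozenset

    def band_mean(self, d_lo: float = -np.inf, d_hi: float = np.inf) -> float:
        mask = (self.D_grid >= d_lo) & (self.D_grid <= d_hi)
        if not mask.any():
            raise ValueError("empty resolution band")
        return float(self.mean_R[mask].mean())


def _check_compatible(pattern: DiffractionPattern, ideal: DiffractionPattern):
    if pattern.detector_meta != ideal.detector_meta:
        raise ValueError("patterns computed on different detector geometries")
    if pattern.orientation is not None and ideal.orientation is not None:
        if not np.allclose(pattern.orientation, ideal.orientation, atol=1e-9):
            raise ValueError("patterns correspond to different orientations")


def r_factor(pattern: DiffractionPattern, ideal: DiffractionPattern,
             detector: DetectorGeometry, D: float) -> float:
    """R factor between two patterns on the same reciprocal space, using
    the cumulative pixel set q <= 2 pi / D."""
    _check_compatible(pattern, ideal)
    mask = detector.q_abs <= 2.0 * np.pi / D * (1.0 + 1e-12)
    if not mask.any():
        raise ValueError(f"no pixels at resolution cutoff D={D} A")
    omega = detector.omega_sr[mask]
    sa = np.sqrt(pattern.counts[mask] / omega)
    sb = np.sqrt(ideal.counts[mask] / omega)
    na, nb = (omega * sa).sum(), (omega * sb).sum()
    if na == 0.0 and nb == 0.0:
        return 0.0
    if na == 0.0 or nb == 0.0:
        return 2.0  # one empty distribution: maximal L1 distance
    return float(np.sum(omega * np.abs(sa / na - sb / nb)))


def r_curve(patterns, ideals, detector: DetectorGeometry, D_grid,
            water_thickness: float | None = None) -> RFactorCurve:
    """Mean and population standard deviation of R(D) over orientations k,
    pairing each damaged pattern with the ideal at the same orientation."""
    patterns, ideals = list(patterns), list(ideals)
    if len(patterns) != len(ideals) or not patterns:
        raise ValueError("need matching, non-empty pattern/ideal sets")
    D_grid = np.asarray(D_grid, dtype=float)
    R = np.empty((len(patterns), len(D_grid)))
    for i, (p, ref) in enumerate(zip(patterns, ideals)):
        for j, D in enumerate(D_grid):
            R[i, j] = r_factor(p, ref, detector, D)
    if water_thickness is None:
        water_thickness = patterns[0].water_thickness
    return RFactorCurve(
        D_grid=D_grid,
        mean_R=R.mean(0),
        std_R=R.std(0),  # population convention (divisor N)
        water_thickness=float(water_thickness),
        n_patterns=len(patterns),
        components=patterns[0].components,
    )


def make_ideal_reference(
    protein: AtomicConfiguration,
    pulse,
    detector: DetectorGeometry,
    orientation,
    components: frozenset = ELASTIC_ONLY,
    tables: ScatteringTables | None = None,
    params: PhysicsParams | None = None,
    precision: str = "single",
) -> DiffractionPattern:
    """Ideal reference pattern: the static, neutral protein (water
    stripped), integrated over the same pulse at the same orientation.
    Elastic-only by default; a flag can add the bound-atom Compton term of
    the undamaged protein."""
    tables = tables or default_tables()
    params = params or PhysicsParams()
    mask = protein.labels != WATER
    if not mask.all():
        stripped = AtomicConfiguration(
            elements=protein.elements[mask],
            positions=protein.positions[mask],
            initial_positions=protein.initial_positions[mask],
            velocities=protein.velocities[mask],
            charges=protein.charges[mask],
            occupancies=protein.occupancies[mask],
            labels=protein.labels[mask],
            water_thickness=0.0,
            provenance=protein.provenance + "+stripped",
        )
    else:
        stripped = protein
    snap = Snapshot.from_configuration(stripped, tables)
    snap.step_index = 0
    static = Trajectory(
        snapshots=[snap],
        pulse_id=pulse.profile_id,
        base_quaternion=np.array([1.0, 0.0, 0.0, 0.0]),
        seed=-1,
        timestep_fs=params.timestep_fs,
        escape_radius_A=0.0,
        params=params,
    )
    return integrate_pattern(
        static, pulse, detector, delta_t=params.timestep_fs * 10,
        components=components, final_orientation=orientation, tables=tables,
        precision=precision,
    )


def summarize_regimes(curves, high_band: float = 10.0, low_band: float = 20.0) -> dict:
    """Compare R curves across water thicknesses in the high-resolution
    band (D <= high_band) and the low-resolution band (D >= low_band).

    Reports the thickness with minimal band-averaged mean R in each band
    and whether the trend interchange (thin layers best at high
    resolution, thick layers best at low resolution) occurs.
    """
    curves = list(curves)
    if len(curves) < 2:
        raise ValueError("need at least two curves to compare regimes")
    D = curves[0].D_grid
    for c in curves:
        if not np.allclose(c.D_grid, D):
            raise ValueError("curves must share the resolution grid")
        if c.components != curves[0].components:
            raise ValueError("curves must share the component set")

    thick = np.array([c.water_thickness for c in curves])
    high = np.array([c.band_mean(d_hi=high_band) for c in curves])
    low = np.array([c.band_mean(d_lo=low_band) for c in curves])

    spread = max(np.ptp(high), np.ptp(low))
    no_discrimination = bool(spread < 1e-12)
    best_high = float(thick[np.argmin(high)])
    best_low = float(thick[np.argmin(low)])
    return {
        "thicknesses": thick.tolist(),
        "high_band_mean_R": high.tolist(),
        "low_band_mean_R": low.tolist(),
        "best_thickness_high_res": best_high,
        "best_thickness_low_res": best_low,
        "crossing": bool(not no_discrimination and best_low > best_high),
        "no_discrimination": no_discrimination,
        "high_band_max_D": high_band,
        "low_band_min_D": low_band,
    }
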