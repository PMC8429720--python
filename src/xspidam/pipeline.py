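"""Experiment orchestration: sample build, pulse ensemble, damage batch per
water thickness, pattern generation on a shared orientation list, R curves.

Seeds are derived from the master seed per (trajectory, role) through
``numpy.random.SeedSequence`` so the same pulse realizations, base
orientations and damage randomness are reused for every water thickness
(common random numbers: thickness comparisons are then paired, which
stands in for the brute-force replication of a full-scale study).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import quaternions
from .atomic_data import default_tables
from .diffraction import (DEFAULT_COMPONENTS, ELASTIC_ONLY, build_detector,
                          integrate_pattern)
from .dynamics import PhysicsParams, run_trajectory
from .pulse import align_time_zero, generate_sase_profile
from .rfactor import (default_resolution_grid, make_ideal_reference, r_curve,
                      summarize_regimes)
from .sample import add_water_shell, build_toy_protein, load_pdb

log = logging.getLogger("xspidam")

# role codes for counter-based seed derivation
_ROLE_SAMPLE, _ROLE_WATER, _ROLE_ORIENT, _ROLE_PULSE, _ROLE_BASEQ, _ROLE_DAMAGE = range(6)


def derive_seed(master_seed: int, role: int, index: int = 0) -> int:
    ss = np.random.SeedSequence(entropy=(int(master_seed), int(role), int(index)))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def sample_orientations(n: int, seed: int) -> np.ndarray:
    """n quaternions uniform on SO(3) (Shoemake construction), (w,x,y,z)."""
    rng = np.random.default_rng(seed)
    return quaternions.random_quaternions(n, rng)


@dataclass
class BeamConfig:
    photon_energy_keV: float = 4.96
    fdhm_fs: float = 9.0
    n_photons: float = 5e11
    coherence_time_fs: float = 0.25
    focus_fwhm_nm: tuple = (250.0, 160.0)


@dataclass
class DetectorConfig:
    n_pixels: tuple = (81, 81)
    pixel_size_um: float = 1200.0
    distance_cm: float = 13.0
    polarization: str = "horizontal"


@dataclass
class ExperimentConfig:
    """Desk-scale defaults: a ~800-atom toy particle with facility-scale beam,
    detector, fluence-per-atom and thickness grid; full-scale values
    (1000 trajectories, 20 patterns each, PDB input) remain valid."""

    water_thicknesses: tuple = (0.0, 2.0, 4.0, 6.0, 10.0, 20.0)
    n_trajectories: int = 20
    patterns_per_trajectory: int = 1
    n_pulse_profiles: int = 55
    toy_n_atoms: int = 800
    toy_radius_A: float = 20.0
    toy_allocation: str = "exact"
    pdb_path: str | None = None
    include_hydrogens: bool = True
    beam: BeamConfig = field(default_factory=BeamConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    physics: PhysicsParams = field(default_factory=PhysicsParams)
    component_sets: tuple = ("elastic+inelastic", "elastic_only")
    resolution_grid: tuple = tuple(default_resolution_grid())
    pattern_precision: str = "single"
    master_seed: int = 1
    output_dir: str | None = None
    save_patterns: bool = False

    def __post_init__(self):
        t = tuple(float(x) for x in self.water_thicknesses)
        if any(x < 0 for x in t) or len(set(t)) != len(t) or list(t) != sorted(t):
            raise ValueError("water thicknesses must be non-negative, unique, sorted")
        self.water_thicknesses = t

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (("beam", BeamConfig), ("detector", DetectorConfig),
                         ("physics", PhysicsParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_COMPONENT_SETS = {
    "elastic+inelastic": DEFAULT_COMPONENTS,
    "elastic_only": ELASTIC_ONLY,
}


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    orientations: np.ndarray
    curves: dict            # (thickness, component_set_name) -> RFactorCurve
    summaries: dict         # component_set_name -> regime report
    event_ledgers: dict     # thickness -> (n_elements, 3) pooled event counts
    heavy_impact_fraction: dict  # thickness -> pooled S/Fe collisional fraction
    manifest: dict

    def curve(self, thickness: float, component_set: str = "elastic+inelastic"):
        return self.curves[(float(thickness), component_set)]


def build_sample(config: ExperimentConfig):
    """Protein-only configuration per config (PDB or toy)."""
    if config.pdb_path:
        return load_pdb(config.pdb_path, include_hydrogens=config.include_hydrogens)
    return build_toy_protein(
        config.toy_n_atoms,
        radius=config.toy_radius_A,
        seed=derive_seed(config.master_seed, _ROLE_SAMPLE),
        allocation=config.toy_allocation,
    )


def make_pulse_ensemble(config: ExperimentConfig):
    beam = config.beam
    profiles = [
        generate_sase_profile(
            photon_energy_keV=beam.photon_energy_keV,
            fdhm_fs=beam.fdhm_fs,
            n_photons=beam.n_photons,
            coherence_time_fs=beam.coherence_time_fs,
            timestep_fs=config.physics.timestep_fs,
            span_fs=config.physics.span_fs,
            seed=derive_seed(config.master_seed, _ROLE_PULSE, i),
            focus_fwhm_nm=beam.focus_fwhm_nm,
            profile_id=i,
        )
        for i in range(config.n_pulse_profiles)
    ]
    return align_time_zero(profiles)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full thickness scan and R-curve analysis.

    For each thickness: hydrate the sample once, run the damage batch
    cycling through the pulse ensemble, integrate patterns at the shared
    orientation list, compare against matched ideal references, and
    aggregate R curves per component set.
    """
    t0 = time.time()
    tables = default_tables()
    detector = build_detector(
        n_pixels=config.detector.n_pixels,
        pixel_size_um=config.detector.pixel_size_um,
        distance_cm=config.detector.distance_cm,
        photon_energy_keV=config.beam.photon_energy_keV,
        polarization=config.detector.polarization,
    )
    protein = build_sample(config)
    pulses = make_pulse_ensemble(config)
    n_orient = config.n_trajectories * config.patterns_per_trajectory
    orientations = sample_orientations(
        n_orient, derive_seed(config.master_seed, _ROLE_ORIENT)
    )
    base_quats = sample_orientations(
        config.n_trajectories, derive_seed(config.master_seed, _ROLE_BASEQ)
    )
    D_grid = np.asarray(config.resolution_grid)

    # matched ideal references, shared by every thickness
    ideal_cache = {}

    def ideal(orient_idx, comp_name):
        key = (orient_idx, comp_name)
        if key not in ideal_cache:
            pulse = pulses[0]
            ideal_cache[key] = make_ideal_reference(
                protein, pulse, detector, orientations[orient_idx],
                components=ELASTIC_ONLY, tables=tables, params=config.physics,
                precision=config.pattern_precision,
            )
        return ideal_cache[key]

    curves, ledgers, heavy_frac = {}, {}, {}
    for thickness in config.water_thicknesses:
        sample = add_water_shell(
            protein, thickness,
            seed=derive_seed(config.master_seed, _ROLE_WATER, int(thickness * 10)),
        )
        log.info("thickness %.1f A: %d atoms (%d water molecules)",
                 thickness, sample.n_atoms, sample.n_water_molecules)
        patterns = {name: [] for name in config.component_sets}
        ideals = {name: [] for name in config.component_sets}
        # trajectories are streamed: patterns are integrated immediately and
        # only the event ledger of the final snapshot is retained
        pooled_events = 0
        heavy_idx = [tables.index(el) for el in ("S", "Fe")]
        heavy_events = np.zeros(3, dtype=np.int64)
        for t in range(config.n_trajectories):
            pulse = pulses[t % len(pulses)]
            traj = run_trajectory(
                sample, pulse, config.physics,
                seed=derive_seed(config.master_seed, _ROLE_DAMAGE, t),
                tables=tables, base_quaternion=base_quats[t], pulse_id=pulse.profile_id,
            )
            counts = traj.final.event_counts
            log.info(
                "  traj %d: events photo=%d auger=%d impact=%d escaped=%d",
                t, counts[:, 0].sum(), counts[:, 1].sum(), counts[:, 2].sum(),
                traj.final.n_escaped,
            )
            pooled_events = pooled_events + counts
            heavy_events += counts[heavy_idx].sum(0)
            for k in range(config.patterns_per_trajectory):
                oi = t * config.patterns_per_trajectory + k
                for name in config.component_sets:
                    pat = integrate_pattern(
                        traj, pulse, detector,
                        components=_COMPONENT_SETS[name],
                        final_orientation=orientations[oi], tables=tables,
                        precision=config.pattern_precision,
                    )
                    pat = dataclasses.replace(pat, water_thickness=float(thickness))
                    patterns[name].append(pat)
                    ideals[name].append(ideal(oi, name))
            del traj
        ledgers[thickness] = pooled_events
        total_heavy = heavy_events.sum()
        heavy_frac[thickness] = float(heavy_events[2] / total_heavy) if total_heavy else 0.0
        for name in config.component_sets:
            curves[(thickness, name)] = r_curve(
                patterns[name], ideals[name], detector, D_grid,
                water_thickness=thickness,
            )
        if config.output_dir and config.save_patterns:
            from .io import save_patterns as _save

            out = Path(config.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            for name in config.component_sets:
                _save(out / f"patterns_t{thickness:g}_{name}.h5",
                      patterns[name], detector)

    summaries = {}
    for name in config.component_sets:
        cs = [curves[(t, name)] for t in config.water_thicknesses]
        if len(cs) >= 2:
            summaries[name] = summarize_regimes(cs)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "n_orientations": n_orient,
        "orientation_hash": hashlib.sha256(
            np.ascontiguousarray(orientations).tobytes()
        ).hexdigest()[:16],
        "runtime_s": round(time.time() - t0, 2),
        "heavy_impact_fraction": {str(k): v for k, v in heavy_frac.items()},
    }
    result = ExperimentResult(
        config=config, orientations=orientations, curves=curves,
        summaries=summaries, event_ledgers=ledgers,
        heavy_impact_fraction=heavy_frac, manifest=manifest,
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .io import save_curves_csv, save_manifest

        save_curves_csv(out / "r_curves.csv", list(curves.values()))
        save_manifest(out / "manifest.json", manifest)
        save_manifest(out / "regime_summary.json", summaries)
    return result
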