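"""On-disk formats: HDF5 for configurations/profiles/patterns (CXI-style
layout for pattern stacks), XYZ text for inspection, CSV for R curves."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .sample import AtomicConfiguration


def save_configuration(path, config: AtomicConfiguration, group: str = "sample") -> None:
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("element", data=np.char.encode(config.elements.astype(str)))
        g.create_dataset("position_A", data=config.positions)
        g.create_dataset("label", data=config.labels)
        g.create_dataset("charge", data=config.charges)
        g.attrs["water_thickness_A"] = config.water_thickness
        g.attrs["provenance"] = config.provenance


def load_configuration(path, group: str = "sample") -> AtomicConfiguration:
    from .sample import _new_config

    with h5py.File(path, "r") as fh:
        g = fh[group]
        elements = np.char.decode(g["element"][...]).astype("U2")
        cfg = _new_config(
            elements,
            g["position_A"][...],
            g["label"][...],
            float(g.attrs["water_thickness_A"]),
            str(g.attrs["provenance"]),
        )
        cfg.charges = g["charge"][...]
    return cfg


def write_xyz(path, config: AtomicConfiguration, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{config.n_atoms}\n{comment or config.provenance}\n")
        for el, (x, y, z) in zip(config.elements, config.positions):
            fh.write(f"{el:2s} {x:12.6f} {y:12.6f} {z:12.6f}\n")


def save_profiles(path, profiles) -> None:
    with h5py.File(path, "w") as fh:
        for p in profiles:
            g = fh.create_group(f"profile_{p.profile_id:03d}")
            g.create_dataset("times_fs", data=p.times)
            g.create_dataset("n0", data=p.n0)
            g.attrs.update(
                photon_energy_keV=p.photon_energy_keV,
                fdhm_fs=p.fdhm_fs,
                focus_fwhm_nm=p.focus_fwhm_nm,
            )


def save_patterns(path, patterns, detector) -> None:
    """CXI-convention-style stack: /entry_1/data_1/data plus geometry."""
    with h5py.File(path, "w") as fh:
        data = fh.create_dataset(
            "entry_1/data_1/data",
            data=np.stack([p.counts.reshape(detector.shape) for p in patterns]),
        )
        fh.create_dataset("entry_1/data_1/orientation",
                          data=np.stack([p.orientation for p in patterns]))
        fh.create_dataset("entry_1/data_1/water_thickness_A",
                          data=[p.water_thickness for p in patterns])
        fh.create_dataset("entry_1/data_1/pulse_id", data=[p.pulse_id for p in patterns])
        fh.create_dataset("entry_1/data_1/seed", data=[p.seed for p in patterns])
        data.attrs["components"] = ",".join(sorted(patterns[0].components))
        g = fh.create_group("entry_1/instrument_1/detector_1")
        g.attrs.update(
            pixel_size_um=detector.pixel_size_um,
            distance_cm=detector.distance_cm,
            photon_energy_keV=detector.photon_energy_keV,
            polarization=detector.polarization,
        )


def save_trajectory(path, trajectory) -> None:
    """Damage-run layout: /snapshots/{i}/... plus /meta/{seed, pulse_id, ...}."""
    with h5py.File(path, "w") as fh:
        meta = fh.create_group("meta")
        meta.attrs.update(
            seed=trajectory.seed,
            pulse_id=trajectory.pulse_id,
            timestep_fs=trajectory.timestep_fs,
            escape_radius_A=trajectory.escape_radius_A,
        )
        meta.create_dataset("quaternion", data=trajectory.base_quaternion)
        first = trajectory.snapshots[0]
        meta.create_dataset("element",
                            data=np.char.encode(first.elements.astype(str)))
        meta.create_dataset("label", data=first.labels)
        meta.create_dataset("initial_positions", data=first.initial_positions)
        for i, snap in enumerate(trajectory.snapshots):
            g = fh.create_group(f"snapshots/{i}")
            g.attrs["time_fs"] = snap.time
            g.attrs["step_index"] = snap.step_index
            g.attrs["n_escaped"] = snap.n_escaped
            g.create_dataset("positions", data=snap.positions)
            g.create_dataset("charges", data=snap.charges)
            g.create_dataset("occupancies", data=snap.occupancies)
            g.create_dataset("electron_positions", data=snap.electron_positions)
            g.create_dataset("electron_velocities", data=snap.electron_velocities)
            g.create_dataset("event_counts", data=snap.event_counts)


def curves_to_frame(curves) -> pd.DataFrame:
    rows = []
    for c in curves:
        for d, m, s in zip(c.D_grid, c.mean_R, c.std_R):
            rows.append(
                dict(D_A=d, mean_R=m, std_R=s, thickness_A=c.water_thickness,
                     components="+".join(sorted(c.components)), n_patterns=c.n_patterns)
            )
    return pd.DataFrame(rows)


def save_curves_csv(path, curves) -> None:
    curves_to_frame(curves).to_csv(path, index=False)


def save_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
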