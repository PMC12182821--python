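"""Persistence: NIfTI volumes, k-space archives, config files, tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .acquire import AcquisitionConfig, KSpaceSet
from .phantom import FlowPhantom, PhantomConfig, TriggerTrain, VesselSpec
from .trajectory import SpiralArm, TRSchedule


def save_nifti(path, data: np.ndarray, voxel_size_mm) -> None:
    """Write a 3D/4D volume with voxel spacing in the affine."""
    vs = np.atleast_1d(np.asarray(voxel_size_mm, dtype=float))
    if vs.size == 1:
        vs = np.repeat(vs, 3)
    affine = np.diag([*vs, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    nib.save(img, str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_phantom(phantom: FlowPhantom, out_dir) -> None:
    """One file per field: magnitude, vx, vy, vz (4D x,y,z,phase) and labels."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vs = phantom.voxel_size_mm
    save_nifti(out_dir / "magnitude.nii.gz", phantom.magnitude, vs)
    for i, name in enumerate(("vx", "vy", "vz")):
        save_nifti(out_dir / f"{name}.nii.gz", phantom.velocity[i], vs)
    save_nifti(out_dir / "labels.nii.gz", phantom.labels.astype(np.int16), vs)


def save_kspace(path, kspace: KSpaceSet) -> None:
    """Single-archive k-space product, loadable without the phantom."""
    np.savez_compressed(
        path,
        data=kspace.data.astype(np.complex64),
        arm_k=kspace.arm.k_samples,
        arm_times=kspace.arm.sample_times_ms,
        arm_turns=kspace.arm.n_turns,
        sched_rotation=kspace.schedule.rotation_deg,
        sched_z=kspace.schedule.slice_z_mm,
        sched_encoding=kspace.schedule.encoding_index,
        sched_time=kspace.schedule.time_ms,
        sched_tr=kspace.schedule.tr_ms,
        sched_shift=kspace.schedule.shift_per_tr_mm,
        sched_golden=kspace.schedule.golden_angle_deg,
        triggers=kspace.triggers.r_peak_times_ms,
        config=json.dumps(dataclasses.asdict(kspace.config)),
    )


def load_kspace(path) -> KSpaceSet:
    with np.load(path, allow_pickle=False) as z:
        config = AcquisitionConfig(**json.loads(str(z["config"])))
        sched = TRSchedule(
            index=np.arange(z["data"].shape[0]),
            rotation_deg=z["sched_rotation"],
            slice_z_mm=z["sched_z"],
            encoding_index=z["sched_encoding"],
            time_ms=z["sched_time"],
            tr_ms=float(z["sched_tr"]),
            shift_per_tr_mm=float(z["sched_shift"]),
            golden_angle_deg=float(z["sched_golden"]),
        )
        arm = SpiralArm(
            k_samples=z["arm_k"],
            sample_times_ms=z["arm_times"],
            n_turns=float(z["arm_turns"]),
        )
        return KSpaceSet(
            data=z["data"].astype(complex),
            schedule=sched,
            arm=arm,
            triggers=TriggerTrain(r_peak_times_ms=z["triggers"]),
            config=config,
        )


def phantom_config_to_yaml(config: PhantomConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["vessels"] = [dataclasses.asdict(v) for v in config.vessels]
    Path(path).write_text(yaml.safe_dump(_plain(d), sort_keys=False))


def phantom_config_from_yaml(path) -> PhantomConfig:
    d = yaml.safe_load(Path(path).read_text())
    vessels = []
    for v in d.pop("vessels", []):
        if v.get("branch_of") is not None:
            v["branch_of"] = tuple(v["branch_of"])
        vessels.append(VesselSpec(**v))
    d["grid_shape"] = tuple(d["grid_shape"])
    d["background_phase_coeffs"] = tuple(d.get("background_phase_coeffs", (0.0,) * 6))
    return PhantomConfig(vessels=tuple(vessels), **d)


def _plain(obj):
    """Recursively convert numpy/tuple values to YAML/JSON-friendly types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
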