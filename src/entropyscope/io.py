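"""File formats: HDF5 recordings and source volumes, CSV event tables,
NIfTI spatial maps.

The HDF5 recording dialect is flat: /data (channels x time), /sfreq,
/channel_positions, /channel_orientations.  Event tables are plain CSV with
columns onset, duration, label, block, excluded plus a JSON sidecar carrying
the full paradigm specification.  Voxel maps defined on the regular source
grid are resampled into a dense 3-D volume and written as NIfTI with an
affine built from the grid spacing and origin.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import nibabel as nib

from .beamforming import SensorRecording, SourceVolume
from .paradigms import Event, ParadigmSpec

__all__ = [
    "write_recording",
    "read_recording",
    "write_events",
    "read_events",
    "write_source_volume",
    "read_source_volume",
    "grid_map_to_nifti",
]


def write_recording(path: str | Path, rec: SensorRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("sfreq", data=rec.sampling_rate)
        f.create_dataset("channel_positions", data=rec.channel_positions)
        f.create_dataset("channel_orientations", data=rec.channel_orientations)


def read_recording(path: str | Path) -> SensorRecording:
    with h5py.File(path, "r") as f:
        return SensorRecording(
            data=f["data"][()],
            sampling_rate=float(f["sfreq"][()]),
            channel_positions=f["channel_positions"][()],
            channel_orientations=f["channel_orientations"][()],
        )


def write_events(path: str | Path, paradigm: ParadigmSpec,
                 sidecar: bool = True) -> None:
    df = pd.DataFrame([{
        "onset": e.onset, "duration": e.duration, "label": e.label,
        "block": e.block, "excluded": e.excluded,
    } for e in paradigm.events])
    df.to_csv(path, index=False)
    if sidecar:
        side = Path(path).with_suffix(".json")
        spec = paradigm.to_dict()
        side.write_text(json.dumps(spec, indent=2))


def read_events(path: str | Path) -> ParadigmSpec:
    """Rebuild a ParadigmSpec from the CSV + JSON sidecar pair."""
    side = Path(path).with_suffix(".json")
    if not side.exists():
        raise FileNotFoundError(f"sidecar {side} required to rebuild the paradigm")
    d = json.loads(side.read_text())
    events = [Event(**e) for e in d.pop("events")]
    d["block_boundaries"] = [tuple(b) for b in d["block_boundaries"]]
    d["rest_windows"] = [tuple(w) for w in d["rest_windows"]]
    d["trial_window"] = tuple(d["trial_window"])
    return ParadigmSpec(events=events, **d)


def write_source_volume(path: str | Path, vol: SourceVolume) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("grid", data=vol.grid)
        f.create_dataset("orientations", data=vol.orientations)
        f.create_dataset("timecourses", data=vol.timecourses)
        f.create_dataset("sfreq", data=vol.sampling_rate)
        if vol.pseudo_z is not None:
            f.create_dataset("pseudo_z", data=vol.pseudo_z)


def read_source_volume(path: str | Path) -> SourceVolume:
    with h5py.File(path, "r") as f:
        return SourceVolume(
            grid=f["grid"][()],
            orientations=f["orientations"][()],
            timecourses=f["timecourses"][()],
            sampling_rate=float(f["sfreq"][()]),
            pseudo_z=f["pseudo_z"][()] if "pseudo_z" in f else None,
        )


def grid_map_to_nifti(grid: np.ndarray, values: np.ndarray,
                      spacing: float) -> nib.Nifti1Image:
    """Scatter per-voxel values on a regular grid into a NIfTI volume.

    The affine encodes the grid spacing (in mm, assuming grid coordinates in
    metres) and the grid origin; voxels off the grid stay zero.
    """
    grid = np.atleast_2d(grid)
    origin = grid.min(axis=0)
    idx = np.round((grid - origin) / spacing).astype(int)
    shape = idx.max(axis=0) + 1
    vol = np.zeros(shape)
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = values
    affine = np.eye(4)
    affine[:3, :3] *= spacing * 1000.0  # metres -> mm
    affine[:3, 3] = origin * 1000.0
    return nib.Nifti1Image(vol, affine)
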