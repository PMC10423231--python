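"""Plain-text and TIFF I/O for the toolkit's data objects.

Decay histograms, intensity trajectories, spectra and calibration tables are
two-column CSVs with header rows; photon-record streams are columnar CSVs
(frame, x, y, channel, microtime_ns); toy trajectories are multi-frame XYZ
with a residue-index sidecar CSV; lifetime and anisotropy images are 32-bit
float TIFFs (0 or NaN sentinels), masks integer-label TIFFs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .decay import DecayHistogram
from .fcs import IntensityTrajectory
from .pocket import Trajectory

__all__ = [
    "read_decay_csv",
    "write_decay_csv",
    "read_photon_stream",
    "write_photon_stream",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_image",
    "write_image",
]


def write_decay_csv(path: str | Path, decay: DecayHistogram) -> None:
    pd.DataFrame(
        {"time_ns": decay.bin_centers, "counts": decay.counts}
    ).to_csv(path, index=False)


def read_decay_csv(path: str | Path, channel: str = "unpolarized") -> DecayHistogram:
    df = pd.read_csv(path)
    t = df["time_ns"].to_numpy(dtype=float)
    bw = t[1] - t[0]
    edges = np.concatenate([t - bw / 2.0, [t[-1] + bw / 2.0]])
    return DecayHistogram(edges, df["counts"].to_numpy(), channel=channel)


def write_photon_stream(path: str | Path, stream: pd.DataFrame) -> None:
    stream.to_csv(path, index=False)


def read_photon_stream(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        dtype={
            "frame": np.int32,
            "x": np.int32,
            "y": np.int32,
            "channel": np.int32,
            "microtime_ns": float,
        },
    )


def write_trajectory_csv(path: str | Path, traj: IntensityTrajectory) -> None:
    pd.DataFrame({"time_s": traj.time, "counts": traj.counts}).to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> IntensityTrajectory:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    return IntensityTrajectory(df["counts"].to_numpy(), bin_time=float(t[1] - t[0]))


def write_xyz_trajectory(
    path: str | Path, coords: np.ndarray, meta: pd.DataFrame | None = None
) -> None:
    """Write a multi-frame XYZ file; optional residue sidecar CSV alongside."""
    path = Path(path)
    with open(path, "w") as fh:
        for f, frame in enumerate(coords):
            fh.write(f"{frame.shape[0]}\n")
            fh.write(f"frame {f}\n")
            for x, y, z in frame:
                fh.write(f"C {x:.6f} {y:.6f} {z:.6f}\n")
    if meta is not None:
        meta.to_csv(path.with_suffix(".residues.csv"), index=False)


def read_xyz_trajectory(path: str | Path) -> Trajectory:
    """Read a multi-frame XYZ file into a C-alpha Trajectory.

    The residue sidecar CSV (``<stem>.residues.csv``) is used for residue
    indices when present.
    """
    path = Path(path)
    frames = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        frames.append(
            np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        )
        i += 2 + n
    coords = np.stack(frames)
    sidecar = path.with_suffix(".residues.csv")
    res_idx = None
    if sidecar.exists():
        res_idx = pd.read_csv(sidecar)["residue_index"].to_numpy()
    return Trajectory.from_calpha(coords, res_idx)


def write_image(path: str | Path, image: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(image))


def read_image(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
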