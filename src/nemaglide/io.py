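"""File formats: director-field grid container, CSV exports, TIFF images.

Fields travel as a compressed binary grid container (NumPy ``.npz`` holding
single-precision angle and mask grids) with a JSON sidecar carrying the
pixel size and confinement geometry; a plain CSV export (x, y, angle, mask)
is available for interoperability. Images and stacks are 8/16-bit grayscale
TIFF via tifffile. Trajectories, defect lists and streamlines are tidy CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .defects import Defect
from .fields import DirectorField
from .sim import Trajectory

__all__ = [
    "save_field",
    "load_field",
    "field_to_csv",
    "save_image",
    "load_image",
    "trajectories_to_csv",
    "trajectories_from_csv",
    "defects_to_csv",
    "defects_from_csv",
    "streamlines_to_csv",
]


def save_field(fld: DirectorField, path) -> None:
    """Write a field as ``<path>`` (.npz) plus a ``<path>.json`` sidecar."""
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else Path(str(path) + ".npz")
    np.savez_compressed(
        npz_path,
        angle=fld.angle.astype(np.float32),
        mask=fld.mask.astype(bool),
    )
    sidecar = {
        "pixel_size_um": fld.pixel_size,
        "shape": list(fld.shape),
        "confinement_radius_um": fld.confinement_radius,
        "confinement_center_um": (
            list(fld.confinement_center) if fld.confinement_center else None
        ),
    }
    npz_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_field(path) -> DirectorField:
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    data = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    center = meta.get("confinement_center_um")
    return DirectorField(
        data["angle"].astype(float),
        meta["pixel_size_um"],
        mask=data["mask"],
        confinement_radius=meta.get("confinement_radius_um"),
        confinement_center=tuple(center) if center else None,
    )


def field_to_csv(fld: DirectorField, path) -> None:
    """Tidy CSV export: one row per node with x_um, y_um, angle_rad, mask."""
    rows, cols = fld.shape
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    pd.DataFrame(
        {
            "x_um": (jj.ravel() * fld.pixel_size),
            "y_um": (ii.ravel() * fld.pixel_size),
            "angle_rad": fld.angle.ravel(),
            "mask": fld.mask.ravel().astype(int),
        }
    ).to_csv(path, index=False)


def save_image(image: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(image))


def load_image(path) -> np.ndarray:
    return tifffile.imread(path)


def trajectories_to_csv(trajectories: list[Trajectory], path) -> None:
    frames = []
    for tr in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "particle_id": tr.particle_id,
                    "t_s": tr.t,
                    "x_um": tr.x,
                    "y_um": tr.y,
                    "theta_rad": tr.theta,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def trajectories_from_csv(path) -> list[Trajectory]:
    df = pd.read_csv(path)
    out = []
    for pid, g in df.groupby("particle_id", sort=True):
        out.append(
            Trajectory(
                g["t_s"].to_numpy(),
                g["x_um"].to_numpy(),
                g["y_um"].to_numpy(),
                g["theta_rad"].to_numpy(),
                particle_id=int(pid),
            )
        )
    return out


def defects_to_csv(defects: list[Defect], path) -> None:
    pd.DataFrame(
        {
            "x_um": [d.position[0] for d in defects],
            "y_um": [d.position[1] for d in defects],
            "charge": [d.charge for d in defects],
            "axis_x": [d.axis[0] if d.axis is not None else np.nan for d in defects],
            "axis_y": [d.axis[1] if d.axis is not None else np.nan for d in defects],
        }
    ).to_csv(path, index=False)


def defects_from_csv(path) -> list[Defect]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        axis = None
        if np.isfinite(r.get("axis_x", np.nan)):
            axis = np.array([r["axis_x"], r["axis_y"]])
        out.append(Defect(np.array([r["x_um"], r["y_um"]]), float(r["charge"]), axis))
    return out


def streamlines_to_csv(streamlines, path, summary_path=None) -> None:
    frames = []
    summary = []
    for sid, s in enumerate(streamlines):
        if len(s.points):
            frames.append(
                pd.DataFrame(
                    {
                        "streamline_id": sid,
                        "order": np.arange(len(s.points)),
                        "x_um": s.points[:, 0],
                        "y_um": s.points[:, 1],
                    }
                )
            )
        summary.append(
            {
                "streamline_id": sid,
                "event": s.event,
                "length_um": s.length,
                "seed_x_um": None if s.seed is None else s.seed.position[0],
                "seed_y_um": None if s.seed is None else s.seed.position[1],
            }
        )
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    else:
        pd.DataFrame(columns=["streamline_id", "order", "x_um", "y_um"]).to_csv(path, index=False)
    if summary_path is not None:
        Path(summary_path).write_text(json.dumps(summary, indent=2))
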