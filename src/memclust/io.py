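"""Trajectory and configuration file I/O.

The canonical interchange format is a documented column-text file
(whitespace-separated):

    # memclust trajectory v1
    # box_length_nm = <float>
    # n_inclusions = <int>
    # columns: frame time_ns inclusion_id x_nm y_nm x_unwrapped_nm y_unwrapped_nm [ox oy oz]
    0 0.0 0 1.0 2.0 1.0 2.0
    ...

A compact binary container (NumPy ``.npz``) holds the same arrays for
large runs.  An optional adapter maps MDAnalysis universes (3D MD data)
onto the membrane plane.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .core import Trajectory, min_image_displacement, wrap_positions

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "read_config",
    "write_config",
    "from_mdanalysis",
]

_TEXT_SUFFIXES = {".txt", ".dat", ".traj"}


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    if path.suffix == ".npz":
        return "npz"
    if path.suffix in _TEXT_SUFFIXES:
        return "text"
    raise ValueError(f"cannot infer trajectory format from suffix {path.suffix!r}")


def write_trajectory(traj: Trajectory, path: Union[str, Path], fmt: str = "auto") -> None:
    """Write a trajectory as column text or ``.npz``."""
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "npz":
        data = dict(
            times=traj.times,
            wrapped=traj.wrapped,
            unwrapped=traj.unwrapped,
            box_length=np.array(traj.box_length),
        )
        if traj.orientations is not None:
            data["orientations"] = traj.orientations
        np.savez_compressed(path, **data)
        return
    has_ori = traj.orientations is not None
    cols = "frame time_ns inclusion_id x_nm y_nm x_unwrapped_nm y_unwrapped_nm"
    if has_ori:
        cols += " ox oy oz"
    with open(path, "w") as fh:
        fh.write("# memclust trajectory v1\n")
        fh.write(f"# box_length_nm = {float(traj.box_length)!r}\n")
        fh.write(f"# n_inclusions = {traj.n}\n")
        fh.write(f"# columns: {cols}\n")
        for f in range(traj.n_frames):
            t = float(traj.times[f])
            for i in range(traj.n):
                row = (
                    f"{f} {t!r} {i} "
                    f"{float(traj.wrapped[f, i, 0])!r} {float(traj.wrapped[f, i, 1])!r} "
                    f"{float(traj.unwrapped[f, i, 0])!r} {float(traj.unwrapped[f, i, 1])!r}"
                )
                if has_ori:
                    o = traj.orientations[f, i]
                    row += f" {float(o[0])!r} {float(o[1])!r} {float(o[2])!r}"
                fh.write(row + "\n")


def read_trajectory(path: Union[str, Path], fmt: str = "auto") -> Trajectory:
    """Read a trajectory, validating shape and wrapped/unwrapped consistency."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, fmt)
    if fmt == "npz":
        with np.load(path) as data:
            return Trajectory(
                times=data["times"],
                wrapped=data["wrapped"],
                unwrapped=data["unwrapped"],
                box_length=float(data["box_length"]),
                orientations=data["orientations"] if "orientations" in data else None,
            )
    return _read_text(path)


def _read_text(path: Path) -> Trajectory:
    box_length: Optional[float] = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "box_length_nm" in line and "=" in line:
                    box_length = float(line.split("=", 1)[1])
                continue
            parts = line.split()
            if len(parts) not in (7, 10):
                raise ValueError(
                    f"{path}:{lineno}: expected 7 or 10 columns, got {len(parts)}"
                )
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed number: {exc}") from None
            rows.append(vals)
    if box_length is None:
        raise ValueError(f"{path}: missing '# box_length_nm = ...' header")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array(rows)
    has_ori = arr.shape[1] == 10
    frames = arr[:, 0].astype(int)
    frame_ids, counts = np.unique(frames, return_counts=True)
    if np.any(counts != counts[0]):
        bad = int(frame_ids[np.argmax(counts != counts[0])])
        raise ValueError(
            f"{path}: inconsistent inclusion count across frames (first bad frame {bad})"
        )
    n = int(counts[0])
    n_frames = len(frame_ids)
    order = np.lexsort((arr[:, 2], arr[:, 0]))
    arr = arr[order]
    times = arr[:: n, 1].copy()
    wrapped = arr[:, 3:5].reshape(n_frames, n, 2)
    unwrapped = arr[:, 5:7].reshape(n_frames, n, 2)
    orientations = arr[:, 7:10].reshape(n_frames, n, 3) if has_ori else None
    return Trajectory(
        times=times,
        wrapped=wrapped,
        unwrapped=unwrapped,
        box_length=box_length,
        orientations=orientations,
    )


def read_config(path: Union[str, Path]) -> dict:
    """Read a YAML config file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_config(cfg: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def from_mdanalysis(
    universe,
    groups: Sequence,
    plane: str = "xy",
) -> Trajectory:
    """Build a 2D membrane-plane trajectory from an MDAnalysis universe.

    ``groups`` is one AtomGroup per inclusion; each frame records the
    in-plane projection of the group centers of mass.  Coordinates are
    wrapped into [0, L) using the lateral box dimension, and unwrapped by
    accumulating minimum-image frame-to-frame displacements (valid when no
    inclusion moves more than half a box per frame).  MDAnalysis lengths
    (Å) are converted to nm.

    Requires MDAnalysis (optional dependency).
    """
    axes = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}
    if plane not in axes:
        raise ValueError("plane must be one of 'xy', 'xz', 'yz'")
    ax = axes[plane]
    times = []
    coords = []
    box_length = None
    for ts in universe.trajectory:
        dims = ts.dimensions
        lat = [dims[ax[0]], dims[ax[1]]]
        if abs(lat[0] - lat[1]) > 1e-3:
            raise ValueError("non-square lateral box not supported")
        box_length = lat[0] / 10.0  # A -> nm
        times.append(ts.time / 1000.0)  # ps -> ns
        frame = np.array([g.center_of_mass()[list(ax)] for g in groups]) / 10.0
        coords.append(frame)
    if not coords:
        raise ValueError("universe has no frames")
    raw = np.array(coords)
    wrapped = wrap_positions(raw, box_length)
    unwrapped = np.empty_like(wrapped)
    unwrapped[0] = wrapped[0]
    for f in range(1, len(wrapped)):
        step = min_image_displacement(wrapped[f] - wrapped[f - 1], box_length)
        unwrapped[f] = unwrapped[f - 1] + step
    return Trajectory(
        times=np.array(times),
        wrapped=wrapped,
        unwrapped=unwrapped,
        box_length=float(box_length),
    )
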