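"""On-disk formats: PNG frame stacks, 16-bit label masks, CSV tables,
JSON manifests.

Video frames are written as zero-padded grayscale PNGs (AVI input is read
through imageio when a decoder is available).  Ethograms and centerlines
use the same CSV schemas for manual annotations and automated output, so a
manually scored file can stand in anywhere the pipeline expects labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd


def write_frame_stack(frames: np.ndarray, directory: str | Path,
                      prefix: str = "frame") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = directory / f"{prefix}_{i:06d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def read_frame_stack(source: str | Path) -> np.ndarray:
    """Read a directory of numbered PNGs or a single video file."""
    source = Path(source)
    if source.is_dir():
        files = sorted(source.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames under {source}")
        return np.stack([iio.imread(f) for f in files])
    return np.asarray(iio.imread(source))


def write_label_masks(labels: np.ndarray, directory: str | Path) -> list[Path]:
    return write_frame_stack(labels.astype(np.uint16), directory, prefix="labels")


def write_ethogram_csv(labels: pd.Series, path: str | Path) -> Path:
    """Columns (track_id, frame, behavior) with behavior in {-1, 0, 1}."""
    path = Path(path)
    df = labels.rename("behavior").reset_index()
    df.columns = ["track_id", "frame", "behavior"]
    df.to_csv(path, index=False)
    return path


def read_ethogram_csv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path)
    return pd.Series(df["behavior"].to_numpy(dtype=int),
                     index=pd.MultiIndex.from_arrays(
                         [df["track_id"], df["frame"]],
                         names=["track_id", "frame"]))


def write_centerlines_csv(centerlines: dict[tuple[int, int], np.ndarray],
                          path: str | Path) -> Path:
    """Rows (track_id, frame, point_index, x_um, y_um)."""
    rows = []
    for (tid, frame), pts in centerlines.items():
        for i, (x, y) in enumerate(pts):
            rows.append((tid, frame, i, x, y))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "point_index",
                                     "x_um", "y_um"])
    df.to_csv(path, index=False)
    return Path(path)


def read_centerlines_csv(path: str | Path) -> dict[tuple[int, int], np.ndarray]:
    df = pd.read_csv(path)
    out = {}
    for (tid, frame), block in df.groupby(["track_id", "frame"]):
        block = block.sort_values("point_index")
        out[(int(tid), int(frame))] = block[["x_um", "y_um"]].to_numpy()
    return out


def write_manifest(path: str | Path, seed: int, artifacts: dict[str, str],
                   extra: dict | None = None) -> Path:
    from . import __version__

    payload = {"seed": seed, "version": __version__, "artifacts": artifacts}
    if extra:
        payload.update(extra)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
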