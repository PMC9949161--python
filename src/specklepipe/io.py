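"""Reading and writing of movies, fingerprints, traces, shift tables and
configs (TIFF / CSV / JSON / YAML)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .demix import ActivitySet, FingerprintSet
from .preprocess import SpeckleMovie


def write_movie(path: str | Path, movie: SpeckleMovie) -> None:
    tifffile.imwrite(
        str(path),
        movie.frames.astype(np.float32),
        photometric="minisblack",
        metadata={
            "pixel_pitch_um": movie.pixel_pitch_um,
            "frame_period_s": movie.frame_period_s,
        },
    )


def read_movie(path: str | Path, pixel_pitch_um: float = 1.0, frame_period_s: float = 1.0) -> SpeckleMovie:
    frames = np.asarray(tifffile.imread(str(path)), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    return SpeckleMovie(frames=frames, pixel_pitch_um=pixel_pitch_um, frame_period_s=frame_period_s)


def write_fingerprints(path: str | Path, fingerprints: FingerprintSet) -> None:
    tifffile.imwrite(str(path), fingerprints.patterns.astype(np.float32), photometric="minisblack")


def read_fingerprints(path: str | Path) -> FingerprintSet:
    pats = np.asarray(tifffile.imread(str(path)), dtype=float)
    if pats.ndim == 2:
        pats = pats[None]
    return FingerprintSet(patterns=np.clip(pats, 0.0, None))


def write_traces(path: str | Path, activities: ActivitySet) -> None:
    df = pd.DataFrame(activities.traces)
    df.index.name = "source_id"
    df.to_csv(path)


def read_traces(path: str | Path) -> ActivitySet:
    df = pd.read_csv(path, index_col=0)
    return ActivitySet(traces=df.to_numpy(dtype=float))


def write_positions(path: str | Path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def write_yaml(path: str | Path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
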