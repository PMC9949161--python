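"""Movie conditioning: background-envelope removal and contrast metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["SpeckleMovie", "highpass_frame", "highpass_movie", "movie_contrast"]


@dataclass
class SpeckleMovie:
    """Intensity frame stack I(t, y, x), nonnegative."""

    frames: np.ndarray  # (T, H, W)
    pixel_pitch_um: float = 1.0
    frame_period_s: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("movie must be (T, H, W) with T >= 2")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def as_matrix(self) -> np.ndarray:
        """Pixels-by-frames matrix (row-major pixel flattening)."""
        t = self.frames.shape[0]
        return self.frames.reshape(t, -1).T


def highpass_frame(frame: np.ndarray, sigma_px: float, mode: str = "clip") -> np.ndarray:
    """Unsharp-mask high-pass: frame minus its Gaussian blur.

    Removes the slowly varying fluorescence envelope while keeping
    grain-scale speckle structure.  Negative values are handled per ``mode``:
    ``clip`` (set to 0, default), ``offset`` (shift so the minimum is 0) or
    ``none`` (leave signed; callers must restore nonnegativity before NMF).
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite pixels")
    hp = frame - gaussian_filter(frame, sigma_px)
    if mode == "clip":
        return np.clip(hp, 0.0, None)
    if mode == "offset":
        return hp - min(hp.min(), 0.0)
    if mode == "none":
        return hp
    raise ValueError(f"unknown mode {mode!r}")


def highpass_movie(movie: SpeckleMovie, sigma_px: float, mode: str = "clip") -> SpeckleMovie:
    """Apply :func:`highpass_frame` to every frame."""
    out = np.stack([highpass_frame(f, sigma_px, mode) for f in movie.frames])
    return SpeckleMovie(out, movie.pixel_pitch_um, movie.frame_period_s)


def movie_contrast(movie: SpeckleMovie) -> np.ndarray:
    """Per-frame speckle contrast, std/mean over pixels."""
    means = movie.frames.mean(axis=(1, 2))
    if np.any(means == 0):
        raise ValueError("contrast undefined for zero-mean frames")
    return movie.frames.std(axis=(1, 2)) / means
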