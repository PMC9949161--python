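"""Synthetic speckle-movie generation with ground truth.

Builds movies with the statistical structure the inverse pipeline assumes:
each point emitter casts a fixed speckle fingerprint on the sensor, nearby
emitters cast laterally shifted copies of the same pattern (memory effect),
distant emitters cast uncorrelated patterns, and every frame is the
nonnegative, incoherent superposition of fingerprints weighted by the
emitters' temporal activity, optionally on top of a temporally constant
out-of-focus background speckle plus shot and read noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.fft import fft2, ifft2
from scipy.ndimage import fourier_shift
from scipy.signal import lfilter

from .demix import ActivitySet, FingerprintSet
from .preprocess import SpeckleMovie

__all__ = [
    "EmitterEnsemble",
    "ScatterModel",
    "TraceModel",
    "BackgroundModel",
    "NoiseModel",
    "GroundTruth",
    "generate_master_speckle",
    "fingerprint_for_emitter",
    "shifted_master_pattern",
    "generate_traces",
    "generate_background",
    "simulate_ground_truth",
    "assemble_movie",
    "measure_sbr",
    "measure_sbr_per_source",
    "place_emitters_disk",
    "place_emitters_chain",
]

# Seed-derivation domain tags. Sub-seeds are SeedSequence([seed, tag, index]):
# a counter scheme, so adding an emitter never reshuffles the streams of the
# existing ones.
_TAG_TRACE = 0x7ACE
_TAG_BG = 0xB6
_TAG_NOISE = 0x401E


class ConfigurationError(ValueError):
    """Invalid model parameters."""


class DataError(ValueError):
    """Inconsistent array shapes or values."""


# ---------------------------------------------------------------------------
# Model types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmitterEnsemble:
    """Point emitters in the object plane.

    positions are (x, y) in micrometers; ``pixel_pitch_um`` converts lateral
    object-plane displacements into camera-pixel shifts of the fingerprints.
    """

    positions: tuple[tuple[float, float], ...]
    pixel_pitch_um: float = 1.0

    def __post_init__(self) -> None:
        pos = tuple((float(x), float(y)) for x, y in self.positions)
        object.__setattr__(self, "positions", pos)
        if len(pos) < 1:
            raise ConfigurationError("need at least one emitter")
        arr = np.asarray(pos, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ConfigurationError("emitter positions must be finite")
        if len({p for p in pos}) != len(pos):
            raise ConfigurationError("emitter positions must be distinct")
        if self.pixel_pitch_um <= 0:
            raise ConfigurationError("pixel_pitch_um must be positive")

    @property
    def n_sources(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class ScatterModel:
    """Phenomenological scattering model.

    ``me_range_um`` is the lateral displacement at which the correlation of a
    fingerprint with the shifted master pattern drops to exp(-1); the decay
    law is Gaussian, ``alpha(d) = exp(-(d / me_range_um)**2)``.
    """

    me_range_um: float = 75.0
    speckle_grain_px: float = 3.0
    frame_shape: tuple[int, int] = (128, 128)
    master_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame_shape", tuple(int(v) for v in self.frame_shape))
        if self.me_range_um <= 0:
            raise ConfigurationError("me_range_um must be positive")
        if self.speckle_grain_px < 2:
            raise ConfigurationError("speckle_grain_px must be >= 2")
        if len(self.frame_shape) != 2 or min(self.frame_shape) < 64:
            raise ConfigurationError("frame_shape must be 2-D with dims >= 64")


@dataclass(frozen=True)
class TraceModel:
    """Calcium-indicator-like activity: Poisson spike train convolved with an
    exponential decay kernel, on a nonnegative baseline."""

    n_frames: int = 500
    spike_rate_per_frame: float = 0.02
    decay_frames: float = 10.0
    baseline: float = 0.05
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        if self.spike_rate_per_frame < 0:
            raise ConfigurationError("spike_rate_per_frame must be >= 0")
        if self.decay_frames <= 0:
            raise ConfigurationError("decay_frames must be positive")
        if self.baseline < 0 or self.amplitude < 0:
            raise ConfigurationError("baseline and amplitude must be >= 0")


@dataclass(frozen=True)
class BackgroundModel:
    """Temporally constant out-of-focus background speckle.

    ``sbr`` is the target signal-to-background energy ratio (time-averaged
    total signal energy over total background energy per frame).  ``n_modes``
    independent speckle realizations are averaged, so the background contrast
    is ~1/sqrt(n_modes): mostly a smooth envelope with weak residual grain,
    as out-of-focus fluorescence produces.
    """

    sbr: float = math.inf
    bg_seed: int = 0
    n_modes: int = 64

    def __post_init__(self) -> None:
        if not self.sbr > 0:
            raise ConfigurationError("sbr must be > 0 (inf disables background)")
        if self.n_modes < 1:
            raise ConfigurationError("n_modes must be >= 1")

    @property
    def enabled(self) -> bool:
        return math.isfinite(self.sbr)


@dataclass(frozen=True)
class NoiseModel:
    """Shot + read noise. ``photon_budget`` is the expected number of photons
    per frame summed over pixels (None disables Poisson sampling);
    ``read_noise_sd`` is Gaussian, in the movie's intensity units."""

    photon_budget: float | None = None
    read_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.photon_budget is not None and self.photon_budget <= 0:
            raise ConfigurationError("photon_budget must be positive or None")
        if self.read_noise_sd < 0:
            raise ConfigurationError("read_noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Generator-side truth: fingerprints W, traces H, per-source pixel shifts
    relative to source 0, and the constant background frame (zeros if off)."""

    fingerprints: FingerprintSet
    traces: ActivitySet
    positions_px: np.ndarray  # (N, 2) (row, col) shifts relative to source 0
    background_frame: np.ndarray
    ensemble: EmitterEnsemble | None = None
    scatter: ScatterModel | None = None

    def __post_init__(self) -> None:
        n = self.fingerprints.patterns.shape[0]
        if self.traces.traces.shape[0] != n or self.positions_px.shape != (n, 2):
            raise DataError("ground-truth shapes are inconsistent")
        if self.background_frame.shape != self.fingerprints.patterns.shape[1:]:
            raise DataError("background frame shape mismatch")
        if (
            np.any(self.fingerprints.patterns < 0)
            or np.any(self.traces.traces < 0)
            or np.any(self.background_frame < 0)
        ):
            raise DataError("ground truth must be nonnegative")

    @property
    def n_sources(self) -> int:
        return self.fingerprints.patterns.shape[0]


# ---------------------------------------------------------------------------
# Speckle synthesis
# ---------------------------------------------------------------------------

# Fields are synthesized on a canvas padded to 2x the frame so that lateral
# shifts are genuine translations of one realization (no wrap-around inside
# the cropped frame for |shift| < frame/2).
#
# Memory-effect decorrelation is stationary in emitter space: the complex
# field of an emitter at object-plane position p is a Gaussian-weighted
# mixture of independent speckle "modes" anchored on a fixed grid in p,
# translated laterally by p (in camera pixels).  Two emitters then share
# mode content according to their separation only, so the intensity
# correlation of any fingerprint pair is alpha(d) = exp(-(d/R)^2) with
# d = |p_i - p_j|, independent of where the pair sits.  The field
# correlation is exp(-d^2/(4 sigma^2)) and the intensity correlation its
# square (circular Gaussian fields), so sigma = R/sqrt(2) yields the target
# intensity kernel; grid spacing <= sigma makes the discrete sum match the
# continuous kernel to ~1e-9 (Poisson summation).

_MODE_SIGMA_FRAC = 1.0 / math.sqrt(2.0)  # envelope sigma / me_range_um
_MODE_SPACING_FRAC = 0.5  # mode grid spacing as a fraction of me_range_um
_MODE_CUTOFF_SIGMAS = 3.0

_TAG_MODE = 0x40DE
_field_cache: dict[tuple, np.ndarray] = {}


def _canvas_shape(frame_shape: tuple[int, int]) -> tuple[int, int]:
    return (2 * frame_shape[0], 2 * frame_shape[1])


def _speckle_field(shape: tuple[int, int], grain_px: float, seed_seq: np.random.SeedSequence) -> np.ndarray:
    """Complex circular-Gaussian speckle field: uniform random phase on a
    circular pupil in Fourier space, inverse transformed.  Mean intensity 1."""
    rng = np.random.default_rng(seed_seq)
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None] * h
    fx = np.fft.fftfreq(w)[None, :] * w
    ry = h / (2.0 * grain_px)
    rx = w / (2.0 * grain_px)
    pupil = (fy / ry) ** 2 + (fx / rx) ** 2 <= 1.0
    phase = rng.uniform(0.0, 2.0 * np.pi, size=shape)
    spectrum = np.where(pupil, np.exp(1j * phase), 0.0)
    fld = ifft2(spectrum)
    fld /= np.sqrt(np.mean(np.abs(fld) ** 2))
    return fld


def _mode_field(model: ScatterModel, seed: int, ab: tuple[int, int]) -> np.ndarray:
    """Independent unit-power speckle field of mode (a, b), cached."""
    key = (int(seed), model.frame_shape, float(model.speckle_grain_px), ab)
    fld = _field_cache.get(key)
    if fld is None:
        seq = np.random.SeedSequence(
            [int(seed), _TAG_MODE, ab[0] + 2**31, ab[1] + 2**31]
        )
        fld = _speckle_field(_canvas_shape(model.frame_shape), model.speckle_grain_px, seq)
        if len(_field_cache) > 128:
            _field_cache.clear()
        _field_cache[key] = fld
    return fld


def _mixture_field(model: ScatterModel, seed: int, position: tuple[float, float]) -> np.ndarray:
    """Complex field of an emitter at ``position`` (um), before the lateral
    memory-effect shift: Gaussian-weighted sum of mode fields, unit power."""
    sigma = model.me_range_um * _MODE_SIGMA_FRAC
    spacing = model.me_range_um * _MODE_SPACING_FRAC
    cutoff = _MODE_CUTOFF_SIGMAS * sigma
    x, y = float(position[0]), float(position[1])
    a_lo = math.floor((x - cutoff) / spacing)
    a_hi = math.ceil((x + cutoff) / spacing)
    b_lo = math.floor((y - cutoff) / spacing)
    b_hi = math.ceil((y + cutoff) / spacing)
    weights: list[tuple[float, tuple[int, int]]] = []
    for a in range(a_lo, a_hi + 1):
        for b in range(b_lo, b_hi + 1):
            d2 = (a * spacing - x) ** 2 + (b * spacing - y) ** 2
            if d2 <= cutoff**2:
                weights.append((math.exp(-d2 / (2.0 * sigma**2)), (a, b)))
    norm = math.sqrt(sum(w * w for w, _ in weights))
    acc = np.zeros(_canvas_shape(model.frame_shape), dtype=complex)
    for w, ab in weights:
        acc += (w / norm) * _mode_field(model, seed, ab)
    return acc


def _crop_center(canvas: np.ndarray, frame_shape: tuple[int, int]) -> np.ndarray:
    h, w = frame_shape
    r0 = (canvas.shape[0] - h) // 2
    c0 = (canvas.shape[1] - w) // 2
    return canvas[r0 : r0 + h, c0 : c0 + w]


def generate_master_speckle(model: ScatterModel, seed: int) -> np.ndarray:
    """One fully developed speckle intensity pattern (contrast ~= 1): the
    fingerprint of an emitter at the origin.  Frame shaped, mean normalized
    to 1, deterministic given (model, seed)."""
    fld = _mixture_field(model, seed, (0.0, 0.0))
    img = np.abs(_crop_center(fld, model.frame_shape)) ** 2
    return img / img.mean()


def _shifted_field(fld: np.ndarray, shift_rc: tuple[float, float]) -> np.ndarray:
    if shift_rc == (0.0, 0.0):
        return fld
    return ifft2(fourier_shift(fft2(fld), shift_rc))


def _px_shift(
    position: tuple[float, float], reference: tuple[float, float], pixel_pitch_um: float
) -> tuple[float, float]:
    """(row, col) pixel shift of the fingerprint, (dy, dx)/pitch."""
    return (
        (position[1] - reference[1]) / pixel_pitch_um,
        (position[0] - reference[0]) / pixel_pitch_um,
    )


def fingerprint_for_emitter(
    master_field_seed: int,
    model: ScatterModel,
    position: tuple[float, float],
    reference: tuple[float, float],
    pixel_pitch_um: float = 1.0,
) -> np.ndarray:
    """Speckle fingerprint of an emitter at ``position`` (um).

    Equals the reference emitter's pattern translated by
    ``(position - reference) / pixel_pitch`` pixels, progressively blended
    with independent speckle content so that its intensity correlation with
    the shifted reference pattern is ``alpha(d) = exp(-(d/me_range_um)**2)``
    at separation ``d`` -- and likewise between any pair of fingerprints of
    the same master seed.  Mean intensity 1.
    """
    fld = _mixture_field(model, master_field_seed, position)
    shifted = _shifted_field(fld, _px_shift(position, reference, pixel_pitch_um))
    img = np.abs(_crop_center(shifted, model.frame_shape)) ** 2
    return img / img.mean()


def shifted_master_pattern(
    master_field_seed: int,
    model: ScatterModel,
    position: tuple[float, float],
    reference: tuple[float, float],
    pixel_pitch_um: float = 1.0,
) -> np.ndarray:
    """Oracle helper: the reference emitter's pattern translated to
    ``position`` WITHOUT memory-effect decorrelation (what a fingerprint at
    ``position`` would look like for an infinite memory-effect range)."""
    fld = _mixture_field(model, master_field_seed, reference)
    shifted = _shifted_field(fld, _px_shift(position, reference, pixel_pitch_um))
    img = np.abs(_crop_center(shifted, model.frame_shape)) ** 2
    return img / img.mean()


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------


def generate_traces(model: TraceModel, n_sources: int, seed: int) -> ActivitySet:
    """Independent per-source traces: baseline + amplitude * (Poisson spike
    train convolved with exp(-t/tau))."""
    if n_sources < 1:
        raise ConfigurationError("n_sources must be >= 1")
    decay = math.exp(-1.0 / model.decay_frames)
    traces = np.empty((n_sources, model.n_frames), dtype=float)
    for s in range(n_sources):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), _TAG_TRACE, s]))
        spikes = rng.poisson(model.spike_rate_per_frame, size=model.n_frames).astype(float)
        conv = lfilter([1.0], [1.0, -decay], spikes)
        traces[s] = model.baseline + model.amplitude * conv
    return ActivitySet(traces=traces)


# ---------------------------------------------------------------------------
# Background and assembly
# ---------------------------------------------------------------------------


def _signal_energy_per_frame(fingerprints: FingerprintSet, traces: ActivitySet) -> float:
    """Time-averaged total signal intensity summed over pixels."""
    per_source_sum = fingerprints.patterns.sum(axis=(1, 2))
    mean_activity = traces.traces.mean(axis=1)
    return float(per_source_sum @ mean_activity)


def generate_background(
    model: BackgroundModel,
    scatter: ScatterModel,
    signal_energy_per_frame: float,
) -> np.ndarray:
    """Constant low-contrast background speckle scaled to the target SBR."""
    if not model.enabled:
        return np.zeros(scatter.frame_shape)
    acc = np.zeros(scatter.frame_shape)
    for m in range(model.n_modes):
        fld = _speckle_field(
            scatter.frame_shape,
            scatter.speckle_grain_px,
            np.random.SeedSequence([int(model.bg_seed), _TAG_BG, m]),
        )
        acc += np.abs(fld) ** 2
    acc /= model.n_modes
    target_total = signal_energy_per_frame / model.sbr
    return acc * (target_total / acc.sum())


def simulate_ground_truth(
    ensemble: EmitterEnsemble,
    scatter: ScatterModel,
    trace_model: TraceModel,
    background: BackgroundModel | None = None,
) -> GroundTruth:
    """Generate fingerprints, traces, pixel shifts and background for an
    emitter ensemble.  Fully deterministic given the model seeds."""
    ref = ensemble.positions[0]
    pitch = ensemble.pixel_pitch_um
    pats = np.stack(
        [
            fingerprint_for_emitter(scatter.master_seed, scatter, p, ref, pitch)
            for p in ensemble.positions
        ]
    )
    positions_px = np.array(
        [[(p[1] - ref[1]) / pitch, (p[0] - ref[0]) / pitch] for p in ensemble.positions]
    )  # (row, col) = (dy, dx)
    traces = generate_traces(trace_model, ensemble.n_sources, scatter.master_seed)
    fset = FingerprintSet(patterns=pats, normalization="mean1")
    if background is None:
        background = BackgroundModel()
    bg = generate_background(background, scatter, _signal_energy_per_frame(fset, traces))
    return GroundTruth(
        fingerprints=fset,
        traces=traces,
        positions_px=positions_px,
        background_frame=bg,
        ensemble=ensemble,
        scatter=scatter,
    )


def assemble_movie(
    gt: GroundTruth,
    noise: NoiseModel | None = None,
    seed: int = 0,
    frame_period_s: float = 0.5,
) -> SpeckleMovie:
    """Forward model: frame k = sum_s w_s * h_s[k] + background, then Poisson
    shot noise at the photon budget and Gaussian read noise, clipped at 0.

    With noise and background disabled the movie is exactly W @ H reshaped.
    """
    noise = noise or NoiseModel()
    w = gt.fingerprints.patterns
    h = gt.traces.traces
    clean = np.einsum("sij,st->tij", w, h, optimize=True)
    if gt.background_frame.any():
        clean = clean + gt.background_frame[None]
    movie = clean
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _TAG_NOISE]))
    if noise.photon_budget is not None:
        scale = noise.photon_budget / max(clean.sum(axis=(1, 2)).mean(), 1e-300)
        movie = rng.poisson(clean * scale).astype(float) / scale
    if noise.read_noise_sd > 0:
        movie = movie + rng.normal(0.0, noise.read_noise_sd, size=movie.shape)
    movie = np.clip(movie, 0.0, None)
    pitch = gt.ensemble.pixel_pitch_um if gt.ensemble is not None else 1.0
    return SpeckleMovie(frames=movie, pixel_pitch_um=pitch, frame_period_s=frame_period_s)


# ---------------------------------------------------------------------------
# SBR readouts
# ---------------------------------------------------------------------------


def measure_sbr(gt: GroundTruth) -> float:
    """Total-signal over total-background energy ratio.

    Numerator: time-averaged total signal intensity summed over pixels
    (all sources); denominator: background intensity summed over pixels.
    """
    bg_total = float(gt.background_frame.sum())
    if bg_total <= 0:
        raise DataError("background absent: SBR undefined")
    return _signal_energy_per_frame(gt.fingerprints, gt.traces) / bg_total


def measure_sbr_per_source(gt: GroundTruth) -> np.ndarray:
    """Secondary readout: per-source energy over total background energy."""
    bg_total = float(gt.background_frame.sum())
    if bg_total <= 0:
        raise DataError("background absent: SBR undefined")
    per_source = gt.fingerprints.patterns.sum(axis=(1, 2)) * gt.traces.traces.mean(axis=1)
    return per_source / bg_total


# ---------------------------------------------------------------------------
# Emitter placement helpers
# ---------------------------------------------------------------------------


def place_emitters_disk(
    n: int,
    diameter_um: float,
    min_spacing_um: float,
    seed: int,
    center: tuple[float, float] = (0.0, 0.0),
    max_tries: int = 20000,
) -> tuple[tuple[float, float], ...]:
    """Rejection-sample ``n`` positions inside a disk with pairwise minimum
    spacing.  Raises if the packing does not fit."""
    rng = np.random.default_rng(seed)
    r = diameter_um / 2.0
    pts: list[tuple[float, float]] = []
    for _ in range(max_tries):
        u = rng.uniform(0, 1)
        theta = rng.uniform(0, 2 * np.pi)
        x = center[0] + r * math.sqrt(u) * math.cos(theta)
        y = center[1] + r * math.sqrt(u) * math.sin(theta)
        if all(math.hypot(x - px, y - py) >= min_spacing_um for px, py in pts):
            pts.append((x, y))
            if len(pts) == n:
                return tuple(pts)
    raise ConfigurationError(
        f"could not place {n} emitters with spacing {min_spacing_um} in diameter {diameter_um}"
    )


def place_emitters_chain(
    n: int,
    step_um: float,
    seed: int,
    jitter: float = 0.25,
) -> tuple[tuple[float, float], ...]:
    """Random near-linear chain with consecutive spacing ~ ``step_um``; useful
    for ensembles that span beyond the memory-effect range while keeping
    nearest-neighbor distances short."""
    rng = np.random.default_rng(seed)
    pts = [(0.0, 0.0)]
    heading = rng.uniform(0, 2 * np.pi)
    for _ in range(n - 1):
        heading += rng.uniform(-jitter, jitter)
        step = step_um * rng.uniform(0.9, 1.1)
        x = pts[-1][0] + step * math.cos(heading)
        y = pts[-1][1] + step * math.sin(heading)
        pts.append((x, y))
    # center the chain on the origin so fingerprint shifts stay in-frame
    cx = sum(p[0] for p in pts) / n
    cy = sum(p[1] for p in pts) / n
    return tuple((x - cx, y - cy) for x, y in pts)
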