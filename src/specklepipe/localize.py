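"""Emitter localization from demixed speckle fingerprints.

Within the memory-effect range, two fingerprints are laterally shifted
copies of (nearly) the same speckle pattern, so the regularized Wiener
deconvolution of one by the other is a delta-like peak offset from the image
center by their relative shift; uncorrelated fingerprints give a flat
noise-like image instead.  Pairwise shifts with a confident peak form a
graph whose edges are synchronized by weighted least squares into global
positions, which remains valid when the ensemble spans several
memory-effect ranges as long as nearest neighbors stay within one.

Sign convention (fixed and tested): if ``w_j`` equals ``w_i`` translated by
``delta`` pixels, ``deconvolve_pair(w_i, w_j)`` peaks ``delta`` away from
the center, i.e. the measured shift for pair (i, j) is ``p_j - p_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from numpy.fft import fft2, fftshift, ifft2
from scipy.ndimage import shift as nd_shift
from scipy.signal.windows import tukey

from .demix import FingerprintSet

__all__ = [
    "ShiftMeasurement",
    "ShiftGraph",
    "LocationMap",
    "deconvolve_pair",
    "extract_peak",
    "measure_shift",
    "build_shift_graph",
    "build_partial_map",
    "solve_global_positions",
    "render_map",
    "localize_fingerprints",
]

DEFAULT_BALANCE = 0.1
DEFAULT_CONFIDENCE_THRESHOLD = 5.0


@dataclass(frozen=True)
class ShiftMeasurement:
    i: int
    j: int
    shift: tuple[float, float]  # (row, col), estimate of p_j - p_i
    peak_amplitude: float
    noise_floor: float
    confidence: float
    correlated: bool


@dataclass
class ShiftGraph:
    """Pairwise shift measurements; edges are the correlated pairs.

    ``graph`` is undirected; each edge (i, j) with i < j stores the
    antisymmetrized shift from i to j and the lower of the two directional
    confidences.  ``measurements`` keeps every directional measurement."""

    graph: nx.Graph
    measurements: list[ShiftMeasurement] = field(default_factory=list)

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)


@dataclass
class LocationMap:
    """Stitched map: accumulated shifted partial maps plus the discrete
    position list (pixels, relative to the reference source)."""

    map_image: np.ndarray
    positions_px: dict[int, tuple[float, float]]
    reference_id: int
    unplaced: list[int] = field(default_factory=list)
    residual_px: float = 0.0


def _apodize(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    w = w - w.mean()
    wy = tukey(w.shape[0], 0.25)
    wx = tukey(w.shape[1], 0.25)
    return w * np.outer(wy, wx)


def deconvolve_pair(w_i: np.ndarray, w_j: np.ndarray, balance: float = DEFAULT_BALANCE) -> np.ndarray:
    """Wiener deconvolution of fingerprint j by fingerprint i.

    Both inputs are mean-subtracted and Tukey-apodized, then
    ``conj(F_i) * F_j / (|F_i|^2 + balance * mean|F_i|^2)`` is inverted;
    the result is centered with fftshift so a zero shift peaks at
    ``(H//2, W//2)``.
    """
    if w_i.shape != w_j.shape:
        raise ValueError("fingerprints must have equal shapes")
    a = _apodize(w_i)
    b = _apodize(w_j)
    if not (a.any() and b.any()):
        raise ValueError("all-zero fingerprint")
    fa = fft2(a)
    fb = fft2(b)
    pa = np.abs(fa) ** 2
    d = np.real(ifft2(np.conj(fa) * fb / (pa + balance * pa.mean())))
    return fftshift(d)


def extract_peak(
    decon_image: np.ndarray,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    exclude_radius: int = 5,
    subpixel: bool = False,
) -> tuple[tuple[float, float], float, float, float, bool]:
    """Locate the dominant peak and rate it against the noise floor.

    Returns ``(shift, peak_amplitude, noise_floor, confidence, correlated)``
    with shift = argmax - center.  The noise floor is median + 3*MAD of the
    image excluding a window around the peak.
    """
    img = np.asarray(decon_image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("non-finite deconvolution image")
    r, c = np.unravel_index(np.argmax(img), img.shape)
    peak = float(img[r, c])
    mask = np.ones(img.shape, dtype=bool)
    r0, r1 = max(r - exclude_radius, 0), min(r + exclude_radius + 1, img.shape[0])
    c0, c1 = max(c - exclude_radius, 0), min(c + exclude_radius + 1, img.shape[1])
    mask[r0:r1, c0:c1] = False
    rest = img[mask]
    med = float(np.median(rest))
    mad = float(np.median(np.abs(rest - med)))
    floor = med + 3.0 * mad
    confidence = peak / floor if floor > 0 else np.inf
    rr, cc = float(r), float(c)
    if subpixel:
        rr += _parabolic_offset(img, r, c, axis=0)
        cc += _parabolic_offset(img, r, c, axis=1)
    center = (img.shape[0] // 2, img.shape[1] // 2)
    shift = (rr - center[0], cc - center[1])
    return shift, peak, floor, float(confidence), bool(confidence > confidence_threshold)


def _parabolic_offset(img: np.ndarray, r: int, c: int, axis: int) -> float:
    idx = r if axis == 0 else c
    n = img.shape[axis]
    if idx == 0 or idx == n - 1:
        return 0.0
    if axis == 0:
        y0, y1, y2 = img[r - 1, c], img[r, c], img[r + 1, c]
    else:
        y0, y1, y2 = img[r, c - 1], img[r, c], img[r, c + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return 0.0
    return float(0.5 * (y0 - y2) / denom)


def measure_shift(
    fingerprints: FingerprintSet,
    i: int,
    j: int,
    balance: float = DEFAULT_BALANCE,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    subpixel: bool = False,
) -> ShiftMeasurement:
    d = deconvolve_pair(fingerprints.patterns[i], fingerprints.patterns[j], balance)
    shift, peak, floor, conf, correlated = extract_peak(
        d, confidence_threshold=confidence_threshold, subpixel=subpixel
    )
    return ShiftMeasurement(i, j, shift, peak, floor, conf, correlated)


def build_shift_graph(
    fingerprints: FingerprintSet,
    balance: float = DEFAULT_BALANCE,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    antisymmetry_tol_px: float = 1.5,
    subpixel: bool = False,
) -> ShiftGraph:
    """Measure all ordered pairs and keep edges where both directions are
    confidently correlated and mutually antisymmetric."""
    n = fingerprints.n_sources
    g = nx.Graph()
    g.add_nodes_from(range(n))
    measurements: list[ShiftMeasurement] = []
    for i in range(n):
        for j in range(i + 1, n):
            mij = measure_shift(fingerprints, i, j, balance, confidence_threshold, subpixel)
            mji = measure_shift(fingerprints, j, i, balance, confidence_threshold, subpixel)
            measurements.extend([mij, mji])
            if not (mij.correlated and mji.correlated):
                continue
            asym = np.hypot(
                mij.shift[0] + mji.shift[0], mij.shift[1] + mji.shift[1]
            )
            if asym > antisymmetry_tol_px:
                continue
            shift = (
                0.5 * (mij.shift[0] - mji.shift[0]),
                0.5 * (mij.shift[1] - mji.shift[1]),
            )
            g.add_edge(i, j, shift=shift, confidence=min(mij.confidence, mji.confidence))
    return ShiftGraph(graph=g, measurements=measurements)


def build_partial_map(
    s: int,
    fingerprints: FingerprintSet,
    balance: float = DEFAULT_BALANCE,
) -> np.ndarray:
    """Partial location map of source s: the sum of the deconvolutions of
    every fingerprint (including uncorrelated ones and s itself) by w_s.
    Peaks mark the neighbors of s within the memory-effect range."""
    acc = np.zeros(fingerprints.patterns.shape[1:])
    for i in range(fingerprints.n_sources):
        acc += deconvolve_pair(fingerprints.patterns[s], fingerprints.patterns[i], balance)
    return acc


def solve_global_positions(
    shift_graph: ShiftGraph,
    reference: int | None = None,
) -> tuple[dict[int, tuple[float, float]], list[int], float]:
    """Confidence-weighted least-squares shift synchronization.

    Minimizes sum over edges of confidence * ||(p_j - p_i) - shift_ij||^2
    with the reference pinned at (0, 0); exact path composition on trees.
    Nodes outside the reference's connected component are reported unplaced.

    Returns ``(positions, unplaced, rms_residual_px)``.
    """
    g = shift_graph.graph
    if g.number_of_nodes() == 0:
        return {}, [], 0.0
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    if reference is None:
        reference = min(components[0])
    comp = next(c for c in components if reference in c)
    nodes = sorted(comp)
    unplaced = sorted(set(g.nodes) - comp)
    index = {n: k for k, n in enumerate(nodes)}

    edges = [(i, j, d) for i, j, d in g.edges(data=True) if i in comp and j in comp]
    positions = {n: (0.0, 0.0) for n in nodes}
    residual = 0.0
    if edges:
        n_unknown = len(nodes)
        a = np.zeros((len(edges) + 1, n_unknown))
        brow = np.zeros(len(edges) + 1)
        bcol = np.zeros(len(edges) + 1)
        for k, (i, j, d) in enumerate(edges):
            wgt = np.sqrt(max(float(d.get("confidence", 1.0)), 1e-12))
            a[k, index[j]] = wgt
            a[k, index[i]] = -wgt
            brow[k] = wgt * d["shift"][0]
            bcol[k] = wgt * d["shift"][1]
        # pin the reference with a heavy weight
        pin = 1e6
        a[-1, index[reference]] = pin
        prow, *_ = np.linalg.lstsq(a, brow, rcond=None)
        pcol, *_ = np.linalg.lstsq(a, bcol, rcond=None)
        positions = {n: (float(prow[index[n]]), float(pcol[index[n]])) for n in nodes}
        res2 = 0.0
        for i, j, d in edges:
            dr = positions[j][0] - positions[i][0] - d["shift"][0]
            dc = positions[j][1] - positions[i][1] - d["shift"][1]
            res2 += dr * dr + dc * dc
        residual = float(np.sqrt(res2 / len(edges)))
    return positions, unplaced, residual


def render_map(
    positions: dict[int, tuple[float, float]],
    partial_maps: dict[int, np.ndarray],
    reference_id: int = 0,
    unplaced: list[int] | None = None,
    residual_px: float = 0.0,
) -> LocationMap:
    """Accumulate each partial map translated by its solved position.

    A partial map of source s peaks at its neighbors' offsets relative to s,
    so translating it by p_s moves those peaks onto absolute positions; the
    accumulated image has a dominant maximum at every placed source."""
    if not positions:
        raise ValueError("no positions solved")
    shape = next(iter(partial_maps.values())).shape
    acc = np.zeros(shape)
    for s, p in positions.items():
        m = partial_maps[s]
        if p == (0.0, 0.0):
            acc += m
        else:
            acc += nd_shift(m, p, order=1, mode="constant", cval=0.0)
    return LocationMap(
        map_image=acc,
        positions_px=positions,
        reference_id=reference_id,
        unplaced=list(unplaced or []),
        residual_px=residual_px,
    )


def localize_fingerprints(
    fingerprints: FingerprintSet,
    balance: float = DEFAULT_BALANCE,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    reference: int | None = None,
    subpixel: bool = False,
    render: bool = True,
) -> tuple[LocationMap, ShiftGraph]:
    """Full localization stage: pairwise shifts -> graph -> synchronized
    positions -> stitched map."""
    sg = build_shift_graph(
        fingerprints,
        balance=balance,
        confidence_threshold=confidence_threshold,
        subpixel=subpixel,
    )
    positions, unplaced, residual = solve_global_positions(sg, reference=reference)
    ref = reference if reference is not None else (min(positions) if positions else 0)
    if render and positions:
        partial = {s: build_partial_map(s, fingerprints, balance) for s in positions}
        loc = render_map(positions, partial, ref, unplaced, residual)
    else:
        shape = fingerprints.patterns.shape[1:]
        loc = LocationMap(np.zeros(shape), positions, ref, unplaced, residual)
    return loc, sg
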