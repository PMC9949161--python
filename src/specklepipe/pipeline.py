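"""End-to-end orchestration: simulate -> preprocess -> demix -> localize ->
evaluate, plus parameter sweeps and shipped experiment presets."""

from __future__ import annotations

import dataclasses
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import demix, io, localize, preprocess, simulate

log = logging.getLogger("specklepipe")

__all__ = ["RunConfig", "EvaluationReport", "run_pipeline", "sweep", "PRESETS"]


@dataclass
class RunConfig:
    """Every knob of the pipeline; YAML round-trippable."""

    # ensemble
    n_sources: int = 5
    layout: str = "disk"  # disk | chain
    span_um: float = 60.0  # disk diameter, or chain step * (n-1) overall span
    min_spacing_um: float = 10.0
    pixel_pitch_um: float = 2.0
    # scattering
    me_range_um: float = 75.0
    speckle_grain_px: float = 3.0
    frame_shape: tuple[int, int] = (128, 128)
    # traces
    n_frames: int = 200
    spike_rate_per_frame: float = 0.05
    decay_frames: float = 8.0
    baseline: float = 0.05
    amplitude: float = 1.0
    frame_period_s: float = 0.5
    # background (sbr = null in YAML disables it)
    sbr: float | None = None
    bg_modes: int = 64
    # noise
    photon_budget: float | None = None
    read_noise_sd: float = 0.0
    # preprocess
    highpass_sigma_px: float | None = None  # default: 4 x speckle grain
    clip_mode: str = "clip"
    # demix
    rank: int | str = "auto"
    rank_margin: int = 2  # auto grid: true/requested rank +/- margin
    w_sparsity: float = 0.0
    h_sparsity: float = 0.01
    max_iter: int = 250
    tol: float = 1e-6
    rank_scan_max_iter: int = 80
    nmf_dtype: str = "float32"
    # localize
    balance: float = localize.DEFAULT_BALANCE
    confidence_threshold: float = localize.DEFAULT_CONFIDENCE_THRESHOLD
    reference: int | None = None
    subpixel: bool = False
    render: bool = False
    # run
    seed: int = 0
    outdir: str | None = None
    tag: str = "run"

    def __post_init__(self) -> None:
        self.frame_shape = tuple(int(v) for v in self.frame_shape)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frame_shape"] = list(self.frame_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        io.write_yaml(path, self.to_dict())

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(io.read_yaml(path))


# Desk-scale analogues of the three demonstration experiments, preserving
# the printed ratios (N, SBR, span relative to the ME range).
PRESETS: dict[str, dict] = {
    "fig1-plain": dict(
        n_sources=19, n_frames=500, frame_shape=(256, 256), span_um=70.0,
        min_spacing_um=8.0, me_range_um=75.0, photon_budget=2e7, sbr=None,
    ),
    "fig3-background": dict(
        n_sources=10, n_frames=500, frame_shape=(128, 128), span_um=60.0,
        min_spacing_um=10.0, me_range_um=75.0, sbr=1.6, photon_budget=2e7,
    ),
    "fig4-beyond-me": dict(
        n_sources=8, layout="chain", span_um=127.5, me_range_um=75.0,
        n_frames=500, frame_shape=(160, 160), photon_budget=2e7, sbr=None,
    ),
}


@dataclass
class EvaluationReport:
    estimated_rank: int
    true_rank: int | None
    residual: float
    trace_correlations: list[float] = field(default_factory=list)
    fingerprint_correlations: list[float] = field(default_factory=list)
    localization_errors_px: list[float] = field(default_factory=list)
    localization_errors_um: list[float] = field(default_factory=list)
    fraction_placed: float = math.nan
    n_placed: int = 0
    measured_sbr: float | None = None
    runtime_s: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build_ensemble(config: RunConfig) -> simulate.EmitterEnsemble:
    if config.layout == "disk":
        pos = simulate.place_emitters_disk(
            config.n_sources, config.span_um, config.min_spacing_um, config.seed
        )
    elif config.layout == "chain":
        step = config.span_um / max(config.n_sources - 1, 1)
        pos = simulate.place_emitters_chain(config.n_sources, step, config.seed)
    else:
        raise ValueError(f"unknown layout {config.layout!r}")
    return simulate.EmitterEnsemble(positions=pos, pixel_pitch_um=config.pixel_pitch_um)


def simulate_from_config(config: RunConfig) -> tuple[simulate.GroundTruth, preprocess.SpeckleMovie]:
    ensemble = _build_ensemble(config)
    scatter = simulate.ScatterModel(
        me_range_um=config.me_range_um,
        speckle_grain_px=config.speckle_grain_px,
        frame_shape=config.frame_shape,
        master_seed=config.seed,
    )
    traces = simulate.TraceModel(
        n_frames=config.n_frames,
        spike_rate_per_frame=config.spike_rate_per_frame,
        decay_frames=config.decay_frames,
        baseline=config.baseline,
        amplitude=config.amplitude,
    )
    background = simulate.BackgroundModel(
        sbr=config.sbr if config.sbr is not None else math.inf,
        bg_seed=config.seed + 1,
        n_modes=config.bg_modes,
    )
    gt = simulate.simulate_ground_truth(ensemble, scatter, traces, background)
    noise = simulate.NoiseModel(
        photon_budget=config.photon_budget, read_noise_sd=config.read_noise_sd
    )
    movie = simulate.assemble_movie(gt, noise, seed=config.seed, frame_period_s=config.frame_period_s)
    return gt, movie


def _evaluate(
    config: RunConfig,
    gt: simulate.GroundTruth,
    result: demix.FactorizationResult,
    loc: localize.LocationMap,
    estimated_rank: int,
    timings: dict,
) -> EvaluationReport:
    perm, fp_corr, tr_corr = demix.match_to_ground_truth(result, gt, allow_unequal=True)
    n = gt.n_sources

    # recovered positions (relative to NMF-component reference) for each
    # ground-truth source; align by the mean offset over placed sources
    rec = np.full((n, 2), np.nan)
    for s in range(n):
        comp = perm[s]
        if comp >= 0 and comp in loc.positions_px:
            rec[s] = loc.positions_px[comp]
    placed = np.all(np.isfinite(rec), axis=1)
    errors_px = np.full(n, np.nan)
    if placed.any():
        offset = (gt.positions_px[placed] - rec[placed]).mean(axis=0)
        diff = gt.positions_px - (rec + offset)
        errors_px[placed] = np.hypot(diff[placed, 0], diff[placed, 1])

    sbr = None
    if gt.background_frame.any():
        sbr = simulate.measure_sbr(gt)

    return EvaluationReport(
        estimated_rank=estimated_rank,
        true_rank=n,
        residual=result.residual,
        trace_correlations=[float(v) for v in tr_corr],
        fingerprint_correlations=[float(v) for v in fp_corr],
        localization_errors_px=[float(v) for v in errors_px],
        localization_errors_um=[float(v * config.pixel_pitch_um) for v in errors_px],
        fraction_placed=float(placed.mean()),
        n_placed=int(placed.sum()),
        measured_sbr=sbr,
        runtime_s=timings,
    )


def run_pipeline(config: RunConfig, save_artifacts: bool | None = None):
    """Run the full chain and, when ground truth is available (simulated
    input), score the recovery.  Returns ``(report, artifacts)`` where
    artifacts maps stage names to their in-memory outputs."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    gt, movie = simulate_from_config(config)
    timings["simulate"] = time.perf_counter() - t0
    log.info("simulated %d sources, %d frames %s", gt.n_sources, movie.n_frames, movie.frame_shape)

    t = time.perf_counter()
    sigma = config.highpass_sigma_px or 4.0 * config.speckle_grain_px
    clean = preprocess.highpass_movie(movie, sigma, mode=config.clip_mode)
    timings["preprocess"] = time.perf_counter() - t

    dtype = np.float32 if config.nmf_dtype == "float32" else np.float64
    t = time.perf_counter()
    if config.rank == "auto":
        grid = list(
            range(max(1, config.n_sources - config.rank_margin), config.n_sources + config.rank_margin + 1)
        )
        estimated_rank, curve = demix.estimate_rank(
            clean,
            grid,
            seed=config.seed,
            w_sparsity=config.w_sparsity,
            h_sparsity=config.h_sparsity,
            max_iter=config.rank_scan_max_iter,
            tol=config.tol,
            dtype=dtype,
        )
    else:
        estimated_rank, curve = int(config.rank), None
    timings["rank"] = time.perf_counter() - t
    log.info("rank estimate: %d", estimated_rank)

    t = time.perf_counter()
    result = demix.factorize(
        clean,
        estimated_rank,
        w_sparsity=config.w_sparsity,
        h_sparsity=config.h_sparsity,
        seed=config.seed,
        max_iter=config.max_iter,
        tol=config.tol,
        dtype=dtype,
    )
    timings["demix"] = time.perf_counter() - t

    t = time.perf_counter()
    loc, sg = localize.localize_fingerprints(
        result.fingerprints,
        balance=config.balance,
        confidence_threshold=config.confidence_threshold,
        reference=config.reference,
        subpixel=config.subpixel,
        render=config.render,
    )
    timings["localize"] = time.perf_counter() - t

    report = _evaluate(config, gt, result, loc, estimated_rank, timings)
    timings["total"] = time.perf_counter() - t0

    artifacts = {
        "ground_truth": gt,
        "movie": movie,
        "preprocessed": clean,
        "rank_curve": curve,
        "factorization": result,
        "location_map": loc,
        "shift_graph": sg,
    }
    if save_artifacts is None:
        save_artifacts = config.outdir is not None
    if save_artifacts and config.outdir:
        _write_artifacts(config, report, artifacts)
    return report, artifacts


def _write_artifacts(config: RunConfig, report: EvaluationReport, artifacts: dict) -> None:
    out = Path(config.outdir) / config.tag
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    io.write_movie(out / "movie.tif", artifacts["movie"])
    io.write_fingerprints(out / "fingerprints.tif", artifacts["factorization"].fingerprints)
    io.write_traces(out / "traces.csv", artifacts["factorization"].activities)
    if artifacts["rank_curve"] is not None:
        artifacts["rank_curve"].to_csv(out / "rank_curve.csv", index=False)
    loc: localize.LocationMap = artifacts["location_map"]
    rows = []
    for node in sorted(artifacts["shift_graph"].graph.nodes):
        p = loc.positions_px.get(node)
        rows.append(
            dict(
                source_id=node,
                row=p[0] if p else math.nan,
                col=p[1] if p else math.nan,
                placed=p is not None,
            )
        )
    io.write_positions(out / "positions.csv", rows)
    srows = [
        dict(i=m.i, j=m.j, drow=m.shift[0], dcol=m.shift[1], confidence=m.confidence, correlated=m.correlated)
        for m in artifacts["shift_graph"].measurements
    ]
    pd.DataFrame(srows).to_csv(out / "shifts.csv", index=False)
    io.write_json(out / "report.json", report.to_dict())


def sweep(
    config: RunConfig,
    parameter: str,
    values: list,
    seeds: list[int] | None = None,
    success_tol_px: float = 2.0,
) -> pd.DataFrame:
    """Cross-product runs over one config parameter; returns a tidy table
    with per-run placement and accuracy summaries."""
    if parameter not in {f.name for f in dataclasses.fields(RunConfig)}:
        raise ValueError(f"unknown parameter {parameter!r}")
    seeds = seeds if seeds is not None else [config.seed]
    rows = []
    for value in values:
        for seed in seeds:
            cfg = dataclasses.replace(config, seed=seed, **{parameter: value})
            report, _ = run_pipeline(cfg, save_artifacts=False)
            err = np.asarray(report.localization_errors_px, dtype=float)
            ok = np.isfinite(err) & (err <= success_tol_px)
            rows.append(
                dict(
                    parameter=parameter,
                    value=value,
                    seed=seed,
                    estimated_rank=report.estimated_rank,
                    true_rank=report.true_rank,
                    fraction_placed=report.fraction_placed,
                    fraction_within_tol=float(ok.mean()),
                    success=bool(ok.all()),
                    max_error_px=float(np.nanmax(err)) if np.isfinite(err).any() else math.nan,
                    min_trace_corr=float(np.nanmin(report.trace_correlations)),
                    runtime_s=report.runtime_s.get("total", math.nan),
                )
            )
    return pd.DataFrame(rows)
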