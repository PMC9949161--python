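import numpy as np
import pytest

from specklepipe import simulate as sim


@pytest.fixture(scope="session")
def small_scatter():
    """128x128 frames, memory-effect range 20 um, grain 3 px."""
    return sim.ScatterModel(me_range_um=20.0, speckle_grain_px=3.0, frame_shape=(128, 128), master_seed=0)


@pytest.fixture(scope="session")
def tiny_scatter():
    """Smallest legal frames, for fast sweeps."""
    return sim.ScatterModel(me_range_um=16.0, speckle_grain_px=2.0, frame_shape=(64, 64), master_seed=0)


def make_ground_truth(
    n_sources=3,
    positions=None,
    scatter=None,
    n_frames=100,
    seed=0,
    sbr=None,
    pixel_pitch_um=1.0,
    spike_rate=0.05,
    baseline=0.05,
):
    """Small deterministic ground truth for unit tests."""
    scatter = scatter or sim.ScatterModel(
        me_range_um=20.0, speckle_grain_px=3.0, frame_shape=(128, 128), master_seed=seed
    )
    if positions is None:
        positions = sim.place_emitters_disk(n_sources, 16.0, 4.0, seed)
    ensemble = sim.EmitterEnsemble(positions=positions, pixel_pitch_um=pixel_pitch_um)
    traces = sim.TraceModel(
        n_frames=n_frames, spike_rate_per_frame=spike_rate, decay_frames=8.0, baseline=baseline
    )
    bg = sim.BackgroundModel(sbr=sbr if sbr is not None else np.inf, bg_seed=seed + 1)
    return sim.simulate_ground_truth(ensemble, scatter, traces, bg)
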