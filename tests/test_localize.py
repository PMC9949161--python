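import itertools
import math

import networkx as nx
import numpy as np
import pytest

from specklepipe import localize as loc
from specklepipe import simulate as sim

from conftest import make_ground_truth


def crosscorr_argmax_shift(a, b):
    """Brute-force oracle: argmax of the circular cross-correlation of
    mean-subtracted images, as a shift from the image center."""
    az = a - a.mean()
    bz = b - b.mean()
    xc = np.fft.fftshift(np.real(np.fft.ifft2(np.conj(np.fft.fft2(az)) * np.fft.fft2(bz))))
    r, c = np.unravel_index(np.argmax(xc), xc.shape)
    return (r - a.shape[0] // 2, c - a.shape[1] // 2)


@pytest.fixture(scope="module")
def speckle(small_scatter):
    return sim.generate_master_speckle(small_scatter, 0)


class TestDeconvolvePair:
    def test_self_deconvolution_peaks_at_center(self, speckle):
        d = loc.deconvolve_pair(speckle, speckle)
        shift, *_ = loc.extract_peak(d)
        assert shift == (0.0, 0.0)

    def test_constructed_translation(self, speckle):
        # sign convention: w_j = w_i shifted by delta -> peak at +delta
        w_j = np.roll(speckle, (5, -3), axis=(0, 1))
        d = loc.deconvolve_pair(speckle, w_j)
        shift, _, _, conf, correlated = loc.extract_peak(d)
        assert shift == (5.0, -3.0)
        assert correlated and conf > 10

    def test_matches_crosscorrelation_oracle(self, small_scatter):
        for s, delta in [(1, (7, 2)), (2, (-4, 9)), (3, (0, -11))]:
            w = sim.generate_master_speckle(small_scatter, s)
            w_j = np.roll(w, delta, axis=(0, 1))
            d = loc.deconvolve_pair(w, w_j)
            shift, *_ = loc.extract_peak(d)
            assert shift == tuple(float(v) for v in delta)
            assert crosscorr_argmax_shift(w, w_j) == delta

    def test_uncorrelated_pair_low_confidence(self, small_scatter):
        confs = []
        for s in range(5):
            a = sim.generate_master_speckle(small_scatter, 100 + s)
            b = sim.generate_master_speckle(small_scatter, 200 + s)
            _, _, _, conf, correlated = loc.extract_peak(loc.deconvolve_pair(a, b))
            confs.append(conf)
            assert not correlated
        assert np.mean(confs) < 3.0

    def test_shape_mismatch_and_zero_input(self, speckle):
        with pytest.raises(ValueError):
            loc.deconvolve_pair(speckle, speckle[:64, :64])
        with pytest.raises(ValueError):
            loc.deconvolve_pair(np.zeros_like(speckle), speckle)


class TestExtractPeak:
    def test_central_delta(self):
        img = np.zeros((64, 64))
        img[32, 32] = 1.0
        shift, peak, floor, conf, correlated = loc.extract_peak(img)
        assert shift == (0.0, 0.0)
        assert peak == 1.0
        assert correlated and conf > 100

    def test_flat_noise_not_correlated(self):
        rng = np.random.default_rng(0)
        img = 1e-6 * rng.normal(size=(64, 64))
        *_, correlated = loc.extract_peak(img)
        assert not correlated

    def test_nonfinite_rejected(self):
        img = np.zeros((64, 64))
        img[0, 0] = np.nan
        with pytest.raises(ValueError):
            loc.extract_peak(img)

    def test_simulated_pair_within_half_me_range(self, small_scatter):
        r = small_scatter.me_range_um
        gt = make_ground_truth(
            positions=((0.0, 0.0), (0.5 * r, 0.0)), scatter=small_scatter, n_frames=10
        )
        m = loc.measure_shift(gt.fingerprints, 0, 1)
        true = gt.positions_px[1] - gt.positions_px[0]
        assert math.hypot(m.shift[0] - true[0], m.shift[1] - true[1]) <= 1.0
        assert m.correlated

    def test_subpixel_refinement_close_to_integer_estimate(self, speckle):
        d = loc.deconvolve_pair(speckle, np.roll(speckle, (3, 1), axis=(0, 1)))
        coarse, *_ = loc.extract_peak(d, subpixel=False)
        fine, *_ = loc.extract_peak(d, subpixel=True)
        assert math.hypot(fine[0] - coarse[0], fine[1] - coarse[1]) < 0.5


class TestAntisymmetry:
    def test_shift_antisymmetry_within_one_pixel(self, small_scatter):
        gt = make_ground_truth(n_sources=4, scatter=small_scatter, n_frames=10, seed=5)
        for i, j in itertools.combinations(range(4), 2):
            mij = loc.measure_shift(gt.fingerprints, i, j)
            mji = loc.measure_shift(gt.fingerprints, j, i)
            if mij.correlated and mji.correlated:
                assert abs(mij.shift[0] + mji.shift[0]) <= 1.0
                assert abs(mij.shift[1] + mji.shift[1]) <= 1.0


class TestPartialMaps:
    def test_single_source_central_peak(self, small_scatter):
        gt = make_ground_truth(positions=((0.0, 0.0),), scatter=small_scatter, n_frames=10)
        m = loc.build_partial_map(0, gt.fingerprints)
        r, c = np.unravel_index(np.argmax(m), m.shape)
        assert (r, c) == (64, 64)

    def test_three_collinear_sources(self, small_scatter):
        gt = make_ground_truth(
            positions=((-8.0, 0.0), (0.0, 0.0), (8.0, 0.0)), scatter=small_scatter, n_frames=10
        )
        m = loc.build_partial_map(1, gt.fingerprints)
        # peaks at (0, -8), (0, 0), (0, +8) relative to center
        for col in (-8, 0, 8):
            window = m[62:67, 64 + col - 2 : 64 + col + 3]
            assert window.max() > np.median(m) + 5 * np.std(m[m < np.percentile(m, 99)])

    def test_isolated_source_has_only_self_peak(self, small_scatter):
        r = small_scatter.me_range_um
        gt = make_ground_truth(
            positions=((0.0, 0.0), (6 * r, 0.0)), scatter=small_scatter, n_frames=10
        )
        m = loc.build_partial_map(0, gt.fingerprints)
        peak_r, peak_c = np.unravel_index(np.argmax(m), m.shape)
        assert (peak_r, peak_c) == (64, 64)
        masked = m.copy()
        masked[59:70, 59:70] = -np.inf
        _, _, _, conf, correlated = loc.extract_peak(np.where(np.isfinite(masked), masked, 0.0))
        assert not correlated


def graph_from_edges(edges):
    g = nx.Graph()
    for i, j, shift, conf in edges:
        g.add_edge(i, j, shift=shift, confidence=conf)
    return loc.ShiftGraph(graph=g)


class TestSolveGlobalPositions:
    def test_path_composition(self):
        sg = graph_from_edges([(0, 1, (2.0, 0.0), 10.0), (1, 2, (3.0, 0.0), 10.0)])
        pos, unplaced, residual = loc.solve_global_positions(sg, reference=0)
        assert unplaced == []
        np.testing.assert_allclose(pos[0], (0.0, 0.0), atol=1e-6)
        np.testing.assert_allclose(pos[1], (2.0, 0.0), atol=1e-6)
        np.testing.assert_allclose(pos[2], (5.0, 0.0), atol=1e-6)
        assert residual < 1e-6

    def test_consistent_triangle(self):
        sg = graph_from_edges(
            [
                (0, 1, (2.0, 1.0), 5.0),
                (1, 2, (3.0, -1.0), 5.0),
                (0, 2, (5.0, 0.0), 5.0),
            ]
        )
        pos, _, residual = loc.solve_global_positions(sg, reference=0)
        np.testing.assert_allclose(pos[2], (5.0, 0.0), atol=1e-6)
        assert residual < 1e-6

    def test_perturbed_triangle_matches_brute_force(self):
        edges = [
            (0, 1, (2.0, 1.0), 4.0),
            (1, 2, (3.0, -1.0), 9.0),
            (0, 2, (6.0, 0.0), 1.0),  # perturbed by (1, 0)
        ]
        sg = graph_from_edges(edges)
        pos, _, residual = loc.solve_global_positions(sg, reference=0)

        # independent oracle: dense weighted normal equations on p1, p2
        def brute(coord):
            a, b = [], []
            for i, j, shift, conf in edges:
                w = math.sqrt(conf)
                row = [0.0, 0.0]
                if i != 0:
                    row[i - 1] = -w
                if j != 0:
                    row[j - 1] = w
                a.append(row)
                b.append(w * shift[coord])
            sol, *_ = np.linalg.lstsq(np.array(a), np.array(b), rcond=None)
            return sol

        rows, cols = brute(0), brute(1)
        np.testing.assert_allclose(pos[1], (rows[0], cols[0]), atol=1e-6)
        np.testing.assert_allclose(pos[2], (rows[1], cols[1]), atol=1e-6)
        # stays within 1 px of the unperturbed truth
        assert math.hypot(pos[2][0] - 5.0, pos[2][1] - 0.0) <= 1.0
        assert residual > 0

    def test_disconnected_graph_reports_unplaced(self):
        sg = graph_from_edges([(0, 1, (1.0, 0.0), 5.0), (2, 3, (0.0, 1.0), 5.0)])
        pos, unplaced, _ = loc.solve_global_positions(sg, reference=0)
        assert sorted(pos) == [0, 1]
        assert unplaced == [2, 3]

    def test_empty_graph(self):
        pos, unplaced, residual = loc.solve_global_positions(loc.ShiftGraph(graph=nx.Graph()))
        assert pos == {} and unplaced == [] and residual == 0.0


class TestEndToEndLocalization:
    def test_within_me_ensemble_placed_exactly(self, small_scatter):
        gt = make_ground_truth(n_sources=5, scatter=small_scatter, n_frames=10, seed=8)
        lmap, sg = loc.localize_fingerprints(gt.fingerprints, render=False)
        assert not lmap.unplaced
        rec = np.array([lmap.positions_px[s] for s in range(5)])
        truth = gt.positions_px - gt.positions_px[lmap.reference_id]
        rec -= rec[lmap.reference_id]
        err = np.hypot(*(rec - truth).T)
        assert np.all(err <= 1.0)

    def test_rigid_motion_equivariance(self, small_scatter):
        base = ((0.0, 0.0), (6.0, 2.0), (-4.0, 5.0))
        shifted = tuple((x + 9.0, y - 7.0) for x, y in base)
        gt_a = make_ground_truth(positions=base, scatter=small_scatter, n_frames=10)
        gt_b = make_ground_truth(positions=shifted, scatter=small_scatter, n_frames=10)
        la, _ = loc.localize_fingerprints(gt_a.fingerprints, render=False)
        lb, _ = loc.localize_fingerprints(gt_b.fingerprints, render=False)
        for s in range(3):
            da = np.subtract(la.positions_px[s], la.positions_px[0])
            db = np.subtract(lb.positions_px[s], lb.positions_px[0])
            assert np.hypot(*(da - db)) <= 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_beyond_me_stitching(self, seed):
        # nearest-neighbor spacing 0.5 R, span ~2 R: >= 95% placed within 2 px
        scatter = sim.ScatterModel(
            me_range_um=16.0, speckle_grain_px=2.0, frame_shape=(96, 96), master_seed=seed
        )
        positions = sim.place_emitters_chain(5, 8.0, seed=seed)
        gt = make_ground_truth(positions=positions, scatter=scatter, n_frames=10, seed=seed)
        lmap, _ = loc.localize_fingerprints(gt.fingerprints, render=False)
        placed = sorted(lmap.positions_px)
        assert len(placed) >= 0.95 * 5
        rec = np.array([lmap.positions_px[s] for s in placed])
        truth = gt.positions_px[placed]
        offset = (truth - rec).mean(axis=0)
        err = np.hypot(*(truth - rec - offset).T)
        assert np.all(err <= 2.0)

    def test_confidence_degrades_toward_me_range(self, small_scatter):
        r = small_scatter.me_range_um
        confs = []
        for frac in (0.2, 0.5, 0.9):
            gt = make_ground_truth(
                positions=((0.0, 0.0), (frac * r, 0.0)), scatter=small_scatter, n_frames=10
            )
            confs.append(loc.measure_shift(gt.fingerprints, 0, 1).confidence)
        assert confs[0] > confs[1] > confs[2]


class TestRenderMap:
    def test_single_source_map_equals_partial_map(self, small_scatter):
        gt = make_ground_truth(positions=((0.0, 0.0),), scatter=small_scatter, n_frames=10)
        partial = loc.build_partial_map(0, gt.fingerprints)
        lmap = loc.render_map({0: (0.0, 0.0)}, {0: partial}, reference_id=0)
        np.testing.assert_allclose(lmap.map_image, partial)

    def test_three_source_map_maxima_match_positions(self, small_scatter):
        from skimage.feature import peak_local_max

        gt = make_ground_truth(
            positions=((0.0, 0.0), (10.0, 0.0), (0.0, 8.0)), scatter=small_scatter, n_frames=10
        )
        lmap, _ = loc.localize_fingerprints(gt.fingerprints, render=True)
        peaks = peak_local_max(lmap.map_image, min_distance=3, num_peaks=3)
        center = np.array([64, 64])
        found = {tuple(p - center) for p in peaks}
        for s, pos in lmap.positions_px.items():
            best = min(found, key=lambda q: math.hypot(q[0] - pos[0], q[1] - pos[1]))
            assert math.hypot(best[0] - pos[0], best[1] - pos[1]) <= 1.0
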