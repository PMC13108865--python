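"""Midline, straightening, kymograph, and wave-geometry tests."""

import networkx as nx
import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.stats import kendalltau
from skimage.morphology import skeletonize

from wormcal.kymograph import (
    Kymograph,
    Midline,
    _skeleton_graph,
    axial_profile,
    detect_wave_geometry,
    extract_midline,
    orient_profiles,
    segment_and_normals,
    straighten,
)
from wormcal.segmentation import extract_trace, refine_mask, segment_frame
from wormcal.simulate import SimConfig, generate_recording, render_frame
from wormcal.trace import WavePeaks, detect_peaks


def make_peaks(times, prominences):
    times = np.asarray(times, float)
    return WavePeaks(
        peak_frames=(times * 15).astype(int),
        peak_times_s=times,
        amplitudes=np.asarray(prominences, float),
        prominences=np.asarray(prominences, float),
    )


class TestExtractMidline:
    def test_rectangle_centerline(self):
        mask = np.zeros((15, 110), bool)
        mask[3:12, 5:105] = True
        mid = extract_midline(mask)
        assert not mid.coiled
        assert mid.arc_length_px == pytest.approx(99.0, abs=2.0)
        assert np.all(np.abs(mid.points[:, 0] - 7.0) <= 2.0)  # near central row

    def test_annulus_flagged_coiled(self):
        yy, xx = np.mgrid[:40, :40]
        r = np.hypot(yy - 20, xx - 20)
        mid = extract_midline((r < 15) & (r > 8))
        assert mid.coiled

    def test_spur_removed_longest_path_kept(self):
        mask = np.zeros((20, 110), bool)
        mask[5:8, 5:105] = True  # long arm
        mask[8:11, 50] = True  # 3 px spur
        mid = extract_midline(mask)
        assert not mid.coiled
        assert mid.points[:, 0].max() <= 7.0  # spur rows excluded
        assert mid.arc_length_px == pytest.approx(99.0, abs=4.0)

    def test_longest_path_matches_graph_oracle(self):
        # brute-force longest endpoint-to-endpoint path on the skeleton graph
        mask = np.zeros((16, 40), bool)
        mask[6:10, 2:38] = True
        mask[10:14, 20:24] = True  # short side branch
        skel = skeletonize(ndi.binary_fill_holes(mask))
        coords, adj = _skeleton_graph(skel)
        g = nx.Graph()
        g.add_nodes_from(range(len(coords)))
        for i, nbrs in enumerate(adj):
            g.add_edges_from((i, j) for j in nbrs)
        ends = [n for n in g if g.degree(n) == 1]
        best = 0
        for i, a in enumerate(ends):
            for b in ends[i + 1:]:
                best = max(best, nx.shortest_path_length(g, a, b) + 1)
        mid = extract_midline(mask)
        # our midline contains the skeleton's longest path (plus tip extensions)
        skel_pts = {tuple(map(int, p)) for p in coords}
        on_skel = sum(tuple(map(int, p)) in skel_pts for p in mid.points)
        assert on_skel == best

    def test_empty_mask_invalid(self):
        assert extract_midline(np.zeros((10, 10), bool)) is None


class TestSegmentsAndNormals:
    def test_straight_line_normals_vertical(self):
        pts = np.column_stack([np.full(120, 10.0), np.linspace(0, 119, 120)])
        mid = Midline(points=pts, arc_length_px=119.0)
        midpoints, normals = segment_and_normals(mid)
        assert len(midpoints) == 100
        np.testing.assert_allclose(np.abs(normals[:, 0]), 1.0, atol=1e-9)
        np.testing.assert_allclose(normals[:, 1], 0.0, atol=1e-9)
        gaps = np.linalg.norm(np.diff(midpoints, axis=0), axis=1)
        np.testing.assert_allclose(gaps, gaps[0], rtol=1e-6)

    def test_quarter_circle_normals_radial(self):
        R = 60.0
        ang = np.linspace(0, np.pi / 2, 400)
        pts = np.column_stack([80 - R * np.sin(ang), 20 + R * np.cos(ang)])
        mid = Midline(points=pts, arc_length_px=R * np.pi / 2)
        midpoints, normals = segment_and_normals(mid)
        radial = midpoints - np.array([80.0, 20.0])
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        cosang = np.abs(np.sum(normals * radial, axis=1))
        assert np.all(np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= 2.0)

    def test_too_short_midline_rejected(self):
        pts = np.column_stack([np.full(10, 5.0), np.linspace(0, 9, 10)])
        with pytest.raises(ValueError):
            segment_and_normals(Midline(points=pts, arc_length_px=9.0))


class TestStraighten:
    def _straight_worm_frame(self, ramp):
        cfg = SimConfig(noise_sd=0.0, seed=0)
        row = 96.0
        pts = np.column_stack([np.full(141, row), np.arange(58.0, 199.0)])
        bf, fl = render_frame(pts, ramp, cfg, rng=None)
        return cfg, pts, bf, fl

    def test_matches_direct_crop_for_straight_worm(self):
        ramp = np.linspace(80, 180, 200)
        cfg, pts, bf, fl = self._straight_worm_frame(ramp)
        mid = Midline(points=pts, arc_length_px=140.0)
        st = straighten(fl, mid, half_width_px=3)
        # away from the tapered ends every perpendicular sample equals the
        # axial value at that midpoint: column-constant rows
        interior = slice(15, 85)
        assert np.nanmax(np.nanstd(st[interior], axis=1)) <= 1e-6
        expected = np.interp(
            (np.arange(100) + 0.5) / 100, np.linspace(0, 1, 200), ramp
        )
        np.testing.assert_allclose(st[interior, 3], expected[interior], rtol=0.02)

    def test_half_width_zero_samples_midline(self):
        ramp = np.full(200, 130.0)
        cfg, pts, bf, fl = self._straight_worm_frame(ramp)
        mid = Midline(points=pts, arc_length_px=140.0)
        st = straighten(fl, mid, half_width_px=0)
        assert st.shape == (100, 1)
        np.testing.assert_allclose(st[10:90, 0], 130.0, atol=1e-9)

    def test_rotational_equivariance(self, rng):
        frame = rng.random((80, 120) ) * 100
        pts = np.column_stack([np.full(90, 40.0), np.linspace(10, 99, 90)])
        mid = Midline(points=pts, arc_length_px=89.0)
        st = straighten(frame, mid, half_width_px=4)
        # rotate frame 90 deg counterclockwise: (r, c) -> (W-1-c, r)
        frame_rot = np.rot90(frame)
        pts_rot = np.column_stack([frame.shape[1] - 1 - pts[:, 1], pts[:, 0]])
        mid_rot = Midline(points=pts_rot, arc_length_px=49.0)
        st_rot = straighten(frame_rot, mid_rot, half_width_px=4)
        np.testing.assert_allclose(st, st_rot, atol=1e-6)


class TestAxialProfile:
    def test_linear_ramp_resampled_exactly(self):
        ramp = np.linspace(3.0, 17.0, 100)
        prof = axial_profile(ramp[:, None], n_out=200)
        assert prof[0] == pytest.approx(3.0, abs=1e-12)
        assert prof[-1] == pytest.approx(17.0, abs=1e-12)
        np.testing.assert_allclose(prof, np.linspace(3.0, 17.0, 200), atol=1e-9)

    def test_constant_input(self):
        prof = axial_profile(np.full((100, 9), 4.2))
        np.testing.assert_allclose(prof, 4.2)

    def test_row_maxima_match_bruteforce(self, rng):
        arr = rng.random((100, 21)) * 50
        prof = axial_profile(arr, n_out=100)  # identity resampling
        expected = np.array([max(row) for row in arr])
        np.testing.assert_allclose(prof, expected)

    def test_all_nan_segment_interpolated(self):
        arr = np.tile(np.arange(100.0)[:, None], (1, 5))
        arr[40] = np.nan
        prof = axial_profile(arr, n_out=100)
        assert prof[40] == pytest.approx(40.0)


class TestOrientation:
    def _profiles(self, dim_at_start=True, n=300):
        prof = np.full((n, 200), 100.0)
        band = slice(0, 24) if dim_at_start else slice(176, 200)
        prof[:, band] = 5.0
        return prof

    def test_dim_end_goes_to_column_zero(self):
        prof = self._profiles(dim_at_start=False)
        oriented, known = orient_profiles(prof, np.ones(300, bool))
        assert known.all()
        assert oriented[:, :24].mean() < oriented[:, -24:].mean()

    def test_mirror_flip_invariance(self):
        prof = self._profiles()
        valid = np.ones(300, bool)
        a, _ = orient_profiles(prof, valid)
        b, _ = orient_profiles(prof[:, ::-1], valid)
        np.testing.assert_allclose(a, b)

    def test_orientation_idempotent(self):
        prof = self._profiles(dim_at_start=False)
        valid = np.ones(300, bool)
        once, _ = orient_profiles(prof, valid)
        twice, _ = orient_profiles(once, valid)
        np.testing.assert_allclose(once, twice)

    def test_symmetric_profile_unknown_and_unflipped(self):
        prof = np.full((100, 200), 50.0)
        oriented, known = orient_profiles(prof, np.ones(100, bool))
        assert not known.any()
        np.testing.assert_allclose(oriented, prof)

    def test_anterior_recovered_on_synthetic_recording(self, regular_kymograph):
        k = regular_kymograph
        v = k.frame_valid
        ant = np.nanmean(k.matrix[v][:, :20], axis=1)
        post = np.nanmean(k.matrix[v][:, -20:], axis=1)
        # pharynx band carries no GCaMP: anterior end dim in ~every frame
        assert np.mean(ant < post) >= 0.99


class TestBuildKymograph:
    def test_column_count_and_validity(self, regular_kymograph, regular_recording):
        rec, _ = regular_recording
        k = regular_kymograph
        assert k.matrix.shape == (rec.n_frames, 200)
        assert k.frame_valid.sum() >= 0.95 * rec.n_frames
        assert np.isnan(k.matrix[~k.frame_valid]).all()

    def test_wave_front_order_matches_ground_truth(
        self, regular_kymograph, regular_recording
    ):
        rec, gt = regular_recording
        k = regular_kymograph
        t0 = gt.normal_wave_times[0]
        f0, f1 = int((t0 - 3) * rec.fps), int((t0 + 6) * rec.fps)
        window = k.matrix[f0:f1]
        cols = np.arange(40, 200, 4)
        onsets = []
        for c in cols:
            col = window[:, c]
            level = np.nanmin(col) + 0.5 * (np.nanmax(col) - np.nanmin(col))
            onsets.append(np.argmax(col >= level))
        # posterior-to-anterior: onset should decrease with axial position
        truth = t0 + (1.0 - cols / 199.0)  # ground-truth arrival times
        tau, _ = kendalltau(onsets, truth)
        assert tau >= 0.8

    def test_coil_fraction_tracks_simulation(self):
        cfg = SimConfig(duration_s=60.0, seed=7, coil_prob_per_frame=0.05)
        rec, gt = generate_recording(cfg)
        _, masks = extract_trace(rec)
        from wormcal.kymograph import build_kymograph

        k = build_kymograph(rec, masks)
        sim_rate = len(gt.coiled_frames) / rec.n_frames
        invalid_rate = (~k.frame_valid).sum() / rec.n_frames
        assert abs(invalid_rate - sim_rate) <= 0.03

    def test_zero_amplitude_rows_constant(self):
        cfg = SimConfig(duration_s=20.0, wave_amplitude=0.0, noise_sd=0.0, seed=5)
        rec, _ = generate_recording(cfg)
        _, masks = extract_trace(rec)
        from wormcal.kymograph import build_kymograph

        k = build_kymograph(rec, masks)
        interior = k.matrix[k.frame_valid][:, 40:160]
        assert np.nanstd(interior, axis=0).max() <= 1.0


class TestWaveGeometry:
    def _synthetic_kymograph(self, event_cols, t0=60.0, amp=150.0, T=1800):
        fps = 15.0
        mat = np.full((T, 200), 100.0)
        t = np.arange(T) / fps
        rise = np.clip((t - t0) / 2.0, 0, 1)
        decay = np.exp(-np.clip(t - t0 - 2.0, 0, None) / 4.0)
        shape = np.where(t >= t0, rise * decay, 0.0)
        mat[:, event_cols] += amp * np.outer(shape, np.ones(len(event_cols)))
        return Kymograph(matrix=mat, frame_valid=np.ones(T, bool), fps=fps)

    def test_medial_confined_event_is_ectopic(self):
        k = self._synthetic_kymograph(np.arange(90, 111))
        peaks = make_peaks([62.0], [100.0])
        (g,) = detect_wave_geometry(k, peaks)
        assert g.ectopic and not g.propagated
        assert g.initiation_axfrac == pytest.approx(0.5, abs=0.06)
        assert g.propagation_extent_axfrac == pytest.approx(21 / 200, abs=0.02)

    def test_full_wave_from_recording_propagates(
        self, regular_kymograph, regular_peaks, regular_recording
    ):
        _, gt = regular_recording
        events = detect_wave_geometry(regular_kymograph, regular_peaks)
        assert len(events) == len(gt.normal_wave_times)
        for g in events:
            assert g.propagated and not g.ectopic
            assert g.initiation_axfrac >= 0.9  # posterior initiation

    def test_no_peaks_no_geometry(self):
        k = self._synthetic_kymograph(np.arange(90, 111))
        assert detect_wave_geometry(k, make_peaks([], [])) == []

    def test_peak_in_invalid_region_undetermined(self):
        k = self._synthetic_kymograph(np.arange(90, 111))
        k.frame_valid[800:1000] = False
        k.matrix[800:1000] = np.nan
        peaks = make_peaks([60.0], [100.0])
        (g,) = detect_wave_geometry(k, peaks)
        assert g.undetermined
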