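"""Midline extraction, worm straightening, kymographs, and wave geometry.

Each segmented frame is thinned to a one-pixel skeleton whose longest
end-to-end path is the body midline.  The midline is divided into 100
equal arc-length segments; fluorescence is sampled along the normal at
each segment midpoint (bilinear interpolation), the per-segment maximum
over that perpendicular line is taken, and the 100 maxima are linearly
resampled to 200 axial positions.  Stacking these profiles over time gives
the kymograph.  The anterior end is identified per frame from the dimness
of the GCaMP-free pharynx and a per-run majority vote fixes one head
identity, so the kymograph always has the anterior at column 0.  Coiled
frames (mask with a hole, cyclic skeleton, or a collapsed midline) cannot
support an open midline and are marked invalid rather than filled in.

Wave geometry is read off the oriented kymograph around each bulk-trace
peak: the axial position of earliest onset gives the initiation site, the
fraction of responding columns gives the propagation extent, and an event
that starts in the medial band without propagating is called ectopic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from scipy.ndimage import map_coordinates, uniform_filter1d
from skimage.morphology import skeletonize

from .segmentation import MaskStack, Recording
from .trace import WavePeaks

logger = logging.getLogger(__name__)

N_SEGMENTS = 100
N_AXIAL_OUT = 200
COIL_LENGTH_FRACTION = 0.6
ORIENTATION_END_FRACTION = 0.15
# 8-adjacency skeletons carry spurious 3-4 pixel cycles at branch points;
# only longer cycles indicate a genuinely looped (coiled) body
CYCLE_MIN_PIXELS = 10


@dataclass
class Midline:
    """Ordered head-to-tail centerline of one frame.

    ``points`` are (row, col) pixel coordinates with index 0 at the
    anterior end once oriented.  ``segment_midpoints`` and ``unit_normals``
    are filled by :func:`segment_and_normals` for non-coiled frames.
    """

    points: np.ndarray  # (N, 2)
    arc_length_px: float
    coiled: bool = False
    segment_midpoints: np.ndarray | None = None
    unit_normals: np.ndarray | None = None
    orientation_known: bool = False


@dataclass
class Kymograph:
    """Time x axial-position matrix of per-segment maxima.

    Rows are frames, columns the 200 axial positions with anterior at
    column 0.  Invalid (coiled or failed) rows are NaN.
    """

    matrix: np.ndarray  # (T, 200) float, NaN where invalid
    frame_valid: np.ndarray  # (T,) bool
    fps: float
    orientation_known: np.ndarray | None = None  # (T,) bool


@dataclass
class WaveEventGeometry:
    """Initiation site and propagation extent of one detected wave."""

    peak_time_s: float
    initiation_axfrac: float
    propagation_extent_axfrac: float
    propagated: bool
    ectopic: bool
    undetermined: bool = False


@dataclass
class KymographParams:
    n_segments: int = N_SEGMENTS
    n_axial_out: int = N_AXIAL_OUT
    half_width_px: int | None = None  # None: 1.5x the mask-derived halfwidth
    orientation_window_frames: int = 15
    orientation_min_asym: float = 0.05


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(skel: np.ndarray) -> tuple[np.ndarray, list[list[int]]]:
    """Skeleton pixels as an 8-adjacency graph: coordinates + adjacency lists."""
    coords = np.argwhere(skel)
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(coords)}
    adj: list[list[int]] = [[] for _ in range(len(coords))]
    for i, (r, c) in enumerate(coords):
        for dr, dc in _NEIGHBORS:
            j = index.get((int(r) + dr, int(c) + dc))
            if j is not None:
                adj[i].append(j)
    return coords, adj


def _bfs(adj: list[list[int]], start: int) -> tuple[dict[int, int], dict[int, int]]:
    """Hop-count BFS; returns distance and parent maps."""
    dist = {start: 0}
    parent = {start: -1}
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    parent[v] = u
                    nxt.append(v)
        frontier = nxt
    return dist, parent


def _longest_skeleton_path(adj: list[list[int]], comp: set[int]) -> list[int]:
    """Longest geodesic between skeleton endpoints (degree-1 pixels).

    BFS from every endpoint makes the search exact over endpoint pairs;
    a skeleton without endpoints (a pure loop) falls back to a two-pass
    farthest-point sweep from an arbitrary pixel.
    """
    ends = [u for u in comp if len(adj[u]) == 1]
    if ends:
        best = (-1, ends[0], ends[0])
        dists = {}
        for e in ends:
            dist, parent = _bfs(adj, e)
            dists[e] = (dist, parent)
            for b in ends:
                if b != e and dist.get(b, -1) > best[0]:
                    best = (dist[b], e, b)
        _, a, b = best
        parent = dists[a][1]
    else:
        start = next(iter(comp))
        dist, _ = _bfs(adj, start)
        a = max(dist, key=dist.get)
        dist, parent = _bfs(adj, a)
        b = max(dist, key=dist.get)
    path = [b]
    while parent[path[-1]] != -1:
        path.append(parent[path[-1]])
    return path[::-1]


def _component_of(adj: list[list[int]], start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def _extend_end(pts: np.ndarray, mask: np.ndarray, max_px: int = 30) -> np.ndarray:
    """Prolong the path's tail (last point of ``pts``) along the direction
    of its last few points, in 1 px steps, while still inside the mask."""
    k = min(5, len(pts) - 1)
    direction = pts[-1] - pts[-1 - k]
    norm = np.linalg.norm(direction)
    if norm == 0:
        return pts
    direction = direction / norm
    extra = []
    pos = pts[-1].copy()
    for _ in range(max_px):
        pos = pos + direction
        r, c = int(round(pos[0])), int(round(pos[1]))
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]):
            break
        extra.append(pos.copy())
    return np.vstack([pts, extra]) if extra else pts


def extract_midline(mask: np.ndarray) -> Midline | None:
    """Skeletonize a mask and trace the longest end-to-end skeleton path.

    The skeleton is treated as a pixel-adjacency graph and the midline is
    the longest geodesic between skeleton endpoints (exact search over
    endpoint pairs), which drops spur branches as a side effect; the tips
    are then extended to the mask boundary.  Coiling is flagged when the
    mask contains a hole or the skeleton graph contains a substantial
    cycle; the recording-level length criterion is applied in
    :func:`build_kymograph`.  Returns None for an empty or degenerate mask.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return None
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    sub = mask[r0:r1, c0:c1]
    filled = ndi.binary_fill_holes(sub)
    if int(filled.sum()) > int(sub.sum()):
        # enclosed background: the body overlaps itself
        return Midline(points=np.zeros((0, 2)), arc_length_px=0.0, coiled=True)

    skel = skeletonize(sub)
    if skel.sum() < 2:
        return None
    coords, adj = _skeleton_graph(skel)
    # restrict to the largest connected component
    best_comp: set[int] = set()
    seen_all: set[int] = set()
    for i in range(len(coords)):
        if i in seen_all:
            continue
        comp = _component_of(adj, i)
        seen_all |= comp
        if len(comp) > len(best_comp):
            best_comp = comp
    g = nx.Graph()
    g.add_nodes_from(best_comp)
    for u in best_comp:
        g.add_edges_from((u, v) for v in adj[u])
    has_cycle = any(
        len(cyc) >= CYCLE_MIN_PIXELS for cyc in nx.cycle_basis(g)
    )

    path = _longest_skeleton_path(adj, best_comp)
    pts = coords[path].astype(np.float64)
    if len(pts) < 2:
        return None
    if not has_cycle:
        # thinning retracts the skeleton from the body tips by roughly the
        # local halfwidth; extend both ends along the end tangent to the
        # mask boundary so the midline spans the whole body
        pts = _extend_end(pts[::-1], sub)[::-1]
        pts = _extend_end(pts, sub)
    pts[:, 0] += r0
    pts[:, 1] += c0
    arc = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    return Midline(points=pts, arc_length_px=arc, coiled=has_cycle)


def segment_and_normals(
    midline: Midline, n_segments: int = N_SEGMENTS
) -> tuple[np.ndarray, np.ndarray]:
    """Equal arc-length segment midpoints and their unit normals.

    The midline is arc-length parameterized and resampled at ``2n + 1``
    equally spaced points; odd indices are the segment midpoints and the
    tangent at each midpoint comes from the central difference of its two
    neighbors.  The normal is the tangent rotated by +90 degrees.

    Raises
    ------
    ValueError
        For a coiled midline or one shorter than ``n_segments / 2`` px.
    """
    if midline.coiled:
        raise ValueError("cannot segment a coiled midline")
    pts = midline.points
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    L = s[-1]
    if L < n_segments * 0.5:
        raise ValueError(f"midline too short ({L:.1f} px) for {n_segments} segments")
    grid = np.linspace(0.0, L, 2 * n_segments + 1)
    rows = np.interp(grid, s, pts[:, 0])
    cols = np.interp(grid, s, pts[:, 1])
    fine = np.column_stack([rows, cols])
    mid = fine[1::2]
    tangent = fine[2::2] - fine[0:-1:2]
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    normals = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    midline.segment_midpoints = mid
    midline.unit_normals = normals
    return mid, normals


def straighten(
    fluorescence_frame: np.ndarray, midline: Midline, half_width_px: int
) -> np.ndarray:
    """Sample fluorescence along each midpoint normal: the straightened worm.

    Returns an ``(n_segments, 2 * half_width_px + 1)`` array, bilinearly
    interpolated; samples falling outside the frame are NaN and excluded
    from downstream maxima.
    """
    if midline.segment_midpoints is None or midline.unit_normals is None:
        segment_and_normals(midline)
    if half_width_px < 0:
        raise ValueError("half_width_px must be non-negative")
    mid = midline.segment_midpoints
    nrm = midline.unit_normals
    offsets = np.arange(-half_width_px, half_width_px + 1, dtype=np.float64)
    coords = mid[:, None, :] + offsets[None, :, None] * nrm[:, None, :]
    frame = np.asarray(fluorescence_frame, dtype=np.float64)
    out = map_coordinates(
        frame,
        [coords[..., 0].ravel(), coords[..., 1].ravel()],
        order=1,
        mode="constant",
        cval=np.nan,
    )
    return out.reshape(mid.shape[0], len(offsets))


def axial_profile(straightened: np.ndarray, n_out: int = N_AXIAL_OUT) -> np.ndarray:
    """Per-segment maxima resampled to ``n_out`` axial points.

    The maximum over each perpendicular line gives one value per segment;
    those maxima are linearly interpolated onto ``n_out`` equally spaced
    positions spanning the same axis, so the endpoints are preserved
    exactly and a linear ramp stays exactly linear.  A segment with no
    valid perpendicular sample is interpolated from its neighbors.
    """
    arr = np.asarray(straightened, dtype=np.float64)
    with np.errstate(all="ignore"):
        maxima = np.nanmax(arr, axis=1, initial=-np.inf)
    empty = ~np.isfinite(maxima)
    if empty.all():
        raise ValueError("no valid perpendicular samples in any segment")
    if empty.any():
        idx = np.arange(len(maxima))
        maxima[empty] = np.interp(idx[empty], idx[~empty], maxima[~empty])
    x_in = np.linspace(0.0, 1.0, len(maxima))
    x_out = np.linspace(0.0, 1.0, n_out)
    return np.interp(x_out, x_in, maxima)


def _nan_moving_average(v: np.ndarray, window: int) -> np.ndarray:
    """Moving average that ignores NaN entries (all-NaN windows stay NaN)."""
    ok = np.isfinite(v)
    num = uniform_filter1d(np.where(ok, v, 0.0), size=window, mode="nearest")
    den = uniform_filter1d(ok.astype(np.float64), size=window, mode="nearest")
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def orient_profiles(
    profiles: np.ndarray,
    frame_valid: np.ndarray,
    window_frames: int = 15,
    min_asym: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Flip per-frame axial profiles so the anterior end is at column 0.

    The pharynx expresses no GCaMP, so of the two axial ends the anterior
    is the dimmer.  Per frame, end means (first vs last 15% of positions)
    are compared after time-averaging over +/- ``window_frames``; frames
    whose relative end asymmetry is below ``min_asym`` get
    ``orientation_known = False``.  A majority vote over each contiguous
    valid run then fixes a single head identity for the run; frames whose
    own vote disagrees are overridden and flagged low-confidence.

    Returns ``(oriented_profiles, orientation_known)``.
    """
    prof = np.array(profiles, dtype=np.float64)
    T, n_ax = prof.shape
    valid = np.asarray(frame_valid, bool)
    n_end = max(int(round(ORIENTATION_END_FRACTION * n_ax)), 1)
    a = np.full(T, np.nan)
    b = np.full(T, np.nan)
    row_mean = np.full(T, np.nan)
    a[valid] = np.nanmean(prof[valid, :n_end], axis=1)
    b[valid] = np.nanmean(prof[valid, -n_end:], axis=1)
    row_mean[valid] = np.nanmean(prof[valid], axis=1)
    win = 2 * window_frames + 1
    a_s = _nan_moving_average(a, win)
    b_s = _nan_moving_average(b, win)
    level = _nan_moving_average(row_mean, win)
    with np.errstate(invalid="ignore"):
        asym = np.abs(a_s - b_s) / np.maximum(np.abs(level), 1e-12)
        vote = np.sign(b_s - a_s)  # +1: head already at column 0
    known = np.isfinite(asym) & (asym >= min_asym) & (vote != 0)

    oriented = prof.copy()
    orientation_known = np.zeros(T, bool)
    # contiguous valid runs
    i = 0
    while i < T:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j < T and valid[j]:
            j += 1
        run = slice(i, j)
        votes = vote[run][known[run]]
        if len(votes) == 0:
            i = j
            continue
        head_at_zero = np.sum(votes > 0) >= np.sum(votes < 0)
        if not head_at_zero:
            oriented[run] = oriented[run, ::-1]
        agree = np.where(head_at_zero, vote[run] > 0, vote[run] < 0)
        orientation_known[run] = known[run] & agree
        i = j
    return oriented, orientation_known


def build_kymograph(
    recording: Recording,
    mask_stack: MaskStack,
    params: KymographParams | None = None,
) -> Kymograph:
    """Full per-frame chain: midline, normals, straightening, axial profile,
    then recording-level orientation.

    Coiled frames (hole, cyclic skeleton, or arc length below 0.6x the
    recording median) and frames whose midline fails are NaN rows.  The
    point order of successive midlines is made consistent by matching
    endpoints to the previous frame before orientation voting.
    """
    params = params or KymographParams()
    T = recording.n_frames
    midlines: list[Midline | None] = []
    for i in range(T):
        if not mask_stack.valid[i]:
            midlines.append(None)
            continue
        midlines.append(extract_midline(mask_stack.masks[i]))

    arcs = np.array(
        [m.arc_length_px for m in midlines if m is not None and not m.coiled]
    )
    if len(arcs) == 0:
        raise RuntimeError("no frame yielded an open midline")
    median_arc = float(np.median(arcs))
    for m in midlines:
        if m is not None and m.arc_length_px < COIL_LENGTH_FRACTION * median_arc:
            m.coiled = True

    half_width = params.half_width_px
    if half_width is None:
        est = [
            mask_stack.area[i] / (2.0 * m.arc_length_px)
            for i, m in enumerate(midlines)
            if m is not None and not m.coiled
        ]
        half_width = int(np.ceil(1.5 * float(np.median(est))))

    matrix = np.full((T, params.n_axial_out), np.nan)
    frame_valid = np.zeros(T, bool)
    ref_head: np.ndarray | None = None
    for i, m in enumerate(midlines):
        if m is None or m.coiled:
            continue
        if ref_head is not None:
            d_keep = np.linalg.norm(m.points[0] - ref_head)
            d_flip = np.linalg.norm(m.points[-1] - ref_head)
            if d_flip < d_keep:
                m.points = m.points[::-1]
        ref_head = m.points[0]
        try:
            segment_and_normals(m, params.n_segments)
            st = straighten(recording.fluorescence[i], m, half_width)
            matrix[i] = axial_profile(st, params.n_axial_out)
            frame_valid[i] = True
        except ValueError:
            continue

    n_invalid = int((~frame_valid).sum())
    if n_invalid == T:
        raise RuntimeError("kymograph empty: every frame invalid")
    if n_invalid > 0.8 * T:
        logger.warning("kymograph mostly invalid: %d of %d frames", n_invalid, T)

    oriented, orientation_known = orient_profiles(
        matrix,
        frame_valid,
        window_frames=params.orientation_window_frames,
        min_asym=params.orientation_min_asym,
    )
    return Kymograph(
        matrix=oriented,
        frame_valid=frame_valid,
        fps=recording.fps,
        orientation_known=orientation_known,
    )


def detect_wave_geometry(
    kymograph: Kymograph,
    peaks: WavePeaks,
    onset_fraction: float = 0.5,
    medial_band: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0),
    propagation_threshold: float = 0.7,
    window_before_s: float = 10.0,
    window_after_s: float = 5.0,
    smooth_window_s: float = 1.0,
) -> list[WaveEventGeometry]:
    """Initiation site, propagation extent, and ectopic call per bulk peak.

    For each peak a ``(peak - 10 s, peak + 5 s)`` window of valid kymograph
    rows is taken and each axial column is smoothed over ``smooth_window_s``
    (the per-segment maxima are extreme-value statistics of the pixel
    noise, so without smoothing their window maxima would sit well above
    baseline even in silent columns).  A column responds when its window
    maximum exceeds baseline (10th percentile) + half the peak's
    prominence; its onset is the crossing of baseline + ``onset_fraction``
    x its excursion that leads into the column maximum.  The initiation site is the median
    axial position among the earliest-onset columns, the extent is the
    responding fraction of all columns, and an event is ectopic when it
    initiates in the medial band without propagating.
    """
    if not 0 < onset_fraction < 1:
        raise ValueError("onset_fraction must lie in (0, 1)")
    T, n_ax = kymograph.matrix.shape
    fps = kymograph.fps
    axfrac = np.linspace(0.0, 1.0, n_ax)
    events: list[WaveEventGeometry] = []
    for t_peak, prom in zip(peaks.peak_times_s, peaks.prominences):
        f0 = max(int(round((t_peak - window_before_s) * fps)), 0)
        f1 = min(int(round((t_peak + window_after_s) * fps)) + 1, T)
        vidx = np.flatnonzero(kymograph.frame_valid[f0:f1]) + f0
        peak_frame = int(round(t_peak * fps))
        window_ok = (
            len(vidx) >= max(3, (f1 - f0) // 2)
            and 0 <= peak_frame < T
            and kymograph.frame_valid[peak_frame]
        )
        if not window_ok:
            events.append(
                WaveEventGeometry(
                    peak_time_s=float(t_peak),
                    initiation_axfrac=float("nan"),
                    propagation_extent_axfrac=float("nan"),
                    propagated=False,
                    ectopic=False,
                    undetermined=True,
                )
            )
            continue
        sub = kymograph.matrix[vidx]
        win = max(int(round(smooth_window_s * fps)), 1)
        sub = uniform_filter1d(sub, size=win, axis=0, mode="nearest")
        baseline = np.percentile(sub, 10, axis=0)
        colmax = sub.max(axis=0)
        responding = colmax > baseline + prom / 2.0
        if not responding.any():
            events.append(
                WaveEventGeometry(
                    peak_time_s=float(t_peak),
                    initiation_axfrac=float("nan"),
                    propagation_extent_axfrac=0.0,
                    propagated=False,
                    ectopic=False,
                    undetermined=True,
                )
            )
            continue
        # initiation is read off the contiguous (gap-tolerant) run of
        # responding columns around the strongest column: a wave spreads
        # through neighboring cells, so isolated responding columns far
        # from the event (segmentation flicker at the body ends) cannot
        # carry the initiation site
        excursion = np.where(responding, colmax - baseline, -np.inf)
        c_star = int(np.argmax(excursion))
        core = np.zeros(n_ax, bool)
        core[c_star] = True
        gap_tol = 2
        gap = 0
        for c in range(c_star + 1, n_ax):
            if responding[c]:
                core[c] = True
                gap = 0
            else:
                gap += 1
                if gap > gap_tol:
                    break
        gap = 0
        for c in range(c_star - 1, -1, -1):
            if responding[c]:
                core[c] = True
                gap = 0
            else:
                gap += 1
                if gap > gap_tol:
                    break
        level = baseline + onset_fraction * (colmax - baseline)
        onset_idx = np.full(n_ax, np.inf)
        resp_cols = np.flatnonzero(responding & core)
        for c in resp_cols:
            col = sub[:, c]
            m = int(np.argmax(col))
            below = np.flatnonzero(col[: m + 1] < level[c])
            # onset = the crossing that leads into the column maximum, so a
            # brief early excursion in a noisy column cannot pre-date the wave
            onset_idx[c] = below[-1] + 1 if len(below) else 0
        t_min = onset_idx[resp_cols].min()
        earliest = resp_cols[onset_idx[resp_cols] == t_min]
        initiation = float(np.median(axfrac[earliest]))
        extent = float(responding.sum() / n_ax)
        propagated = extent >= propagation_threshold
        ectopic = (
            medial_band[0] <= initiation <= medial_band[1]
        ) and not propagated
        events.append(
            WaveEventGeometry(
                peak_time_s=float(t_peak),
                initiation_axfrac=initiation,
                propagation_extent_axfrac=extent,
                propagated=propagated,
                ectopic=ectopic,
            )
        )
    return events
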