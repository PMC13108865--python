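"""Synthetic dual-channel worm recordings with known ground truth.

Emulates the data the analysis pipeline assumes: a dark, undulating,
drifting worm on a bright background in the brightfield channel, and an
intestinal GCaMP signal in the fluorescence channel with periodic
posterior-initiated Ca2+ waves that sweep the body axis (~50 s period in
regular animals), an anterior pharyngeal band devoid of GCaMP, optional
ectopic medial initiation events that fail to spread, additive sensor
noise, and occasional coiled postures.

Every output is a pure function of (config, seed): per-frame random streams
are derived from the config seed, so recordings are bit-reproducible.

The posture model is a traveling sinusoid on a slowly rotating, drifting
chord; a coiled frame replaces the open midline with a self-overlapping
circular arc.  Real worms bend less regularly, foreshorten, and touch the
lawn texture; none of that is modeled — the generator is a benchmark for
the measurement chain, not a behavioral simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
from scipy import ndimage as ndi

from .segmentation import Recording

# fixed shape constants of the forward model
BF_CONTRAST = 80.0  # brightfield body darkening below background_level
WAVE_RISE_S = 2.0  # linear intensity rise at each axial position
WAVE_DECAY_TAU_S = 4.0  # exponential decay time constant
WAVE_DECAY_LENGTH_AXFRAC = 2.0  # spatial amplitude decay of normal waves
MIN_WAVE_GAP_S = 5.0  # truncation of the inter-wave interval draw
ROTATION_RAD_S = 0.005  # slow rotation of the worm's chord
TAPER_FRACTION = 0.10  # body halfwidth tapers over this end fraction
N_AXIAL = 200  # axial sample points of the ground-truth lookup
COIL_TURNS = 1.25  # a coiled posture wraps this many turns


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic recording.

    Acquisition geometry (frame size, worm length in px, drift speed) is
    not constrained by any published calibration, so the defaults are
    invented round numbers at a scale where a 4x-objective field of view
    would plausibly hold one adult worm; treat them as arbitrary units.
    """

    duration_s: float = 300.0
    fps: float = 15.0
    frame_height: int = 192
    frame_width: int = 256
    worm_length_px: float = 140.0
    worm_halfwidth_px: float = 5.0
    undulation_amplitude_px: float = 10.0
    undulation_wavelength_px: float = 70.0
    undulation_freq_hz: float = 0.4
    drift_speed_px_s: float = 3.0
    mean_wave_period_s: float = 50.0
    period_jitter_sd_s: float = 1.5
    wave_speed_axfrac_s: float = 1.0
    wave_direction: str = "posterior_to_anterior"
    wave_amplitude: float = 150.0
    gcamp_baseline: float = 100.0
    background_level: float = 200.0
    noise_sd: float = 5.0
    pharynx_fraction: float = 0.12
    ectopic_rate_per_min: float = 0.0
    ectopic_position_range: tuple[float, float] = (0.35, 0.65)
    ectopic_propagation_axfrac: float = 0.05
    coil_prob_per_frame: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be positive")
        if self.worm_length_px <= 0 or self.worm_halfwidth_px <= 0:
            raise ValueError("worm dimensions must be positive")
        if self.undulation_wavelength_px <= 0:
            raise ValueError("undulation_wavelength_px must be positive")
        if self.undulation_amplitude_px < 0 or self.drift_speed_px_s < 0:
            raise ValueError("amplitude and drift speed must be non-negative")
        if self.mean_wave_period_s <= MIN_WAVE_GAP_S:
            raise ValueError(
                f"mean_wave_period_s must exceed {MIN_WAVE_GAP_S} s"
            )
        if self.period_jitter_sd_s < 0 or self.wave_speed_axfrac_s <= 0:
            raise ValueError("jitter must be >= 0 and wave speed > 0")
        if self.wave_direction not in ("posterior_to_anterior", "anterior_to_posterior"):
            raise ValueError(f"unknown wave_direction {self.wave_direction!r}")
        if not 0.0 < self.pharynx_fraction < 0.3:
            raise ValueError("pharynx_fraction must lie in (0, 0.3)")
        lo, hi = self.ectopic_position_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("ectopic_position_range must be a sub-interval of [0, 1]")
        if self.ectopic_rate_per_min < 0 or self.ectopic_propagation_axfrac <= 0:
            raise ValueError("ectopic rate must be >= 0 and spread > 0")
        if not 0.0 <= self.coil_prob_per_frame <= 1.0:
            raise ValueError("coil_prob_per_frame must be a probability")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        margin = self._bound_radius
        if 2 * margin >= min(self.frame_height, self.frame_width):
            raise ValueError(
                "frame too small: worm (length/2 + amplitude + halfwidth) "
                "cannot stay inside with margin"
            )

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))

    @property
    def _bound_radius(self) -> float:
        # conservative radius of the worm around its center, any rotation
        return (
            self.worm_length_px / 2
            + self.undulation_amplitude_px
            + self.worm_halfwidth_px
            + 3.0
        )


@dataclass
class GroundTruth:
    """Truth channel of one synthetic recording."""

    midlines: list[np.ndarray]  # per frame, (N, 2) (row, col), head first
    wave_schedule: list[tuple[float, float, bool]]  # (t_s, axfrac, is_ectopic)
    per_frame_axial_intensity: np.ndarray  # (T, N_AXIAL), anterior at col 0
    coiled_frames: set[int]

    @property
    def normal_wave_times(self) -> list[float]:
        return [t for t, _, e in self.wave_schedule if not e]

    @property
    def ectopic_events(self) -> list[tuple[float, float]]:
        return [(t, x) for t, x, e in self.wave_schedule if e]


def _stream(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *key])


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold an unbounded coordinate into [lo, hi] by reflection."""
    span = hi - lo
    if span <= 0:
        return lo
    y = (x - lo) % (2 * span)
    return lo + (span - abs(y - span))


def _pose_params(config: SimConfig) -> tuple[float, float, float, np.ndarray]:
    rng = _stream(config, 3)
    theta0 = rng.uniform(-0.3, 0.3)
    phase0 = rng.uniform(0, 2 * np.pi)
    drift_angle = rng.uniform(0, 2 * np.pi)
    center0 = np.array(
        [
            rng.uniform(config._bound_radius, config.frame_height - config._bound_radius),
            rng.uniform(config._bound_radius, config.frame_width - config._bound_radius),
        ]
    )
    return theta0, phase0, drift_angle, center0


def _center_at(config: SimConfig, t: float) -> np.ndarray:
    _, _, drift_angle, center0 = _pose_params(config)
    R = config._bound_radius
    vr = config.drift_speed_px_s * np.sin(drift_angle)
    vc = config.drift_speed_px_s * np.cos(drift_angle)
    return np.array(
        [
            _reflect(center0[0] + vr * t, R, config.frame_height - R),
            _reflect(center0[1] + vc * t, R, config.frame_width - R),
        ]
    )


def simulate_posture(
    config: SimConfig, frame_index: int, n_points: int = 150
) -> tuple[np.ndarray, bool]:
    """Midline of one frame as ordered (row, col) points, head first.

    Returns ``(points, coiled)``.  The open posture is a traveling sinusoid
    of the given amplitude/wavelength riding on a drifting, slowly rotating
    chord, cut to arc length ``worm_length_px`` and resampled uniformly by
    arc length.  With probability ``coil_prob_per_frame`` the frame is
    coiled instead: the midline becomes a circular arc wrapping more than a
    full turn, so the rendered body overlaps itself.
    """
    if not 0 <= frame_index < config.n_frames:
        raise IndexError(f"frame_index {frame_index} outside recording")
    t = frame_index / config.fps
    theta0, phase0, _, _ = _pose_params(config)
    center = _center_at(config, t)
    coil_rng = _stream(config, 7, frame_index)
    if coil_rng.random() < config.coil_prob_per_frame:
        return _coiled_midline(config, center, coil_rng, n_points), True

    L = config.worm_length_px
    theta = theta0 + ROTATION_RAD_S * t
    e_chord = np.array([np.sin(theta), np.cos(theta)])
    e_perp = np.array([np.cos(theta), -np.sin(theta)])
    # dense parametric curve on the chord, then cut an arc-length-L window
    # centred (in arc length) on the chord origin
    u = np.arange(-0.8 * L, 0.8 * L, 0.25)
    off = config.undulation_amplitude_px * np.sin(
        2 * np.pi * u / config.undulation_wavelength_px
        - 2 * np.pi * config.undulation_freq_hz * t
        + phase0
    )
    pts = center[None, :] + u[:, None] * e_chord[None, :] + off[:, None] * e_perp[None, :]
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    s_mid = np.interp(0.0, u, s)
    s_grid = np.linspace(s_mid - L / 2, s_mid + L / 2, n_points)
    rows = np.interp(s_grid, s, pts[:, 0])
    cols = np.interp(s_grid, s, pts[:, 1])
    return np.column_stack([rows, cols]), False


def _coiled_midline(
    config: SimConfig, center: np.ndarray, rng: np.random.Generator, n_points: int
) -> np.ndarray:
    L = config.worm_length_px
    radius = L / (2 * np.pi * COIL_TURNS)
    a0 = rng.uniform(0, 2 * np.pi)
    ang = a0 + np.linspace(0, 2 * np.pi * COIL_TURNS, n_points)
    rows = center[0] + radius * np.sin(ang)
    cols = center[1] + radius * np.cos(ang)
    return np.column_stack([rows, cols])


def _wave_response(dt: np.ndarray) -> np.ndarray:
    """Temporal shape at one axial position: linear 2 s rise to 1, then
    exponential decay with a 4 s time constant.  Zero before onset."""
    out = np.zeros_like(dt)
    rising = (dt >= 0) & (dt < WAVE_RISE_S)
    out[rising] = dt[rising] / WAVE_RISE_S
    decaying = dt >= WAVE_RISE_S
    out[decaying] = np.exp(-(dt[decaying] - WAVE_RISE_S) / WAVE_DECAY_TAU_S)
    return out


def simulate_calcium(
    config: SimConfig,
) -> tuple[list[tuple[float, float, bool]], np.ndarray]:
    """Wave schedule plus the noiseless per-frame axial intensity lookup.

    Normal waves start at the posterior (axis fraction 1 for
    posterior-to-anterior propagation) at times separated by truncated
    (> 5 s) Normal(mean_wave_period_s, period_jitter_sd_s) draws, and sweep
    the full axis at ``wave_speed_axfrac_s`` with spatial amplitude decay
    exp(-distance / 2 body lengths).  Ectopic events are a Poisson process
    at ``ectopic_rate_per_min``, positioned uniformly in
    ``ectopic_position_range`` and confined to ``ectopic_propagation_axfrac``
    of the axis.  The anterior pharynx band carries zero signal.
    """
    rng = _stream(config, 11)
    duration = config.duration_s
    schedule: list[tuple[float, float, bool]] = []
    init_x = 1.0 if config.wave_direction == "posterior_to_anterior" else 0.0
    t = 0.0
    while True:
        gap = rng.normal(config.mean_wave_period_s, config.period_jitter_sd_s)
        for _ in range(1000):
            if gap > MIN_WAVE_GAP_S:
                break
            gap = rng.normal(config.mean_wave_period_s, config.period_jitter_sd_s)
        t += gap
        if t >= duration:
            break
        schedule.append((t, init_x, False))

    erng = _stream(config, 13)
    n_ect = erng.poisson(config.ectopic_rate_per_min * duration / 60.0)
    if n_ect > 0:
        times = np.sort(erng.uniform(0, duration, n_ect))
        lo, hi = config.ectopic_position_range
        pos = erng.uniform(lo, hi, n_ect)
        schedule.extend((float(tt), float(xx), True) for tt, xx in zip(times, pos))
    schedule.sort(key=lambda w: w[0])

    T = config.n_frames
    x = np.linspace(0.0, 1.0, N_AXIAL)
    times = np.arange(T) / config.fps
    intensity = np.full((T, N_AXIAL), config.gcamp_baseline)
    for t0, x0, ectopic in schedule:
        dist = np.abs(x - x0)
        if ectopic:
            amp = np.where(
                dist <= config.ectopic_propagation_axfrac, config.wave_amplitude, 0.0
            )
        else:
            amp = config.wave_amplitude * np.exp(-dist / WAVE_DECAY_LENGTH_AXFRAC)
        onset = t0 + dist / config.wave_speed_axfrac_s
        # only frames that can respond
        t_hi = t0 + 1.0 / config.wave_speed_axfrac_s + WAVE_RISE_S + 8 * WAVE_DECAY_TAU_S
        f0 = max(int(np.floor(t0 * config.fps)), 0)
        f1 = min(int(np.ceil(t_hi * config.fps)) + 1, T)
        if f0 >= f1:
            continue
        dt = times[f0:f1, None] - onset[None, :]
        intensity[f0:f1] += amp[None, :] * _wave_response(dt)
    intensity[:, x < config.pharynx_fraction] = 0.0
    return schedule, intensity


def render_frame(
    midline: np.ndarray,
    axial_intensity_row: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one frame pair from a midline and its axial intensity.

    The body is the set of pixels within the (end-tapered) halfwidth of the
    midline.  Brightfield paints the body a fixed contrast below the
    background; fluorescence paints each body pixel with the axial
    intensity at its nearest midline position.  Gaussian noise of SD
    ``noise_sd`` is added to both channels and values are clipped at zero.
    """
    H, W = config.frame_height, config.frame_width
    pts = np.asarray(midline, dtype=np.float64)
    hw = config.worm_halfwidth_px
    if (
        pts[:, 0].min() < hw
        or pts[:, 1].min() < hw
        or pts[:, 0].max() > H - 1 - hw
        or pts[:, 1].max() > W - 1 - hw
    ):
        raise ValueError("midline too close to the frame edge (margin < halfwidth)")

    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    L = s[-1]
    # densify to <= 0.5 px spacing so nearest-rasterized-pixel lookups are accurate
    n_dense = max(int(np.ceil(L / 0.5)) + 1, len(pts))
    sd = np.linspace(0, L, n_dense)
    rd = np.interp(sd, s, pts[:, 0])
    cd = np.interp(sd, s, pts[:, 1])

    margin = int(np.ceil(hw)) + 2
    r0 = max(int(np.floor(rd.min())) - margin, 0)
    r1 = min(int(np.ceil(rd.max())) + margin + 1, H)
    c0 = max(int(np.floor(cd.min())) - margin, 0)
    c1 = min(int(np.ceil(cd.max())) + margin + 1, W)

    ir = np.clip(np.rint(rd).astype(int) - r0, 0, r1 - r0 - 1)
    ic = np.clip(np.rint(cd).astype(int) - c0, 0, c1 - c0 - 1)
    on_mid = np.zeros((r1 - r0, c1 - c0), bool)
    idx_img = np.zeros((r1 - r0, c1 - c0), np.int32)
    on_mid[ir, ic] = True
    idx_img[ir, ic] = np.arange(n_dense)

    dist, (nr, nc) = ndi.distance_transform_edt(~on_mid, return_indices=True)
    nearest = idx_img[nr, nc]
    s_near = sd[nearest]
    taper = np.sqrt(
        np.clip(np.minimum(s_near, L - s_near) / (TAPER_FRACTION * L), 0.0, 1.0)
    )
    body = dist <= hw * taper

    axf = s_near / L
    n_ax = len(axial_intensity_row)
    fl_vals = np.interp(axf, np.linspace(0, 1, n_ax), axial_intensity_row)

    bf = np.full((H, W), config.background_level, np.float32)
    fl = np.zeros((H, W), np.float32)
    bf_box = bf[r0:r1, c0:c1]
    fl_box = fl[r0:r1, c0:c1]
    bf_box[body] = config.background_level - BF_CONTRAST
    fl_box[body] = fl_vals[body].astype(np.float32)

    if rng is not None and config.noise_sd > 0:
        bf += rng.standard_normal((H, W), dtype=np.float32) * config.noise_sd
        fl += rng.standard_normal((H, W), dtype=np.float32) * config.noise_sd
    np.clip(bf, 0, None, out=bf)
    np.clip(fl, 0, None, out=fl)
    return bf, fl


def rasterize_body(midline: np.ndarray, config: SimConfig) -> np.ndarray:
    """Ground-truth body support mask (independent of the rendered frames
    only in that it skips noise); used as the segmentation oracle."""
    bf, _ = render_frame(
        midline, np.zeros(N_AXIAL), config, rng=None
    )
    return bf < config.background_level - BF_CONTRAST / 2


def generate_recording(config: SimConfig) -> tuple[Recording, GroundTruth]:
    """Full synthetic recording: ``round(fps * duration_s)`` frame pairs
    (uint16) plus the matching ground truth; bit-reproducible from the
    config seed."""
    T = config.n_frames
    schedule, intensity = simulate_calcium(config)
    H, W = config.frame_height, config.frame_width
    bf_stack = np.empty((T, H, W), np.uint16)
    fl_stack = np.empty((T, H, W), np.uint16)
    midlines: list[np.ndarray] = []
    coiled_frames: set[int] = set()
    for i in range(T):
        midline, coiled = simulate_posture(config, i)
        if coiled:
            coiled_frames.add(i)
        rng = _stream(config, 17, i)
        bf, fl = render_frame(midline, intensity[i], config, rng)
        bf_stack[i] = np.clip(np.rint(bf), 0, 65535).astype(np.uint16)
        fl_stack[i] = np.clip(np.rint(fl), 0, 65535).astype(np.uint16)
        midlines.append(midline)
    rec = Recording(
        brightfield=bf_stack,
        fluorescence=fl_stack,
        fps=config.fps,
        source_id=f"sim-seed{config.seed}",
    )
    gt = GroundTruth(
        midlines=midlines,
        wave_schedule=schedule,
        per_frame_axial_intensity=intensity,
        coiled_frames=coiled_frames,
    )
    return rec, gt


def cohort_configs(
    base_config: SimConfig,
    n_animals: int,
    per_animal_overrides: dict[int, dict] | None = None,
    seed: int = 0,
) -> list[SimConfig]:
    """Per-animal configs with seeds derived from one master seed.

    ``per_animal_overrides`` maps animal index to config-field overrides
    (for example ``{"mean_wave_period_s": 1e6}`` yields a wave-free animal,
    ``{"period_jitter_sd_s": 15.0}`` an irregular one).
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    overrides = per_animal_overrides or {}
    bad = [i for i in overrides if not 0 <= i < n_animals]
    if bad:
        raise IndexError(f"override indices out of range: {bad}")
    configs = []
    for i in range(n_animals):
        child = int(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, i]).generate_state(1)[0]
            % (2**31)
        )
        cfg = replace(base_config, seed=child, **overrides.get(i, {}))
        configs.append(cfg)
    return configs


def generate_cohort(
    base_config: SimConfig,
    n_animals: int,
    per_animal_overrides: dict[int, dict] | None = None,
    seed: int = 0,
) -> Iterator[tuple[Recording, GroundTruth]]:
    """Lazily generate a cohort of recordings (one ~300 s recording is
    hundreds of MB in memory, so the cohort is yielded animal by animal)."""
    for cfg in cohort_configs(base_config, n_animals, per_animal_overrides, seed):
        yield generate_recording(cfg)
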