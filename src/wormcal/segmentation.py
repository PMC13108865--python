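"""Worm-body segmentation and bulk Ca2+ signal extraction.

The brightfield channel shows the worm as a dark elongated object on a
brighter background.  Each frame is thresholded with Otsu's method, the
foreground is reduced to its largest 8-connected component, and the mask is
refined by morphological closing (dilation then erosion with a disk) plus
hole filling.  The bulk Ca2+ signal of a frame is the mean GCaMP intensity
inside the mask minus the mean intensity outside it, which cancels global
illumination offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), bool)  # 8-connectivity


@dataclass
class Recording:
    """Paired brightfield + fluorescence time-lapse stacks.

    Both stacks are ``(T, H, W)`` grayscale intensity arrays acquired
    simultaneously and assumed pre-aligned.
    """

    brightfield: np.ndarray
    fluorescence: np.ndarray
    fps: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.brightfield.shape != self.fluorescence.shape:
            raise ValueError(
                f"channel shape mismatch: brightfield {self.brightfield.shape} "
                f"vs fluorescence {self.fluorescence.shape}"
            )
        if self.brightfield.ndim != 3 or self.brightfield.shape[0] < 1:
            raise ValueError("stacks must be (T, H, W) with T >= 1")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.brightfield.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass
class MaskStack:
    """Per-frame binary body masks with validity flags."""

    masks: np.ndarray  # (T, H, W) bool
    foreground_polarity: str
    area: np.ndarray  # (T,) pixel counts
    valid: np.ndarray  # (T,) bool


@dataclass
class BulkTrace:
    """Background-subtracted whole-body fluorescence time series."""

    values: np.ndarray  # (T,)
    time_s: np.ndarray  # (T,)
    valid: np.ndarray  # (T,) bool
    fps: float

    def __post_init__(self) -> None:
        if not (len(self.values) == len(self.time_s) == len(self.valid)):
            raise ValueError("values, time_s and valid must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")


@dataclass
class SegmentationParams:
    foreground_polarity: str = "dark_object"
    n_bins: int = 256
    r_dilate: int = 2
    r_erode: int = 2


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Otsu threshold as a histogram-bin edge.

    Maximizes the between-class variance over ``n_bins`` equal-width bins
    spanning ``[min, max]`` of the image.  Class means are computed from the
    exact per-bin intensity sums, so the result agrees with an exhaustive
    search over the same candidate edges.  Ties take the lowest threshold.

    Raises
    ------
    ValueError
        If the image is constant, or no bin edge separates two non-empty
        classes.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = np.asarray(image, dtype=np.float64).ravel()
    vmin, vmax = vals.min(), vals.max()
    if vmin == vmax:
        raise ValueError("constant image: Otsu threshold undefined")
    edges = np.linspace(vmin, vmax, n_bins + 1)
    # single-pass binning (equivalent to np.histogram with range=(vmin, vmax))
    idx = ((vals - vmin) * (n_bins / (vmax - vmin))).astype(np.intp)
    np.clip(idx, 0, n_bins - 1, out=idx)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    c = np.cumsum(counts)
    s = np.cumsum(sums)
    n, total = c[-1], s[-1]
    # candidate thresholds are interior edges k = 1 .. n_bins-1;
    # class 0 = bins [0, k), class 1 = bins [k, n_bins)
    n0 = c[:-1].astype(np.float64)
    n1 = n - n0
    ok = (n0 > 0) & (n1 > 0)
    if not ok.any():
        raise ValueError("degenerate histogram: cannot split into two classes")
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = s[:-1] / n0
        mu1 = (total - s[:-1]) / n1
        sigma_b = n0 * n1 * (mu0 - mu1) ** 2
    sigma_b[~ok] = -np.inf
    k = int(np.argmax(sigma_b))  # argmax returns first (lowest) maximum
    return float(edges[k + 1])


def segment_frame(
    brightfield_frame: np.ndarray,
    polarity: str = "dark_object",
    n_bins: int = 256,
) -> np.ndarray:
    """Threshold one brightfield frame and keep the largest component.

    Foreground pixels lie strictly below the Otsu threshold for
    ``dark_object`` polarity, strictly above it for ``bright_object``.
    Returns an all-False mask when the frame is constant or the foreground
    is empty; such frames are flagged invalid by the caller.
    """
    if polarity not in ("dark_object", "bright_object"):
        raise ValueError(f"unknown polarity {polarity!r}")
    frame = np.asarray(brightfield_frame)
    try:
        thr = otsu_threshold(frame, n_bins=n_bins)
    except ValueError:
        return np.zeros(frame.shape, bool)
    fg = frame < thr if polarity == "dark_object" else frame > thr
    if not fg.any():
        return fg
    return _largest_component(fg)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndi.label(mask, structure=_STRUCT8)
    if n <= 1:
        return mask
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == int(np.argmax(sizes))


def refine_mask(mask: np.ndarray, r_dilate: int = 2, r_erode: int = 2) -> np.ndarray:
    """Morphological closing (dilate then erode by disks), then keep the
    largest 8-connected component and fill interior holes.

    With ``r_dilate == r_erode`` this is a standard closing: extensive
    (output contains input) and idempotent.  Radii of zero reduce to
    largest-component selection plus hole filling.
    """
    if r_dilate < 0 or r_erode < 0:
        raise ValueError("structuring-element radii must be non-negative")
    mask = np.asarray(mask, bool)
    if not mask.any():
        return mask.copy()
    # operate on a padded bounding box: cheap and border-safe for dilation
    pad = max(r_dilate, r_erode) + 1
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = max(rows[0] - pad, 0), min(rows[-1] + pad + 1, mask.shape[0])
    c0, c1 = max(cols[0] - pad, 0), min(cols[-1] + pad + 1, mask.shape[1])
    sub = mask[r0:r1, c0:c1]
    if r_dilate > 0:
        sub = ndi.binary_dilation(sub, structure=disk(r_dilate))
    if r_erode > 0:
        # border_value=1: outside the image counts as foreground during
        # erosion, so closing stays extensive for objects clipped at the
        # frame edge
        sub = ndi.binary_erosion(sub, structure=disk(r_erode), border_value=1)
    sub = _largest_component(sub)
    sub = ndi.binary_fill_holes(sub)
    out = np.zeros_like(mask)
    out[r0:r1, c0:c1] = sub
    return out


def bulk_signal(fluorescence_frame: np.ndarray, mask: np.ndarray) -> float:
    """Mean fluorescence inside the mask minus mean outside it.

    Invariant under a global additive offset and equivariant (scales by k)
    under a global multiplicative gain.
    """
    mask = np.asarray(mask, bool)
    frame = np.asarray(fluorescence_frame, dtype=np.float64)
    if frame.shape != mask.shape:
        raise ValueError("frame and mask shapes differ")
    n_in = int(mask.sum())
    if n_in == 0 or n_in == mask.size:
        raise ValueError("mask must be non-empty and not cover the full frame")
    total = frame.sum()
    inside = frame[mask].sum()
    mean_in = inside / n_in
    mean_out = (total - inside) / (mask.size - n_in)
    return float(mean_in - mean_out)


def extract_trace(
    recording: Recording, params: SegmentationParams | None = None
) -> tuple[BulkTrace, MaskStack]:
    """Run the per-frame bulk-signal pipeline over a whole recording.

    Frames where segmentation fails (empty or full-frame foreground) are
    flagged invalid; their trace values are linearly interpolated between
    the neighboring valid frames (end frames extend the nearest valid
    value) so the trace keeps length T for peak detection.
    """
    params = params or SegmentationParams()
    T = recording.n_frames
    masks = np.zeros(recording.brightfield.shape, bool)
    values = np.full(T, np.nan)
    valid = np.zeros(T, bool)
    for i in range(T):
        mask = segment_frame(
            recording.brightfield[i], params.foreground_polarity, params.n_bins
        )
        if mask.any():
            mask = refine_mask(mask, params.r_dilate, params.r_erode)
        if not mask.any() or mask.all():
            continue
        masks[i] = mask
        values[i] = bulk_signal(recording.fluorescence[i], mask)
        valid[i] = True
    if not valid.any():
        raise RuntimeError("segmentation failed on every frame")
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("interpolating %d invalid frame(s) of %d", n_bad, T)
        idx = np.arange(T)
        values[~valid] = np.interp(idx[~valid], idx[valid], values[valid])
    trace = BulkTrace(
        values=values, time_s=recording.time_s, valid=valid, fps=recording.fps
    )
    areas = masks.sum(axis=(1, 2))
    stack = MaskStack(
        masks=masks,
        foreground_polarity=params.foreground_polarity,
        area=areas,
        valid=valid,
    )
    return trace, stack
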