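"""Chromosome scanning: medial-axis tracing, perpendicular-segment intensity
averaging, centromere-anchored calibration, window binning and averaging.

The procedure mirrors how a quantitative band profile is extracted from an
immunostained metaphase chromosome image:

1. the chromatid's medial axis is traced on the DAPI-like channel (the
   original workflow traced it manually; here an automated skeleton-based
   trace is provided, and a ``provided`` mode accepts a manual polyline);
2. at each point along the axis, pixel intensities are averaged over a
   short segment perpendicular to the local tangent, giving one mean value
   per channel per axis position (a :class:`RawScan`);
3. the centromere is located as the argmax of the blue marker channel, and
   arc-length positions are mapped piecewise-linearly per arm onto genomic
   megabases, anchoring the centromere segment exactly at the spec's
   centromere position (so differential stretching of the two arms during
   preparation is corrected);
4. each channel is rescaled to percent of its own maximum, summed within
   the spec's equal scan windows per chromatid, averaged across chromatids
   (mean and sample SD per window), and the centromere window's mean is
   subtracted as background (clipping at zero).
"""

from __future__ import annotations

import dataclasses
import logging
from collections import deque

import numpy as np
from scipy import interpolate, ndimage
from skimage import filters, measure, morphology

from .errors import (
    CalibrationError,
    MarkerMissingError,
    SegmentationError,
    ValidationError,
)
from .specs import ChromSpec
from .synth import ChromImage

logger = logging.getLogger("chromoband.scan")

__all__ = [
    "MedialPath",
    "RawScan",
    "CalibratedScan",
    "WindowProfile",
    "MeanProfile",
    "trace_medial_axis",
    "scan_profile",
    "locate_centromere",
    "calibrate",
    "bin_profile",
    "average_profiles",
    "subtract_background",
]


@dataclasses.dataclass
class MedialPath:
    """Ordered medial-axis polyline, pter first, with cumulative arc length."""

    points_rc: np.ndarray  # (n, 2) float (row, col)
    arc_length: np.ndarray  # (n,) cumulative, starting at 0

    def __post_init__(self) -> None:
        self.points_rc = np.asarray(self.points_rc, dtype=float)
        self.arc_length = np.asarray(self.arc_length, dtype=float)
        if len(self.points_rc) < 2:
            raise ValidationError("medial path needs >= 2 vertices")
        if (np.diff(self.arc_length) <= 0).any():
            raise ValidationError("arc length must be strictly increasing")

    @classmethod
    def from_points(cls, points_rc: np.ndarray) -> "MedialPath":
        pts = np.asarray(points_rc, dtype=float)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        keep = np.concatenate([[True], seg > 0])
        pts = pts[keep]
        arc = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
        )
        return cls(pts, arc)

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])


@dataclasses.dataclass
class RawScan:
    """Per-segment mean channel intensities along a traced chromatid."""

    arc_fraction: np.ndarray
    mean_green: np.ndarray
    mean_red: np.ndarray
    mean_blue: np.ndarray
    width_px: float
    image_id: str = ""

    def __post_init__(self) -> None:
        self.arc_fraction = np.asarray(self.arc_fraction, dtype=float)
        if (np.diff(self.arc_fraction) <= 0).any():
            raise ValidationError("arc fractions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.arc_fraction)


@dataclasses.dataclass
class CalibratedScan:
    """Scan calibrated to Mb positions and percent-of-maximum intensities."""

    position_mb: np.ndarray
    pct_green: np.ndarray
    pct_red: np.ndarray
    centromere_index: int
    spec: ChromSpec
    image_id: str = ""


@dataclasses.dataclass
class WindowProfile:
    """Per-window aggregated normalized intensity for one chromatid."""

    green: np.ndarray
    red: np.ndarray
    spec: ChromSpec
    stat: str = "sum"
    chromatid_id: str = ""
    n_samples: np.ndarray | None = None


@dataclasses.dataclass
class MeanProfile:
    """Across-chromatid mean and SD of window profiles.

    ``background`` records the per-channel value subtracted (None before
    background subtraction).
    """

    mean_green: np.ndarray
    sd_green: np.ndarray
    mean_red: np.ndarray
    sd_red: np.ndarray
    n_chromatids: int
    spec: ChromSpec
    stat: str = "sum"
    background_window: int | None = None
    background: dict | None = None


# ---------------------------------------------------------------------------
# segmentation and axis tracing


def _object_mask(image: ChromImage) -> np.ndarray:
    chan = np.asarray(image.red, dtype=float)
    if chan.max() <= chan.min():
        raise SegmentationError("image has no contrast in the DAPI channel")
    thresh = filters.threshold_otsu(chan)
    mask = chan > thresh
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        raise SegmentationError("no object above threshold")
    sizes = np.bincount(labels.ravel())[1:]
    order = np.argsort(sizes)[::-1]
    if len(sizes) > 1 and sizes[order[1]] >= 0.1 * sizes[order[0]]:
        raise SegmentationError(
            f"multiple comparable objects found ({len(sizes)} components)"
        )
    return labels == order[0] + 1


_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _longest_skeleton_path(skel: np.ndarray) -> np.ndarray:
    """Longest geodesic path through a skeleton (double BFS; exact on trees)."""
    coords = [tuple(p) for p in np.argwhere(skel)]
    if len(coords) < 2:
        raise SegmentationError("skeleton too small to trace")
    cset = set(coords)

    def bfs(start):
        dist = {start: 0}
        parent = {start: None}
        q = deque([start])
        far = start
        while q:
            r, c = q.popleft()
            for dr, dc in _NBRS:
                nb = (r + dr, c + dc)
                if nb in cset and nb not in dist:
                    dist[nb] = dist[(r, c)] + 1
                    parent[nb] = (r, c)
                    if dist[nb] > dist[far]:
                        far = nb
                    q.append(nb)
        return far, parent

    a, _ = bfs(coords[0])
    b, parent = bfs(a)
    path = []
    node = b
    while node is not None:
        path.append(node)
        node = parent[node]
    return np.asarray(path, dtype=float)


def _smooth_resample(points_rc: np.ndarray, smooth: float) -> np.ndarray:
    """Spline-smooth a pixel path and resample at ~1 px arc steps."""
    pts = points_rc
    if len(pts) >= 8:
        k = 3
        tck, _ = interpolate.splprep(
            [pts[:, 0], pts[:, 1]], s=smooth * len(pts), k=k
        )
        u = np.linspace(0.0, 1.0, 8 * len(pts))
        r, c = interpolate.splev(u, tck)
        pts = np.column_stack([r, c])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(np.floor(cum[-1])) + 1, 2)
    targets = np.linspace(0.0, cum[-1], n)
    r = np.interp(targets, cum, pts[:, 0])
    c = np.interp(targets, cum, pts[:, 1])
    return np.column_stack([r, c])


def _extend_to_caps(pts: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extend both path ends along the tangent to the rounded cap centres.

    Discrete skeletons retract from the ends of a constant-width tube; the
    cap centre is where the in-object distance transform stops being the
    full tube half-width, so we march each end outward while the distance
    transform stays near the tube's interior value.
    """
    dt = ndimage.distance_transform_edt(mask)

    def dt_at(p):
        return float(
            ndimage.map_coordinates(dt, [[p[0]], [p[1]]], order=1, mode="constant")[0]
        )

    ref = np.median(
        [dt_at(p) for p in pts[:: max(len(pts) // 50, 1)]]
    )
    out = [pts]
    for end, other in ((0, 1), (-1, -2)):
        tang = pts[end] - pts[other]
        tang = tang / np.linalg.norm(tang)
        ext = []
        p = pts[end].copy()
        for _ in range(int(4 * ref) + 4):
            cand = p + 0.5 * tang
            if dt_at(cand) < ref - 0.75:
                break
            p = cand
            ext.append(p.copy())
        if ext:
            if end == 0:
                out.insert(0, np.asarray(ext)[::-1])
            else:
                out.append(np.asarray(ext))
    return np.vstack(out)


def trace_medial_axis(
    image: ChromImage,
    mode: str = "auto",
    provided_path: MedialPath | None = None,
    pter_end: str | None = None,
    smooth: float = 2.0,
) -> MedialPath:
    """Trace the chromatid medial axis from pter to qter.

    ``auto`` mode thresholds the DAPI channel (Otsu), keeps the largest
    connected component, skeletonizes it, prunes to the longest geodesic
    path and smooths it with a spline.  ``provided`` mode validates and
    returns a user-supplied polyline (the manual workflow).

    Orientation: ``pter_end`` may be ``"left"``/``"right"`` (by image
    column); if omitted and the image carries simulator truth, the path is
    oriented to match the truth axis; otherwise the traced order is kept.
    """
    if mode == "provided":
        if provided_path is None:
            raise ValidationError("provided mode requires provided_path")
        mask = _object_mask(image)
        pr = np.clip(np.round(provided_path.points_rc[:, 0]).astype(int), 0, mask.shape[0] - 1)
        pc = np.clip(np.round(provided_path.points_rc[:, 1]).astype(int), 0, mask.shape[1] - 1)
        inb = (
            (provided_path.points_rc[:, 0] >= -0.5)
            & (provided_path.points_rc[:, 0] <= mask.shape[0] - 0.5)
            & (provided_path.points_rc[:, 1] >= -0.5)
            & (provided_path.points_rc[:, 1] <= mask.shape[1] - 0.5)
        )
        if not inb.all() or not mask[pr, pc].all():
            raise ValidationError("provided path exits the chromatid mask")
        return provided_path
    if mode != "auto":
        raise ValidationError(f"unknown mode {mode!r}")

    mask = _object_mask(image)
    skel = morphology.skeletonize(mask)
    raw = _longest_skeleton_path(skel)
    pts = _smooth_resample(raw, smooth)
    pts = _extend_to_caps(pts, mask)

    flip = False
    if pter_end == "left":
        flip = pts[0, 1] > pts[-1, 1]
    elif pter_end == "right":
        flip = pts[0, 1] < pts[-1, 1]
    elif image.truth is not None:
        t0 = image.truth.axis_rc[0]
        flip = np.linalg.norm(pts[0] - t0) > np.linalg.norm(pts[-1] - t0)
    if flip:
        pts = pts[::-1]
    return MedialPath.from_points(pts)


# ---------------------------------------------------------------------------
# perpendicular-segment scanning


def default_scan_width(image: ChromImage, path: MedialPath) -> float:
    """60% of the measured local chromatid width (median along the axis)."""
    mask = _object_mask(image)
    dist = ndimage.distance_transform_edt(mask)
    pr = np.clip(np.round(path.points_rc[:, 0]).astype(int), 0, mask.shape[0] - 1)
    pc = np.clip(np.round(path.points_rc[:, 1]).astype(int), 0, mask.shape[1] - 1)
    halfwidth = np.median(dist[pr, pc])
    return max(1.0, 0.6 * 2.0 * float(halfwidth))


def scan_profile(
    image: ChromImage,
    path: MedialPath,
    width_px: float | None = None,
    mask_marker: bool = True,
) -> RawScan:
    """Average channel intensities over perpendicular segments along the axis.

    The axis is resampled at 1 px arc steps; the perpendicular at each point
    comes from the local tangent; pixel values are sampled by bilinear
    interpolation at 1 px spacing across ``width_px``.  Sample points where
    the blue marker is present are excluded from the green/red means (the
    marker overwrites the underlying stain), unless ``mask_marker`` is
    False.  Segments leaving the image are clamped with a logged warning.
    """
    if width_px is None:
        width_px = default_scan_width(image, path)
    if width_px < 1:
        raise ValidationError("width_px must be >= 1")

    pts = _resample_path(path)
    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    )
    tang_r = np.gradient(pts[:, 0])
    tang_c = np.gradient(pts[:, 1])
    norms = np.hypot(tang_r, tang_c)
    norms[norms == 0] = 1.0
    normal = np.column_stack([-tang_c / norms, tang_r / norms])

    k = max(int(round(width_px)), 1)
    offsets = np.arange(k) - (k - 1) / 2.0
    rows = pts[:, 0][:, None] + offsets[None, :] * normal[:, 0][:, None]
    cols = pts[:, 1][:, None] + offsets[None, :] * normal[:, 1][:, None]

    H, W = image.shape
    out_of_bounds = (rows < 0) | (rows > H - 1) | (cols < 0) | (cols > W - 1)
    if out_of_bounds.any():
        logger.warning(
            "scan: %d perpendicular sample points left the image; clamped",
            int(out_of_bounds.sum()),
        )

    def sample(chan):
        return ndimage.map_coordinates(
            np.asarray(chan, dtype=float),
            [rows.ravel(), cols.ravel()],
            order=1,
            mode="nearest",
        ).reshape(rows.shape)

    g = sample(image.green)
    r = sample(image.red)
    b = sample(image.blue)

    if mask_marker and b.max() > 0.25:
        valid = b <= 0.25
        allbad = ~valid.any(axis=1)
        valid[allbad] = True  # fall back to unmasked mean
        w = valid.astype(float)
        denom = w.sum(axis=1)
        mean_green = (g * w).sum(axis=1) / denom
        mean_red = (r * w).sum(axis=1) / denom
    else:
        mean_green = g.mean(axis=1)
        mean_red = r.mean(axis=1)
    mean_blue = b.mean(axis=1)

    return RawScan(
        arc_fraction=arc / arc[-1],
        mean_green=mean_green,
        mean_red=mean_red,
        mean_blue=mean_blue,
        width_px=float(width_px),
        image_id=image.image_id,
    )


def _resample_path(path: MedialPath) -> np.ndarray:
    """Resample a medial path at uniform ~1 px arc steps."""
    cum = path.arc_length
    n = max(int(np.floor(cum[-1])) + 1, 2)
    targets = np.linspace(0.0, cum[-1], n)
    r = np.interp(targets, cum, path.points_rc[:, 0])
    c = np.interp(targets, cum, path.points_rc[:, 1])
    return np.column_stack([r, c])


# ---------------------------------------------------------------------------
# calibration and binning


def locate_centromere(scan: RawScan) -> int:
    """Index of the maximal blue-channel segment (ties -> lowest index)."""
    blue = scan.mean_blue
    if not np.any(blue > 0):
        raise MarkerMissingError("blue marker channel is identically zero")
    best = float(blue.max())
    hits = np.flatnonzero(blue == best)
    if len(hits) > 1:
        logger.warning(
            "centromere marker tie across %d segments; using lowest index %d",
            len(hits),
            hits[0],
        )
    return int(hits[0])


def calibrate(scan: RawScan, centromere_idx: int, spec: ChromSpec) -> CalibratedScan:
    """Anchor arc fractions at the centromere and map per arm to Mb.

    Arc fractions on [0, f_cen] map linearly onto [0, centromere_mb], and
    on [f_cen, 1] onto [centromere_mb, length_mb]; each channel is then
    rescaled to percent of its own maximum.
    """
    n = len(scan)
    if not 0 < centromere_idx < n - 1:
        raise CalibrationError(
            "centromere at a scan endpoint: no arm on one side"
        )
    f = scan.arc_fraction
    fc = f[centromere_idx]
    cen, L = spec.centromere_mb, spec.length_mb
    pos = np.where(f <= fc, cen * f / fc, cen + (L - cen) * (f - fc) / (1.0 - fc))
    pos[centromere_idx] = cen  # exact anchor

    def pct(v):
        m = v.max()
        if m <= 0:
            raise CalibrationError("channel with nonpositive maximum")
        # divide first: v/m <= 1.0 exactly, so the max is exactly 100.0
        return (v / m) * 100.0

    return CalibratedScan(
        position_mb=pos,
        pct_green=pct(scan.mean_green),
        pct_red=pct(scan.mean_red),
        centromere_index=centromere_idx,
        spec=spec,
        image_id=scan.image_id,
    )


def bin_profile(cal: CalibratedScan, spec: ChromSpec, stat: str = "sum") -> WindowProfile:
    """Aggregate a calibrated scan into the spec's equal scan windows.

    Windows are half-open with the last closed at qter; each sampled value
    falls in exactly one window.  ``stat`` is ``"sum"`` (default, matching
    per-chromatid total fluorescence per window) or ``"mean"``.
    """
    if stat not in ("sum", "mean"):
        raise ValidationError("stat must be 'sum' or 'mean'")
    n = spec.n_scan_windows
    w = spec.length_mb / n
    idx = np.minimum((cal.position_mb / w).astype(int), n - 1)
    counts = np.bincount(idx, minlength=n)
    if (counts == 0).any():
        logger.warning(
            "bin_profile: %d empty windows (value 0)", int((counts == 0).sum())
        )
    green = np.bincount(idx, weights=cal.pct_green, minlength=n)
    red = np.bincount(idx, weights=cal.pct_red, minlength=n)
    if stat == "mean":
        safe = np.maximum(counts, 1)
        green = green / safe
        red = red / safe
    return WindowProfile(
        green=green,
        red=red,
        spec=spec,
        stat=stat,
        chromatid_id=cal.image_id,
        n_samples=counts,
    )


def average_profiles(profiles: list[WindowProfile]) -> MeanProfile:
    """Per-window mean and sample SD across chromatids."""
    if not profiles:
        raise ValidationError("need at least one profile")
    spec = profiles[0].spec
    stat = profiles[0].stat
    for p in profiles[1:]:
        if p.spec != spec or p.stat != stat:
            raise ValidationError("profiles mix specs or window statistics")
    greens = np.stack([p.green for p in profiles])
    reds = np.stack([p.red for p in profiles])
    nc = len(profiles)
    ddof = 1 if nc > 1 else 0
    return MeanProfile(
        mean_green=greens.mean(axis=0),
        sd_green=greens.std(axis=0, ddof=ddof),
        mean_red=reds.mean(axis=0),
        sd_red=reds.std(axis=0, ddof=ddof),
        n_chromatids=nc,
        spec=spec,
        stat=stat,
    )


def subtract_background(
    profile: MeanProfile, background_window: int | str = "centromere"
) -> MeanProfile:
    """Subtract the background window's mean from every window, clipping at 0.

    ``"centromere"`` resolves to the scan window containing the spec's
    centromere position.  SDs are unchanged; the subtracted values are
    recorded per channel.
    """
    spec = profile.spec
    if background_window == "centromere":
        bw = spec.scan_window_of(spec.centromere_mb)
    else:
        bw = int(background_window)
        if not 0 <= bw < spec.n_scan_windows:
            raise ValidationError(f"background window {bw} out of range")
    bg_g = float(profile.mean_green[bw])
    bg_r = float(profile.mean_red[bw])
    return MeanProfile(
        mean_green=np.maximum(profile.mean_green - bg_g, 0.0),
        sd_green=profile.sd_green.copy(),
        mean_red=np.maximum(profile.mean_red - bg_r, 0.0),
        sd_red=profile.sd_red.copy(),
        n_chromatids=profile.n_chromatids,
        spec=spec,
        stat=profile.stat,
        background_window=bw,
        background={"green": bg_g, "red": bg_r},
    )
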