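"""Per-frame cell geometry from phase-contrast frame stacks.

Each frame is segmented (Otsu threshold, largest connected object), the
object contour is extracted and a least-squares ellipse gives the long and
short axis, the in-plane orientation and the relative brightness of the
cell body.  Frames where detection fails are linearly interpolated when
isolated; traces with too many failures are flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .protocols import StretchProtocol

__all__ = [
    "AxisTrace",
    "Morphology",
    "detect_contour",
    "fit_ellipse",
    "trace_axes",
    "compute_morphology",
]

#: Smallest connected component treated as a cell, in pixels.
MIN_OBJECT_AREA_PX = 20
#: Longest run of failed frames that is still interpolated.
MAX_INTERP_RUN = 2
#: Fraction of failed frames above which a trace is invalid.
MAX_FAIL_FRACTION = 0.10


@dataclass
class AxisTrace:
    """Raw axis measurement of one cell over a full protocol.

    ``phase_marks`` holds the frame indices of the first stretch-phase
    frame and the last stretch-phase frame.
    """

    cell_id: str
    time: np.ndarray
    long_um: np.ndarray
    short_um: np.ndarray
    orientation_deg: np.ndarray
    brightness: np.ndarray
    phase_marks: tuple[int, int]
    protocol: StretchProtocol
    valid: bool = True

    def __post_init__(self) -> None:
        for name in ("time", "long_um", "short_um", "orientation_deg", "brightness"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.time.size
        if any(
            getattr(self, f).size != n
            for f in ("long_um", "short_um", "orientation_deg", "brightness")
        ):
            raise ValueError("all trace columns must share one length")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        i0, i1 = self.phase_marks
        if not (0 <= i0 < i1 < n):
            raise ValueError("phase_marks must satisfy 0 <= start < end < n")
        if self.valid and np.any(self.long_um < self.short_um):
            raise ValueError("long axis must be >= short axis on every frame")
        if self.valid and np.any(self.short_um <= 0):
            raise ValueError("short axis must be > 0")

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class Morphology:
    """Pre-stretch morphology descriptors of one cell."""

    effective_radius: float  # um, sqrt(area/pi)
    area: float  # um^2
    mean_brightness: float  # relative to background
    initial_ellipticity: float  # resting long/short ratio, >= 1
    rotation_degree: float  # cumulative |orientation change| during stretch


def phase_marks_from_protocol(protocol: StretchProtocol, time: np.ndarray) -> tuple[int, int]:
    """Frame indices of the first and last stretch-phase frame."""
    t0 = protocol.pre_stretch_duration
    t1 = t0 + protocol.stretch_duration
    i0 = int(np.searchsorted(time, t0 - 1e-9))
    i1 = int(np.searchsorted(time, t1 + 1e-9, side="right") - 1)
    return i0, i1


def detect_contour(frame: np.ndarray, threshold: float | None = None,
                   min_area_px: int = MIN_OBJECT_AREA_PX) -> np.ndarray | None:
    """Segment the largest bright object and return its closed contour.

    The threshold defaults to Otsu's method.  Returns an (N, 2) array of
    (row, col) sub-pixel coordinates, or ``None`` when no object larger
    than ``min_area_px`` is found (detection failure; the frame is handled
    upstream).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("frame is empty")
    if threshold is None:
        if np.ptp(frame) == 0:
            return None
        threshold = threshold_otsu(frame)
    mask = frame > threshold
    labels = measure.label(mask)
    if labels.max() == 0:
        return None
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    lab = int(np.argmax(sizes))
    if sizes[lab] < min_area_px:
        return None
    # contrast guard: a threshold cutting through pure background noise
    # yields a foreground barely above the background; require a clear gap
    obj = labels == lab
    fg, bg = frame[obj], frame[~mask]
    if bg.size:
        sigma_bg = 1.4826 * np.median(np.abs(bg - np.median(bg)))
        if np.median(fg) - np.median(bg) < 4.0 * sigma_bg:
            return None
    contours = measure.find_contours(obj.astype(float), 0.5)
    if not contours:
        return None
    return max(contours, key=len)


def fit_ellipse(contour: np.ndarray, pixel_scale: float) -> tuple[float, float, float]:
    """Least-squares ellipse through a contour.

    Returns (long axis, short axis) in micrometres and the major-axis
    orientation in degrees within [0, 180).
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[0] < 5:
        raise ValueError("ellipse fit needs at least 5 contour points")
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be > 0")
    # EllipseModel works in (x, y) = (col, row)
    xy = contour[:, ::-1]
    model = measure.EllipseModel.from_estimate(xy)
    if not model:
        raise ValueError("degenerate contour: ellipse fit failed")
    long_px, short_px = model.axis_lengths  # (major, minor) semi-axes
    theta = model.theta  # major-axis angle
    if not np.all(np.isfinite([long_px, short_px, theta])) or short_px <= 0:
        raise ValueError("degenerate contour: ellipse fit failed")
    orientation = float(np.degrees(theta) % 180.0)
    return 2 * long_px * pixel_scale, 2 * short_px * pixel_scale, orientation


def _interpolate_failures(cols: dict[str, np.ndarray], failed: np.ndarray) -> bool:
    """Linearly fill isolated failed frames in place.

    Returns False when a failure run is too long or touches the ends with
    no anchor, in which case the trace cannot be repaired.
    """
    n = failed.size
    idx = np.flatnonzero(failed)
    if idx.size == 0:
        return True
    # reject long runs
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    if any(len(r) > MAX_INTERP_RUN for r in runs) or failed[0] or failed[-1]:
        return False
    good = ~failed
    xs = np.flatnonzero(good)
    for name, col in cols.items():
        col[failed] = np.interp(idx, xs, col[good])
    return True


def trace_axes(
    stack: np.ndarray,
    protocol: StretchProtocol,
    pixel_scale: float,
    cell_id: str = "cell",
    threshold: float | None = None,
) -> AxisTrace:
    """Assemble an :class:`AxisTrace` from a grayscale frame stack.

    Per-frame brightness is the mean interior intensity divided by the
    median background intensity.  Isolated detection failures (runs of at
    most two frames) are linearly interpolated; traces with more than 10%
    failed frames are returned with ``valid=False``.
    """
    stack = np.asarray(stack)
    n = stack.shape[0]
    if n != protocol.n_frames:
        raise ValueError(
            f"stack length {n} does not match protocol frame count {protocol.n_frames}"
        )
    time = np.arange(n) / protocol.frame_rate
    cols = {
        k: np.full(n, np.nan) for k in ("long", "short", "orient", "bright")
    }
    failed = np.zeros(n, dtype=bool)
    for i, frame in enumerate(stack):
        contour = detect_contour(frame, threshold=threshold)
        if contour is None:
            failed[i] = True
            continue
        try:
            L, S, ang = fit_ellipse(contour, pixel_scale)
        except ValueError:
            failed[i] = True
            continue
        mask = measure.grid_points_in_poly(frame.shape, contour)
        bg = frame[~mask]
        interior = frame[mask]
        bright = float(np.mean(interior) / np.median(bg)) if bg.size and interior.size else np.nan
        cols["long"][i], cols["short"][i] = L, S
        cols["orient"][i], cols["bright"][i] = ang, bright

    ok = (np.mean(failed) <= MAX_FAIL_FRACTION) and _interpolate_failures(cols, failed)
    if not ok:
        # keep whatever was measured but flag the trace unusable downstream
        for c in cols.values():
            np.nan_to_num(c, copy=False, nan=1.0)
    long_um = np.maximum(cols["long"], cols["short"])
    short_um = np.minimum(cols["long"], cols["short"])
    return AxisTrace(
        cell_id=cell_id,
        time=time,
        long_um=long_um,
        short_um=short_um,
        orientation_deg=cols["orient"],
        brightness=cols["bright"],
        phase_marks=phase_marks_from_protocol(protocol, time),
        protocol=protocol,
        valid=bool(ok),
    )


def _wrapped_diff_deg(angles: np.ndarray) -> np.ndarray:
    """Frame-to-frame orientation steps unwrapped modulo 180 degrees."""
    d = np.diff(angles)
    return (d + 90.0) % 180.0 - 90.0


def compute_morphology(trace: AxisTrace) -> Morphology:
    """Morphology descriptors from the pre-stretch window plus the degree
    of rotation accumulated during the stretch phase.

    Area is the ellipse area pi (L/2)(S/2) averaged over the baseline; the
    effective radius is sqrt(area/pi), so radius-area consistency holds by
    construction.  The rotation degree is the summed absolute orientation
    change over the stretch phase with 180-degree wrap unwrapping, which is
    invariant under a global orientation offset.
    """
    i0, i1 = trace.phase_marks
    if i0 < 1:
        raise ValueError("trace has no pre-stretch frames")
    area = float(np.mean(np.pi * (trace.long_um[:i0] / 2) * (trace.short_um[:i0] / 2)))
    rotation = float(np.sum(np.abs(_wrapped_diff_deg(trace.orientation_deg[i0 : i1 + 1]))))
    return Morphology(
        effective_radius=float(np.sqrt(area / np.pi)),
        area=area,
        mean_brightness=float(np.mean(trace.brightness[:i0])),
        initial_ellipticity=float(np.mean(trace.long_um[:i0] / trace.short_um[:i0])),
        rotation_degree=rotation,
    )
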