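"""Gaze event detection and the three gaze metrics.

Saccades are found with an adaptive velocity threshold: velocities come from
a centered moving-window differentiator, per-axis thresholds are a multiple
of a median-based velocity spread, and samples outside the resulting
elliptic criterion are saccadic.  Fixations are the complement of saccades
and blinks within the analysis span.  Fixations are assigned to rectangular
areas of interest by centroid containment, and the metrics layer counts
fixations per AOI, the mean fixation duration on the picture AOI, and the
number of direct text<->picture switches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import BlinkEvent, FixationEvent, SaccadeEvent

__all__ = [
    "AOI",
    "GazeMetrics",
    "interpolate_blinks",
    "detect_saccades",
    "derive_fixations",
    "assign_aoi",
    "gaze_metrics",
]


@dataclass(frozen=True)
class AOI:
    """Screen rectangle, origin top-left, half-open on the max edges."""

    label: str
    rect: tuple[float, float, float, float]  # x0, y0, x1, y1

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rect
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate AOI rect {self.rect}")

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.rect
        return x0 <= x < x1 and y0 <= y < y1


@dataclass
class GazeMetrics:
    n_fixations_per_aoi: dict[str, int]
    mean_fixation_duration_ms: float  # over picture-AOI fixations; nan if none
    n_transitions: int


# ---------------------------------------------------------------------------
# blinks
# ---------------------------------------------------------------------------

def interpolate_blinks(
    pupil: np.ndarray,
    rate: float,
    pad_ms: float = 50.0,
    *,
    sentinel: float = 0.0,
) -> tuple[np.ndarray, list[BlinkEvent]]:
    """Fill pupil dropouts by linear interpolation over padded blink spans.

    Each maximal run of sentinel (or non-finite) samples, widened by
    ``pad_ms`` on both sides, is replaced by a straight line between the
    nearest valid samples; runs touching a recording edge are filled with
    the nearest valid value.  Samples outside every padded span are returned
    bit-identical.  Returned blink events cover the unpadded sentinel runs,
    half-open in ET samples.
    """
    pupil = np.asarray(pupil, dtype=float)
    bad = ~np.isfinite(pupil) | (pupil == sentinel)
    if bad.all():
        raise ValueError("pupil channel contains no valid samples")
    out = pupil.copy()
    if not bad.any():
        return out, []
    pad = int(round(pad_ms / 1000.0 * rate))
    n = pupil.size
    edges = np.flatnonzero(np.diff(np.concatenate([[0], bad.view(np.int8), [0]])))
    blinks: list[BlinkEvent] = []
    fill = np.zeros(n, dtype=bool)
    for onset, offset in edges.reshape(-1, 2):
        blinks.append(BlinkEvent(int(onset), int(offset)))
        fill[max(0, onset - pad): min(n, offset + pad)] = True
    valid_idx = np.flatnonzero(~fill)
    gaps = np.flatnonzero(np.diff(np.concatenate([[0], fill.view(np.int8), [0]])))
    for a, b in gaps.reshape(-1, 2):  # fill span [a, b)
        lo = valid_idx[valid_idx < a]
        hi = valid_idx[valid_idx >= b]
        if lo.size and hi.size:
            i0, i1 = lo[-1], hi[0]
            t = (np.arange(a, b) - i0) / (i1 - i0)
            out[a:b] = out[i0] + t * (out[i1] - out[i0])
        elif hi.size:  # run touches the left edge
            out[a:b] = out[hi[0]]
        else:  # run touches the right edge
            out[a:b] = out[lo[-1]]
    return out, blinks


# ---------------------------------------------------------------------------
# saccades
# ---------------------------------------------------------------------------

def _window_velocity(x: np.ndarray, rate: float, window: int) -> np.ndarray:
    """Centered moving-window differentiator.

    For an odd ``window`` = 2m+1 the velocity at sample i is
    ``sum_{k=1..m} (x[i+k] - x[i-k]) / (2*dt*sum_{k=1..m} k)`` — the classic
    5-sample form for m=2.  Edge samples where the window does not fit get
    velocity 0.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("smooth_window must be an odd integer >= 3")
    m = (window - 1) // 2
    n = x.size
    v = np.zeros(n, dtype=float)
    denom = 2.0 * (1.0 / rate) * (m * (m + 1) / 2.0)
    core = np.zeros(n - 2 * m, dtype=float)
    for k in range(1, m + 1):
        core += x[m + k: n - m + k] - x[m - k: n - m - k]
    v[m: n - m] = core / denom
    return v


def _median_sd(v: np.ndarray) -> float:
    """sqrt(median(v^2) - median(v)^2), the detector's robust spread."""
    return float(np.sqrt(max(np.median(v**2) - np.median(v) ** 2, 0.0)))


def detect_saccades(
    gaze_x: np.ndarray,
    gaze_y: np.ndarray,
    rate: float,
    lambda_thresh: float = 6.0,
    min_duration_ms: float = 12.0,
    smooth_window: int = 5,
) -> list[SaccadeEvent]:
    """Adaptive velocity-based saccade detection on one eye's gaze trace.

    Thresholds scale with a median-based velocity spread, so the detector is
    equivariant to uniform rescaling of the gaze coordinates.  Saccadic runs
    shorter than ``min_duration_ms`` are dropped; runs separated by fewer
    than ``smooth_window`` samples are merged.

    Returns an empty list (after emitting no events) when either axis shows
    no velocity variability at all.
    """
    x = np.asarray(gaze_x, dtype=float)
    y = np.asarray(gaze_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("gaze_x and gaze_y must have the same length")
    if lambda_thresh <= 0:
        raise ValueError("lambda_thresh must be > 0")
    if x.size < smooth_window:
        raise ValueError(f"trace of {x.size} samples shorter than smooth_window")
    vx = _window_velocity(x, rate, smooth_window)
    vy = _window_velocity(y, rate, smooth_window)
    sx, sy = _median_sd(vx), _median_sd(vy)
    if sx == 0.0 or sy == 0.0:
        return []  # no variability -> nothing to threshold against
    ex, ey = lambda_thresh * sx, lambda_thresh * sy
    saccadic = (vx / ex) ** 2 + (vy / ey) ** 2 > 1.0
    edges = np.flatnonzero(
        np.diff(np.concatenate([[0], saccadic.view(np.int8), [0]]))
    ).reshape(-1, 2)
    if not edges.size:
        return []
    # merge runs separated by < smooth_window samples
    merged: list[list[int]] = [list(edges[0])]
    for onset, offset in edges[1:]:
        if onset - merged[-1][1] < smooth_window:
            merged[-1][1] = offset
        else:
            merged.append([onset, offset])
    min_len = int(np.ceil(min_duration_ms / 1000.0 * rate))
    speed = np.hypot(vx, vy)
    events: list[SaccadeEvent] = []
    for onset, offset in merged:
        if offset - onset < min_len:
            continue
        amplitude = float(np.hypot(x[offset - 1] - x[onset], y[offset - 1] - y[onset]))
        events.append(
            SaccadeEvent(
                int(onset),
                int(offset),
                peak_velocity=float(speed[onset:offset].max()),
                amplitude=amplitude,
            )
        )
    return events


# ---------------------------------------------------------------------------
# fixations
# ---------------------------------------------------------------------------

def derive_fixations(
    saccades: list[SaccadeEvent],
    blinks: list[BlinkEvent],
    rate: float,
    session_span: tuple[int, int],
    min_fix_ms: float = 50.0,
    *,
    gaze_x: np.ndarray | None = None,
    gaze_y: np.ndarray | None = None,
) -> list[FixationEvent]:
    """Fixations = complement of saccades and blinks within the span.

    Intervals shorter than ``min_fix_ms`` are dropped.  Centroids are the
    mean gaze position over the interval when gaze traces are provided,
    else nan.
    """
    start, end = session_span
    occupied = sorted(
        [(ev.onset, ev.offset) for ev in saccades]
        + [(ev.onset, ev.offset) for ev in blinks]
    )
    for (a0, a1), (b0, b1) in zip(occupied, occupied[1:]):
        if b0 < a1:
            raise ValueError(f"overlapping input events at samples {b0} < {a1}")
    min_len = int(np.ceil(min_fix_ms / 1000.0 * rate))
    fixations: list[FixationEvent] = []
    cursor = start
    bounds = occupied + [(end, end)]
    for ev_on, ev_off in bounds:
        ev_on = min(ev_on, end)
        if ev_on - cursor >= min_len:
            onset, offset = cursor, ev_on
            if gaze_x is not None and gaze_y is not None:
                centroid = (
                    float(np.mean(gaze_x[onset:offset])),
                    float(np.mean(gaze_y[onset:offset])),
                )
            else:
                centroid = (float("nan"), float("nan"))
            fixations.append(
                FixationEvent(
                    int(onset),
                    int(offset),
                    duration_ms=(offset - onset) / rate * 1000.0,
                    centroid=centroid,
                )
            )
        cursor = max(cursor, ev_off)
    return fixations


def assign_aoi(fixations: list[FixationEvent], aois: list[AOI]) -> list[FixationEvent]:
    """Label each fixation by centroid containment in a non-overlapping AOI set."""
    for i, a in enumerate(aois):
        for b in aois[i + 1:]:
            ax0, ay0, ax1, ay1 = a.rect
            bx0, by0, bx1, by1 = b.rect
            if ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1:
                raise ValueError(f"overlapping AOIs {a.label!r} and {b.label!r}")
    out = []
    for fix in fixations:
        label = None
        for a in aois:
            if a.contains(*fix.centroid):
                label = a.label
                break
        out.append(fix.with_aoi(label))
    return out


def gaze_metrics(
    fixations: list[FixationEvent],
    *,
    text_label: str = "text",
    picture_label: str = "picture",
) -> GazeMetrics:
    """Counts per AOI, mean picture-fixation duration, and direct switches.

    A transition is an *adjacent* pair in the raw fixation sequence whose
    AOI labels are {text, picture} in either order; an intervening fixation
    outside both AOIs breaks adjacency and counts no transition.
    """
    counts: dict[str, int] = {}
    for fix in fixations:
        if fix.aoi is not None:
            counts[fix.aoi] = counts.get(fix.aoi, 0) + 1
    pic_durs = [f.duration_ms for f in fixations if f.aoi == picture_label]
    mean_dur = float(np.mean(pic_durs)) if pic_durs else float("nan")
    pair = {text_label, picture_label}
    n_trans = sum(
        1
        for a, b in zip(fixations, fixations[1:])
        if a.aoi is not None and b.aoi is not None and {a.aoi, b.aoi} == pair
    )
    return GazeMetrics(counts, mean_dur, n_trans)
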