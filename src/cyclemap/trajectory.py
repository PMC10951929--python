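"""Single-cell trajectory analytics on the projected manifold.

With the projection orientation-normalised (mitosis at the UMAP1 minimum),
the UMAP1-versus-time curve of one cell reads like a landscape of the
cycle: the two lowest troughs are the mitoses bounding a full cycle, the
first peak after birth is G1, the following trough early S, and the highest
peak late S.  The UMAP2-versus-time curve oscillates with the cycle, so the
time between its two most prominent troughs estimates the cycle duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.signal import find_peaks

__all__ = ["TrajectoryCurve", "KeyEvents", "smooth_bspline",
           "running_average", "find_extrema", "assign_key_stages",
           "infer_lateS_time", "estimate_cycle_duration",
           "duration_from_troughs"]


@dataclass
class TrajectoryCurve:
    """A per-frame scalar series (UMAP1 or UMAP2) and its smoothed version."""

    raw: np.ndarray
    smoothed: np.ndarray
    method: str
    times_min: np.ndarray | None = None

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=np.float64)
        self.smoothed = np.asarray(self.smoothed, dtype=np.float64)
        if self.raw.shape != self.smoothed.shape:
            raise ValueError("smoothed series must match raw length")
        if not np.isfinite(self.smoothed).all():
            raise ValueError("non-finite smoothed values")


@dataclass
class KeyEvents:
    """Detected extrema with stage assignments on a UMAP1 curve."""

    peaks: np.ndarray
    troughs: np.ndarray
    assignments: dict[int, str] = field(default_factory=dict)
    inflections: np.ndarray = field(default_factory=lambda: np.array([], int))
    cycle_duration_minutes: float | None = None

    def frames_of(self, stage: str) -> list[int]:
        return [f for f, s in self.assignments.items() if s == stage]


def smooth_bspline(series: np.ndarray, smoothing_factor: float | None = None
                   ) -> TrajectoryCurve:
    """Cubic smoothing B-spline evaluated at the original frames.

    ``smoothing_factor`` is the allowed residual sum of squares; 0 gives an
    interpolating spline, ``None`` uses ``T * (0.15 * std)^2`` which tracks
    the curve while suppressing frame-to-frame jitter.  A constant series
    comes back unchanged.
    """
    series = np.asarray(series, dtype=np.float64)
    if len(series) < 8:
        raise ValueError("need at least 8 frames for B-spline smoothing")
    if smoothing_factor is None:
        smoothing_factor = len(series) * (0.15 * np.std(series)) ** 2
    x = np.arange(len(series), dtype=np.float64)
    spline = UnivariateSpline(x, series, k=3, s=smoothing_factor)
    return TrajectoryCurve(raw=series, smoothed=spline(x), method="bspline")


def running_average(series: np.ndarray, window: int = 10) -> TrajectoryCurve:
    """Centered moving mean with truncated windows at the boundaries."""
    series = np.asarray(series, dtype=np.float64)
    if window < 1 or window > len(series):
        raise ValueError("window must be in [1, len(series)]")
    half_lo = (window - 1) // 2
    half_hi = window // 2
    csum = np.concatenate([[0.0], np.cumsum(series)])
    idx = np.arange(len(series))
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi, len(series) - 1)
    out = (csum[hi + 1] - csum[lo]) / (hi + 1 - lo)
    return TrajectoryCurve(raw=series, smoothed=out, method="running_average")


def _as_curve(curve) -> TrajectoryCurve:
    if isinstance(curve, TrajectoryCurve):
        return curve
    series = np.asarray(curve, dtype=np.float64)
    return TrajectoryCurve(raw=series, smoothed=series, method="raw")


def find_extrema(curve, min_prominence: float | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Interior peaks and troughs of the smoothed curve.

    ``min_prominence`` defaults to a quarter of the smoothed curve's range,
    making detection invariant to offset and amplitude scaling.  Troughs are
    the peaks of the negated curve.
    """
    y = _as_curve(curve).smoothed
    if min_prominence is None:
        min_prominence = 0.25 * float(np.ptp(y)) if np.ptp(y) > 0 else 0.0
    peaks, _ = find_peaks(y, prominence=min_prominence or None)
    troughs, _ = find_peaks(-y, prominence=min_prominence or None)
    return peaks, troughs


def assign_key_stages(umap1_curve, min_prominence: float | None = None
                      ) -> KeyEvents:
    """Map extrema of an orientation-normalised UMAP1 curve to key stages.

    The two lowest troughs are the mitoses bounding a cycle; between them
    the first peak is G1, the highest peak late S, and the trough between
    those two peaks early S.  With fewer than two troughs no cycle can be
    delimited and a partial (possibly empty) assignment is returned.
    """
    curve = _as_curve(umap1_curve)
    y = curve.smoothed
    if min_prominence is None:
        # more inclusive than the generic extrema default: the cycle is
        # delimited by trough depth, and secondary peaks (G1) are genuinely
        # less prominent than the late-S maximum
        min_prominence = 0.1 * float(np.ptp(y)) if np.ptp(y) > 0 else 0.0
    peaks, troughs = find_extrema(curve, min_prominence)
    events = KeyEvents(peaks=peaks, troughs=troughs)
    if len(troughs) < 2:
        warnings.warn("fewer than two troughs: cannot delimit a cycle")
        return events
    lowest = troughs[np.argsort(y[troughs])[:2]]
    m1, m2 = int(lowest.min()), int(lowest.max())
    events.assignments[m1] = "M"
    events.assignments[m2] = "M"
    inner_peaks = peaks[(peaks > m1) & (peaks < m2)]
    if len(inner_peaks) == 0:
        return events
    late_s = int(inner_peaks[np.argmax(y[inner_peaks])])
    first = int(inner_peaks[0])
    if first != late_s:
        events.assignments[first] = "G1"
        inner_troughs = troughs[(troughs > first) & (troughs < late_s)]
        if len(inner_troughs):
            events.assignments[int(inner_troughs[0])] = "earlyS"
    events.assignments[late_s] = "lateS"
    # transitions: inflections of the smoothed curve between the boundary mitoses
    curv = np.diff(y, 2)
    infl = np.flatnonzero(np.sign(curv[:-1]) * np.sign(curv[1:]) < 0) + 1
    events.inflections = infl[(infl > m1) & (infl < m2)]
    return events


def infer_lateS_time(events: KeyEvents) -> int:
    """Frame of the late-S peak (feeds the G1-G2 constraint)."""
    frames = events.frames_of("lateS")
    if not frames:
        raise ValueError("no late-S peak assigned; constraint not applicable")
    return frames[0]


def duration_from_troughs(trough_a: int, trough_b: int,
                          frame_interval: float) -> float:
    """Hours between two trough frames at a given frame interval (minutes)."""
    return abs(trough_b - trough_a) * frame_interval / 60.0


def estimate_cycle_duration(curve, frame_interval: float = 5.9,
                            window: int = 10,
                            min_prominence: float | None = None,
                            select: str = "prominent") -> float | None:
    """Cycle duration in hours from a projected trajectory curve.

    The raw series is smoothed with a centered running average (10 frames by
    default) and the spacing of two troughs gives the period.  With
    ``select="prominent"`` (the oscillation reading, e.g. a UMAP2 curve
    whose sudden drops mark consecutive cycle starts) the two most prominent
    troughs are used, at a default prominence floor of a quarter of the
    smoothed range.  With ``select="deepest"`` (the landscape reading: the
    two lowest troughs of an orientation-normalised UMAP1 curve are the
    mitoses bounding a full cycle) the two lowest-valued troughs are used,
    at a floor of 5% of the range — near the trajectory boundary prominence
    is truncated and systematically under-measured, while depth is not.

    Returns ``None`` when fewer than two troughs are found.  Invariant to
    adding a constant to the series and to uniform amplitude scaling.
    """
    if select not in ("prominent", "deepest"):
        raise ValueError("select must be 'prominent' or 'deepest'")
    tcurve = _as_curve(curve)
    if tcurve.method == "raw":
        tcurve = running_average(tcurve.raw,
                                 window=min(window, len(tcurve.raw)))
    y = tcurve.smoothed
    if min_prominence is None:
        frac = 0.25 if select == "prominent" else 0.05
        min_prominence = frac * float(np.ptp(y)) if np.ptp(y) > 0 else 0.0
    troughs, props = find_peaks(-y, prominence=min_prominence or None)
    if len(troughs) < 2:
        return None
    if select == "prominent":
        two = troughs[np.sort(np.argsort(props["prominences"])[-2:])]
    else:
        two = troughs[np.sort(np.argsort(y[troughs])[:2])]
    return duration_from_troughs(int(two[0]), int(two[1]), frame_interval)
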