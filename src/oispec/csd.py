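"""Detection and quantification of the spreading-depression episode.

Electrode insertion triggers a cortical spreading depression: a travelling
wave whose haemodynamic signature is a constriction dip in fractional HbT,
a transient rebound, and a prolonged undershoot below baseline. This
module detects the episode in the ROI-mean series, measures its amplitude
extrema, the mean fractional HbT over a late reporting window (default
625-1250 s after insertion), the time of sustained recovery to baseline,
and — from the pixel-level field — the wavefront propagation speed via a
regression of per-pixel arrival times on distance from the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import HaemSeries

__all__ = ["CSDEvent", "detect_csd", "wavefront_speed"]

#: Late reporting window (s after insertion) for the undershoot mean.
LATE_WINDOW = (625.0, 1250.0)
#: Sustained-recovery band: fractional HbT within 1 ± band for ≥ dwell s.
RECOVERY_BAND = 0.02
RECOVERY_DWELL = 60.0


@dataclass
class CSDEvent:
    """Summary of one spreading-depression episode.

    ``undershoot_mean`` is the mean fractional HbT over ``late_window``;
    ``recovery_time`` (s after insertion) is the start of the first
    sustained return into the baseline band, or None if the series never
    recovers. ``speed_mm_per_min`` is filled in by
    :func:`wavefront_speed`. ``truncated`` flags a recording shorter than
    the late window.
    """

    t_onset: float
    dip_value: float
    dip_time: float
    rebound_value: float
    rebound_time: float
    undershoot_mean: float
    late_window: tuple[float, float]
    recovery_time: float | None
    truncated: bool
    t_insert: float
    speed_mm_per_min: float | None = None
    speed_r2: float | None = None
    speed_flag: str | None = None

    def __post_init__(self) -> None:
        if self.dip_value > 1.0:
            raise ValueError("dip_value must not exceed baseline (1.0)")
        if self.t_onset < self.t_insert:
            raise ValueError("onset cannot precede insertion")


def detect_csd(
    series: HaemSeries,
    t_insert: float = 0.0,
    dip_threshold: float = 0.05,
    min_sustain: float = 2.0,
    late_window: tuple[float, float] = LATE_WINDOW,
    recovery_band: float = RECOVERY_BAND,
    recovery_dwell: float = RECOVERY_DWELL,
) -> CSDEvent | None:
    """Find the first sustained constriction dip after electrode insertion.

    Onset is the first post-insertion time at which fractional HbT stays
    below ``1 − dip_threshold`` for at least ``min_sustain`` seconds;
    returns None when no such dip exists. The late window is expressed
    relative to ``t_insert``; if the recording ends inside it, what fits is
    used and the event is flagged truncated.
    """
    frac = series.to_fractional()
    if frac.hbt.ndim != 1:
        raise ValueError("detect_csd expects an ROI-level (1-D) series")
    t = frac.times
    hbt = frac.hbt
    dt = 1.0 / frac.frame_rate
    n_sustain = max(int(round(min_sustain * frac.frame_rate)), 1)

    post = t >= t_insert
    below = (hbt < 1.0 - dip_threshold) & post
    # first run of >= n_sustain consecutive below-threshold samples
    onset_idx = None
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= n_sustain:
            onset_idx = i - n_sustain + 1
            break
    if onset_idx is None:
        return None
    t_onset = float(t[onset_idx])

    # the constriction dip precedes the late undershoot window by definition
    lw0, lw1 = t_insert + late_window[0], t_insert + late_window[1]
    dip_search = np.nonzero((t >= t_onset) & (t < lw0))[0]
    if dip_search.size == 0:
        dip_search = np.arange(onset_idx, hbt.size)
    i_dip = dip_search[int(np.argmin(hbt[dip_search]))]
    dip_value = float(hbt[i_dip])
    dip_time = float(t[i_dip])

    # rebound: maximum between the dip and the start of the undershoot window
    reb_idx = (t > dip_time) & (t <= lw0)
    if reb_idx.any():
        j = np.nonzero(reb_idx)[0]
        i_reb = j[np.argmax(hbt[j])]
    else:
        i_reb = i_dip
    rebound_value = float(hbt[i_reb])
    rebound_time = float(t[i_reb])

    late_idx = (t >= lw0) & (t < lw1)
    truncated = t[-1] + dt < lw1
    if not late_idx.any():
        undershoot_mean = float("nan")
        truncated = True
    else:
        undershoot_mean = float(hbt[late_idx].mean())

    # sustained recovery: first time after the dip with |HbT - 1| <= band
    # continuously for recovery_dwell seconds
    n_dwell = max(int(round(recovery_dwell * frac.frame_rate)), 1)
    in_band = np.abs(hbt - 1.0) <= recovery_band
    recovery_time = None
    run = 0
    for i in range(i_dip, hbt.size):
        run = run + 1 if in_band[i] else 0
        if run >= n_dwell:
            start = i - n_dwell + 1
            # require the band to hold until the end of the recording too?
            # sustained = dwell satisfied; report the entry time
            recovery_time = float(t[start] - t_insert)
            break
    return CSDEvent(
        t_onset=t_onset,
        dip_value=dip_value,
        dip_time=dip_time,
        rebound_value=rebound_value,
        rebound_time=rebound_time,
        undershoot_mean=undershoot_mean,
        late_window=late_window,
        recovery_time=recovery_time,
        truncated=bool(truncated),
        t_insert=float(t_insert),
    )


def wavefront_speed(
    h: HaemSeries,
    event: CSDEvent,
    origin: tuple[int, int] | None = None,
    min_arrivals: int = 10,
    min_slope_s_per_mm: float = 1.0,
    min_sustain: float = 2.0,
) -> CSDEvent:
    """Estimate propagation speed from per-pixel half-dip arrival times.

    A pixel's arrival time is its first *sustained* crossing below half
    the dip amplitude (fractional HbT < 1 − (1 − dip_value)/2 held for
    ``min_sustain`` seconds, so single noisy frames do not fake an early
    arrival). Arrival time is regressed on Euclidean distance from the
    origin (least squares); speed is the inverse slope converted to
    mm/min and the fit quality is the regression R². Fewer than
    ``min_arrivals`` crossing pixels, or a slope shallower than
    ``min_slope_s_per_mm`` (synchronous field), leave the speed absent
    with an explanatory flag. With no origin given, the earliest-arrival
    pixel is used.
    """
    frac = h.to_fractional()
    if frac.hbt.ndim != 3:
        raise ValueError("wavefront_speed needs a pixel-level (T, H, W) series")
    if not h.pixel_pitch_um or h.pixel_pitch_um <= 0:
        raise ValueError("pixel pitch must be known to express speed in mm/min")
    t = frac.times
    thresh = 1.0 - (1.0 - event.dip_value) / 2.0
    below = frac.hbt < thresh  # (T, H, W)
    n_sustain = max(int(round(min_sustain * frac.frame_rate)), 1)
    if n_sustain > 1:
        # sustained = all of the next n_sustain frames below threshold
        windows = np.lib.stride_tricks.sliding_window_view(below, n_sustain, axis=0)
        sustained = windows.all(axis=-1)  # (T - n + 1, H, W)
    else:
        sustained = below
    ever = sustained.any(axis=0)
    n_arr = int(ever.sum())
    if n_arr < min_arrivals:
        event.speed_mm_per_min = None
        event.speed_r2 = None
        event.speed_flag = f"only {n_arr} pixels reach the half-dip criterion"
        return event
    first_idx = np.argmax(sustained, axis=0)  # first True along time
    arrival = t[first_idx]
    if origin is None:
        flat = np.where(ever, arrival, np.inf)
        origin = np.unravel_index(int(np.argmin(flat)), ever.shape)
    rr, cc = np.ogrid[: ever.shape[0], : ever.shape[1]]
    dist_mm = (
        np.sqrt((rr - origin[0]) ** 2 + (cc - origin[1]) ** 2) * h.pixel_pitch_um / 1000.0
    )
    x = dist_mm[ever]
    y = arrival[ever]
    if np.ptp(x) == 0:
        event.speed_mm_per_min = None
        event.speed_flag = "all arrivals at one distance; cannot fit"
        return event
    fit = stats.linregress(x, y)
    event.speed_r2 = float(fit.rvalue**2)
    if fit.slope < min_slope_s_per_mm:
        event.speed_mm_per_min = None
        event.speed_flag = "non-propagating (arrival times flat in distance)"
        return event
    event.speed_mm_per_min = float(60.0 / fit.slope)
    event.speed_flag = None
    return event
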