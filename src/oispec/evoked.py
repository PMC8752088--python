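"""Trial structuring and stimulus-evoked response metrics.

Each stimulation run contains repeated trials (30 for 2 s stimuli, 15 for
16 s stimuli in the study conditions). Trials are epoched around their
onsets, re-baselined to their own pre-stimulus mean, averaged, and
summarised by the quantities reported for evoked haemodynamics: peak
fractional change, time to peak, 10-90% rise time, and area under the
curve. The shape of the deoxyhaemoglobin washout is classified as
biphasic (plain washout) or triphasic (an early supra-noise positive
deflection before the washout). The hypercapnia challenge is summarised
by mean fractional change and AUC over the challenge window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import HaemSeries

__all__ = [
    "TrialSet",
    "EvokedTrace",
    "EvokedSummary",
    "trial_average",
    "summarise_evoked",
    "classify_hbr",
    "gas_challenge_response",
]


@dataclass(frozen=True)
class TrialSet:
    """Trial structure of a stimulation run.

    ``pre_window`` seconds before each onset define the per-trial
    baseline; ``post_window`` seconds after onset are kept in the epoch.
    """

    onsets: tuple
    stim_duration: float = 2.0
    pre_window: float = 4.0
    post_window: float = 20.0

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        if onsets.size == 0:
            raise ValueError("need at least one trial onset")
        if np.any(np.diff(onsets) < 0):
            raise ValueError("onsets must be sorted")
        # epoch of trial i spans [onset - pre, onset + post]; epochs may not overlap
        if onsets.size >= 2 and np.any(np.diff(onsets) < self.pre_window + self.post_window):
            raise ValueError("trials overlap within their epoch windows")

    @property
    def n_trials(self) -> int:
        return len(self.onsets)


@dataclass
class EvokedTrace:
    """Trial-averaged epoch, time measured from stimulus onset."""

    times: np.ndarray  # (n,), negative values = pre-stimulus
    hbt: np.ndarray
    hbo: np.ndarray
    hbr: np.ndarray
    sem_hbt: np.ndarray | None
    sem_hbo: np.ndarray | None
    sem_hbr: np.ndarray | None
    n_trials: int
    stim_duration: float
    trial_hbt: np.ndarray | None = None  # (n_trials, n) per-trial HbT epochs


@dataclass
class EvokedSummary:
    """Scalar metrics of one trial-averaged component trace."""

    peak: float
    time_to_peak: float | None
    rise_time: float | None
    auc: float

    def __post_init__(self) -> None:
        if self.time_to_peak is not None and self.time_to_peak < 0:
            raise ValueError("time_to_peak must be non-negative")


def trial_average(series: HaemSeries, trials: TrialSet) -> EvokedTrace:
    """Epoch, re-baseline and average trials; SEM across trials per time point.

    Each epoch is divided by its own pre-window mean so every trial starts
    at a fractional baseline of 1.0 before averaging. With a single trial
    the SEM is reported as absent.
    """
    frac = series.to_fractional()
    if frac.hbt.ndim != 1:
        raise ValueError("trial_average expects an ROI-level (1-D) series")
    dt = 1.0 / frac.frame_rate
    n_pre = int(round(trials.pre_window * frac.frame_rate))
    n_post = int(round(trials.post_window * frac.frame_rate))
    rel_times = (np.arange(n_pre + n_post) - n_pre) * dt

    comps = {"hbt": frac.hbt, "hbo": frac.hbo, "hbr": frac.hbr}
    epochs = {k: [] for k in comps}
    for i, onset in enumerate(trials.onsets):
        j0 = int(round(onset * frac.frame_rate)) - n_pre
        j1 = j0 + n_pre + n_post
        if j0 < 0 or j1 > frac.n_frames:
            raise ValueError(
                f"trial {i} (onset {onset:g} s) extends beyond the recording "
                f"[0, {frac.n_frames / frac.frame_rate:g} s]"
            )
        for k, arr in comps.items():
            ep = arr[j0:j1]
            base = ep[:n_pre].mean()
            epochs[k].append(ep / base)
    stacked = {k: np.array(v) for k, v in epochs.items()}
    n = trials.n_trials
    mean = {k: v.mean(axis=0) for k, v in stacked.items()}
    if n > 1:
        sem = {k: v.std(axis=0, ddof=1) / np.sqrt(n) for k, v in stacked.items()}
    else:
        sem = {k: None for k in stacked}
    return EvokedTrace(
        times=rel_times,
        hbt=mean["hbt"],
        hbo=mean["hbo"],
        hbr=mean["hbr"],
        sem_hbt=sem["hbt"],
        sem_hbo=sem["hbo"],
        sem_hbr=sem["hbr"],
        n_trials=n,
        stim_duration=trials.stim_duration,
        trial_hbt=stacked["hbt"],
    )


def summarise_evoked(
    times: np.ndarray,
    trace: np.ndarray,
    stim_duration: float,
    signed: bool = False,
    auc_post: float = 10.0,
) -> EvokedSummary:
    """Peak, time-to-peak, 10-90% rise time and AUC of one fractional trace.

    ``times`` are measured from stimulus onset (pre-stimulus samples are
    negative). For HbT/HbO the peak is the post-onset maximum deviation
    above baseline; with ``signed=True`` (HbR) it is the extremum of the
    largest magnitude, keeping its sign, so a washout reports a negative
    peak. AUC integrates the deviation from baseline over
    [0, stim_duration + auc_post] by the trapezoid rule. A flat trace
    reports peak 0 with absent timing metrics.
    """
    times = np.asarray(times, dtype=float)
    dev = np.asarray(trace, dtype=float) - 1.0
    post = times >= 0
    if not post.any():
        raise ValueError("trace contains no post-onset samples")
    t_post = times[post]
    d_post = dev[post]
    if signed:
        i_peak = int(np.argmax(np.abs(d_post)))
        peak = float(d_post[i_peak])
    else:
        i_peak = int(np.argmax(d_post))
        peak = float(d_post[i_peak])
    auc_idx = post & (times <= stim_duration + auc_post)
    auc = float(np.trapezoid(dev[auc_idx], times[auc_idx]))
    if peak == 0.0 or (not signed and peak <= 0.0):
        return EvokedSummary(peak=max(peak, 0.0) if not signed else peak,
                             time_to_peak=None, rise_time=None, auc=auc)
    time_to_peak = float(t_post[i_peak])
    # sub-sample refinement: vertex of the parabola through the extremum
    # and its neighbours removes the frame-grid quantisation of the peak time
    if 0 < i_peak < d_post.size - 1:
        y0, y1, y2 = d_post[i_peak - 1], d_post[i_peak], d_post[i_peak + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0.0:
            shift = 0.5 * (y0 - y2) / denom
            if abs(shift) <= 1.0:
                dt = t_post[i_peak + 1] - t_post[i_peak]
                time_to_peak = float(t_post[i_peak] + shift * dt)
    # 10% -> 90% of the peak deviation, on the rising limb before the peak
    mag = np.abs(d_post[: i_peak + 1])
    target_lo, target_hi = 0.1 * abs(peak), 0.9 * abs(peak)
    above_lo = np.nonzero(mag >= target_lo)[0]
    above_hi = np.nonzero(mag >= target_hi)[0]
    if above_lo.size and above_hi.size:
        rise_time = float(t_post[above_hi[0]] - t_post[above_lo[0]])
    else:
        rise_time = None
    return EvokedSummary(peak=peak, time_to_peak=time_to_peak, rise_time=rise_time, auc=auc)


def _has_run(mask: np.ndarray, min_run: int) -> bool:
    run = 0
    for m in mask:
        run = run + 1 if m else 0
        if run >= min_run:
            return True
    return False


def classify_hbr(
    times: np.ndarray,
    hbr_trace: np.ndarray,
    noise_floor: float | None = None,
    min_run: int = 3,
) -> str:
    """Label an HbR epoch ``'triphasic'``, ``'biphasic'`` or ``'flat'``.

    Triphasic: a supra-noise positive deflection *precedes* the main
    negative (washout) deflection, both exceeding the noise floor
    (default 2 × SD of the pre-onset samples). Biphasic: only the washout
    is supra-noise. Flat: neither. A *deflection* must hold the floor for
    ``min_run`` consecutive samples — isolated noise excursions beyond
    2 SD are expected by chance and do not count.
    """
    times = np.asarray(times, dtype=float)
    dev = np.asarray(hbr_trace, dtype=float) - 1.0
    pre = times < 0
    if noise_floor is None:
        if not pre.any():
            raise ValueError("need pre-onset samples (or an explicit noise_floor)")
        noise_floor = 2.0 * float(dev[pre].std())
    post = times >= 0
    d = dev[post]
    i_min = int(np.argmin(d))
    has_washout = d[i_min] < -noise_floor and _has_run(d < -noise_floor, min_run)
    if not has_washout:
        return "flat"
    has_early_bump = _has_run(d[: i_min] > noise_floor, min_run)
    return "triphasic" if has_early_bump else "biphasic"


def gas_challenge_response(
    series: HaemSeries,
    challenge_window: tuple[float, float],
    baseline_window: tuple[float, float],
) -> tuple[float, float]:
    """Vascular-reactivity summary for a CO2 challenge.

    Returns ``(mean fractional HbT change, trapezoid AUC)`` of the HbT
    deviation over the challenge window, relative to the pre-challenge
    baseline mean.
    """
    frac = series.to_fractional()
    if frac.hbt.ndim != 1:
        raise ValueError("gas_challenge_response expects an ROI-level series")
    base_idx = frac.window_index(baseline_window)
    chal_idx = frac.window_index(challenge_window)
    if not base_idx.any() or not chal_idx.any():
        raise ValueError("challenge or baseline window lies outside the recording")
    base = frac.hbt[base_idx].mean()
    dev = frac.hbt / base - 1.0
    mean_change = float(dev[chal_idx].mean())
    auc = float(np.trapezoid(dev[chal_idx], frac.times[chal_idx]))
    return mean_change, auc
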