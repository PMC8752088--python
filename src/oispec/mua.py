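"""Multi-unit activity extraction from multichannel extracellular voltage.

The recording is high-pass filtered above 500 Hz to strip field-potential
and drift components, split into 100 ms bins, and within each bin the
upward crossings of a per-channel threshold (baseline mean + 1.5 SD of the
filtered trace) are counted. Counts are reported as fractional changes
relative to the mean baseline bin count, the form in which evoked neural
responses are compared across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "ElectrodeRecording",
    "MUASeries",
    "highpass",
    "bin_threshold",
    "depth_select",
]

#: Default channel block assumed to span the cortical depth (16-ch probe).
CORTICAL_CHANNELS = slice(0, 12)
#: Default channel block exported as the depth-profile heat map.
HEATMAP_CHANNELS = slice(4, 9)


@dataclass
class ElectrodeRecording:
    """Multichannel voltage, shape ``(n_channels, n_samples)``."""

    traces: np.ndarray
    sampling_rate: float
    channel_spacing_um: float = 100.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if not self.sampling_rate > 1000.0:
            raise ValueError("sampling_rate must exceed 1 kHz for multi-unit work")

    @property
    def n_channels(self) -> int:
        return self.traces.shape[0]

    @property
    def duration(self) -> float:
        return self.traces.shape[1] / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.traces.shape[1]) / self.sampling_rate


@dataclass
class MUASeries:
    """Binned threshold-crossing counts per channel.

    ``counts`` has shape ``(n_channels, n_bins)``; ``fractional`` is
    ``counts`` divided by the per-channel mean baseline bin count.
    """

    counts: np.ndarray
    fractional: np.ndarray
    bin_width: float
    bin_starts: np.ndarray
    threshold_k: float
    hp_cutoff: float
    baseline_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.counts.shape[0]

    def pooled_fractional(self) -> np.ndarray:
        """Channel-mean fractional MUA per bin."""
        return self.fractional.mean(axis=0)


def highpass(rec: ElectrodeRecording, cutoff: float = 500.0, order: int = 4) -> ElectrodeRecording:
    """Zero-phase Butterworth high-pass; removes DC, drift and LFP-band power."""
    nyq = rec.sampling_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff {cutoff:g} Hz must lie below Nyquist ({nyq:g} Hz)")
    sos = signal.butter(order, cutoff, btype="highpass", fs=rec.sampling_rate, output="sos")
    # channel-by-channel keeps peak memory at one padded trace
    filtered = np.empty_like(rec.traces)
    for ch in range(rec.traces.shape[0]):
        filtered[ch] = signal.sosfiltfilt(sos, rec.traces[ch])
    return ElectrodeRecording(
        traces=filtered,
        sampling_rate=rec.sampling_rate,
        channel_spacing_um=rec.channel_spacing_um,
        meta={**rec.meta, "hp_cutoff": cutoff, "hp_order": order},
    )


def bin_threshold(
    filtered: ElectrodeRecording,
    baseline_window: tuple[float, float],
    bin_width: float = 0.1,
    k: float = 1.5,
    rectify: bool = False,
) -> MUASeries:
    """Count supra-threshold events per 100 ms bin, per channel.

    The threshold is ``baseline mean + k × baseline SD`` of the filtered
    trace, computed per channel over ``baseline_window``. A *crossing* is a
    sign change from below to above threshold, so one spike contributes one
    event regardless of its width. ``rectify=True`` additionally counts
    downward crossings of the mirrored threshold (negative-going spikes).
    Fractional output divides each bin count by the channel's mean
    baseline bin count.
    """
    t = filtered.times
    base_idx = (t >= baseline_window[0]) & (t < baseline_window[1])
    n_base_bins = (baseline_window[1] - baseline_window[0]) / bin_width
    if n_base_bins < 10:
        raise ValueError(
            f"baseline window must cover at least 10 bins, got {n_base_bins:.1f}"
        )
    x = filtered.traces
    mu = x[:, base_idx].mean(axis=1, keepdims=True)
    sd = x[:, base_idx].std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero baseline SD on at least one channel (degenerate trace)")
    thr = mu + k * sd

    above = x > thr
    crossings = (~above[:, :-1]) & above[:, 1:]  # upward crossings at sample i+1
    if rectify:
        below = x < (mu - k * sd)
        crossings |= (~below[:, :-1]) & below[:, 1:]
    cross_idx = np.zeros_like(x, dtype=bool)
    cross_idx[:, 1:] = crossings

    samples_per_bin = int(round(bin_width * filtered.sampling_rate))
    n_bins = x.shape[1] // samples_per_bin
    counts = (
        cross_idx[:, : n_bins * samples_per_bin]
        .reshape(filtered.n_channels, n_bins, samples_per_bin)
        .sum(axis=2)
    )
    bin_starts = np.arange(n_bins) * bin_width
    base_bins = (bin_starts >= baseline_window[0]) & (bin_starts + bin_width <= baseline_window[1])
    base_mean = counts[:, base_bins].mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        fractional = np.where(base_mean > 0, counts / base_mean, np.nan)
    return MUASeries(
        counts=counts,
        fractional=fractional,
        bin_width=bin_width,
        bin_starts=bin_starts,
        threshold_k=k,
        hp_cutoff=float(filtered.meta.get("hp_cutoff", np.nan)),
        baseline_window=baseline_window,
    )


def depth_select(mua: MUASeries, channels: slice | np.ndarray = CORTICAL_CHANNELS) -> MUASeries:
    """Restrict to a channel block (e.g. the 12 cortical channels), order kept.

    The returned ``fractional`` values are unchanged for the selected
    channels: per-channel normalisation commutes with selection.
    """
    idx = np.arange(mua.n_channels)[channels] if isinstance(channels, slice) else np.asarray(channels)
    if idx.size == 0 or idx.min() < 0 or idx.max() >= mua.n_channels:
        raise ValueError(
            f"channel selection {idx.tolist() if idx.size < 20 else channels} out of "
            f"range for {mua.n_channels} channels"
        )
    return MUASeries(
        counts=mua.counts[idx],
        fractional=mua.fractional[idx],
        bin_width=mua.bin_width,
        bin_starts=mua.bin_starts,
        threshold_k=mua.threshold_k,
        hp_cutoff=mua.hp_cutoff,
        baseline_window=mua.baseline_window,
    )
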